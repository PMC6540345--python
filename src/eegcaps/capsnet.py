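"""Capsule-network classifier for 18x18 multiband feature matrices.

Architecture (model A defaults): a no-padding 3x3 convolution with ReLU
(18x18 -> 16x16 x 256 channels), a primary-capsule convolution (3x3,
stride 2 -> 7x7 x 256) whose output is read as 49 capsules of 256
dimensions and squashed, a per-pair linear map into 2 emotion capsules of
32 dimensions coupled by dynamic routing (3 iterations), and a 512-1024-324
fully connected decoder that reconstructs the flattened input from the
(masked) emotion capsules. Classification reads the emotion-capsule norms;
the loss is the two-sided margin loss plus a small weighted
sum-of-squared-errors reconstruction term.

Everything is NumPy. Forward and backward passes are written by hand and
the backward pass is exact — gradients flow through every routing
iteration, including the softmax of the routing logits — which lets the
whole graph be validated against central finite differences. Optimization
is Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapsNetConfig:
    """Hyperparameters; defaults are the best-performing variant (model A)."""

    input_side: int = 18
    conv_kernel: int = 3
    conv_filters: int = 256
    conv_stride: int = 1
    primary_kernel: int = 3
    primary_stride: int = 2
    primary_types: int = 1            # capsule groups in the primary layer
    primary_capsule_dim: int = 256    # dimension of each primary capsule
    emotion_capsule_dim: int = 32
    n_classes: int = 2
    routing_iterations: int = 3
    decoder_units: tuple[int, ...] = (512, 1024, 324)
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    reconstruction_weight: float = 0.0005   # per element, SSE summed
    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        if min(self.conv_filters, self.primary_types, self.primary_capsule_dim,
               self.emotion_capsule_dim, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")
        if self.m_minus >= self.m_plus:
            raise ValueError("m_minus must be below m_plus")
        if self.routing_iterations < 1:
            raise ValueError("routing needs at least one iteration")
        if self.decoder_units[-1] != self.input_side ** 2:
            raise ValueError("decoder output must match the flattened input size")
        if self.conv_side < 1 or self.primary_side < 1:
            raise ValueError("convolution kernels do not fit the input")

    # valid (no-padding) convolution output side: floor((n - k) / stride) + 1
    @property
    def conv_side(self) -> int:
        return (self.input_side - self.conv_kernel) // self.conv_stride + 1

    @property
    def primary_side(self) -> int:
        return (self.conv_side - self.primary_kernel) // self.primary_stride + 1

    @property
    def primary_channels(self) -> int:
        return self.primary_types * self.primary_capsule_dim

    @property
    def n_primary(self) -> int:
        return self.primary_side ** 2 * self.primary_types


#: Hyperparameter variants: the coarse capacity sweep ("1"-"5") and the fine
#: structure sweep ("A"-"F"); model A is the adopted configuration.
MODEL_PRESETS: dict[str, dict] = {
    "1": dict(conv_filters=32, primary_capsule_dim=32, emotion_capsule_dim=16),
    "2": dict(conv_filters=128, primary_capsule_dim=128, emotion_capsule_dim=16),
    "3": dict(conv_filters=256, primary_capsule_dim=256, emotion_capsule_dim=16),
    "4": dict(conv_filters=384, primary_capsule_dim=384, emotion_capsule_dim=16),
    "5": dict(conv_filters=512, primary_capsule_dim=512, emotion_capsule_dim=16),
    "A": dict(conv_kernel=3, conv_filters=256, primary_capsule_dim=256,
              emotion_capsule_dim=32),
    "B": dict(conv_kernel=5, conv_filters=256, primary_capsule_dim=256,
              emotion_capsule_dim=16),
    "C": dict(conv_kernel=9, conv_filters=256, primary_types=32,
              primary_capsule_dim=8, emotion_capsule_dim=32),
    "D": dict(conv_kernel=3, conv_filters=128, primary_capsule_dim=128,
              emotion_capsule_dim=32),
    "E": dict(conv_kernel=5, conv_filters=128, primary_capsule_dim=128,
              emotion_capsule_dim=16),
    "F": dict(conv_kernel=9, conv_filters=128, primary_types=16,
              primary_capsule_dim=8, emotion_capsule_dim=32),
}


def preset_config(name: str, **overrides) -> CapsNetConfig:
    """Config for a named model variant, with optional field overrides."""
    if name not in MODEL_PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(MODEL_PRESETS)}")
    cfg = replace(CapsNetConfig(), **{**MODEL_PRESETS[name], **overrides})
    cfg.validate()
    return cfg


def config_from_yaml(path: str | Path) -> CapsNetConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    preset = raw.pop("preset", None)
    if "decoder_units" in raw:
        raw["decoder_units"] = tuple(raw["decoder_units"])
    cfg = preset_config(preset, **raw) if preset else replace(CapsNetConfig(), **raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Norm-preserving-direction nonlinearity: ||out|| = ||s||^2 / (1 + ||s||^2).

    Short vectors shrink toward 0, long vectors saturate just below 1; the
    zero vector maps to itself.
    """
    if not np.isfinite(s).all():
        raise ValueError("squash input must be finite")
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(n2 + EPS)
    return s * (n / (1.0 + n2))


def _squash_backward(s: np.ndarray, dv: np.ndarray, axis: int = -1) -> np.ndarray:
    # v = q(n) * s with q = n / (1 + n^2);  ds = q dv + q'(n)/n (s . dv) s
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(n2 + EPS)
    q = n / (1.0 + n2)
    dq_dn = (1.0 - n2) / (1.0 + n2) ** 2
    s_dot_dv = np.sum(s * dv, axis=axis, keepdims=True)
    return q * dv + (dq_dn / n) * s_dot_dv * s


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def dynamic_routing(
    u_hat: np.ndarray, iterations: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Routing-by-agreement over predictions ``u_hat`` [..., n_lower, n_higher, dim].

    Logits start at zero; per iteration the couplings are the softmax of the
    logits over the higher index, the higher-capsule input is the
    coupling-weighted sum of predictions, its squash is the output, and each
    logit grows by the prediction-output dot product. Returns the final
    couplings (summing to 1 over the higher index) and outputs.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    c, v, _ = _routing_forward(u_hat, iterations)
    return c[-1], v[-1]


def _routing_forward(u_hat: np.ndarray, iterations: int):
    """All per-iteration couplings, outputs and pre-squash sums (for backprop)."""
    b = np.zeros(u_hat.shape[:-1], dtype=u_hat.dtype)
    cs, vs, ss = [], [], []
    for r in range(iterations):
        c = _softmax(b, axis=-1)
        s = np.einsum("...ij,...ije->...je", c, u_hat, optimize=True)
        v = squash(s)
        cs.append(c)
        ss.append(s)
        vs.append(v)
        if r < iterations - 1:
            b = b + np.einsum("...ije,...je->...ij", u_hat, v, optimize=True)
    return cs, vs, ss


def _routing_backward(u_hat, cs, vs, ss, dv_last):
    """Exact reverse pass through every routing iteration."""
    R = len(cs)
    du_hat = np.zeros_like(u_hat)
    dv = dv_last
    db = None
    for r in range(R - 1, -1, -1):
        if db is not None:
            # b_{r+1} = b_r + u_hat . v_r  contributed after iteration r
            du_hat += db[..., None] * vs[r][..., None, :, :]
            dv = dv + np.einsum("...ij,...ije->...je", db, u_hat, optimize=True)
        ds = _squash_backward(ss[r], dv)
        dc = np.einsum("...ije,...je->...ij", u_hat, ds, optimize=True)
        du_hat += cs[r][..., None] * ds[..., None, :, :]
        # softmax backward over the higher index, plus the identity path
        # b_{r+1} = b_r + (u_hat . v_r) carrying the incoming logit gradient
        db_r = cs[r] * (dc - np.sum(cs[r] * dc, axis=-1, keepdims=True))
        if db is not None:
            db_r = db_r + db
        db = db_r if r > 0 else None
        dv = np.zeros_like(dv)
    return du_hat


# -- valid convolution via im2col --------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int):
    # x: [B, H, W, C] -> cols [B, Ho*Wo, k*k*C] in (ki, kj, C) order
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, (k, k), axis=(1, 2))       # [B,Ho',Wo',C,k,k]
    win = win[:, ::stride, ::stride]
    B, Ho, Wo = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho * Wo, -1)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    B, H, W, C = x_shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    dwin = dcols.reshape(B, Ho, Wo, k, k, C)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += (
                dwin[:, :, :, i, j, :]
            )
    return dx


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def init_params(cfg: CapsNetConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seed-controlled initialization.

    Convolutions and decoder use fan-in-scaled normals; the per-pair capsule
    transformation matrices use a truncated normal with sd 0.05.
    """
    cfg.validate()

    def trunc_normal(shape, sd):
        w = rng.standard_normal(shape)
        np.clip(w, -2.0, 2.0, out=w)
        return sd * w

    k1, f1 = cfg.conv_kernel, cfg.conv_filters
    k2, c2 = cfg.primary_kernel, cfg.primary_channels
    d_in = cfg.n_classes * cfg.emotion_capsule_dim
    u1, u2, u3 = cfg.decoder_units
    p = {
        "W1": rng.standard_normal((k1, k1, 1, f1)) * np.sqrt(2.0 / (k1 * k1)),
        "b1": np.zeros(f1),
        "W2": rng.standard_normal((k2, k2, f1, c2)) * np.sqrt(2.0 / (k2 * k2 * f1)),
        "b2": np.zeros(c2),
        "Wij": trunc_normal(
            (cfg.n_primary, cfg.n_classes, cfg.primary_capsule_dim, cfg.emotion_capsule_dim),
            0.05,
        ),
        "W3": rng.standard_normal((d_in, u1)) * np.sqrt(2.0 / d_in),
        "b3": np.zeros(u1),
        "W4": rng.standard_normal((u1, u2)) * np.sqrt(2.0 / u1),
        "b4": np.zeros(u2),
        "W5": rng.standard_normal((u2, u3)) * np.sqrt(1.0 / u2),
        "b5": np.zeros(u3),
    }
    return p


def forward(
    params: dict[str, np.ndarray],
    cfg: CapsNetConfig,
    x: np.ndarray,
    targets: np.ndarray | None = None,
) -> dict:
    """Full forward pass on a batch of MFMs ``x`` [B, side, side].

    Returns a cache holding, among intermediates, the emotion-capsule norms
    (``norms`` [B, n_classes]) and the decoder reconstruction (``recon``
    [B, side*side]). When ``targets`` is given the decoder sees only the
    target class's capsule (training mask); otherwise the predicted one.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    B, h, w = x.shape
    if (h, w) != (cfg.input_side, cfg.input_side):
        raise ValueError(f"expected {cfg.input_side}x{cfg.input_side} inputs, got {h}x{w}")

    # conv + ReLU
    cols1, H1, W1 = _im2col(x[..., None], cfg.conv_kernel, cfg.conv_stride)
    W1m = params["W1"].reshape(-1, cfg.conv_filters)
    z1 = cols1 @ W1m + params["b1"]
    h1 = np.maximum(z1, 0.0).reshape(B, H1, W1, cfg.conv_filters)

    # primary capsules: conv, group into capsules, squash
    cols2, H2, W2 = _im2col(h1, cfg.primary_kernel, cfg.primary_stride)
    W2m = params["W2"].reshape(-1, cfg.primary_channels)
    z2 = cols2 @ W2m + params["b2"]
    u_raw = z2.reshape(B, cfg.n_primary, cfg.primary_capsule_dim)
    u = squash(u_raw)

    # prediction vectors and routing to emotion capsules
    u_hat = np.einsum("ijpe,bip->bije", params["Wij"], u, optimize=True)
    cs, vs, ss = _routing_forward(u_hat, cfg.routing_iterations)
    v = vs[-1]                                   # [B, n_classes, dim]
    norms = np.sqrt(np.sum(v * v, axis=-1) + EPS)

    # decoder on the masked capsule
    if targets is not None:
        mask = np.eye(cfg.n_classes)[np.asarray(targets, dtype=int)]
    else:
        mask = np.eye(cfg.n_classes)[np.argmax(norms, axis=1)]
    d_in = (v * mask[..., None]).reshape(B, -1)
    z3 = d_in @ params["W3"] + params["b3"]
    a3 = np.maximum(z3, 0.0)
    z4 = a3 @ params["W4"] + params["b4"]
    a4 = np.maximum(z4, 0.0)
    z5 = a4 @ params["W5"] + params["b5"]
    recon = 1.0 / (1.0 + np.exp(-z5))

    return dict(
        x=x, cols1=cols1, z1=z1, h1=h1, cols2=cols2, z2=z2, u_raw=u_raw, u=u,
        u_hat=u_hat, cs=cs, vs=vs, ss=ss, v=v, norms=norms, mask=mask,
        d_in=d_in, a3=a3, a4=a4, recon=recon,
    )


def margin_loss(
    norms: np.ndarray, targets: np.ndarray, cfg: CapsNetConfig
) -> float:
    """Two-sided margin loss, summed over classes, averaged over the batch.

    The present class is pushed above ``m_plus``, absent classes below
    ``m_minus`` with down-weighting ``lambda_down``.
    """
    targets = np.asarray(targets, dtype=int)
    if targets.min() < 0 or targets.max() >= cfg.n_classes:
        raise ValueError("target outside the class set")
    T = np.eye(cfg.n_classes)[targets]
    pos = np.maximum(0.0, cfg.m_plus - norms) ** 2
    neg = np.maximum(0.0, norms - cfg.m_minus) ** 2
    per_class = T * pos + cfg.lambda_down * (1.0 - T) * neg
    return float(per_class.sum(axis=1).mean())


def reconstruction_loss(recon: np.ndarray, x: np.ndarray) -> float:
    """Sum of squared differences to the flattened input, batch-averaged."""
    diff = recon - x.reshape(x.shape[0], -1)
    return float((diff * diff).sum(axis=1).mean())


def total_loss(margin: float, recon: float, cfg: CapsNetConfig) -> float:
    return margin + cfg.reconstruction_weight * recon


def loss_and_grads(
    params: dict[str, np.ndarray],
    cfg: CapsNetConfig,
    x: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, dict[str, np.ndarray], dict]:
    """Total loss and exact parameter gradients for one batch."""
    cache = forward(params, cfg, x, targets)
    x = cache["x"]
    B = x.shape[0]
    targets = np.asarray(targets, dtype=int)
    T = np.eye(cfg.n_classes)[targets]
    norms, v = cache["norms"], cache["v"]

    m_loss = margin_loss(norms, targets, cfg)
    r_loss = reconstruction_loss(cache["recon"], x)
    loss = total_loss(m_loss, r_loss, cfg)

    # -- margin loss -> emotion capsules
    dnorm = (
        -2.0 * T * np.maximum(0.0, cfg.m_plus - norms)
        + 2.0 * cfg.lambda_down * (1.0 - T) * np.maximum(0.0, norms - cfg.m_minus)
    ) / B
    dv = dnorm[..., None] * (v / norms[..., None])

    # -- reconstruction -> decoder -> masked capsules
    x_flat = x.reshape(B, -1)
    drecon = cfg.reconstruction_weight * 2.0 * (cache["recon"] - x_flat) / B
    dz5 = drecon * cache["recon"] * (1.0 - cache["recon"])
    gW5 = cache["a4"].T @ dz5
    gb5 = dz5.sum(0)
    da4 = dz5 @ params["W5"].T
    dz4 = da4 * (cache["a4"] > 0)
    gW4 = cache["a3"].T @ dz4
    gb4 = dz4.sum(0)
    da3 = dz4 @ params["W4"].T
    dz3 = da3 * (cache["a3"] > 0)
    gW3 = cache["d_in"].T @ dz3
    gb3 = dz3.sum(0)
    dd_in = dz3 @ params["W3"].T
    dv = dv + dd_in.reshape(v.shape) * cache["mask"][..., None]

    # -- routing (exact, through every iteration)
    du_hat = _routing_backward(cache["u_hat"], cache["cs"], cache["vs"], cache["ss"], dv)

    # -- prediction vectors
    gWij = np.einsum("bip,bije->ijpe", cache["u"], du_hat, optimize=True)
    du = np.einsum("ijpe,bije->bip", params["Wij"], du_hat, optimize=True)

    # -- primary squash and conv
    du_raw = _squash_backward(cache["u_raw"], du)
    dz2 = du_raw.reshape(B, -1, cfg.primary_channels)
    W2m = params["W2"].reshape(-1, cfg.primary_channels)
    gW2 = np.einsum("bpk,bpc->kc", cache["cols2"], dz2, optimize=True)
    gb2 = dz2.sum((0, 1))
    dcols2 = dz2 @ W2m.T
    dh1 = _col2im(dcols2, cache["h1"].shape, cfg.primary_kernel, cfg.primary_stride)

    # -- first conv
    dz1 = dh1.reshape(B, -1, cfg.conv_filters) * (cache["z1"] > 0)
    W1m_shape = params["W1"].shape
    gW1 = np.einsum("bpk,bpc->kc", cache["cols1"], dz1, optimize=True)
    gb1 = dz1.sum((0, 1))

    grads = {
        "W1": gW1.reshape(W1m_shape), "b1": gb1,
        "W2": gW2.reshape(params["W2"].shape), "b2": gb2,
        "Wij": gWij,
        "W3": gW3, "b3": gb3, "W4": gW4, "b4": gb4, "W5": gW5, "b5": gb5,
    }
    return loss, grads, dict(margin=m_loss, reconstruction=r_loss, cache=cache)


# ---------------------------------------------------------------------------
# optimizer and the trainable model wrapper
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class CapsNetModel:
    """A configured capsule network with training, prediction and persistence."""

    def __init__(self, cfg: CapsNetConfig | None = None, preset: str | None = None):
        if cfg is None:
            cfg = preset_config(preset) if preset else CapsNetConfig()
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.params = init_params(cfg, self.rng)
        self.optimizer = Adam(self.params, lr=cfg.learning_rate)
        self.history: list[dict] = []

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int | None = None,
        batch_size: int | None = None,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        verbose: bool = False,
    ) -> "CapsNetModel":
        """Mini-batch Adam training on MFMs ``x`` [n, side, side], labels ``y``."""
        epochs = self.cfg.epochs if epochs is None else epochs
        batch = self.cfg.batch_size if batch_size is None else batch_size
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        n = x.shape[0]
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            m_sum = r_sum = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                loss, grads, parts = loss_and_grads(self.params, self.cfg, x[idx], y[idx])
                self.optimizer.step(self.params, grads)
                m_sum += parts["margin"] * len(idx)
                r_sum += parts["reconstruction"] * len(idx)
            rec = dict(epoch=epoch, margin=m_sum / n, reconstruction=r_sum / n)
            if x_val is not None:
                rec["val_accuracy"] = self.evaluate(x_val, y_val)["accuracy"]
            self.history.append(rec)
            if verbose:
                msg = ", ".join(f"{k}={v:.4f}" for k, v in rec.items() if k != "epoch")
                print(f"epoch {epoch + 1}/{epochs}: {msg}")
        return self

    def predict_scores(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Emotion-capsule norms [n, n_classes] (class presence scores)."""
        x = np.asarray(x, dtype=np.float64)
        out = []
        for start in range(0, x.shape[0], batch):
            out.append(forward(self.params, self.cfg, x[start : start + batch])["norms"])
        return np.concatenate(out) if out else np.zeros((0, self.cfg.n_classes))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_scores(x), axis=1)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> dict:
        """Accuracy and 2x2 confusion counts (tn/fp/fn/tp for binary)."""
        y = np.asarray(y, dtype=int)
        pred = self.predict(x)
        acc = float((pred == y).mean()) if len(y) else float("nan")
        k = self.cfg.n_classes
        conf = np.zeros((k, k), dtype=int)
        np.add.at(conf, (y, pred), 1)
        return dict(accuracy=acc, confusion=conf)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        cfg_dict = asdict(self.cfg)
        cfg_dict["decoder_units"] = list(cfg_dict["decoder_units"])
        np.savez(
            path,
            __config__=np.frombuffer(yaml.safe_dump(cfg_dict).encode(), dtype=np.uint8),
            **self.params,
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "CapsNetModel":
        with np.load(path) as data:
            raw = yaml.safe_load(bytes(data["__config__"]).decode())
            raw["decoder_units"] = tuple(raw["decoder_units"])
            model = cls(CapsNetConfig(**raw))
            for k in model.params:
                model.params[k] = data[k]
        return model
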