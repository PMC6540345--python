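"""Capsule-network unit results: squash, routing, losses, shapes, gradients."""

import numpy as np
import pytest

from eegcaps import (
    CapsNetConfig,
    CapsNetModel,
    dynamic_routing,
    forward,
    init_params,
    loss_and_grads,
    margin_loss,
    preset_config,
    reconstruction_loss,
    squash,
    total_loss,
)

TINY = CapsNetConfig(
    input_side=8, conv_filters=4, primary_capsule_dim=4, emotion_capsule_dim=3,
    decoder_units=(8, 10, 64), routing_iterations=3, reconstruction_weight=0.01,
    seed=1,
)


# -- squash ------------------------------------------------------------

def test_squash_zero_vector():
    assert np.allclose(squash(np.zeros(5)), 0.0)


def test_squash_unit_vector_has_half_norm():
    v = squash(np.array([0.0, 1.0, 0.0]))
    assert np.linalg.norm(v) == pytest.approx(0.5, abs=1e-9)


def test_squash_saturates_against_scalar_oracle():
    # closed form: ||out|| = n^2 / (1 + n^2)
    for n in (0.1, 1.0, 3.0, 1000.0):
        v = squash(np.array([n, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(n**2 / (1 + n**2), rel=1e-6)
    assert abs(np.linalg.norm(squash(np.array([1000.0, 0.0]))) - 1.0) < 1e-3


def test_squash_preserves_direction_and_monotone():
    s = np.array([3.0, -4.0])
    v = squash(s)
    assert np.allclose(v / np.linalg.norm(v), s / np.linalg.norm(s))
    norms = [np.linalg.norm(squash(np.array([x, 0.0]))) for x in np.linspace(0.1, 10, 50)]
    assert (np.diff(norms) > 0).all()
    assert all(n < 1 for n in norms)


def test_squash_rejects_non_finite():
    with pytest.raises(ValueError):
        squash(np.array([np.inf, 0.0]))


# -- routing -----------------------------------------------------------

def test_routing_singleton_higher_capsule():
    uh = np.random.default_rng(0).standard_normal((3, 5, 1, 4))
    c, _ = dynamic_routing(uh, 3)
    assert np.allclose(c, 1.0)  # softmax over a single class


def test_routing_first_iteration_uniform():
    uh = np.random.default_rng(1).standard_normal((2, 6, 3, 4))
    c, _ = dynamic_routing(uh, 1)
    assert np.allclose(c, 1.0 / 3.0)  # softmax of zero logits


def test_coupling_sums_to_one_every_iteration():
    uh = np.random.default_rng(2).standard_normal((4, 7, 2, 5))
    for iters in (1, 2, 3, 5):
        c, v = dynamic_routing(uh, iters)
        assert np.allclose(c.sum(axis=-1), 1.0, atol=1e-12)
        assert (np.linalg.norm(v, axis=-1) < 1.0).all()


def test_routing_matches_hand_unrolled_trace():
    """3 iterations on 2-D toy capsules against an explicit scalar trace."""
    uh = np.array([  # [n_lower=2, n_higher=2, dim=2]
        [[1.0, 0.0], [-1.0, 0.0]],
        [[0.9, 0.1], [0.0, -1.0]],
    ])

    # independent hand-unrolled trace with explicit loops
    b = np.zeros((2, 2))
    for r in range(3):
        c = np.empty_like(b)
        for i in range(2):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        s = np.zeros((2, 2))
        for j in range(2):
            for i in range(2):
                s[j] += c[i, j] * uh[i, j]
        v = np.zeros((2, 2))
        for j in range(2):
            n = np.linalg.norm(s[j])
            if n > 0:
                v[j] = (n**2 / (1 + n**2)) * s[j] / n
        if r < 2:
            for i in range(2):
                for j in range(2):
                    b[i, j] += uh[i, j] @ v[j]

    c_pkg, v_pkg = dynamic_routing(uh[None], 3)
    assert np.allclose(c_pkg[0], c, atol=1e-9)
    assert np.allclose(v_pkg[0], v, atol=1e-9)


def test_agreeing_capsules_win_coupling():
    """Two lower capsules agreeing with class A strictly gain coupling."""
    uh = np.zeros((1, 2, 2, 2))
    uh[0, :, 0, :] = [1.0, 0.0]       # both predict A strongly
    uh[0, 0, 1, :] = [-1.0, 0.0]      # and disagree about B
    uh[0, 1, 1, :] = [0.0, -1.0]
    prev = 0.5
    for iters in (1, 2, 3, 4):
        c, _ = dynamic_routing(uh, iters)
        cA = c[0, :, 0].mean()
        if iters > 1:
            assert cA > prev
        prev = cA


# -- losses ------------------------------------------------------------

def test_margin_loss_hinge_points():
    cfg = CapsNetConfig()
    # present class exactly at m+ and absent exactly at m-: zero loss
    norms = np.array([[0.9, 0.1]])
    assert margin_loss(norms, np.array([0]), cfg) == pytest.approx(0.0, abs=1e-12)


def test_margin_loss_zero_vector_is_m_plus_squared():
    cfg = CapsNetConfig()
    norms = np.array([[0.0, 0.0]])
    # present-class term (0.9)^2 = 0.81; absent class at 0 contributes 0
    assert margin_loss(norms, np.array([0]), cfg) == pytest.approx(0.81, abs=1e-12)


def test_margin_loss_rejects_bad_target():
    with pytest.raises(ValueError):
        margin_loss(np.array([[0.5, 0.5]]), np.array([2]), CapsNetConfig())


def test_total_loss_arithmetic():
    cfg = CapsNetConfig(reconstruction_weight=0.0005)
    assert total_loss(0.2, 100.0, cfg) == pytest.approx(0.25)
    assert total_loss(0.2, 100.0, CapsNetConfig(reconstruction_weight=0.0)) == 0.2
    assert reconstruction_loss(np.ones((2, 4)), np.ones((2, 2, 2))) == 0.0


# -- architecture shapes ----------------------------------------------

def test_model_a_shape_contract():
    cfg = preset_config("A")
    assert cfg.conv_side == 16          # floor((18 - 3) / 1) + 1
    assert cfg.primary_side == 7        # floor((16 - 3) / 2) + 1
    assert cfg.n_primary == 49
    assert cfg.primary_capsule_dim == 256
    assert cfg.emotion_capsule_dim == 32
    assert cfg.decoder_units[-1] == 324

    model = CapsNetModel(cfg)
    out = forward(model.params, cfg, np.random.default_rng(0).uniform(0, 1, (2, 18, 18)))
    assert out["h1"].shape == (2, 16, 16, 256)
    assert out["u"].shape == (2, 49, 256)
    assert out["v"].shape == (2, 2, 32)
    assert out["recon"].shape == (2, 324)


@pytest.mark.parametrize(
    "preset, conv_side, n_primary, cap_dim",
    [("B", 14, 36, 256), ("C", 10, 512, 8), ("D", 16, 49, 128), ("F", 10, 256, 8)],
)
def test_preset_shape_arithmetic(preset, conv_side, n_primary, cap_dim):
    cfg = preset_config(preset)
    assert cfg.conv_side == conv_side
    assert cfg.n_primary == n_primary
    assert cfg.primary_capsule_dim == cap_dim


def test_config_validation():
    with pytest.raises(ValueError):
        CapsNetConfig(m_plus=0.1, m_minus=0.9).validate()
    with pytest.raises(ValueError):
        CapsNetConfig(routing_iterations=0).validate()
    with pytest.raises(ValueError):
        CapsNetConfig(decoder_units=(512, 1024, 100)).validate()


def test_forward_rejects_wrong_input_side():
    model = CapsNetModel(TINY)
    with pytest.raises(ValueError, match="8x8"):
        forward(model.params, TINY, np.zeros((1, 18, 18)))


# -- gradients ---------------------------------------------------------

def test_gradients_match_finite_differences():
    """Autodiff vs central differences on a 4-sample batch: rel err < 1e-4."""
    rng = np.random.default_rng(2)
    params = init_params(TINY, rng)
    x = rng.uniform(0, 1, (4, 8, 8))
    y = np.array([0, 1, 1, 0])
    _, grads, _ = loss_and_grads(params, TINY, x, y)

    eps = 1e-6
    an_all, fd_all = [], []
    for name in params:
        flat = params[name].ravel()
        g = grads[name].ravel()
        for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_and_grads(params, TINY, x, y)[0]
            flat[i] = orig - eps
            lm = loss_and_grads(params, TINY, x, y)[0]
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an_all.append(g[i])
            fd_all.append(fd)
            # per-coordinate, with a floor excluding coordinates whose
            # gradient is below the finite-difference rounding noise
            assert abs(fd - g[i]) / max(abs(fd), abs(g[i]), 1e-6) < 1e-4
    an_all, fd_all = np.array(an_all), np.array(fd_all)
    rel = np.linalg.norm(fd_all - an_all) / max(
        np.linalg.norm(fd_all), np.linalg.norm(an_all)
    )
    assert rel < 1e-4


# -- training mechanics ------------------------------------------------

def test_fit_is_deterministic_per_seed():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, (24, 8, 8))
    y = (rng.uniform(size=24) < 0.5).astype(int)
    runs = []
    for _ in range(2):
        model = CapsNetModel(TINY)
        model.fit(x, y, epochs=2, batch_size=8)
        runs.append((model.predict_scores(x), model.history[-1]["margin"]))
    assert np.array_equal(runs[0][0], runs[1][0])
    assert runs[0][1] == runs[1][1]


def test_training_reduces_loss():
    from dataclasses import replace

    rng = np.random.default_rng(4)
    # two classes with different spatial mean level: trivially learnable
    x = np.concatenate([
        rng.uniform(0.0, 0.4, (16, 8, 8)), rng.uniform(0.6, 1.0, (16, 8, 8)),
    ])
    y = np.array([0] * 16 + [1] * 16)
    model = CapsNetModel(replace(TINY, learning_rate=3e-3))
    model.fit(x, y, epochs=60, batch_size=8)
    assert model.history[-1]["margin"] < model.history[0]["margin"]
    assert model.evaluate(x, y)["accuracy"] >= 0.9


def test_save_load_round_trip(tmp_path):
    model = CapsNetModel(TINY)
    x = np.random.default_rng(5).uniform(0, 1, (3, 8, 8))
    path = model.save(tmp_path / "model.npz")
    back = CapsNetModel.load(path)
    assert back.cfg == model.cfg
    assert np.array_equal(back.predict_scores(x), model.predict_scores(x))
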