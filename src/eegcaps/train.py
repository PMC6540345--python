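"""Cross-validated and hold-out training/evaluation on MFM datasets.

The default protocol mirrors the study design: all subjects' MFMs are
pooled and split by sample into 10 folds (so windows of one trial can land
on both sides of a split — a trial-grouped leakage-safe mode is available
as an option), a fresh model is trained per fold, and the three affective
dimensions (valence, arousal, dominance) are three independent binary
runs over the same features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, GroupKFold

from .capsnet import CapsNetConfig, CapsNetModel
from .io import EEGRecording
from .features import BandScheme, DEFAULT_SCHEME, extract_features, normalize_subject
from .mfm import DEFAULT_LAYOUT, DEFAULT_MONTAGE, MFMDataset, mfm_dataset
from .segmentation import segment_recording


@dataclass
class EvalProtocol:
    """Evaluation settings: 10-fold CV (default) or stratified 8:1:1 hold-out."""

    mode: str = "kfold"                  # "kfold" | "holdout"
    k: int = 10
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    epochs: int = 400
    batch_size: int = 40
    dimension: str = "valence"
    seed: int = 0
    group_by_trial: bool = False         # leakage-safe variant

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("hold-out proportions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class EvalResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusions: list[np.ndarray]
    skipped_folds: list[int] = field(default_factory=list)
    histories: list[list[dict]] = field(default_factory=list)


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint shuffled index sets partitioning [0, n), sizes within 1."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.arange(n))]


def holdout_split(
    labels: np.ndarray,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test split at the given per-label proportions."""
    labels = np.asarray(labels)
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 10:
            raise ValueError(f"label {lab!r} has only {len(idx)} samples (< 10)")
        rng.shuffle(idx)
        n_tr = int(round(proportions[0] * len(idx)))
        n_va = int(round(proportions[1] * len(idx)))
        train.append(idx[:n_tr])
        val.append(idx[n_tr : n_tr + n_va])
        test.append(idx[n_tr + n_va :])
    return (np.concatenate(train), np.concatenate(val), np.concatenate(test))


def evaluate(model: CapsNetModel, mfms: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy (correct/total) and confusion counts on a labelled MFM set."""
    return model.evaluate(mfms, labels)


def run_cv(
    dataset: MFMDataset,
    cfg: CapsNetConfig,
    protocol: EvalProtocol,
    verbose: bool = False,
) -> EvalResult:
    """Train a fresh model per fold and report per-fold test accuracy.

    A fold whose training data contains a single class is recorded as
    skipped. Fold assignment and every model initialization derive from the
    protocol seed, so a run is reproducible end to end.
    """
    protocol.validate()
    x = dataset.mfms
    y = dataset.labels(protocol.dimension)
    if len(x) == 0 or len(np.unique(y)) < 2:
        raise ValueError("dataset must be nonempty with both classes present")

    if protocol.group_by_trial:
        groups = (
            dataset.keys["subject_id"].astype(str) + "/" + dataset.keys["trial_id"].astype(str)
        ).to_numpy()
        folds = [test for _, test in GroupKFold(n_splits=protocol.k).split(x, y, groups)]
    else:
        folds = kfold_split(len(x), protocol.k, protocol.seed)

    accs, confs, skipped, hists = [], [], [], []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(x), dtype=bool)
        train_mask[test_idx] = False
        y_tr = y[train_mask]
        if len(np.unique(y_tr)) < 2:
            import warnings

            warnings.warn(f"fold {f} skipped: training data has a single class")
            skipped.append(f)
            continue
        from dataclasses import replace

        model = CapsNetModel(replace(cfg, seed=cfg.seed + 1000 * f + protocol.seed))
        model.fit(
            x[train_mask], y_tr,
            epochs=protocol.epochs, batch_size=protocol.batch_size, verbose=verbose,
        )
        res = model.evaluate(x[test_idx], y[test_idx])
        if verbose:
            print(f"fold {f}: accuracy {res['accuracy']:.4f}")
        accs.append(res["accuracy"])
        confs.append(res["confusion"])
        hists.append(model.history)
    return EvalResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)) if accs else float("nan"),
        confusions=confs,
        skipped_folds=skipped,
        histories=hists,
    )


# ---------------------------------------------------------------------------
# end-to-end convenience: recordings -> MFM dataset
# ---------------------------------------------------------------------------

def recordings_to_mfms(
    recordings: list[EEGRecording],
    scheme: BandScheme = DEFAULT_SCHEME,
    orientation: str = "inverted",
    montage: dict[str, tuple[int, int]] = DEFAULT_MONTAGE,
    layout: dict[str, tuple[int, int]] = DEFAULT_LAYOUT,
    baseline_seconds: float = 3.0,
    window_seconds: float = 3.0,
) -> MFMDataset:
    """Segment, featurize, normalize per subject and build MFMs for a cohort.

    Subjects are processed one at a time (per-subject normalization needs no
    cross-subject state), so memory stays bounded by one recording.
    """
    import pandas as pd

    all_mfms, all_keys = [], []
    for rec in recordings:
        segs = segment_recording(rec, baseline_seconds, window_seconds)
        table = extract_features(segs, scheme, rec.channel_names)
        table = normalize_subject(table, orientation)
        ds = mfm_dataset(table, montage, layout)
        all_mfms.append(ds.mfms)
        all_keys.append(ds.keys)
    if not all_mfms:
        return MFMDataset(mfms=np.zeros((0, 18, 18)), keys=pd.DataFrame())
    return MFMDataset(
        mfms=np.concatenate(all_mfms),
        keys=pd.concat(all_keys, ignore_index=True),
    )
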