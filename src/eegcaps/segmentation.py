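"""Trial segmentation and rating binarization.

Each 63 s trial drops its 3 s pre-stimulus baseline and is cut into
non-overlapping 3 s windows (20 per trial at the defaults); every window
inherits its trial's binarized low/high labels on the three target
dimensions. A rating below the threshold (default 5) maps to low (0), a
rating at or above it to high (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEGRecording

#: The three binary classification targets, in label-vector order.
TARGET_DIMS = ("valence", "arousal", "dominance")


@dataclass
class Segment:
    """One fixed-length window of one trial, with inherited labels."""

    subject_id: str
    trial_id: int
    segment_index: int
    signal: np.ndarray          # [n_channels, window_samples]
    fs: float
    labels: dict[str, int]      # dimension -> 0 (low) / 1 (high)


def binarize_rating(rating: float, threshold: float = 5.0) -> int:
    """0 (low) iff ``rating < threshold``; 1 (high) iff ``rating >= threshold``."""
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating!r} outside the 1-9 scale")
    return int(rating >= threshold)


def binarize_trial(ratings_row: np.ndarray, threshold: float = 5.0) -> dict[str, int]:
    """Binarized labels for the three target dimensions of one trial.

    ``ratings_row`` is the stored (valence, arousal, dominance, liking) row;
    liking is carried in the data but is not a classification target.
    """
    return {
        "valence": binarize_rating(float(ratings_row[0]), threshold),
        "arousal": binarize_rating(float(ratings_row[1]), threshold),
        "dominance": binarize_rating(float(ratings_row[2]), threshold),
    }


def segment_trial(
    trial_signal: np.ndarray,
    fs: float,
    baseline_seconds: float = 3.0,
    window_seconds: float = 3.0,
    *,
    subject_id: str = "",
    trial_id: int = 0,
    labels: dict[str, int] | None = None,
) -> list[Segment]:
    """Cut one channels x time trial into disjoint contiguous windows.

    The first ``baseline_seconds`` are discarded (not subtracted); then
    ``floor((T - baseline) / window)`` full windows are emitted and any
    shorter remainder is dropped.
    """
    n_base = int(round(baseline_seconds * fs))
    n_win = int(round(window_seconds * fs))
    n_total = trial_signal.shape[1]
    if n_total < n_base + n_win:
        raise ValueError(
            f"trial {trial_id} of subject {subject_id!r}: {n_total} samples is "
            f"shorter than baseline + one window ({n_base + n_win})"
        )
    n_seg = (n_total - n_base) // n_win
    labels = labels or {}
    return [
        Segment(
            subject_id=subject_id,
            trial_id=trial_id,
            segment_index=k,
            signal=trial_signal[:, n_base + k * n_win : n_base + (k + 1) * n_win],
            fs=fs,
            labels=dict(labels),
        )
        for k in range(n_seg)
    ]


def segment_recording(
    rec: EEGRecording,
    baseline_seconds: float = 3.0,
    window_seconds: float = 3.0,
    threshold: float = 5.0,
) -> list[Segment]:
    """Segment every trial of a recording, attaching binarized labels."""
    rec.validate()
    out: list[Segment] = []
    for t in range(rec.n_trials):
        out.extend(
            segment_trial(
                rec.signal[t],
                rec.fs,
                baseline_seconds,
                window_seconds,
                subject_id=rec.subject_id,
                trial_id=t,
                labels=binarize_trial(rec.ratings[t], threshold),
            )
        )
    return out


def segment_table(segments: list[Segment]) -> pd.DataFrame:
    """Metadata table (subject, trial, index, labels) for a segment list."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "trial_id": [s.trial_id for s in segments],
            "segment_index": [s.segment_index for s in segments],
            **{d: [s.labels.get(d, -1) for s in segments] for d in TARGET_DIMS},
        }
    )
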