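"""Band-power features: Welch PSD averaged per band, per-subject min-max scaling.

For each 3 s segment the one-sided PSD of every channel is estimated by
Welch's method (1 s Hann windows, 50% overlap) and averaged over the bins of
the four canonical bands theta (4-8 Hz), alpha (8-15 Hz), beta (15-32 Hz)
and gamma (32-45 Hz); band intervals are half-open [low, high) so a shared
edge belongs to the upper band only. Features are then min-max scaled per
subject and per channel-band column.

The default scaling is the inverted map

    F' = (Fmax - F) / (Fmax - Fmin)

which sends each subject-column's maximum to 0 and minimum to 1; the
conventional orientation (F - Fmin) / (Fmax - Fmin) is available via
``orientation="conventional"``. A degenerate column (Fmax == Fmin) maps
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segmentation import Segment, segment_table


def _default_bands() -> dict[str, tuple[float, float]]:
    return {"theta": (4.0, 8.0), "alpha": (8.0, 15.0), "beta": (15.0, 32.0), "gamma": (32.0, 45.0)}


@dataclass(frozen=True)
class BandScheme:
    """Ordered band name -> (low, high) edges in Hz."""

    bands: dict[str, tuple[float, float]] = field(default_factory=_default_bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def validate(self, fs: float) -> None:
        edges = sorted(self.bands.values())
        for (l1, h1), (l2, _h2) in zip(edges, edges[1:]):
            if l1 >= h1 or h1 > l2:
                raise ValueError("bands must be ordered and non-overlapping")
        if max(h for _, h in edges) > fs / 2:
            raise ValueError("band edge above Nyquist")


DEFAULT_SCHEME = BandScheme()


def band_psd(
    segment: Segment,
    scheme: BandScheme = DEFAULT_SCHEME,
    nperseg: int = 128,
    noverlap: int | None = None,
    window: str = "hann",
) -> np.ndarray:
    """Mean PSD per channel per band for one segment.

    Returns a [n_channels, n_bands] array in linear units (uV^2/Hz),
    channel-major. Welch parameters default to 1 s Hann windows with 50%
    overlap (three averaged windows over a 384-sample segment at 128 Hz).
    """
    return _band_psd_block(
        segment.signal[None], segment.fs, scheme, nperseg, noverlap, window
    )[0]


def _band_psd_block(
    signals: np.ndarray,
    fs: float,
    scheme: BandScheme = DEFAULT_SCHEME,
    nperseg: int = 128,
    noverlap: int | None = None,
    window: str = "hann",
) -> np.ndarray:
    """Vectorized band PSD over a [n_segments, n_channels, n_samples] block."""
    scheme.validate(fs)
    n = signals.shape[-1]
    if n < nperseg:
        raise ValueError(f"segment of {n} samples shorter than PSD window {nperseg}")
    freqs, psd = sps.welch(
        signals, fs=fs, window=window, nperseg=nperseg,
        noverlap=nperseg // 2 if noverlap is None else noverlap, axis=-1,
    )
    out = np.empty(signals.shape[:-1] + (len(scheme.bands),), dtype=np.float64)
    for b, (lo, hi) in enumerate(scheme.bands.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[..., b] = psd[..., mask].mean(axis=-1)
    return out


@dataclass
class FeatureTable:
    """Per-segment band-power features and their normalized form.

    ``raw`` and ``normalized`` are [n_segments, n_channels, n_bands]; ``keys``
    is the segment metadata table (subject, trial, index, labels) aligned
    row-for-row with the feature arrays.
    """

    keys: pd.DataFrame
    raw: np.ndarray
    band_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    normalized: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return self.raw.shape[0]

    def labels(self, dimension: str) -> np.ndarray:
        return self.keys[dimension].to_numpy()


def extract_features(
    segments: list[Segment],
    scheme: BandScheme = DEFAULT_SCHEME,
    channel_names: tuple[str, ...] = (),
    nperseg: int = 128,
) -> FeatureTable:
    """Band PSD for a list of same-shape segments (not yet normalized)."""
    if not segments:
        return FeatureTable(
            keys=segment_table(segments),
            raw=np.zeros((0, 0, len(scheme.bands))),
            band_names=scheme.names,
            channel_names=channel_names,
        )
    block = np.stack([s.signal for s in segments])
    raw = _band_psd_block(block, segments[0].fs, scheme, nperseg)
    return FeatureTable(
        keys=segment_table(segments),
        raw=raw,
        band_names=scheme.names,
        channel_names=channel_names,
    )


def _minmax(raw: np.ndarray, lo: np.ndarray, hi: np.ndarray, orientation: str) -> np.ndarray:
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    if orientation == "inverted":
        out = (hi - raw) / safe
    elif orientation == "conventional":
        out = (raw - lo) / safe
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.where(span > 0, out, 0.0)


def save_features(table: FeatureTable, path) -> None:
    """Persist a feature table (raw, normalized, keys) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features/raw", data=table.raw.astype(np.float32))
        if table.normalized is not None:
            f.create_dataset("features/norm", data=table.normalized.astype(np.float32))
        f.attrs["band_names"] = list(table.band_names)
        f.attrs["channel_names"] = list(table.channel_names)
        for col in table.keys.columns:
            data = table.keys[col].to_numpy()
            if data.dtype == object:
                data = data.astype(h5py.string_dtype("utf-8"))
            f.create_dataset(f"keys/{col}", data=data)


def load_features(path) -> FeatureTable:
    import h5py

    with h5py.File(path, "r") as f:
        keys = {}
        for col in f["keys"]:
            data = f[f"keys/{col}"][()]
            if data.dtype.kind in ("S", "O"):
                data = np.array([x.decode() if isinstance(x, bytes) else x for x in data])
            keys[col] = data
        return FeatureTable(
            keys=pd.DataFrame(keys),
            raw=f["features/raw"][()].astype(np.float64),
            band_names=tuple(f.attrs["band_names"]),
            channel_names=tuple(f.attrs["channel_names"]),
            normalized=(
                f["features/norm"][()].astype(np.float64)
                if "norm" in f["features"] else None
            ),
        )


def normalize_subject(
    table: FeatureTable,
    orientation: str = "inverted",
    fit_rows: np.ndarray | None = None,
) -> FeatureTable:
    """Min-max scale each channel-band column within each subject.

    Extrema are taken over all of a subject's segments (the stated
    procedure, applied before any train/test split); passing ``fit_rows``
    restricts extrema to those rows (e.g. training folds) for a
    leakage-safe variant, with out-of-range values clipped to [0, 1].
    """
    norm = np.empty_like(table.raw)
    subjects = table.keys["subject_id"].to_numpy()
    fit_mask = np.ones(table.n_segments, dtype=bool)
    if fit_rows is not None:
        fit_mask = np.zeros(table.n_segments, dtype=bool)
        fit_mask[fit_rows] = True
    for subj in pd.unique(subjects):
        rows = subjects == subj
        fit = rows & fit_mask
        if not fit.any():
            fit = rows
        lo = table.raw[fit].min(axis=0)
        hi = table.raw[fit].max(axis=0)
        norm[rows] = np.clip(_minmax(table.raw[rows], lo, hi, orientation), 0.0, 1.0)
    return FeatureTable(
        keys=table.keys,
        raw=table.raw,
        band_names=table.band_names,
        channel_names=table.channel_names,
        normalized=norm,
    )
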