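"""Reading and writing EEG recordings, ratings, features and MFM datasets.

The canonical on-disk container is one HDF5 file per subject:

    /signal         float32 [n_trials, n_channels, n_samples]
    /ratings        float32 [n_trials, 4]   (valence, arousal, dominance, liking)
    /channel_names  UTF-8 string list
    attrs: fs, subject_id

A loader for the DEAP preprocessed per-subject pickle (keys ``data`` and
``labels``) is provided as an optional dialect; only the first 32 channels
(the EEG electrodes, in DEAP's documented order) are kept.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Rating columns, in the order stored on disk and in DEAP's ``labels`` array.
RATING_DIMS = ("valence", "arousal", "dominance", "liking")

#: The 32 EEG electrodes of the DEAP montage, in DEAP's documented channel order.
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)


class ValidationError(ValueError):
    """Raised when a recording violates its structural invariants."""


@dataclass
class EEGRecording:
    """One subject's trial-indexed multi-channel EEG block.

    Parameters
    ----------
    subject_id : str
        Identifier carried through features and MFMs.
    signal : ndarray, shape (n_trials, n_channels, n_samples)
        Microvolt-scaled samples.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        Electrode labels (10–20 system), one per channel, order preserved.
    ratings : ndarray, shape (n_trials, 4)
        Per-trial self-assessment ratings (valence, arousal, dominance,
        liking), each on the continuous 1–9 scale.
    """

    subject_id: str
    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = field(default=DEAP_CHANNELS)
    ratings: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.ratings is None:
            self.ratings = np.zeros((self.signal.shape[0], 4), dtype=np.float32)
        self.ratings = np.asarray(self.ratings, dtype=np.float32)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 3:
            raise ValidationError(
                f"signal must be [trials, channels, samples], got shape {self.signal.shape}"
            )
        n_trials, n_channels, _ = self.signal.shape
        if n_channels != len(self.channel_names):
            raise ValidationError(
                f"signal has {n_channels} channels but {len(self.channel_names)} names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names are not unique")
        if not np.isfinite(self.signal).all():
            raise ValidationError("signal contains non-finite values")
        if self.ratings.shape != (n_trials, 4):
            raise ValidationError(
                f"ratings must be [n_trials, 4]; got {self.ratings.shape} for "
                f"{n_trials} trials"
            )
        if n_trials:
            bad = np.where((self.ratings < 1) | (self.ratings > 9))
            if bad[0].size:
                t = int(bad[0][0])
                raise ValidationError(
                    f"trial {t} has rating {self.ratings[bad[0][0], bad[1][0]]:g} "
                    "outside [1, 9]"
                )

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.fs == other.fs
            and self.channel_names == other.channel_names
            and self.signal.shape == other.signal.shape
            and np.array_equal(self.signal, other.signal)
            and np.array_equal(self.ratings, other.ratings)
        )


# -- canonical container ------------------------------------------------


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a validated recording to the canonical HDF5 container."""
    rec.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype(np.float32))
        f.create_dataset("ratings", data=rec.ratings.astype(np.float32))
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["fs"] = float(rec.fs)
        f.attrs["subject_id"] = rec.subject_id
    return path


def read_recording(path: str | Path, dialect: str = "portable") -> EEGRecording:
    """Read a recording.

    ``dialect="portable"`` reads the canonical HDF5 container;
    ``dialect="deap-pickle"`` reads a DEAP preprocessed per-subject pickle
    (``data`` [40, 40, 8064], ``labels`` [40, 4]) keeping the 32 EEG channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "portable":
        with h5py.File(path, "r") as f:
            return EEGRecording(
                subject_id=str(f.attrs["subject_id"]),
                signal=f["signal"][()],
                fs=float(f.attrs["fs"]),
                channel_names=tuple(
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["channel_names"][()]
                ),
                ratings=f["ratings"][()],
            )
    if dialect == "deap-pickle":
        with open(path, "rb") as fh:
            obj = pickle.load(fh, encoding="latin1")
        data = np.asarray(obj["data"], dtype=np.float32)
        labels = np.asarray(obj["labels"], dtype=np.float32)
        return EEGRecording(
            subject_id=path.stem,
            signal=data[:, : len(DEAP_CHANNELS), :],
            fs=128.0,
            channel_names=DEAP_CHANNELS,
            ratings=labels,
        )
    raise ValueError(f"unsupported dialect: {dialect!r}")


def ratings_to_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Sidecar CSV of the ratings matrix for quick inspection."""
    df = pd.DataFrame(rec.ratings, columns=list(RATING_DIMS))
    df.insert(0, "trial_id", np.arange(rec.n_trials))
    path = Path(path)
    df.to_csv(path, index=False)
    return path
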