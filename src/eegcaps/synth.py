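"""Synthetic DEAP-shaped EEG with class-dependent band-power structure.

The generator emulates the preprocessed DEAP layout — per subject, 40 trials
of 63 s at 128 Hz over 32 electrodes, with 1–9 self-assessment ratings — and
injects a recoverable signal: for each affective dimension a latent binary
class per trial modulates the amplitude of a narrowband carrier in one
frequency band on a subset of channels. Ratings are drawn away from the
binarization threshold so that thresholding at 5 recovers the latent class
exactly, which makes every downstream stage testable without real data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import DEAP_CHANNELS, EEGRecording

#: Band edges in Hz (shared with the feature module's default scheme).
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 15.0), "beta": (15.0, 32.0), "gamma": (32.0, 45.0)}


@dataclass(frozen=True)
class BandEffect:
    """Class-dependent amplitude effect: in ``band`` on ``channels``, the
    carrier amplitude is multiplied by ``multiplier`` when the trial's latent
    class for ``dimension`` is high."""

    dimension: str          # "valence" | "arousal" | "dominance"
    band: str               # key of BANDS
    channels: tuple[str, ...]
    multiplier: float = 3.0


def _default_effects() -> tuple[BandEffect, ...]:
    return (
        BandEffect("arousal", "beta", ("Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "Fz", "F7", "F8")),
        BandEffect("valence", "alpha", ("P3", "P4", "Pz", "P7", "P8", "PO3", "PO4", "O1", "O2")),
        BandEffect("dominance", "gamma", ("T7", "T8", "C3", "C4", "FC5", "FC6", "CP5", "CP6")),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults mirror the DEAP preprocessed layout
    (32 subjects x 40 trials x 32 channels, 63 s at 128 Hz with a 3 s
    pre-stimulus baseline)."""

    n_subjects: int = 32
    n_trials: int = 40
    n_channels: int = 32
    trial_seconds: float = 63.0
    baseline_seconds: float = 3.0
    fs: float = 128.0
    band_effects: tuple[BandEffect, ...] = field(default_factory=_default_effects)
    carrier_amplitude: float = 1.0
    carrier: str = "narrowband"   # "narrowband" (filtered noise) or "tone"
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.trial_seconds <= self.baseline_seconds:
            raise ValueError("trial must be longer than the baseline")
        if self.fs <= 2 * 45.0:
            raise ValueError("fs must exceed twice the highest band edge (45 Hz)")
        for eff in self.band_effects:
            if eff.band not in BANDS:
                raise ValueError(f"unknown band {eff.band!r}")
            if eff.multiplier <= 0:
                raise ValueError("multipliers must be positive")
        if min(self.n_trials, self.n_channels) < 0 or self.n_subjects < 1:
            raise ValueError("counts must be non-negative")


def _background(rng: np.random.Generator, shape: tuple[int, ...], sd: float, fs: float) -> np.ndarray:
    """Mildly colored (low-pass-smoothed) Gaussian background noise."""
    if sd == 0:
        return np.zeros(shape, dtype=np.float32)
    white = rng.standard_normal(shape)
    # one-pole smoothing gives a gently decaying spectrum across all bands
    b, a = sps.butter(1, 45.0 / (fs / 2), btype="low")
    colored = sps.lfilter(b, a, white, axis=-1)
    colored *= sd / max(colored.std(), 1e-12)
    return colored.astype(np.float32)


def _carriers(
    rng: np.random.Generator, m: int, n: int, band: tuple[float, float], fs: float, kind: str
) -> np.ndarray:
    """``m`` independent unit-RMS carriers of length ``n`` confined to ``band``."""
    lo, hi = band
    if kind == "tone":
        f0 = 0.5 * (lo + hi)
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=(m, 1))
        x = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phases)
    else:
        b, a = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
        x = sps.lfilter(b, a, rng.standard_normal((m, n + 256)), axis=-1)[:, 256:]
        x /= np.maximum(x.std(axis=-1, keepdims=True), 1e-12)
    return x.astype(np.float32)


def generate_recording(cfg: SynthConfig, subject_id: str = "synth-00") -> EEGRecording:
    """Generate one subject.

    The signal is background noise plus, per effect, a band-limited carrier on
    the designated channels whose amplitude is ``carrier_amplitude`` when the
    trial's latent class is low and ``carrier_amplitude * multiplier`` when it
    is high. The 3 s baseline contains background noise only. Ratings for the
    three target dimensions are drawn uniform on [6, 9] (high) or [1, 4]
    (low); liking is uniform on [1, 9]. Deterministic for a fixed seed.
    """
    cfg.validate()
    # stable per-subject stream: process-independent hash of the subject id
    rng = np.random.default_rng([cfg.seed, zlib.crc32(subject_id.encode())])
    fs = cfg.fs
    n_total = int(round(cfg.trial_seconds * fs))
    n_base = int(round(cfg.baseline_seconds * fs))
    channels = DEAP_CHANNELS[: cfg.n_channels]
    ch_index = {c: i for i, c in enumerate(channels)}

    signal = _background(rng, (cfg.n_trials, cfg.n_channels, n_total), cfg.noise_sd, fs)
    ratings = np.empty((cfg.n_trials, 4), dtype=np.float32)
    dims = ("valence", "arousal", "dominance")
    latent = {d: rng.integers(0, 2, size=cfg.n_trials) for d in dims}

    for t in range(cfg.n_trials):
        for eff in cfg.band_effects:
            cls = latent.get(eff.dimension)
            if cls is None:
                continue
            amp = cfg.carrier_amplitude * (eff.multiplier if cls[t] else 1.0)
            idx = [ch_index[c] for c in eff.channels if c in ch_index]
            if idx:
                cars = _carriers(rng, len(idx), n_total - n_base, BANDS[eff.band], fs, cfg.carrier)
                signal[t, idx, n_base:] += amp * cars
        for d, col in (("valence", 0), ("arousal", 1), ("dominance", 2)):
            ratings[t, col] = rng.uniform(6.0, 9.0) if latent[d][t] else rng.uniform(1.0, 4.0)
        ratings[t, 3] = rng.uniform(1.0, 9.0)

    return EEGRecording(
        subject_id=subject_id,
        signal=signal,
        fs=fs,
        channel_names=channels,
        ratings=ratings,
    )


def generate_cohort(cfg: SynthConfig, n_subjects: int | None = None) -> list[EEGRecording]:
    """Generate ``n_subjects`` recordings with per-subject derived seeds."""
    cfg.validate()
    n = cfg.n_subjects if n_subjects is None else n_subjects
    return [
        generate_recording(replace(cfg, seed=cfg.seed), f"synth-{i:02d}") for i in range(n)
    ]
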