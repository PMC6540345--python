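"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from eegcaps import EEGRecording, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Reduced generator settings for fast unit tests: 6 trials of 15 s."""
    return SynthConfig(n_trials=6, trial_seconds=15.0, seed=42)


@pytest.fixture(scope="session")
def small_recording(small_cfg) -> EEGRecording:
    return generate_recording(small_cfg, "unit-subject")


@pytest.fixture(scope="session")
def deap_shaped_recording() -> EEGRecording:
    """One full DEAP-layout subject: 40 trials x 32 channels x 8064 samples."""
    return generate_recording(SynthConfig(seed=7), "deap-shaped")


@pytest.fixture()
def tiny_recording() -> EEGRecording:
    """Hand-built 2-trial recording with deterministic ratings."""
    rng = np.random.default_rng(0)
    return EEGRecording(
        subject_id="tiny",
        signal=rng.standard_normal((2, 32, 128 * 9)).astype(np.float32),
        fs=128.0,
        ratings=np.array(
            [[2.0, 7.0, 5.0, 1.0], [8.0, 4.99, 1.0, 9.0]], dtype=np.float32
        ),
    )
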