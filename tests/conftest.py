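"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from finchsong import synthetic as syn
from finchsong import segmentation as seg

SR = 44100


@pytest.fixture(scope="session")
def tutor_syllables():
    return syn.default_tutor_syllables()


@pytest.fixture(scope="session")
def tutor_syntax():
    return syn.default_tutor_syntax()


@pytest.fixture(scope="session")
def tutor_bout(tutor_syntax, tutor_syllables):
    """One deterministic tutor bout with ground truth."""
    rng = np.random.default_rng(7)
    return syn.generate_bout(tutor_syntax, tutor_syllables, rng)


def harmonic_spec(label="t", f0=600.0, n_harmonics=8, noise_fraction=0.0,
                  duration_ms=100.0, amplitude_db=-6.0, **kw) -> syn.SyllableSpec:
    return syn.SyllableSpec(
        label=label, f0=f0, n_harmonics=n_harmonics, harmonic_rolloff=0.75,
        noise_fraction=noise_fraction, duration_ms=duration_ms,
        amplitude_db=amplitude_db, **kw,
    )


def tone(freq_hz: float, duration_s: float = 1.0, amplitude: float = 0.5,
         sample_rate: int = SR) -> seg.AudioRecording:
    t = np.arange(round(duration_s * sample_rate)) / sample_rate
    return seg.AudioRecording(amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate)
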