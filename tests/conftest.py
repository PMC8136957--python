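"""Shared fixtures: synthetic recordings with known spectral ground truth.

Heavy speckle simulations are session-scoped so the spectral-oracle,
null-spectrogram and gain-recovery checks reuse the same realizations.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biodyn.simulate import (
    SpeckleSimConfig,
    apply_drug_response,
    generate_baseline_speckle,
)
from biodyn.spectrogram import compute_spectrogram

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def lorentzian_density(freqs, config):
    """Analytic one-sided spectral density of the generator for slope 2,
    normalized to the configured fluctuation variance (the oracle for the
    spectral estimator)."""
    f_nyq = config.sampling_rate / 2
    c = config.fluctuation_sd**2 / (
        config.knee_frequency * np.arctan(f_nyq / config.knee_frequency)
    )
    return c / (1.0 + (freqs / config.knee_frequency) ** 2)


@pytest.fixture(scope="session")
def lorentz_config():
    return SpeckleSimConfig(
        n_pixels=8,
        baseline_duration=1024.0,
        post_duration=1024.0,
        knee_frequency=0.5,
        spectral_slope=2.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def lorentz_recording(lorentz_config):
    """2048 s stationary recording with a knee-spectrum ground truth."""
    return generate_baseline_speckle(lorentz_config)


@pytest.fixture(scope="session")
def signature_config():
    """Apoptosis-like band gains: lo and hi motion up, mid motion down."""
    return SpeckleSimConfig(
        n_pixels=16,
        baseline_duration=1800.0,
        post_duration=3600.0,
        onset_duration=120.0,
        band_gains={"lo": 0.2, "mid": -0.2, "hi": 0.3},
        seed=7,
    )


@pytest.fixture(scope="session")
def signature_well(signature_config):
    """Recording carrying the full injected signature at maximal dose."""
    base = generate_baseline_speckle(signature_config)
    return apply_drug_response(base, signature_config, "100")


@pytest.fixture(scope="session")
def signature_spectrogram(signature_well):
    return compute_spectrogram(signature_well, window=300.0, step=300.0)


@pytest.fixture(scope="session")
def null_config():
    return SpeckleSimConfig(
        n_pixels=16,
        baseline_duration=2048.0,
        post_duration=2048.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_spectrogram(null_config):
    """Spectrogram of a 4096 s recording with zero drug effect."""
    rec = generate_baseline_speckle(null_config)
    rec = apply_drug_response(rec, null_config, "CTRL")
    return compute_spectrogram(rec, window=512.0, step=512.0, segment_length=128.0)
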