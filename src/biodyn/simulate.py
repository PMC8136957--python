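"""Synthetic dynamic-speckle recordings and subject cohorts.

Every downstream stage (spectra, spectrograms, biomarkers, selection, ROC)
is tested against recordings with known ground truth, so the generators
here are first-class, deterministic components.

The baseline speckle process is spectrally shaped Gaussian noise: white
noise is filtered in the Fourier domain to a knee (Lorentzian-like)
fluctuation spectrum ``S(f) ~ 1 / (1 + (f/f_knee)^slope)`` and superposed
on a constant mean intensity. A drug response multiplies the amplitude of
each frequency band by ``exp(gain/2)`` after the application time — i.e.
shifts the log band power by ``gain = band_gain * dose_scaling(dose)`` —
with a linear onset ramp.

Plates follow the assay design: 5 conditions (DMSO control; doxorubicin
0.1, 1, 10, 100 uM) x 4 tissue replicates. Cohorts couple a latent
marrow-sensitivity variable to both a biomarker value and a logistic
proportionate neutrophil drop, mimicking the clinical association the
analysis is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .conditions import CONDITIONS, CTRL, N_REPLICATES, validate_condition
from .errors import ConfigurationError
from .spectra import WellRecording
from .spectrogram import BAND_EDGES, BANDS

#: Default dose -> gain multiplier: saturating, monotone in dose, zero for
#: the vehicle control.
DEFAULT_DOSE_SCALING: dict[str, float] = {
    CTRL: 0.0,
    "0.1": 0.25,
    "1": 0.5,
    "10": 0.75,
    "100": 1.0,
}


def _zero_gains() -> dict[str, float]:
    return {b: 0.0 for b in BANDS}


@dataclass
class SpeckleSimConfig:
    """Parameters of the speckle-recording generator.

    Desk-scale defaults (16x16 pixels, 25 Hz, 1 h baseline + 2 h post)
    keep 0.01 Hz resolvable at minutes-scale runtime; the full protocol
    (4 h + 10 h) is available via :func:`full_protocol_config`.
    """

    sampling_rate: float = 25.0  # Hz; >= 25 so Nyquist covers 12.5 Hz
    n_pixels: int = 16  # side of the square pixel grid
    baseline_duration: float = 3600.0  # s before drug application
    post_duration: float = 7200.0  # s after drug application
    knee_frequency: float = 0.5  # Hz, knee of the baseline spectrum
    spectral_slope: float = 2.0  # power-law exponent above the knee
    mean_intensity: float = 100.0  # arbitrary units
    fluctuation_sd: float = 10.0  # RMS fluctuation about the mean
    band_gains: dict[str, float] = field(default_factory=_zero_gains)
    dose_scaling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_SCALING)
    )
    onset_duration: float = 600.0  # s, linear ramp of the drug effect
    seed: int = 0

    def validate(self) -> "SpeckleSimConfig":
        if self.sampling_rate < 25.0:
            raise ConfigurationError(
                "sampling_rate must be >= 25 Hz so the Nyquist frequency covers 12.5 Hz"
            )
        if self.n_pixels < 1:
            raise ConfigurationError("n_pixels must be a positive grid side")
        if self.baseline_duration <= 0:
            raise ConfigurationError("baseline_duration must be positive")
        if self.post_duration <= 0:
            raise ConfigurationError("post_duration must be positive")
        if not (0.01 < self.knee_frequency < 12.5):
            raise ConfigurationError("knee_frequency must lie within (0.01, 12.5) Hz")
        if self.mean_intensity <= 0:
            raise ConfigurationError("mean_intensity must be positive")
        if self.fluctuation_sd <= 0:
            raise ConfigurationError("fluctuation_sd must be positive")
        if self.onset_duration < 0:
            raise ConfigurationError("onset_duration must be nonnegative")
        unknown = set(self.band_gains) - set(BANDS)
        if unknown:
            raise ConfigurationError(f"band_gains has unknown bands {sorted(unknown)}")
        for label in self.dose_scaling:
            validate_condition(label)
        doses = [c for c in CONDITIONS if c in self.dose_scaling]
        scales = [self.dose_scaling[c] for c in doses]
        if any(b > a for a, b in zip(scales[1:], scales[:-1])):
            raise ConfigurationError("dose_scaling must be monotone non-decreasing in dose")
        return self


def full_protocol_config(**overrides) -> SpeckleSimConfig:
    """Config at the full assay durations: 4 h baseline, 10 h post-drug,
    30 min drug-onset ramp."""
    base = dict(
        baseline_duration=4 * 3600.0,
        post_duration=10 * 3600.0,
        onset_duration=1800.0,
    )
    base.update(overrides)
    return SpeckleSimConfig(**base)


@dataclass
class CohortSimConfig:
    """Parameters of the direct cohort generator (biomarker tables plus
    neutrophil counts), a lightweight stand-in for a 10-dog study.

    A latent marrow sensitivity ``s ~ N(0, 1)`` per subject drives both the
    biomarker (``effect * s + noise``) and the proportionate neutrophil
    drop (``logistic(s; steepness, midpoint)``).
    """

    n_subjects: int = 10
    biomarker_effect: float = 1.0  # RU per unit latent sensitivity
    biomarker_noise_sd: float = 0.3  # RU
    pre_count_range: tuple[float, float] = (4.0, 30.0)  # 10^3 cells/uL
    drop_steepness: float = 4.0
    drop_midpoint: float = 0.0
    signal_biomarker: str = "Hi Dox 1/CTRL"
    n_noise_biomarkers: int = 0
    seed: int = 0

    def validate(self) -> "CohortSimConfig":
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.biomarker_noise_sd < 0:
            raise ConfigurationError("biomarker_noise_sd must be >= 0")
        lo, hi = self.pre_count_range
        if not (0 < lo < hi):
            raise ConfigurationError("pre_count_range must be positive and ordered")
        if self.n_noise_biomarkers < 0:
            raise ConfigurationError("n_noise_biomarkers must be >= 0")
        return self


@dataclass
class SimulatedPlate:
    """One subject's plate: 5 conditions x 4 replicates plus the ground
    truth (the generating config and the injected per-condition band
    changes in log-power units)."""

    wells: list[WellRecording]
    truth: dict

    def wells_by_condition(self) -> dict[str, list[WellRecording]]:
        out: dict[str, list[WellRecording]] = {c: [] for c in CONDITIONS}
        for w in self.wells:
            out[w.condition].append(w)
        return out


def _shaped_noise(config: SpeckleSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped zero-mean Gaussian field, (n_pixels^2, n_time)."""
    n_px = config.n_pixels ** 2
    n_t = int(round((config.baseline_duration + config.post_duration)
                    * config.sampling_rate))
    white = rng.standard_normal((n_px, n_t)).astype(np.float32)
    spec = sfft.rfft(white, axis=1)
    freqs = sfft.rfftfreq(n_t, d=1.0 / config.sampling_rate)
    amp = np.zeros_like(freqs, dtype=np.float32)
    amp[1:] = 1.0 / np.sqrt(
        1.0 + (freqs[1:] / config.knee_frequency) ** config.spectral_slope
    )
    spec *= amp  # DC removed
    x = sfft.irfft(spec, n=n_t, axis=1)
    x *= config.fluctuation_sd / x.std()
    return x


def generate_baseline_speckle(
    config: SpeckleSimConfig,
    rng: np.random.Generator | None = None,
    **well_meta,
) -> WellRecording:
    """Stationary pre-drug speckle recording spanning baseline + post.

    Each pixel series is an independent realization of a stationary
    Gaussian process whose one-sided fluctuation spectrum follows
    ``S(f) ~ 1/(1 + (f/f_knee)^slope)``, superposed on ``mean_intensity``.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _shaped_noise(config, rng)
    intensities = config.mean_intensity + x
    # mean >> fluctuation sd in all defaults; floor guards pathological configs
    np.maximum(intensities, 1e-9 * config.mean_intensity, out=intensities)
    return WellRecording(
        intensities=intensities.astype(np.float32),
        sampling_rate=config.sampling_rate,
        drug_time=config.baseline_duration,
        **well_meta,
    )


def _onset_envelope(recording: WellRecording, onset: float) -> np.ndarray:
    """0 before drug application, linear ramp to 1 over ``onset`` seconds."""
    t = recording.times  # relative to drug application
    if onset == 0:
        return (t >= 0).astype(np.float64)
    return np.clip(t / onset, 0.0, 1.0)


def apply_drug_response(
    recording: WellRecording,
    config: SpeckleSimConfig,
    dose: str,
) -> WellRecording:
    """Inject a band-wise drug response into a baseline recording.

    After the drug time the log power of each frequency band is shifted by
    ``band_gains[band] * dose_scaling[dose]``, ramped linearly over
    ``onset_duration``; the signal before drug application is unchanged.
    Implemented by Fourier band decomposition of the fluctuation and a
    time-varying amplitude envelope per band, so the injected log-power
    change is exact once the ramp completes.

    Raises
    ------
    ConfigurationError
        For a dose label outside the allowed condition set.
    """
    config.validate()
    validate_condition(dose)
    if dose not in config.dose_scaling:
        raise ConfigurationError(
            f"dose {dose!r} missing from dose_scaling; configured doses: "
            f"{sorted(config.dose_scaling)}"
        )
    scale = config.dose_scaling[dose]
    x = np.asarray(recording.intensities, dtype=np.float32)
    means = x.mean(axis=1, keepdims=True)
    fluct = x - means
    spec = sfft.rfft(fluct, axis=1)
    freqs = sfft.rfftfreq(recording.n_time, d=1.0 / recording.sampling_rate)
    env = _onset_envelope(recording, config.onset_duration)

    out = None
    untouched = np.ones_like(freqs, dtype=bool)
    for band, (lo, hi) in BAND_EDGES.items():
        mask = (freqs >= lo) & ((freqs < hi) if band != "hi" else (freqs <= hi))
        untouched &= ~mask
        comp = sfft.irfft(spec * mask, n=recording.n_time, axis=1)
        gain = config.band_gains.get(band, 0.0) * scale
        comp *= np.exp(gain * env / 2.0).astype(np.float32)[None, :]
        out = comp if out is None else out + comp
    out += sfft.irfft(spec * untouched, n=recording.n_time, axis=1)
    out += means
    np.maximum(out, 1e-9 * float(means.mean()), out=out)
    return WellRecording(
        intensities=out.astype(np.float32),
        sampling_rate=recording.sampling_rate,
        drug_time=recording.drug_time,
        condition=dose,
        replicate=recording.replicate,
        subject_id=recording.subject_id,
    )


def generate_plate(
    config: SpeckleSimConfig, subject_id: str = "S0"
) -> SimulatedPlate:
    """Simulate one subject's plate: 4 replicate wells at each of the 5
    conditions, with per-well seeds derived deterministically from the
    master seed and the ground truth recorded alongside."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(CONDITIONS) * N_REPLICATES)
    wells = []
    injected = {
        cond: {
            band: config.band_gains.get(band, 0.0) * config.dose_scaling[cond]
            for band in BANDS
        }
        for cond in CONDITIONS
    }
    i = 0
    for cond in CONDITIONS:
        for rep in range(N_REPLICATES):
            rng = np.random.default_rng(children[i])
            base = generate_baseline_speckle(
                config, rng=rng, condition=cond, replicate=rep, subject_id=subject_id
            )
            wells.append(apply_drug_response(base, config, cond))
            i += 1
    truth = {"config": config, "injected_band_changes": injected}
    return SimulatedPlate(wells=wells, truth=truth)


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a subject cohort table directly at the biomarker level.

    Returns a DataFrame with columns ``subject_id``, the signal biomarker,
    any noise biomarkers (``Noise 1`` ...), ``pre_count`` and
    ``post_count`` (10^3 cells/uL). Latent sensitivity ``s ~ N(0,1)``;
    biomarker = effect*s + noise; proportionate drop = logistic(s);
    post = pre * (1 - drop), so all counts stay positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    s = rng.standard_normal(n)
    biomarker = (
        config.biomarker_effect * s
        + rng.normal(0.0, config.biomarker_noise_sd, size=n)
    )
    drop = 1.0 / (1.0 + np.exp(-config.drop_steepness * (s - config.drop_midpoint)))
    pre = rng.uniform(*config.pre_count_range, size=n)
    post = pre * (1.0 - drop)
    data = {"subject_id": [f"S{i + 1}" for i in range(n)],
            config.signal_biomarker: biomarker}
    for j in range(config.n_noise_biomarkers):
        data[f"Noise {j + 1}"] = rng.normal(
            0.0, max(config.biomarker_noise_sd, 1e-12), size=n
        )
    data["pre_count"] = pre
    data["post_count"] = post
    return pd.DataFrame(data)
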