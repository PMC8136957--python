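"""Fluctuation spectroscopy of dynamic-speckle recordings.

The instrument records temporal fluctuations of low-coherence light
back-scattered from living tissue; fluctuation frequency content between
0.01 and 12.5 Hz is a surrogate for intracellular motion, with a Doppler
frequency ``f`` mapping to a scatterer speed ``v = f * wavelength / (2 n)``
in backscatter geometry.

This module converts pixel x time intensity arrays into pixel-averaged
fluctuation power spectra (Welch estimates on a common log-frequency grid),
normalized-standard-deviation (NSD) time series, and physical speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ComputationError, DataError, RangeError

#: Frequency span of the assay, Hz.
FREQ_MIN = 0.01
FREQ_MAX = 12.5

#: Log-frequency grid density (bins per decade).
BINS_PER_DECADE = 50

#: Centre wavelength of the superluminescent light source, metres.
WAVELENGTH_M = 836.2e-9

#: Default refractive index (aqueous tissue).
REFRACTIVE_INDEX = 1.33


@dataclass
class WellRecording:
    """Intensity fluctuations of one tissue replicate under one condition.

    Parameters
    ----------
    intensities
        Array of shape (n_pixels, n_time), positive, arbitrary units.
    sampling_rate
        Frames per second, Hz.
    drug_time
        Seconds from the start of the recording at which the drug was
        applied; analysis times are reported relative to this instant.
    condition
        Dose label (see :mod:`biodyn.conditions`).
    replicate
        Replicate index within the condition.
    subject_id
        Identifier of the subject the tissue came from.
    """

    intensities: np.ndarray
    sampling_rate: float
    drug_time: float
    condition: str = "CTRL"
    replicate: int = 0
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise DataError("intensities must be a 2-D pixel x time array")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if not (0 < self.drug_time < self.duration):
            raise DataError("drug_time must fall inside the recording")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_time(self) -> int:
        return self.intensities.shape[1]

    @property
    def duration(self) -> float:
        """Total recording length in seconds."""
        return self.intensities.shape[1] / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to drug application."""
        return np.arange(self.n_time) / self.sampling_rate - self.drug_time


@dataclass
class FluctuationSpectrum:
    """Pixel-averaged one-sided fluctuation power spectrum.

    ``power`` is a spectral density (units^2 / Hz) on strictly increasing
    ``frequencies`` within [0.01, 12.5] Hz. ``window_center`` is the centre
    of the analysis window in seconds relative to drug application.
    """

    frequencies: np.ndarray
    power: np.ndarray
    window_center: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise DataError("frequencies and power must have the same shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise DataError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise DataError("power must be nonnegative")


@dataclass
class NSDSeries:
    """Normalized standard deviation per analysis window.

    NSD is the per-pixel standard deviation of the intensity fluctuations
    divided by the pixel's mean intensity, averaged over pixels — a global
    (full-spectrum) measure of aggregate intracellular motion. ``times``
    are window centres in seconds relative to drug application.
    """

    times: np.ndarray
    nsd: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nsd = np.asarray(self.nsd, dtype=float)
        if self.times.shape != self.nsd.shape:
            raise DataError("times and nsd must have the same shape")
        if np.any(self.nsd < 0):
            raise DataError("nsd must be nonnegative")


def log_frequency_grid(
    f_min: float = FREQ_MIN,
    f_max: float = FREQ_MAX,
    bins_per_decade: int = BINS_PER_DECADE,
) -> np.ndarray:
    """Fixed log-spaced frequency grid shared by all spectra.

    A common grid lets spectra and spectrograms from different wells be
    compared bin by bin regardless of record length.
    """
    n_decades = np.log10(f_max / f_min)
    n = int(round(n_decades * bins_per_decade)) + 1
    return np.geomspace(f_min, f_max, n)


def _welch_segment(recording: WellRecording, start: int, stop: int,
                   nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, 50%-overlap Welch density averaged over pixels."""
    seg = np.asarray(recording.intensities[:, start:stop], dtype=np.float64)
    seg = seg - seg.mean(axis=1, keepdims=True)
    freqs, pxx = signal.welch(
        seg,
        fs=recording.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, pxx.mean(axis=0)


def compute_power_spectrum(
    recording: WellRecording,
    window: float,
    window_center: float = 0.0,
    segment_length: float | None = None,
    log_grid: bool = True,
) -> FluctuationSpectrum:
    """Pixel-averaged fluctuation power spectrum of one analysis window.

    Parameters
    ----------
    recording
        Input well recording.
    window
        Analysis window length in seconds.
    window_center
        Window centre in seconds relative to drug application.
    segment_length
        Welch segment length in seconds (Hann taper, 50% overlap);
        defaults to half the window. A full-window segment yields the
        per-pixel periodogram averaged over pixels.
    log_grid
        If True (default), resample onto the shared log-frequency grid
        restricted to [max(1/segment, 0.01), min(12.5, Nyquist)] Hz. If
        False, return the raw Welch bins over the full frequency axis
        (used e.g. for Parseval checks).

    Raises
    ------
    RangeError
        If the window does not fit inside the recording.
    """
    fs = recording.sampling_rate
    center_abs = window_center + recording.drug_time
    start = int(round((center_abs - window / 2) * fs))
    stop = int(round((center_abs + window / 2) * fs))
    if start < 0 or stop > recording.n_time:
        raise RangeError(
            f"analysis window [{center_abs - window / 2:.1f}, "
            f"{center_abs + window / 2:.1f}] s exceeds recording bounds "
            f"[0, {recording.duration:.1f}] s"
        )
    if segment_length is None:
        segment_length = window / 2
    nperseg = min(stop - start, max(8, int(round(segment_length * fs))))
    freqs, pxx = _welch_segment(recording, start, stop, nperseg)

    if not log_grid:
        keep = freqs > 0
        return FluctuationSpectrum(freqs[keep], pxx[keep], window_center)

    f_lo = max(fs / nperseg, FREQ_MIN)
    f_hi = min(FREQ_MAX, fs / 2)
    grid = log_frequency_grid()
    grid = grid[(grid >= f_lo) & (grid <= f_hi)]
    if grid.size == 0:
        raise RangeError("no log-grid frequencies are resolvable for this window")
    keep = freqs > 0
    log_p = np.interp(np.log(grid), np.log(freqs[keep]), np.log(pxx[keep]))
    return FluctuationSpectrum(grid, np.exp(log_p), window_center)


def compute_nsd(recording: WellRecording, window: float) -> NSDSeries:
    """NSD time series over non-overlapping windows.

    For each window and pixel, std(intensity)/mean(intensity); the window
    value is the mean over pixels. Windows tile the recording from its
    start; the last partial window is dropped.

    Raises
    ------
    RangeError
        If not even one window fits.
    ComputationError
        If a pixel has zero mean intensity in some window (identifies the
        pixel and window).
    """
    fs = recording.sampling_rate
    w = int(round(window * fs))
    if w <= 1 or w > recording.n_time:
        raise RangeError(f"window of {window} s does not fit the recording")
    n_win = recording.n_time // w
    x = np.asarray(recording.intensities[:, : n_win * w], dtype=np.float64)
    x = x.reshape(recording.n_pixels, n_win, w)
    means = x.mean(axis=2)
    if np.any(means == 0):
        px, wi = np.argwhere(means == 0)[0]
        raise ComputationError(
            f"pixel {px} has zero mean intensity in window {wi}; NSD undefined"
        )
    stds = x.std(axis=2, ddof=1)
    nsd = (stds / means).mean(axis=0)
    centers = (np.arange(n_win) + 0.5) * w / fs - recording.drug_time
    return NSDSeries(centers, nsd)


def doppler_speed(
    frequency: float | np.ndarray,
    wavelength: float = WAVELENGTH_M,
    refractive_index: float = REFRACTIVE_INDEX,
) -> float | np.ndarray:
    """Scatterer speed for a Doppler fluctuation frequency, backscatter
    geometry: ``v = f * wavelength / (2 * n)`` in m/s.

    With the 836.2 nm source and n = 1.33 this maps the 0.01–12.5 Hz
    assay span to roughly 3 nm/s – 4 um/s.

    Raises
    ------
    DataError
        For nonpositive wavelength, refractive index < 1, or negative
        frequency.
    """
    if wavelength <= 0:
        raise DataError("wavelength must be positive")
    if refractive_index < 1:
        raise DataError("refractive_index must be >= 1")
    if np.any(np.asarray(frequency) < 0):
        raise DataError("frequency must be nonnegative")
    return frequency * wavelength / (2.0 * refractive_index)
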