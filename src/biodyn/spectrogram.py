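"""Drug-response spectrograms.

A drug-response spectrogram is a time x frequency map of the relative
change in fluctuation spectral power after drug application, normalized to
the pre-drug baseline: ``D(f, t) = ln S(f, t) - ln S0(f)``. Positive values
mean increased intracellular motion, negative values decreased motion.
Time t = 0 is the instant of drug application.

Values are in RU (relative units), here the log-relative spectral power.

Frequency bands (half-open, boundary assigned to the upper band):

- ``lo``  [0.01, 0.1) Hz — whole-cell scale motion (shape/integrity);
- ``mid`` [0.1, 0.5) Hz — membrane undulation and nuclear motion;
- ``hi``  [0.5, 12.5] Hz — organelle and vesicle transport.

The apoptotic response signature is increased lo- and hi-band motion with
decreased mid-band motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, DataError
from .spectra import FluctuationSpectrum, WellRecording, compute_power_spectrum

#: Band edges in Hz. Intervals are half-open [low, high); the top band is
#: closed above so the three bands partition [0.01, 12.5].
BAND_EDGES: dict[str, tuple[float, float]] = {
    "lo": (0.01, 0.1),
    "mid": (0.1, 0.5),
    "hi": (0.5, 12.5),
}

BANDS = tuple(BAND_EDGES)

#: Default analysis window and step, seconds.
DEFAULT_WINDOW = 1200.0
DEFAULT_STEP = 600.0


@dataclass
class DrugResponseSpectrogram:
    """Relative spectral change versus the pre-drug baseline.

    ``values[i, j]`` is ``ln S(frequencies[j], times[i]) - ln S0(frequencies[j])``
    with ``times`` in seconds relative to drug application (negative rows
    are baseline) and ``baseline_spectrum`` the time-averaged pre-drug
    spectrum used for normalization.
    """

    times: np.ndarray
    frequencies: np.ndarray
    values: np.ndarray
    baseline_spectrum: FluctuationSpectrum

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.frequencies.size):
            raise DataError("values must be a time x frequency matrix")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DataError("spectrogram values must be finite")


def band_mask(frequencies: np.ndarray, band: str) -> np.ndarray:
    """Boolean mask selecting the grid frequencies of one band.

    Bands are half-open [low, high) — a boundary frequency belongs to the
    upper band — except the top of the ``hi`` band, which is closed so the
    three masks partition the 0.01–12.5 Hz grid.

    Raises
    ------
    DataError
        For an unknown band name, listing the valid names.
    """
    if band not in BAND_EDGES:
        raise DataError(f"unknown band {band!r}; valid bands are {list(BAND_EDGES)}")
    low, high = BAND_EDGES[band]
    freqs = np.asarray(frequencies, dtype=float)
    if band == "hi":
        return (freqs >= low) & (freqs <= high)
    return (freqs >= low) & (freqs < high)


def compute_baseline_spectrum(
    recording: WellRecording,
    window: float = DEFAULT_WINDOW,
    segment_length: float | None = None,
) -> FluctuationSpectrum:
    """Time-averaged pre-drug spectrum.

    Averages the Welch spectra of all complete non-overlapping windows that
    fit in the baseline segment (tiled backwards from the drug time).

    Raises
    ------
    DataError
        If no complete baseline window exists.
    """
    n = int(recording.drug_time // window)
    if n < 1:
        raise DataError(
            f"baseline of {recording.drug_time:.0f} s holds no complete "
            f"{window:.0f} s window"
        )
    spectra = []
    for i in range(n):
        center = -(i + 0.5) * window  # relative to drug_time
        spectra.append(
            compute_power_spectrum(recording, window, center, segment_length)
        )
    freqs = spectra[0].frequencies
    power = np.mean([s.power for s in spectra], axis=0)
    return FluctuationSpectrum(freqs, power, window_center=-recording.drug_time / 2)


def compute_spectrogram(
    recording: WellRecording,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    segment_length: float | None = None,
) -> DrugResponseSpectrogram:
    """Drug-response spectrogram of one well.

    Windows of length ``window`` advance by ``step`` from the start of the
    recording; each row is the log-ratio of that window's spectrum to the
    baseline spectrum on the common log-frequency grid.

    Raises
    ------
    DataError
        If window or step is nonpositive or baseline is absent.
    ComputationError
        If the baseline spectrum contains zeros.
    """
    if window <= 0 or step <= 0:
        raise DataError("window and step must be positive")
    baseline = compute_baseline_spectrum(recording, window, segment_length)
    if np.any(baseline.power == 0):
        raise ComputationError("baseline spectrum contains zero power bins")
    log_s0 = np.log(baseline.power)

    times = []
    rows = []
    center_abs = window / 2
    while center_abs + window / 2 <= recording.duration + 1e-9:
        spec = compute_power_spectrum(
            recording, window, center_abs - recording.drug_time, segment_length
        )
        with np.errstate(divide="ignore"):
            rows.append(np.log(spec.power) - log_s0)
        times.append(center_abs - recording.drug_time)
        center_abs += step
    values = np.vstack(rows)
    if not np.all(np.isfinite(values)):
        raise ComputationError("spectrogram contains non-finite values")
    return DrugResponseSpectrogram(
        np.asarray(times), baseline.frequencies, values, baseline
    )


def export_spectrogram_csv(spec: DrugResponseSpectrogram, path) -> None:
    """Write the spectrogram as a CSV matrix (rows = time, columns =
    frequency) with a JSON sidecar carrying the axes."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(
        spec.values,
        index=pd.Index(spec.times, name="time_s"),
        columns=[f"{f:.6g}" for f in spec.frequencies],
    )
    df.to_csv(path, float_format="%.6g")
    sidecar = {
        "times_s": spec.times.tolist(),
        "frequencies_hz": spec.frequencies.tolist(),
        "units": "log-relative spectral power (RU)",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def plot_spectrogram(spec: DrugResponseSpectrogram, path=None):
    """Render the spectrogram as a log-frequency heatmap (red = motion
    increase, blue = decrease, horizontal line at drug application).

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 6))
    vmax = np.abs(spec.values).max() or 1.0
    mesh = ax.pcolormesh(
        spec.frequencies,
        spec.times / 3600.0,
        spec.values,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        shading="nearest",
    )
    ax.set_xscale("log")
    ax.axhline(0.0, color="k", lw=1.5)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("time from drug application (h)")
    fig.colorbar(mesh, ax=ax, label="log-relative spectral power (RU)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
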