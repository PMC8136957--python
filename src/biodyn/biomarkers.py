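"""Scalar motion biomarkers from spectrograms and NSD series.

Biomarkers are signed relative units (RU). *Local* biomarkers are band
means of the drug-response spectrogram (lo/mid/hi); the *global* biomarker
is the relative change in aggregate NSD from pre- to post-drug. Cross-dose
contrasts (e.g. ``Hi Dox 1/CTRL``, ``DNSD Dox 10/1``) are differences of
the log-relative quantities — "relative to" is subtraction here because RU
values are signed, so a ratio would be ill-defined.

Per-subject values are means over the four tissue replicates per
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, condition_display, dose_pairs
from .errors import ComputationError, DataError
from .spectra import NSDSeries, compute_nsd
from .spectrogram import (
    BANDS,
    DrugResponseSpectrogram,
    band_mask,
    compute_spectrogram,
)

#: Base biomarker names and their family.
BASE_FAMILIES = {"Lo": "local", "Mid": "local", "Hi": "local", "DNSD": "global"}

_BAND_TO_BASE = {"lo": "Lo", "mid": "Mid", "hi": "Hi"}

#: Default NSD window, seconds (10 min, non-overlapping).
DEFAULT_NSD_WINDOW = 600.0


@dataclass
class BiomarkerValue:
    """A named scalar biomarker for one subject.

    ``family`` is ``local`` when the value derives from a frequency band of
    the spectrogram and ``global`` when it derives from full-spectrum
    aggregates (NSD). ``condition_pair`` is (numerator, reference) for a
    contrast, or a single condition label.
    """

    name: str
    value: float
    family: str
    condition_pair: tuple[str, ...]
    subject_id: str = "S0"


@dataclass
class BiomarkerPanel:
    """Per-subject table of replicate-averaged biomarker values.

    ``values`` is a wide DataFrame (index = subject_id, columns =
    biomarker names, RU); ``families`` maps each column to local/global;
    ``replicates`` retains the per-replicate raw values (tidy) for
    provenance.
    """

    values: pd.DataFrame
    families: dict[str, str]
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.families)
        if missing:
            raise DataError(f"biomarkers without a family: {sorted(missing)}")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy CSV-ready frame: subject_id, biomarker, family, value."""
        long = self.values.reset_index().melt(
            id_vars="subject_id", var_name="biomarker", value_name="value"
        )
        long["family"] = long["biomarker"].map(self.families)
        return long[["subject_id", "biomarker", "family", "value"]]

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.8g")


def band_biomarker(spectrogram: DrugResponseSpectrogram, band: str) -> float:
    """Mean log-relative spectral change over one band and all post-drug
    times (t > 0): a local biomarker.

    Raises
    ------
    DataError
        If the band holds no grid frequencies or there are no post-drug
        rows.
    """
    fmask = band_mask(spectrogram.frequencies, band)
    tmask = spectrogram.times > 0
    if not fmask.any():
        raise DataError(f"band {band!r} holds no frequencies of this spectrogram")
    if not tmask.any():
        raise DataError("spectrogram has no post-drug rows")
    return float(spectrogram.values[np.ix_(tmask, fmask)].mean())


def delta_nsd(nsd: NSDSeries) -> float:
    """Relative change in aggregate motion: (mean post-drug NSD - mean
    pre-drug NSD) / mean pre-drug NSD. Signed, dimensionless; positive
    values mean increased aggregate intracellular motion.

    Raises
    ------
    DataError
        If pre- or post-drug windows are missing.
    ComputationError
        If the baseline NSD is zero.
    """
    pre = nsd.nsd[nsd.times < 0]
    post = nsd.nsd[nsd.times > 0]
    if pre.size == 0 or post.size == 0:
        raise DataError("NSD series needs both pre- and post-drug windows")
    base = float(pre.mean())
    if base == 0:
        raise ComputationError("baseline NSD is zero; DNSD undefined")
    return float((post.mean() - base) / base)


def contrast_biomarker(
    values: Mapping[str, float],
    numerator: str,
    reference: str,
    name: str | None = None,
    family: str = "local",
    subject_id: str = "S0",
) -> BiomarkerValue:
    """Cross-condition contrast: biomarker(numerator) - biomarker(reference).

    Raises
    ------
    DataError
        Naming a missing condition.
    """
    for cond in (numerator, reference):
        if cond not in values:
            raise DataError(f"condition {cond!r} missing from the panel values")
    if name is None:
        name = f"Dox {numerator}/{reference}"
    return BiomarkerValue(
        name=name,
        value=float(values[numerator]) - float(values[reference]),
        family=family,
        condition_pair=(numerator, reference),
        subject_id=subject_id,
    )


def average_replicates(values: Sequence[float]) -> tuple[float, int]:
    """Arithmetic mean across replicates plus the contributing count.

    Raises
    ------
    DataError
        For an empty list.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise DataError("no replicate values to average")
    return float(vals.mean()), int(vals.size)


def contrast_name(base: str, numerator: str, reference: str) -> str:
    """Name of a cross-dose contrast, e.g. ``Hi Dox 1/CTRL``."""
    return f"{base} Dox {numerator}/{reference}"


def condition_biomarker_name(base: str, condition: str) -> str:
    """Name of a per-condition biomarker, e.g. ``Hi Dox 10`` or ``Hi CTRL``."""
    return f"{base} {condition_display(condition)}"


def well_biomarkers(
    recording,
    window: float = 1200.0,
    step: float = 600.0,
    nsd_window: float = DEFAULT_NSD_WINDOW,
    segment_length: float | None = None,
) -> dict[str, float]:
    """All base biomarkers of a single well: lo/mid/hi band means and DNSD."""
    spec = compute_spectrogram(recording, window, step, segment_length)
    out = {
        _BAND_TO_BASE[band]: band_biomarker(spec, band) for band in BANDS
    }
    out["DNSD"] = delta_nsd(compute_nsd(recording, nsd_window))
    return out


def assemble_panel(
    plates: Mapping[str, "SimulatedPlate"] | Iterable[tuple[str, "SimulatedPlate"]],
    window: float = 1200.0,
    step: float = 600.0,
    nsd_window: float = DEFAULT_NSD_WINDOW,
    segment_length: float | None = None,
) -> BiomarkerPanel:
    """Reduce per-subject plates to a replicate-averaged biomarker panel.

    Per subject and condition, every replicate well yields the four base
    biomarkers (lo/mid/hi band means, DNSD); replicate means give the
    per-condition values, and all higher-vs-lower dose contrasts are added
    for every base (including the named ones, e.g. ``Hi Dox 1/CTRL``,
    ``Hi Dox 10/1``, ``DNSD Dox 10/CTRL``, ``DNSD Dox 10/1``).

    Raises
    ------
    DataError
        Listing, per subject, conditions with no replicates.
    """
    if isinstance(plates, Mapping):
        items = plates.items()
    else:
        items = plates

    rows = {}
    families: dict[str, str] = {}
    replicate_rows = []
    for subject_id, plate in items:
        by_cond = plate.wells_by_condition()
        missing = [c for c in CONDITIONS if not by_cond.get(c)]
        if missing:
            raise DataError(
                f"subject {subject_id!r} lacks replicates for conditions {missing}"
            )
        per_cond: dict[str, dict[str, float]] = {}
        for cond in CONDITIONS:
            per_rep = []
            for well in by_cond[cond]:
                vals = well_biomarkers(well, window, step, nsd_window, segment_length)
                per_rep.append(vals)
                for base, v in vals.items():
                    replicate_rows.append(
                        {
                            "subject_id": subject_id,
                            "condition": cond,
                            "replicate": well.replicate,
                            "biomarker": base,
                            "value": v,
                        }
                    )
            per_cond[cond] = {
                base: average_replicates([r[base] for r in per_rep])[0]
                for base in per_rep[0]
            }

        row: dict[str, float] = {}
        for base, family in BASE_FAMILIES.items():
            cond_values = {c: per_cond[c][base] for c in CONDITIONS}
            for cond in CONDITIONS:
                name = condition_biomarker_name(base, cond)
                row[name] = cond_values[cond]
                families[name] = family
            for num, ref in dose_pairs():
                name = contrast_name(base, num, ref)
                row[name] = contrast_biomarker(
                    cond_values, num, ref, name=name, family=family,
                    subject_id=subject_id,
                ).value
                families[name] = family
        rows[subject_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "subject_id"
    replicates = pd.DataFrame(replicate_rows)
    return BiomarkerPanel(values=values, families=families, replicates=replicates)


def panel_from_table(
    table: pd.DataFrame,
    families: Mapping[str, str] | None = None,
) -> BiomarkerPanel:
    """Wrap a wide subject x biomarker table (e.g. a simulated cohort CSV)
    into a panel; unknown biomarkers default to the local family."""
    df = table.copy()
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    df = df.drop(columns=[c for c in ("pre_count", "post_count") if c in df.columns])
    df = df.select_dtypes(include="number")
    if df.empty or not len(df.columns):
        raise DataError("cohort table holds no numeric biomarker columns")
    fams = {c: "local" for c in df.columns}
    for c in df.columns:
        if c.startswith("DNSD"):
            fams[c] = "global"
    if families:
        fams.update(families)
    return BiomarkerPanel(values=df.astype(float), families=fams)
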