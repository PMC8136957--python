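"""End-to-end orchestration and I/O.

Stages: simulate a study (per-subject plates + neutrophil counts) ->
drug-response spectrograms -> biomarker panel -> pooling/normalization/
one-hold-out selection -> neutrophil outcomes -> ROC summaries.

Formats: HDF5 for recordings (layout
``/wells/<condition>/<replicate>/intensities`` with attributes
``sampling_rate``, ``drug_time``, ``subject_id``), CSV for all tabular
artifacts, JSON for nested results and the run manifest, YAML for
configuration. All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import BiomarkerPanel, assemble_panel, panel_from_table
from .conditions import CONDITIONS, N_REPLICATES, validate_condition
from .errors import ConfigurationError, FormatError
from .outcomes import cohort_outcomes, label_endpoints
from .selection import normalize_panel, pool_biomarkers, rank_one_hold_out
from .simulate import SimulatedPlate, SpeckleSimConfig
from .spectra import WellRecording

logger = logging.getLogger("biodyn")

_WELL_ATTRS = ("sampling_rate", "drug_time", "subject_id")


def write_plate(path, plate: SimulatedPlate) -> None:
    """Write a plate to an HDF5 container (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        wells = f.create_group("wells")
        for well in plate.wells:
            grp = wells.require_group(well.condition).create_group(str(well.replicate))
            dset = grp.create_dataset("intensities", data=well.intensities)
            dset.attrs["sampling_rate"] = well.sampling_rate
            dset.attrs["drug_time"] = well.drug_time
            dset.attrs["subject_id"] = well.subject_id
        truth = dict(plate.truth)
        if isinstance(truth.get("config"), SpeckleSimConfig):
            truth["config"] = dataclasses.asdict(truth["config"])
        f.attrs["truth"] = json.dumps(truth)


def read_plate(path) -> SimulatedPlate:
    """Read a plate container written by :func:`write_plate`.

    Raises
    ------
    FormatError
        Naming the missing attribute/group or an invalid condition label.
    """
    wells = []
    with h5py.File(path, "r") as f:
        if "wells" not in f:
            raise FormatError("container lacks the /wells group")
        for cond in f["wells"]:
            try:
                validate_condition(cond)
            except ConfigurationError as exc:
                raise FormatError(str(exc)) from exc
            for rep in f["wells"][cond]:
                grp = f["wells"][cond][rep]
                if "intensities" not in grp:
                    raise FormatError(
                        f"well {cond}/{rep} lacks the intensities dataset"
                    )
                dset = grp["intensities"]
                for attr in _WELL_ATTRS:
                    if attr not in dset.attrs:
                        raise FormatError(
                            f"well {cond}/{rep} lacks required attribute {attr!r}"
                        )
                wells.append(
                    WellRecording(
                        intensities=dset[()],
                        sampling_rate=float(dset.attrs["sampling_rate"]),
                        drug_time=float(dset.attrs["drug_time"]),
                        condition=cond,
                        replicate=int(rep),
                        subject_id=str(dset.attrs["subject_id"]),
                    )
                )
        truth = json.loads(f.attrs.get("truth", "{}"))
    wells.sort(key=lambda w: (CONDITIONS.index(w.condition), w.replicate))
    return SimulatedPlate(wells=wells, truth=truth)


@dataclass
class StudySimConfig:
    """A full synthetic study: per-subject plates plus neutrophil counts.

    Each subject carries a latent marrow sensitivity ``s ~ N(0,1)`` that
    scales the injected band gains (logistic multiplier, so more sensitive
    marrow shows a stronger ex vivo drug response) and sets the in vivo
    proportionate neutrophil drop through the same logistic.
    """

    n_subjects: int = 10
    speckle: SpeckleSimConfig = field(default_factory=SpeckleSimConfig)
    sensitivity_steepness: float = 3.0
    sensitivity_midpoint: float = 0.0
    pre_count_range: tuple[float, float] = (4.0, 30.0)
    seed: int = 0

    def validate(self) -> "StudySimConfig":
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        lo, hi = self.pre_count_range
        if not (0 < lo < hi):
            raise ConfigurationError("pre_count_range must be positive and ordered")
        self.speckle.validate()
        return self


def simulate_study(config: StudySimConfig):
    """Yield ``(subject_id, plate)`` pairs and return the cohort counts.

    Returns
    -------
    plates : iterator of (subject_id, SimulatedPlate)
    cohort : DataFrame with subject_id, latent_sensitivity, pre_count,
        post_count.
    """
    from .simulate import generate_plate

    config.validate()
    rng = np.random.default_rng(config.seed)
    s = rng.standard_normal(config.n_subjects)
    multiplier = 1.0 / (
        1.0 + np.exp(-config.sensitivity_steepness * (s - config.sensitivity_midpoint))
    )
    pre = rng.uniform(*config.pre_count_range, size=config.n_subjects)
    post = pre * (1.0 - multiplier)
    subject_ids = [f"S{i + 1}" for i in range(config.n_subjects)]
    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "latent_sensitivity": s,
            "pre_count": pre,
            "post_count": post,
        }
    )

    def plates():
        for i, sid in enumerate(subject_ids):
            speckle = dataclasses.replace(
                config.speckle,
                band_gains={
                    b: g * multiplier[i] for b, g in config.speckle.band_gains.items()
                },
                seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                         % 2**31),
            )
            yield sid, generate_plate(speckle, subject_id=sid)

    return plates(), cohort


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run."""

    out_dir: str = "results/pipeline"
    plate_dir: str | None = None  # defaults to <out_dir>/plates
    cohort_csv: str | None = None  # run outcomes/ROC on an existing cohort
    study: StudySimConfig = field(default_factory=StudySimConfig)
    window: float = 300.0  # spectrogram window, s
    step: float = 300.0  # spectrogram step, s
    nsd_window: float = 120.0  # NSD window, s
    pooling_threshold: float = 0.9
    k: int = 4
    endpoint: str = "deep_drop"
    seed: int = 0
    log_level: str = "INFO"
    keep_plates: bool = False  # write HDF5 plate containers

    def validate(self) -> "PipelineConfig":
        if self.endpoint not in ("deep_drop", "grade2plus"):
            raise ConfigurationError(
                "endpoint must be 'deep_drop' or 'grade2plus'"
            )
        if self.window <= 0 or self.step <= 0 or self.nsd_window <= 0:
            raise ConfigurationError("window, step and nsd_window must be positive")
        self.study.seed = self.seed
        self.study.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study_raw = raw.pop("study", {})
        speckle_raw = study_raw.pop("speckle", {}) if isinstance(study_raw, dict) else {}
        speckle = SpeckleSimConfig(**speckle_raw)
        if "pre_count_range" in study_raw:
            study_raw["pre_count_range"] = tuple(study_raw["pre_count_range"])
        study = StudySimConfig(speckle=speckle, **study_raw)
        return cls(study=study, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_outcomes_stage(cohort: pd.DataFrame, out_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    outcomes = cohort_outcomes(cohort)
    labels = label_endpoints(outcomes)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False, float_format="%.8g")
    logger.info("outcomes: %d subjects", len(outcomes))
    return outcomes, labels


def run_pipeline(config: PipelineConfig, outcomes_only: bool = False) -> dict:
    """Run the full pipeline; returns a dict of output paths.

    Deterministic given ``config.seed``: rerunning writes byte-identical
    CSV outputs. With ``outcomes_only`` (requires ``cohort_csv``) only the
    outcome columns are computed.
    """
    from .roc import summaries_to_frame, summarize

    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
    }

    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv, dtype={"subject_id": str})
        logger.info("loaded cohort %s: %d subjects", config.cohort_csv, len(cohort))
    else:
        cohort = None

    if outcomes_only:
        if cohort is None:
            raise ConfigurationError("outcomes-only mode needs cohort_csv")
        run_outcomes_stage(cohort, out_dir)
        outputs["outcomes"] = str(out_dir / "outcomes.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        outputs["manifest"] = str(out_dir / "manifest.json")
        return outputs

    if cohort is not None and not {"pre_count", "post_count"} - set(cohort.columns):
        # biomarker-table cohort: skip the speckle stage
        panel = panel_from_table(cohort)
        logger.info("panel from cohort table: %d biomarkers", len(panel.biomarkers))
    else:
        plates, cohort = simulate_study(config.study)
        logger.info(
            "simulated study: %d subjects, %d wells each",
            config.study.n_subjects,
            len(CONDITIONS) * N_REPLICATES,
        )
        stored = []
        plate_dir = Path(config.plate_dir or out_dir / "plates")
        for sid, plate in plates:
            if config.keep_plates:
                write_plate(plate_dir / f"{sid}.h5", plate)
            stored.append((sid, plate))
        panel = assemble_panel(
            stored, window=config.window, step=config.step,
            nsd_window=config.nsd_window,
        )
        cohort.to_csv(out_dir / "cohort.csv", index=False, float_format="%.8g")
        outputs["cohort"] = str(out_dir / "cohort.csv")
        logger.info("panel assembled: %d biomarkers", len(panel.biomarkers))

    panel.to_csv(out_dir / "panel.csv")
    outputs["panel"] = str(out_dir / "panel.csv")

    outcomes, labels = run_outcomes_stage(cohort, out_dir)
    outputs["outcomes"] = str(out_dir / "outcomes.csv")
    endpoint_labels = labels[config.endpoint]

    pooled, pooling = pool_biomarkers(panel, config.pooling_threshold)
    normalized = normalize_panel(pooled)
    selection = rank_one_hold_out(normalized, endpoint_labels, k=config.k)
    selection.pooling = pooling
    (out_dir / "selection.json").write_text(
        json.dumps(selection.to_json_dict(), indent=1)
    )
    outputs["selection"] = str(out_dir / "selection.json")
    logger.info("selection: stable set %s", selection.stable)

    summaries = summarize(
        normalized, endpoint_labels, endpoint=config.endpoint,
        biomarkers=selection.stable or selection.ranking[: config.k],
    )
    frame = summaries_to_frame(summaries)
    frame.to_csv(out_dir / "roc_summary.csv", index=False, float_format="%.6g")
    outputs["roc_summary"] = str(out_dir / "roc_summary.csv")

    report = [
        f"biodyn pipeline report (config {manifest['config_hash']})",
        f"subjects: {len(cohort)}; endpoint: {config.endpoint} "
        f"({int(endpoint_labels.sum())} positive / {int((~endpoint_labels).sum())} negative)",
        f"stable biomarkers (one-hold-out stability 1.0, k={config.k}): "
        + (", ".join(selection.stable) if selection.stable else "none"),
        "",
        frame.to_string(index=False),
        "",
    ]
    (out_dir / "report.txt").write_text("\n".join(report))
    outputs["report"] = str(out_dir / "report.txt")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    outputs["manifest"] = str(out_dir / "manifest.json")
    logger.info("pipeline complete: %s", out_dir)
    return outputs
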