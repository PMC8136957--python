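"""Neutrophil outcome measures and endpoint labels.

Counts are in 10^3 cells/uL. Neutropenia is an absolute neutrophil count
below 3.0 (i.e. < 3,000 /uL), graded per VCOG-CTCAE v1.1:

- grade 0: >= 3.0
- grade 1: [1.5, 3.0)
- grade 2: [1.0, 1.5)
- grade 3: [0.5, 1.0)
- grade 4: < 0.5

Intervals are closed at the lower bound — the only convention consistent
with the reference cohort's printed grades. Two binary endpoints are
derived: a proportionate neutrophil decrease strictly greater than 50%
("deep drop"; a subject at exactly -0.500 is negative), and neutropenia of
grade >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError

#: Neutropenia threshold, 10^3 cells/uL.
NEUTROPENIA_THRESHOLD = 3.0

#: Lower bounds of grades 1..4, 10^3 cells/uL (closed at the lower bound).
GRADE_LOWER_BOUNDS = (1.5, 1.0, 0.5, 0.0)


@dataclass
class NeutrophilOutcome:
    """Pre/post neutrophil counts and derived outcome measures for one
    subject (counts in 10^3 cells/uL)."""

    subject_id: str
    pre_count: float
    post_count: float
    absolute_change: float
    proportionate_change: float
    vcog_grade: int
    neutropenic: bool


def assign_vcog_grade(post: float) -> int:
    """VCOG-CTCAE v1.1 neutropenia grade from the post-treatment count.

    Raises
    ------
    DataError
        For a negative count.
    """
    if post < 0:
        raise DataError("neutrophil count cannot be negative")
    if post >= NEUTROPENIA_THRESHOLD:
        return 0
    if post >= 1.5:
        return 1
    if post >= 1.0:
        return 2
    if post >= 0.5:
        return 3
    return 4


def compute_outcome(pre: float, post: float, subject_id: str = "S0") -> NeutrophilOutcome:
    """Outcome record from pre- and post-treatment counts.

    absolute change = post - pre; proportionate change = (post - pre)/pre;
    neutropenic iff post < 3.0 (x10^3/uL).

    Raises
    ------
    DataError
        For pre <= 0 or post < 0.
    """
    if pre <= 0:
        raise DataError("pre-treatment count must be positive")
    if post < 0:
        raise DataError("post-treatment count cannot be negative")
    return NeutrophilOutcome(
        subject_id=subject_id,
        pre_count=float(pre),
        post_count=float(post),
        absolute_change=float(post - pre),
        proportionate_change=float((post - pre) / pre),
        vcog_grade=assign_vcog_grade(post),
        neutropenic=post < NEUTROPENIA_THRESHOLD,
    )


def cohort_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`compute_outcome` to a cohort table.

    Expects columns ``subject_id``, ``pre_count``, ``post_count``; returns
    those plus ``absolute_change``, ``proportionate_change`` (also rounded
    to 3 decimals in ``proportionate_change_3dp``, the reporting
    convention), ``vcog_grade`` and ``neutropenic``.
    """
    required = {"subject_id", "pre_count", "post_count"}
    missing = required - set(cohort.columns)
    if missing:
        raise DataError(f"cohort table lacks columns {sorted(missing)}")
    records = [
        compute_outcome(row.pre_count, row.post_count, str(row.subject_id))
        for row in cohort.itertuples()
    ]
    out = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "pre_count": [r.pre_count for r in records],
            "post_count": [r.post_count for r in records],
            "absolute_change": [r.absolute_change for r in records],
            "proportionate_change": [r.proportionate_change for r in records],
            "vcog_grade": [r.vcog_grade for r in records],
            "neutropenic": [r.neutropenic for r in records],
        }
    )
    out["proportionate_change_3dp"] = out["proportionate_change"].round(3)
    return out


def label_endpoints(outcomes: pd.DataFrame | list[NeutrophilOutcome]) -> pd.DataFrame:
    """Binary endpoint labels per subject.

    ``deep_drop``: proportionate decrease strictly > 50% (change < -0.5);
    ``grade2plus``: VCOG grade >= 2.
    """
    if isinstance(outcomes, list):
        if not outcomes:
            raise DataError("no outcomes to label")
        outcomes = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in outcomes],
                "proportionate_change": [r.proportionate_change for r in outcomes],
                "vcog_grade": [r.vcog_grade for r in outcomes],
            }
        )
    if outcomes.empty:
        raise DataError("no outcomes to label")
    labels = pd.DataFrame(
        {
            "subject_id": outcomes["subject_id"].astype(str),
            "deep_drop": outcomes["proportionate_change"] < -0.5,
            "grade2plus": outcomes["vcog_grade"] >= 2,
        }
    )
    return labels.set_index("subject_id")


def grade_census(outcomes: pd.DataFrame) -> dict[int, int]:
    """Number of subjects at each VCOG grade (0-4)."""
    counts = outcomes["vcog_grade"].value_counts()
    return {g: int(counts.get(g, 0)) for g in range(5)}


def load_reference_cohort() -> pd.DataFrame:
    """The bundled 10-dog doxorubicin cohort (pre/post segmented neutrophil
    counts in 10^3 cells/uL, with tumour type)."""
    with resources.files("biodyn.data").joinpath(
        "canine_doxorubicin_cohort.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"subject_id": str})
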