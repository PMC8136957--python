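"""Biomarker selection: pooling, family-wise normalization, z-factor
scoring, and one-hold-out stability ranking.

The screening statistic is the standard z-factor (Zhang, Chung & Oldenburg
1999): ``Z = 1 - 3 (sigma_A + sigma_B) / |mu_A - mu_B|`` for the biomarker
distributions of the two outcome groups. Z <= 1 always; Z approaches 1 for
a perfectly separating assay and goes negative when the groups overlap
widely. The selection loop recomputes z-factors with each subject held out
in turn and keeps biomarkers that stay in the top-k in every fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerPanel
from .errors import DataError, StatisticsError


@dataclass
class ZFactorRecord:
    """z-factor of one biomarker between two outcome groups."""

    biomarker: str
    z_factor: float  # <= 1; NaN when undefined (equal group means)
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.z_factor)


@dataclass
class SelectionResult:
    """Outcome of the one-hold-out selection procedure.

    ``ranking`` orders biomarkers by mean z-factor across folds (best
    first); ``stability`` is the fraction of folds in which the biomarker
    landed in the per-fold top-k; ``stable`` lists the biomarkers with
    stability 1.0; ``fold_z`` is the per-fold z-factor table (folds x
    biomarkers); ``skipped_folds`` lists held-out subjects whose fold lost
    a label class; ``pooling`` maps pooled names to their members.
    """

    ranking: list[str]
    mean_z: pd.Series
    stability: pd.Series
    stable: list[str]
    fold_z: pd.DataFrame
    skipped_folds: list[str]
    pooling: dict[str, list[str]] = field(default_factory=dict)
    k: int = 1

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "ranking": self.ranking,
            "mean_z": {b: _jsonable(v) for b, v in self.mean_z.items()},
            "stability": {b: float(v) for b, v in self.stability.items()},
            "stable": self.stable,
            "fold_z": {
                str(f): {b: _jsonable(v) for b, v in row.items()}
                for f, row in self.fold_z.iterrows()
            },
            "skipped_folds": self.skipped_folds,
            "pooling": self.pooling,
        }


def _jsonable(v: float):
    return None if not np.isfinite(v) else float(v)


def z_factor(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Screening z-factor between two groups of biomarker values.

    Sample (n-1) standard deviations. Returns NaN (flagged undefined) when
    the group means coincide; a group of size 1 contributes SD 0 with a
    warning (deterministic group).

    Raises
    ------
    StatisticsError
        If either group is empty.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticsError("z-factor needs both groups nonempty")
    sds = []
    for name, g in (("A", a), ("B", b)):
        if g.size < 2:
            warnings.warn(
                f"group {name} has a single value; its SD is taken as 0",
                stacklevel=2,
            )
            sds.append(0.0)
        else:
            sds.append(float(g.std(ddof=1)))
    delta = abs(float(a.mean()) - float(b.mean()))
    if delta == 0:
        return float("nan")
    return 1.0 - 3.0 * (sds[0] + sds[1]) / delta


def z_factor_record(
    biomarker: str, group_a: Sequence[float], group_b: Sequence[float]
) -> ZFactorRecord:
    """z-factor plus the group summaries that produced it."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = z_factor(a, b)
    return ZFactorRecord(
        biomarker=biomarker,
        z_factor=z,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def pool_biomarkers(
    panel: BiomarkerPanel, correlation_threshold: float = 0.9
) -> tuple[BiomarkerPanel, dict[str, list[str]]]:
    """Pool closely associated biomarkers to improve signal-to-noise.

    Single-linkage grouping (connected components) on |Pearson r| >=
    threshold across subjects, computed within each family so pooled
    biomarkers keep a family for the later family-wise normalization.
    Pooled value = per-subject mean of the members; unpooled biomarkers
    pass through. Zero-variance biomarkers are excluded from pooling with
    a warning.

    Returns the pooled panel and the pooling map (pooled/unpooled name ->
    member list).
    """
    if not (0 < correlation_threshold <= 1):
        raise DataError("correlation_threshold must lie in (0, 1]")
    if len(panel.values) < 2:
        raise DataError("pooling needs at least two subjects")

    values = panel.values
    new_cols: dict[str, pd.Series] = {}
    families: dict[str, str] = {}
    pooling: dict[str, list[str]] = {}

    for family in sorted(set(panel.families.values())):
        cols = [c for c in values.columns if panel.families[c] == family]
        sds = values[cols].std(ddof=1)
        constant = [c for c in cols if sds[c] == 0 or not np.isfinite(sds[c])]
        if constant:
            warnings.warn(
                f"constant biomarkers excluded from pooling: {constant}",
                stacklevel=2,
            )
        active = [c for c in cols if c not in constant]
        # union-find over |r| >= threshold edges == single linkage
        parent = {c: c for c in active}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        if len(active) >= 2:
            corr = values[active].corr().abs()
            for i, c1 in enumerate(active):
                for c2 in active[i + 1 :]:
                    if corr.loc[c1, c2] >= correlation_threshold:
                        parent[find(c1)] = find(c2)
        groups: dict[str, list[str]] = {}
        for c in active:
            groups.setdefault(find(c), []).append(c)
        for members in groups.values():
            members = sorted(members, key=cols.index)
            if len(members) == 1:
                name = members[0]
                new_cols[name] = values[name]
            else:
                # compact name for wide pools; the pooling map keeps members
                if len(members) <= 3:
                    name = "Pool(" + " + ".join(members) + ")"
                else:
                    name = f"Pool({members[0]} + {len(members) - 1} others)"
                new_cols[name] = values[members].mean(axis=1)
            pooling[name] = members
            families[name] = family
        for c in constant:
            new_cols[c] = values[c]
            pooling[c] = [c]
            families[c] = family

    pooled = pd.DataFrame(new_cols, index=values.index)
    return BiomarkerPanel(values=pooled, families=families), pooling


def normalize_panel(panel: BiomarkerPanel) -> BiomarkerPanel:
    """Family-wise normalization: divide every biomarker by the smallest
    across-subject standard deviation within its family (local and global
    biomarkers normalized independently), so the least-variable biomarker
    of each family attains SD 1.

    Raises
    ------
    StatisticsError
        If some family has no biomarker with nonzero SD.
    """
    values = panel.values.copy()
    for family in sorted(set(panel.families.values())):
        cols = [c for c in values.columns if panel.families[c] == family]
        sds = values[cols].std(ddof=1)
        positive = sds[sds > 0]
        if positive.empty:
            raise StatisticsError(
                f"family {family!r} has no biomarker with nonzero SD; "
                "normalization undefined"
            )
        values[cols] = values[cols] / positive.min()
    return BiomarkerPanel(
        values=values, families=dict(panel.families), replicates=panel.replicates
    )


def _fold_z(values: pd.DataFrame, labels: pd.Series) -> pd.Series:
    pos = values[labels]
    neg = values[~labels]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in values.columns:
            out[col] = z_factor(pos[col], neg[col])
    return pd.Series(out)


def rank_one_hold_out(
    panel: BiomarkerPanel, labels: pd.Series, k: int = 4
) -> SelectionResult:
    """One-hold-out z-factor ranking with a stability criterion.

    For each held-out subject the z-factors of all biomarkers are
    recomputed on the remaining subjects; biomarkers are ranked by their
    mean z-factor across folds, and a biomarker's stability is the
    fraction of folds in which it fell in that fold's top-k. The stable
    set (stability 1.0) is the selection outcome. Folds that lose a label
    class are skipped with a warning and reported.

    Raises
    ------
    StatisticsError
        For fewer than 3 subjects or a single label class overall.
    """
    values = panel.values
    labels = labels.reindex(values.index).astype(bool)
    if labels.isna().any():
        raise DataError("labels missing for some subjects")
    n = len(values)
    if n < 3:
        raise StatisticsError("one-hold-out ranking needs at least 3 subjects")
    if labels.all() or (~labels).all():
        raise StatisticsError("both label classes must be present")

    fold_rows = {}
    skipped = []
    for held_out in values.index:
        rest = values.drop(index=held_out)
        rest_labels = labels.drop(index=held_out)
        if rest_labels.all() or (~rest_labels).all():
            warnings.warn(
                f"fold holding out {held_out!r} lost a label class; skipped",
                stacklevel=2,
            )
            skipped.append(str(held_out))
            continue
        fold_rows[held_out] = _fold_z(rest, rest_labels)
    if not fold_rows:
        raise StatisticsError("every fold lost a label class")
    fold_z = pd.DataFrame(fold_rows).T
    fold_z.index.name = "held_out"

    # NaN (undefined z) ranks below every finite value
    scored = fold_z.fillna(-np.inf)
    mean_z = scored.mean(axis=0)
    ranking = list(mean_z.sort_values(ascending=False).index)
    in_top = scored.rank(axis=1, ascending=False, method="min") <= k
    stability = in_top.mean(axis=0)
    stable = [b for b in ranking if stability[b] == 1.0]
    return SelectionResult(
        ranking=ranking,
        mean_z=mean_z,
        stability=stability,
        stable=stable,
        fold_z=fold_z,
        skipped_folds=skipped,
        k=k,
    )
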