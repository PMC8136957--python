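"""ROC analysis of biomarkers against binary endpoints.

AUC is the Mann-Whitney estimator (fraction of positive/negative pairs
ordered correctly, ties counted 1/2). Operating points maximize the Youden
index J = sensitivity - false-positive rate over midpoints between
adjacent distinct scores, with the score direction chosen so AUC >= 0.5.
The 95% confidence interval attached to each biomarker is the exact
binomial (Clopper-Pearson) interval on the classification accuracy at the
optimal cut-point — e.g. 10/10 correct at n=10 gives (0.692, 1.000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import BiomarkerPanel
from .errors import DataError, StatisticsError


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StatisticsError("scores and labels must be 1-D and aligned")
    if labels.all() or (~labels).all():
        raise StatisticsError("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie).

    Computed from midranks, which counts tied pairs as 1/2.

    Raises
    ------
    StatisticsError
        If only one class is present.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CutoffResult:
    """Optimal ROC operating point of one score vector."""

    cutoff: float
    direction: str  # ">=" (score >= cutoff positive) or "<="
    sensitivity: float  # percent
    fp_rate: float  # percent
    accuracy: float  # fraction correct
    youden: float  # J = sensitivity - FP rate, fractions

    def classify(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.direction == ">=":
            return scores >= self.cutoff
        return scores <= self.cutoff


def optimal_cutoff(scores, labels) -> CutoffResult:
    """Youden-optimal provisional cut-point.

    Candidate thresholds are midpoints between adjacent distinct scores;
    ties on J break toward higher sensitivity, then the lower threshold.
    The direction (``>=`` or ``<=``) is chosen so that AUC >= 0.5 for the
    thresholded score.

    Raises
    ------
    StatisticsError
        If only one class is present.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    direction = ">=" if auc(scores, labels) >= 0.5 else "<="
    work = scores if direction == ">=" else -scores

    uniq = np.unique(work)
    if uniq.size > 1:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        candidates = uniq
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for thr in candidates:
        pred = work >= thr
        sens = (pred & labels).sum() / n_pos
        fp = (pred & ~labels).sum() / n_neg
        j = sens - fp
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, fp)
    _, thr, sens, fp = best
    cutoff = thr if direction == ">=" else -thr
    pred = (work >= thr)
    accuracy = float((pred == labels).mean())
    return CutoffResult(
        cutoff=float(cutoff),
        direction=direction,
        sensitivity=float(sens * 100),
        fp_rate=float(fp * 100),
        accuracy=accuracy,
        youden=float(sens - fp),
    )


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval via beta
    quantiles. The lower bound is 0 when successes = 0 and the upper bound
    1 when successes = trials.

    Raises
    ------
    DataError
        For invalid counts or level.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise DataError("need 0 <= successes <= trials and trials >= 1")
    if not (0 < level < 1):
        raise DataError("level must lie in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        low = 0.0
    else:
        low = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        high = 1.0
    else:
        high = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


@dataclass
class ROCSummary:
    """Per-biomarker ROC summary mirroring the reporting table: AUC, exact
    binomial 95% CI on accuracy at the optimal cutoff, the cutoff with its
    direction, sensitivity %, false-positive %, accuracy, class sizes."""

    biomarker: str
    endpoint: str
    auc: float
    ci_low: float
    ci_high: float
    optimal_cutoff: float
    direction: str
    sensitivity: float
    fp_rate: float
    accuracy: float
    n_pos: int
    n_neg: int


def summarize(
    panel: BiomarkerPanel,
    labels: pd.Series,
    endpoint: str = "endpoint",
    biomarkers: list[str] | None = None,
) -> list[ROCSummary]:
    """ROC summary of each panel biomarker against one endpoint.

    ``labels`` is a boolean Series indexed by subject_id.

    Raises
    ------
    DataError
        Listing subjects present in only one of panel and labels.
    """
    values = panel.values
    mismatch = set(values.index).symmetric_difference(labels.index)
    if mismatch:
        raise DataError(f"panel and outcomes disagree on subjects: {sorted(map(str, mismatch))}")
    labels = labels.reindex(values.index).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    out = []
    for name in biomarkers or values.columns:
        scores = values[name].to_numpy(dtype=float)
        a = auc(scores, labels.to_numpy())
        cut = optimal_cutoff(scores, labels.to_numpy())
        correct = int(round(cut.accuracy * len(values)))
        low, high = clopper_pearson(correct, len(values))
        out.append(
            ROCSummary(
                biomarker=name,
                endpoint=endpoint,
                auc=a,
                ci_low=low,
                ci_high=high,
                optimal_cutoff=cut.cutoff,
                direction=cut.direction,
                sensitivity=cut.sensitivity,
                fp_rate=cut.fp_rate,
                accuracy=cut.accuracy,
                n_pos=n_pos,
                n_neg=n_neg,
            )
        )
    return out


def summaries_to_frame(summaries: list[ROCSummary]) -> pd.DataFrame:
    """Tabulate ROC summaries (one row per biomarker)."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def roc_points(scores, labels) -> pd.DataFrame:
    """Full ROC curve: (threshold, sensitivity, fp_rate) at every distinct
    score (``>=`` direction), for export/plotting."""
    scores, labels = _validate_scores_labels(scores, labels)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        rows.append(
            {
                "threshold": thr,
                "sensitivity": (pred & labels).sum() / n_pos,
                "fp_rate": (pred & ~labels).sum() / n_neg,
            }
        )
    return pd.DataFrame(rows)
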