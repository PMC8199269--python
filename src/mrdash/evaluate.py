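"""ROC-based score validation.

Builds the empirical ROC curve of an integer (or any real-valued) score,
computes the c-statistic (AUC) with a DeLong 95 % confidence interval,
selects the operating cutoff by minimal Euclidean distance to the ideal
point (0, 1) in (1 - specificity, sensitivity) space, and evaluates the
five split draws: the cutoff is chosen on each derivation cohort and applied
unchanged to the matching validation cohort (no leakage), with an optional
independently re-derived validation cutoff reported alongside.

Candidate cutoffs sit at midpoints between consecutive distinct observed
scores (half-integers for an integer score) plus sentinels; "screen
positive" means score strictly greater than the cutoff.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .cohort import SubjectRecord
from .score import ScoreDefinition, DrawResult, score_subjects

__all__ = [
    "RocCurve",
    "CutoffMetrics",
    "DrawEvaluation",
    "EvaluationReport",
    "roc_auc",
    "delong_ci",
    "optimal_cutoff",
    "cutoff_metrics",
    "evaluate_draws",
]


class RocCurve(BaseModel):
    """Empirical ROC curve with per-cutoff confusion counts.

    ``thresholds`` are ascending candidate cutoffs; at index i,
    ``tp[i]``/``fp[i]`` count subjects with score > thresholds[i], so the
    curve runs from (1,1) down to (0,0) as the cutoff rises.
    """

    thresholds: list[float]
    tp: list[int]
    fp: list[int]
    n_pos: int = Field(gt=0)
    n_neg: int = Field(gt=0)
    auc: float = Field(ge=0, le=1)
    auc_ci_low: float
    auc_ci_high: float

    @model_validator(mode="after")
    def _check(self) -> "RocCurve":
        if not self.auc_ci_low <= self.auc <= self.auc_ci_high:
            raise ValueError("CI must contain the AUC")
        return self

    @property
    def fpr(self) -> np.ndarray:
        return np.asarray(self.fp, float) / self.n_neg

    @property
    def tpr(self) -> np.ndarray:
        return np.asarray(self.tp, float) / self.n_pos


class CutoffMetrics(BaseModel):
    """Confusion-matrix metrics at one operating cutoff (positive: score > cutoff)."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]

    @model_validator(mode="after")
    def _identities(self) -> "CutoffMetrics":
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both classes must be present")
        return self


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC with trapezoid AUC and DeLong 95 % CI.

    The trapezoid AUC over midpoint cutoffs equals the tie-aware
    pair-counting concordance P(case > control) + 0.5 P(tie) exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 0.5], mids, [distinct[-1] + 0.5]])
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    # counts strictly above each threshold
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")

    # fpr and tpr are both non-increasing in the threshold, so reversing
    # yields the ROC path from (0,0) to (1,1) with vertical runs intact
    fpr = fp / n_neg
    tpr = tp / n_pos
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    lo, hi = delong_ci(s[y], s[~y])
    return RocCurve(
        thresholds=[float(t) for t in thresholds],
        tp=[int(v) for v in tp], fp=[int(v) for v in fp],
        n_pos=n_pos, n_neg=n_neg,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
    )


def _placements(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """For each x_i: fraction of ref strictly below, ties counted half."""
    ref_sorted = np.sort(ref)
    below = np.searchsorted(ref_sorted, x, side="left")
    below_or_eq = np.searchsorted(ref_sorted, x, side="right")
    return (below + 0.5 * (below_or_eq - below)) / len(ref)


def delong_ci(
    case_scores: np.ndarray, control_scores: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """DeLong variance-based CI for the AUC, clipped to [0, 1].

    Var(AUC) = S10/m + S01/n with S10 the sample variance of the case
    placement values and S01 that of the control placements.
    """
    x = np.asarray(case_scores, float)
    yv = np.asarray(control_scores, float)
    v10 = _placements(x, yv)
    v01 = 1.0 - _placements(yv, x)
    auc = float(v10.mean())
    var = 0.0
    if len(x) > 1:
        var += float(np.var(v10, ddof=1)) / len(x)
    if len(yv) > 1:
        var += float(np.var(v01, ddof=1)) / len(yv)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def cutoff_metrics(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> CutoffMetrics:
    """Confusion metrics at a fixed cutoff; positive means score > cutoff.

    PPV/NPV are None when no subject screens positive/negative.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    positive = s > cutoff
    tp = int((positive & y).sum())
    fp = int((positive & ~y).sum())
    fn = int((~positive & y).sum())
    tn = int((~positive & ~y).sum())
    return CutoffMetrics(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
    )


def optimal_cutoff(curve: RocCurve) -> CutoffMetrics:
    """Operating point minimizing the distance to (0, 1) on the ROC.

    distance = sqrt((1 - sensitivity)^2 + (1 - specificity)^2); exact ties
    resolve to the lower cutoff.
    """
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    dist = np.hypot(1.0 - sens, 1.0 - spec)
    best = int(np.argmin(dist))  # argmin takes the first, i.e. lowest cutoff
    cutoff = curve.thresholds[best]
    tp, fp = curve.tp[best], curve.fp[best]
    fn, tn = curve.n_pos - tp, curve.n_neg - fp
    return CutoffMetrics(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
    )


class DrawEvaluation(BaseModel):
    draw_index: int
    degenerate: bool = False
    derivation_roc: Optional[RocCurve] = None
    derivation_metrics: Optional[CutoffMetrics] = None
    validation_roc: Optional[RocCurve] = None
    # derivation-selected cutoff applied unchanged to the validation cohort
    validation_metrics: Optional[CutoffMetrics] = None
    # cutoff independently re-derived on the validation cohort, for comparison
    validation_rederived_metrics: Optional[CutoffMetrics] = None


class EvaluationReport(BaseModel):
    draws: list[DrawEvaluation]
    mean_derivation_auc: Optional[float]
    mean_validation_auc: Optional[float]
    derivation_auc_range: Optional[tuple[float, float]]
    validation_auc_range: Optional[tuple[float, float]]


def evaluate_draws(
    subjects: Sequence[SubjectRecord],
    draws: Sequence[DrawResult],
    score: ScoreDefinition,
) -> EvaluationReport:
    """Per-draw derivation/validation ROC analysis of the integer score.

    The operating cutoff is selected on the derivation subset only and
    applied unchanged to validation; validation labels never inform cutoff
    choice.  Draws whose derivation or validation subset contains a single
    outcome class are flagged degenerate and excluded from the summary
    means and ranges.
    """
    scores, _ = score_subjects(subjects, score)
    outcome = {s.id: s.af_status == "silent_af" for s in subjects}

    evals = []
    for draw in draws:
        entry = DrawEvaluation(draw_index=draw.draw_index)
        parts = {}
        for name, ids in (("derivation", draw.derivation_ids),
                          ("validation", draw.validation_ids)):
            ids = [i for i in ids if i in scores]
            vals = np.array([scores[i] for i in ids], float)
            labs = np.array([outcome[i] for i in ids], bool)
            if labs.all() or not labs.any() or len(np.unique(vals)) < 2:
                entry.degenerate = True
                parts = {}
                break
            parts[name] = (vals, labs)
        if not entry.degenerate:
            d_vals, d_labs = parts["derivation"]
            v_vals, v_labs = parts["validation"]
            entry.derivation_roc = roc_auc(d_vals, d_labs)
            entry.derivation_metrics = optimal_cutoff(entry.derivation_roc)
            entry.validation_roc = roc_auc(v_vals, v_labs)
            entry.validation_metrics = cutoff_metrics(
                v_vals, v_labs, entry.derivation_metrics.cutoff
            )
            entry.validation_rederived_metrics = optimal_cutoff(entry.validation_roc)
        evals.append(entry)

    good = [e for e in evals if not e.degenerate]
    d_aucs = [e.derivation_roc.auc for e in good]
    v_aucs = [e.validation_roc.auc for e in good]
    return EvaluationReport(
        draws=evals,
        mean_derivation_auc=float(np.mean(d_aucs)) if d_aucs else None,
        mean_validation_auc=float(np.mean(v_aucs)) if v_aucs else None,
        derivation_auc_range=(min(d_aucs), max(d_aucs)) if d_aucs else None,
        validation_auc_range=(min(v_aucs), max(v_aucs)) if v_aucs else None,
    )
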