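"""Risk-factor association analysis.

Group comparisons (chi-square for binary factors, t-test for age),
univariate 2x2 odds ratios, multivariable logistic regression with Wald
confidence intervals, and point-estimate poststratification weights.

Inference is Wald-based throughout (log-OR +/- 1.96 SE, normal p-values),
the convention of the mainstream clinical statistics packages this analysis
surface mirrors.  Weights act as frequency weights on point estimates only;
design-based (complex-survey) variances are deliberately out of scope and
weighted outputs are labelled as point-estimate-only.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, Field, model_validator
from scipy import stats

__all__ = [
    "OrEstimate",
    "WeightSpec",
    "FitError",
    "contingency_or",
    "group_tests",
    "fit_logistic",
    "poststratify",
]

Z95 = stats.norm.ppf(0.975)


class OrEstimate(BaseModel):
    """An odds ratio with its 95 % Wald interval and p-value."""

    factor: str
    odds_ratio: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)
    p_value: float = Field(ge=0, le=1)
    adjusted: bool = False
    n_used: int = 0
    continuity_corrected: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "OrEstimate":
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")
        return self


class WeightSpec(BaseModel):
    """Poststratification targets over joint strata cells.

    ``strata`` names the columns defining cells; ``target_shares`` maps the
    "|"-joined cell label (values in ``strata`` order) to its population
    share.  Weights are rescaled to mean 1.
    """

    strata: list[str]
    target_shares: dict[str, float]

    @model_validator(mode="after")
    def _shares(self) -> "WeightSpec":
        total = sum(self.target_shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"target shares must sum to 1, got {total}")
        if any(v < 0 for v in self.target_shares.values()):
            raise ValueError("target shares must be non-negative")
        return self


class FitError(RuntimeError):
    """Logistic fit failed (separation, non-convergence, or rank deficiency)."""


def contingency_or(
    exposed_cases: float,
    unexposed_cases: float,
    exposed_controls: float,
    unexposed_controls: float,
) -> OrEstimate:
    """Cross-product odds ratio from a 2x2 table with Wald CI and p.

    OR = (a*d)/(b*c) with a = exposed cases, b = unexposed cases,
    c = exposed controls, d = unexposed controls; SE(log OR) =
    sqrt(1/a + 1/b + 1/c + 1/d).  Any zero cell triggers the Haldane
    correction (0.5 added to every cell) and flags the estimate.
    """
    cells = [exposed_cases, unexposed_cases, exposed_controls, unexposed_controls]
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    corrected = any(c == 0 for c in cells)
    a, b, c, d = (x + 0.5 for x in cells) if corrected else cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OrEstimate(
        factor="exposure",
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        adjusted=False,
        n_used=int(round(sum(cells))),
        continuity_corrected=corrected,
    )


def group_tests(
    frame: pd.DataFrame,
    grouping: str = "af",
    factors: Optional[Sequence[str]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparison table: chi-square per binary factor, t-test for age.

    ``grouping`` is ``"af"`` (AF-negative vs all AF) or ``"saf"``
    (AF-negative vs silent AF).  The frame must carry an ``af_status``
    column as written by the phenotyping stage.  Chi-square is Pearson
    without continuity correction; the age t-test is pooled-variance by
    default with a Welch variant by flag.  Rows where any expected cell
    falls below 1 carry a warning annotation.
    """
    if grouping not in ("af", "saf"):
        raise ValueError("grouping must be 'af' or 'saf'")
    neg = frame[frame["af_status"] == "no_af"]
    if grouping == "af":
        pos = frame[frame["af_status"].isin(["symptomatic_af", "silent_af"])]
    else:
        pos = frame[frame["af_status"] == "silent_af"]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both comparison groups must be non-empty")
    if factors is None:
        factors = [c for c in frame.columns
                   if frame[c].dropna().isin([True, False, 0, 1]).all()
                   and c not in ("af_detected", "symptomatic", "latent_af")
                   and frame[c].notna().any()]

    rows = []
    t_stat, t_p = stats.ttest_ind(pos["age"], neg["age"], equal_var=not welch)
    rows.append({
        "factor": "age", "test": "t",
        "group_neg_mean": float(neg["age"].mean()),
        "group_pos_mean": float(pos["age"].mean()),
        "statistic": float(t_stat), "p_value": float(t_p), "warning": "",
    })
    for f in factors:
        table = np.array([
            [int(pos[f].sum()), int(len(pos) - pos[f].sum())],
            [int(neg[f].sum()), int(len(neg) - neg[f].sum())],
        ], dtype=float)
        warning = ""
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = 0.0, 1.0
            warning = "degenerate margin"
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if expected.min() < 1:
                warning = "expected cell < 1"
        rows.append({
            "factor": f, "test": "chi2",
            "group_neg_mean": float(neg[f].mean()),
            "group_pos_mean": float(pos[f].mean()),
            "statistic": float(chi2), "p_value": float(p), "warning": warning,
        })
    return pd.DataFrame(rows)


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
    maxiter: int = 100,
    tol: float = 1e-10,
) -> list[OrEstimate]:
    """Maximum-likelihood logistic regression; one :class:`OrEstimate` per column.

    An intercept is added internally and not reported.  Optional weights
    enter as frequency weights in the log-likelihood.  Raises
    :class:`FitError` on rank deficiency (listing collinear columns), on
    separation, or on non-convergence, naming the offending predictor.
    """
    X = design.astype(float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match design")
    if len(np.unique(y)) < 2:
        raise FitError("outcome has a single class")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify columns that do not increase rank when appended
        collinear = []
        base = Xc.to_numpy()[:, [0]]
        for j, name in enumerate(Xc.columns[1:], start=1):
            cand = np.column_stack([base, Xc.to_numpy()[:, j]])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                collinear.append(name)
            else:
                base = cand
        raise FitError(f"design is rank deficient; collinear columns: {collinear}")

    model = sm.GLM(y, Xc, family=sm.families.Binomial(),
                   freq_weights=None if weights is None else np.asarray(weights, float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(maxiter=maxiter, tol=tol)
        except Exception as err:  # PerfectSeparation and numerical failures
            raise FitError(f"logistic fit failed: {err}") from err
    params = result.params
    if not getattr(result, "converged", True) or np.abs(params).max() > 30:
        worst = params.drop("const").abs().idxmax()
        raise FitError(
            f"fit did not converge (possible separation); offending predictor: {worst}"
        )

    se = result.bse
    pvals = result.pvalues
    n_used = int(len(y) if weights is None else round(float(np.sum(weights))))
    out = []
    for name in X.columns:
        b, s = float(params[name]), float(se[name])
        out.append(OrEstimate(
            factor=str(name),
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * s)),
            ci_high=float(np.exp(b + Z95 * s)),
            p_value=float(pvals[name]),
            adjusted=X.shape[1] > 1,
            n_used=n_used,
        ))
    return out


def poststratify(frame: pd.DataFrame, target: WeightSpec) -> np.ndarray:
    """Per-subject poststratification weights, rescaled to mean 1.

    w_cell = target share / sample share over the joint strata cells.  A
    sample cell absent from the targets is an error (the weighting scheme
    must cover the sample).
    """
    cells = frame[target.strata].astype(str).agg("|".join, axis=1)
    sample_share = cells.value_counts(normalize=True)
    weights = np.empty(len(frame), dtype=float)
    for cell, share in sample_share.items():
        if cell not in target.target_shares:
            raise ValueError(f"sample cell {cell!r} has no target share")
        weights[cells.to_numpy() == cell] = target.target_shares[cell] / share
    return weights / weights.mean()
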