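"""MR-DASH score derivation.

The score is derived on the population without overt (symptomatic) AF.  That
population is split at random into a 2/3 derivation and 1/3 validation
cohort; a six-factor multivariable logistic model of silent AF — Male sex,
Renal failure (CKD), Diabetes, Age >= 75, Stroke/TIA, Heart failure — is fit
on the derivation cohort; and the whole procedure is repeated for five
independent draws to check consistency.

Integer points are then assigned per factor: a factor significant
(Wald p < alpha) in at least ``consistency_threshold`` draws (default 4 of 5)
scores the rounded mean of its odds ratios across draws (half away from
zero, floored at 1); a factor significant in fewer draws scores 1 point.
A subject's score is the sum of points over the factors present, so it lies
in [0, sum of all points].
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .association import FitError, OrEstimate, fit_logistic
from .cohort import SubjectRecord
from .phenotyping import AfStatus

__all__ = [
    "DEFAULT_SCORE_FACTORS",
    "ScoreBuilderConfig",
    "DrawResult",
    "ScoreDefinition",
    "split_population",
    "eligible_subjects",
    "score_model_frame",
    "run_draws",
    "assign_points",
    "score_subjects",
]

# Factor order mirrors the scale's acronym: M, R, D, A, S, H.
DEFAULT_SCORE_FACTORS: tuple[str, ...] = (
    "male", "ckd", "dm", "age_ge_75", "ics_tia", "heart_failure",
)


class ScoreBuilderConfig(BaseModel):
    n_draws: int = Field(default=5, ge=1)
    derivation_fraction: float = 2.0 / 3.0
    alpha: float = Field(default=0.05, gt=0, lt=1)
    consistency_threshold: int = Field(default=4, ge=1)
    factors: tuple[str, ...] = DEFAULT_SCORE_FACTORS
    age_cut: float = 75.0
    # average ORs over all draws, or over the significant draws only
    or_average: Literal["all_draws", "significant_draws"] = "all_draws"
    # manual per-factor overrides of the assigned points (e.g. to reproduce a
    # published variant); applied after the rule
    points_override: dict[str, int] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScoreBuilderConfig":
        if not 0.0 < self.derivation_fraction < 1.0:
            raise ValueError("derivation_fraction must be in (0,1)")
        if self.consistency_threshold > self.n_draws:
            raise ValueError("consistency_threshold cannot exceed n_draws")
        return self


class DrawResult(BaseModel):
    draw_index: int
    derivation_ids: list[str]
    validation_ids: list[str]
    estimates: dict[str, OrEstimate]

    @model_validator(mode="after")
    def _disjoint(self) -> "DrawResult":
        if set(self.derivation_ids) & set(self.validation_ids):
            raise ValueError("derivation and validation sets overlap")
        return self


class ScoreDefinition(BaseModel):
    """Per-factor integer points plus the per-draw evidence behind them."""

    points: dict[str, int]
    evidence: dict[str, dict]  # factor -> {significant_draws, ors, p_values}
    max_score: int
    age_cut: float = 75.0

    @model_validator(mode="after")
    def _consistent(self) -> "ScoreDefinition":
        if any(p < 1 for p in self.points.values()):
            raise ValueError("every included factor scores at least 1 point")
        if self.max_score != sum(self.points.values()):
            raise ValueError("max_score must equal the sum of points")
        return self


def split_population(
    eligible_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Simple random split into round(fraction*n) and the remainder.

    Deterministic per seed; input order does not matter (ids are sorted
    before permuting).
    """
    ids = sorted(eligible_ids)
    n = len(ids)
    if n < 2:
        raise ValueError(f"population too small to split (n={n})")
    k = int(np.floor(fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    derivation = [ids[i] for i in perm[:k]]
    validation = [ids[i] for i in perm[k:]]
    return derivation, validation


def eligible_subjects(subjects: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Subjects without overt AF: the silent-AF and AF-negative groups."""
    missing = [s.id for s in subjects if s.af_status is None]
    if missing:
        raise ValueError(
            f"{len(missing)} subjects lack af_status; run phenotyping first"
        )
    return [s for s in subjects if s.af_status != AfStatus.SYMPTOMATIC_AF.value]


def score_model_frame(
    subjects: Sequence[SubjectRecord],
    factors: Sequence[str] = DEFAULT_SCORE_FACTORS,
    age_cut: float = 75.0,
) -> pd.DataFrame:
    """Design frame for the score model: one binary column per factor plus
    the silent-AF outcome, indexed by subject id."""
    rows = []
    for s in subjects:
        row: dict[str, object] = {"id": s.id}
        for f in factors:
            row[f] = _factor_value(s, f, age_cut)
        row["saf"] = s.af_status == AfStatus.SILENT_AF.value
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def _factor_value(s: SubjectRecord, factor: str, age_cut: float) -> Optional[bool]:
    if factor == "age_ge_75":
        return bool(s.age >= age_cut)
    if factor == "male":
        return s.sex == "male"
    value = getattr(s, factor)
    return None if value is None else bool(value)


def run_draws(
    subjects: Sequence[SubjectRecord], cfg: ScoreBuilderConfig
) -> list[DrawResult]:
    """The repeated split-and-fit procedure.

    For each of ``cfg.n_draws`` draws: split the eligible (no-overt-AF)
    population 2/3–1/3, fit the six-factor silent-AF model on the derivation
    subset, and record the per-factor odds ratios.  A pure function of
    (cohort, cfg); draw d uses a child seed spawned from (cfg.seed, d).
    """
    eligible = eligible_subjects(subjects)
    if len(eligible) < 10:
        raise ValueError(f"eligible population too small (n={len(eligible)})")
    frame = score_model_frame(eligible, cfg.factors, cfg.age_cut)
    if frame[list(cfg.factors)].isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"missing factor flags {bad}; run phenotyping first")

    results = []
    for d in range(cfg.n_draws):
        child_seed = int(np.random.SeedSequence([cfg.seed, d]).generate_state(1)[0])
        derivation, validation = split_population(
            frame.index.tolist(), cfg.derivation_fraction, child_seed
        )
        sub = frame.loc[derivation]
        try:
            estimates = fit_logistic(sub[list(cfg.factors)], sub["saf"].to_numpy())
        except FitError as err:
            raise FitError(f"draw {d}: {err}") from err
        results.append(DrawResult(
            draw_index=d,
            derivation_ids=derivation,
            validation_ids=validation,
            estimates={e.factor: e for e in estimates},
        ))
    return results


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def assign_points(
    draws: Sequence[DrawResult], cfg: ScoreBuilderConfig | None = None
) -> ScoreDefinition:
    """Integer points from the per-draw evidence.

    A factor significant (p < alpha) in at least ``consistency_threshold``
    draws scores round(mean OR) — half away from zero, never below 1; a
    factor significant in fewer draws scores exactly 1.
    """
    cfg = cfg or ScoreBuilderConfig()
    if not draws:
        raise ValueError("need at least one draw")
    points: dict[str, int] = {}
    evidence: dict[str, dict] = {}
    factors = list(draws[0].estimates)
    for f in factors:
        ors = [d.estimates[f].odds_ratio for d in draws]
        pvals = [d.estimates[f].p_value for d in draws]
        n_sig = sum(p < cfg.alpha for p in pvals)
        if n_sig >= cfg.consistency_threshold:
            pool = (ors if cfg.or_average == "all_draws"
                    else [o for o, p in zip(ors, pvals) if p < cfg.alpha])
            pts = max(1, _round_half_away(float(np.mean(pool))))
        else:
            pts = 1
        if f in cfg.points_override:
            pts = cfg.points_override[f]
        points[f] = pts
        evidence[f] = {"significant_draws": n_sig, "ors": ors, "p_values": pvals}
    return ScoreDefinition(
        points=points, evidence=evidence,
        max_score=sum(points.values()), age_cut=cfg.age_cut,
    )


def score_subjects(
    subjects: Sequence[SubjectRecord], score: ScoreDefinition
) -> tuple[dict[str, int], list[tuple[str, str]]]:
    """Apply the score: per-subject sum of points over the factors present.

    Returns ``(scores, excluded)``; subjects missing a required flag are
    excluded with the offending factor logged.
    """
    scores: dict[str, int] = {}
    excluded: list[tuple[str, str]] = []
    for s in subjects:
        total = 0
        for f, pts in score.points.items():
            value = _factor_value(s, f, score.age_cut)
            if value is None:
                excluded.append((s.id, f))
                total = -1
                break
            total += pts * int(value)
        if total >= 0:
            scores[s.id] = total
    return scores, excluded
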