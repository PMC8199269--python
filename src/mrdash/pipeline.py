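"""End-to-end orchestration: simulate -> phenotype -> associate -> derive -> evaluate.

Each stage writes machine-readable JSON (the source of truth) and a CSV view
of the tabular reports, plus a run manifest carrying the config hash, seed
and library versions so every numeric output is traceable.  The pipeline is
a pure function of its config: rerunning with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .association import group_tests, fit_logistic, poststratify, WeightSpec
from .cohort import (
    MODEL_FACTORS, CohortSpec, SubjectRecord, cohort_to_frame, read_cohort,
    write_cohort,
)
from .evaluate import EvaluationReport, evaluate_draws
from .phenotyping import PhenotypeThresholds, phenotype_cohort
from .score import (
    DrawResult, ScoreBuilderConfig, ScoreDefinition, assign_points, run_draws,
)

__all__ = [
    "PipelineConfig", "PipelineResult", "run_pipeline",
    "prevalence_summary", "association_table", "draw_table", "metrics_table",
]


class PipelineConfig(BaseModel):
    """Configuration for a full run.

    A cohort is either loaded from ``cohort_csv`` or generated from
    ``cohort_spec``; ``seed`` overrides the cohort-spec and score-builder
    seeds so one integer reproduces the whole run.
    """

    cohort_csv: Optional[str] = None
    cohort_spec: CohortSpec = Field(default_factory=CohortSpec)
    thresholds: PhenotypeThresholds = Field(default_factory=PhenotypeThresholds)
    association_outcome: Literal["af", "saf"] = "saf"
    weighted: bool = False
    weight_spec: Optional[WeightSpec] = None
    score: ScoreBuilderConfig = Field(default_factory=ScoreBuilderConfig)
    out_dir: Optional[str] = None
    seed: Optional[int] = None


class PipelineResult(BaseModel):
    prevalences: dict[str, float]
    exclusions: list[tuple[str, str]]
    group_tests_af: Optional[list[dict]] = None
    group_tests_saf: Optional[list[dict]] = None
    or_table: list[dict]
    draws: list[DrawResult]
    score_definition: ScoreDefinition
    evaluation: EvaluationReport
    manifest: dict


def prevalence_summary(
    n_total: int,
    n_monitored: int,
    n_af: int,
    n_symptomatic_af: int,
    n_saf: int,
) -> dict[str, float]:
    """Headline prevalence arithmetic, on the percent scale reports print.

    Percentages of the total cohort are rounded to one decimal; the silent
    share of AF is rounded to the nearest whole percent.
    """
    if n_af != n_symptomatic_af + n_saf:
        raise ValueError("AF count must equal symptomatic + silent counts")
    return {
        "n_total": n_total,
        "monitored_pct": round(100.0 * n_monitored / n_total, 1),
        "af_pct": round(100.0 * n_af / n_total, 1),
        "symptomatic_af_pct": round(100.0 * n_symptomatic_af / n_total, 1),
        "saf_pct": round(100.0 * n_saf / n_total, 1),
        "saf_share_of_af_pct": round(100.0 * n_saf / n_af) if n_af else float("nan"),
    }


def association_table(
    subjects: Sequence[SubjectRecord],
    outcome: str = "saf",
    weights: Optional[np.ndarray] = None,
    factors: Sequence[str] = MODEL_FACTORS,
) -> list[dict]:
    """Multivariable OR table for overall AF or silent AF.

    For the silent-AF model, symptomatic-AF subjects are excluded so the
    contrast is silent AF vs no AF.  Age enters per 5 years above 65.
    """
    frame = cohort_to_frame(subjects)
    if outcome == "saf":
        keep = frame["af_status"] != "symptomatic_af"
        y = (frame.loc[keep, "af_status"] == "silent_af").to_numpy()
    elif outcome == "af":
        keep = frame["af_status"].notna()
        y = frame.loc[keep, "af_status"].isin(["silent_af", "symptomatic_af"]).to_numpy()
    else:
        raise ValueError("outcome must be 'af' or 'saf'")
    sub = frame.loc[keep]
    design = pd.DataFrame(index=sub.index)
    for f in factors:
        if f == "age5":
            design[f] = (sub["age"] - 65.0) / 5.0
        elif f == "male":
            design[f] = (sub["sex"] == "male").astype(float)
        else:
            design[f] = sub[f].astype(float)
    w = None if weights is None else np.asarray(weights)[keep.to_numpy()]
    ests = fit_logistic(design, y, weights=w)
    return [e.model_dump() for e in ests]


def draw_table(draws: Sequence[DrawResult], score: ScoreDefinition) -> pd.DataFrame:
    """Per-draw OR/CI/p table with the assigned points row appended."""
    factors = list(score.points)
    rows = []
    for d in draws:
        for f in factors:
            e = d.estimates[f]
            rows.append({
                "draw": d.draw_index + 1, "factor": f,
                "odds_ratio": e.odds_ratio, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "p_value": e.p_value,
            })
    table = pd.DataFrame(rows)
    pts = pd.DataFrame([
        {"draw": "points", "factor": f, "odds_ratio": score.points[f],
         "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan}
        for f in factors
    ])
    return pd.concat([table, pts], ignore_index=True)


def metrics_table(report: EvaluationReport) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV per draw and cohort, percent scale."""
    rows = []
    for e in report.draws:
        for cohort, m in (("derivation", e.derivation_metrics),
                          ("validation", e.validation_metrics)):
            if m is None:
                continue
            roc = e.derivation_roc if cohort == "derivation" else e.validation_roc
            rows.append({
                "draw": e.draw_index + 1, "cohort": cohort, "cutoff": m.cutoff,
                "auc": roc.auc, "auc_ci_low": roc.auc_ci_low,
                "auc_ci_high": roc.auc_ci_high,
                "sensitivity_pct": 100 * m.sensitivity,
                "specificity_pct": 100 * m.specificity,
                "ppv_pct": None if m.ppv is None else 100 * m.ppv,
                "npv_pct": None if m.npv is None else 100 * m.npv,
            })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage; write the report bundle when ``out_dir`` is set."""
    cfg = cfg.model_copy(deep=True)
    if cfg.seed is not None:
        cfg.cohort_spec.seed = cfg.seed
        cfg.score.seed = cfg.seed

    if cfg.cohort_csv is not None:
        subjects, _ = read_cohort(cfg.cohort_csv)
    else:
        from .cohort import generate_cohort
        subjects = generate_cohort(cfg.cohort_spec)

    phenotyped, exclusions = phenotype_cohort(subjects, cfg.thresholds)
    frame = cohort_to_frame(phenotyped)

    n_total = len(phenotyped)
    n_af = int((frame["af_status"] != "no_af").sum())
    n_saf = int((frame["af_status"] == "silent_af").sum())
    prevalences = prevalence_summary(
        n_total=n_total, n_monitored=n_total, n_af=n_af,
        n_symptomatic_af=n_af - n_saf, n_saf=n_saf,
    )

    weights = None
    if cfg.weighted:
        if cfg.weight_spec is None:
            raise ValueError("weighted=True requires a weight_spec")
        weights = poststratify(frame, cfg.weight_spec)

    tests_af = group_tests(frame, "af").to_dict("records")
    tests_saf = group_tests(frame, "saf").to_dict("records")
    or_table = association_table(
        phenotyped, outcome=cfg.association_outcome, weights=weights
    )

    draws = run_draws(phenotyped, cfg.score)
    score_def = assign_points(draws, cfg.score)
    evaluation = evaluate_draws(phenotyped, draws, score_def)

    # the hash fingerprints the analysis, not where its outputs land
    canonical = cfg.model_dump_json(exclude={"out_dir"})
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": cfg.seed if cfg.seed is not None else cfg.cohort_spec.seed,
        "mrdash_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_subjects": n_total,
        "n_excluded": len(exclusions),
    }

    result = PipelineResult(
        prevalences=prevalences, exclusions=exclusions,
        group_tests_af=tests_af, group_tests_saf=tests_saf,
        or_table=or_table, draws=draws, score_definition=score_def,
        evaluation=evaluation, manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_bundle(result, phenotyped, cfg)
    return result


def _write_bundle(
    result: PipelineResult, subjects: list[SubjectRecord], cfg: PipelineConfig
) -> None:
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(subjects, out / "cohort.csv",
                 cfg.cohort_spec if cfg.cohort_csv is None else None)
    (out / "prevalences.json").write_text(json.dumps(result.prevalences, indent=2))
    pd.DataFrame(result.group_tests_af).to_csv(out / "table1_af.csv", index=False)
    pd.DataFrame(result.group_tests_saf).to_csv(out / "table1_saf.csv", index=False)
    pd.DataFrame(result.or_table).to_csv(out / "table2.csv", index=False)
    (out / "table2.json").write_text(json.dumps(result.or_table, indent=2))
    draw_table(result.draws, result.score_definition).to_csv(
        out / "table3.csv", index=False)
    (out / "score_definition.json").write_text(
        result.score_definition.model_dump_json(indent=2))
    metrics_table(result.evaluation).to_csv(out / "table4.csv", index=False)
    (out / "evaluation.json").write_text(result.evaluation.model_dump_json(indent=2))
    roc_rows = []
    for e in result.evaluation.draws:
        for cohort, roc in (("derivation", e.derivation_roc),
                            ("validation", e.validation_roc)):
            if roc is None:
                continue
            for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
                roc_rows.append({"draw": e.draw_index + 1, "cohort": cohort,
                                 "threshold": t, "fpr": float(f), "tpr": float(s)})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
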