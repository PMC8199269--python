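"""Synthetic elderly-cohort generator.

Emulates the statistical structure of a nationwide prolonged-ECG screening
study of adults aged >= 65: n ~ 3014, age 77.5 +/- 7.9 truncated at 65,
binary risk-factor prevalences matching the study population, laboratory
values drawn so that guideline phenotyping reproduces the published condition
prevalences, and AF / silent-AF outcomes drawn from logistic models with the
published adjusted odds ratios, intercept-calibrated to the published
prevalences (overall AF 22.6 %, symptomatic 13.3 %, silent 9.3 %).

Subjects carry a list of confirmed ECG episode durations so that the
">30 s" AF rule is exercised end to end: every AF-positive subject has at
least one qualifying episode, and a configurable fraction of AF-negative
subjects carry only sub-30-s episodes.

Covariates are generated from a Gaussian copula that is diagonal by default
(independent covariates -- the study reports only marginals); pairwise
latent correlations can be switched on through ``CohortSpec.copula_corr``.
"""

from __future__ import annotations

import json
import math
import pathlib
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import optimize, special, stats

from .phenotyping import creatinine_for_egfr

__all__ = [
    "BINARY_FACTORS",
    "MODEL_FACTORS",
    "CohortSpec",
    "EcgEpisode",
    "SubjectRecord",
    "calibrate_intercept",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort",
    "read_cohort",
]

# Canonical factor order. "age5" is age in 5-year units above 65,
# (age - 65) / 5, the scale on which the age odds ratio is expressed.
BINARY_FACTORS: tuple[str, ...] = (
    "male",
    "mi",
    "chd",
    "thyroid",
    "pulmonary",
    "thromboembolism",
    "lead",
    "ics_tia",
    "pci_cabg",
    "dm",
    "heart_failure",
    "ha",
    "ckd",
    "physical_activity",
    "obesity",
    "hscrp_high",
    "ntprobnp_high",
)
MODEL_FACTORS: tuple[str, ...] = ("age5",) + BINARY_FACTORS

# Whole-population prevalences of the binary factors.
DEFAULT_PREVALENCES: dict[str, float] = {
    "male": 0.509,
    "mi": 0.148,
    "chd": 0.221,
    "thyroid": 0.139,
    "pulmonary": 0.120,
    "thromboembolism": 0.080,
    "lead": 0.138,
    "ics_tia": 0.121,
    "pci_cabg": 0.122,
    "dm": 0.292,
    "heart_failure": 0.223,
    "ha": 0.807,
    "ckd": 0.333,
    "physical_activity": 0.429,
    "obesity": 0.306,
    "hscrp_high": 0.187,
    "ntprobnp_high": 0.759,
}

# Adjusted odds ratios for overall AF and for silent AF (age per 5 years).
DEFAULT_AF_ORS: dict[str, float] = {
    "age5": 1.26,
    "male": 2.05,
    "mi": 0.96,
    "chd": 1.30,
    "thyroid": 1.44,
    "pulmonary": 0.87,
    "thromboembolism": 1.28,
    "lead": 0.96,
    "ics_tia": 1.28,
    "pci_cabg": 0.43,
    "dm": 1.39,
    "heart_failure": 2.98,
    "ha": 1.29,
    "ckd": 1.25,
    "physical_activity": 1.03,
    "obesity": 1.43,
    "hscrp_high": 0.89,
    "ntprobnp_high": 1.95,
}
DEFAULT_SAF_ORS: dict[str, float] = {
    "age5": 1.36,
    "male": 2.58,
    "mi": 0.68,
    "chd": 1.10,
    "thyroid": 1.41,
    "pulmonary": 0.67,
    "thromboembolism": 1.41,
    "lead": 1.11,
    "ics_tia": 1.59,
    "pci_cabg": 0.64,
    "dm": 1.48,
    "heart_failure": 2.06,
    "ha": 0.85,
    "ckd": 1.39,
    "physical_activity": 1.02,
    "obesity": 1.21,
    "hscrp_high": 0.83,
    "ntprobnp_high": 2.37,
}

# Conditional lab distributions given the latent condition flags. Values are
# chosen to be clinically plausible for an elderly population; the flag
# prevalences themselves come from DEFAULT_PREVALENCES, so phenotyping
# recovers them by construction (labs are truncated at the diagnostic
# cut-point on the side the flag dictates).
DEFAULT_LAB_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "hba1c": {
        "treated_frac": 0.80,  # diabetics on glucose-lowering agents
        "dm_mean": 7.1, "dm_sd": 1.1, "dm_lo": 4.8, "dm_hi": 13.0,
        "nondm_mean": 5.6, "nondm_sd": 0.45, "nondm_lo": 4.0, "nondm_hi": 6.49,
    },
    "bp": {
        "treated_frac": 0.75,  # hypertensives on antihypertensive drugs
        "treated_sbp_mean": 138.0, "treated_sbp_sd": 14.0,
        "treated_dbp_mean": 80.0, "treated_dbp_sd": 9.0,
        "untreated_sbp_mean": 150.0, "untreated_sbp_sd": 12.0,
        "untreated_dbp_mean": 84.0, "untreated_dbp_sd": 9.0,
        "normo_sbp_mean": 126.0, "normo_sbp_sd": 9.0,
        "normo_dbp_mean": 77.0, "normo_dbp_sd": 7.0,
    },
    "kidney": {
        "low_egfr_frac": 0.80,  # CKD via eGFR < 60 vs via albuminuria only
        "ckd_egfr_lo": 20.0, "ckd_egfr_hi": 59.5,
        "alb_egfr_lo": 60.0, "alb_egfr_hi": 95.0,
        "nonckd_egfr_lo": 60.5, "nonckd_egfr_hi": 105.0,
        "acr_norm_logmean": math.log(8.0), "acr_norm_logsd": 0.9,
        "acr_high_logmean": math.log(60.0), "acr_high_logsd": 0.8,
    },
    "bmi": {
        "obese_mean": 33.0, "obese_sd": 3.2, "obese_hi": 55.0,
        "nonobese_mean": 26.5, "nonobese_sd": 2.8, "nonobese_lo": 16.0,
    },
    "ntprobnp": {"high_logmean": math.log(400.0), "high_logsd": 0.9,
                 "low_logmean": math.log(70.0), "low_logsd": 0.5},
    "hscrp": {"high_logmean": math.log(9.0), "high_logsd": 0.6,
              "low_logmean": math.log(1.5), "low_logsd": 0.8},
}

REGIONS = ("north", "south", "east", "west")
REGION_PROBS = (0.25, 0.30, 0.25, 0.20)
URBAN_PROB = 0.60


class EcgEpisode(BaseModel):
    """One confirmed arrhythmia episode on the long-term ECG record."""

    start_offset: float = Field(ge=0.0, description="seconds from monitoring start")
    duration: float = Field(gt=0.0, description="episode duration in seconds")


class SubjectRecord(BaseModel):
    """One participant: raw fields plus phenotypes derived later.

    Derived fields (``egfr`` through ``af_status``) are ``None`` until the
    phenotyping stage fills them. ``latent_af`` and ``symptomatic`` are
    generator ground truth; phenotyping must recover ``latent_af`` from the
    episode list via the >30 s rule.
    """

    id: str
    age: float
    sex: Literal["male", "female"]
    region: str = "north"
    environment: Literal["urban", "rural"] = "urban"
    # self-reported history flags
    mi: bool = False
    chd: bool = False
    thyroid: bool = False
    pulmonary: bool = False
    thromboembolism: bool = False
    lead: bool = False
    ics_tia: bool = False
    pci_cabg: bool = False
    heart_failure: bool = False
    physical_activity: bool = False
    # medications
    antihypertensive: bool = False
    glucose_lowering: bool = False
    # laboratory and anthropometric measurements
    creatinine_mg_dl: Optional[float] = None
    acr_mg_g: Optional[float] = None
    hba1c_pct: Optional[float] = None
    ntprobnp_pg_ml: Optional[float] = None
    hscrp_mg_l: Optional[float] = None
    bmi: Optional[float] = None
    sbp_mmhg: Optional[float] = None
    dbp_mmhg: Optional[float] = None
    # monitoring
    episodes: list[EcgEpisode] = Field(default_factory=list)
    effective_monitoring_s: float = 0.0
    symptomatic: bool = False
    latent_af: bool = False
    # derived phenotypes (filled by mrdash.phenotyping)
    egfr: Optional[float] = None
    ha: Optional[bool] = None
    dm: Optional[bool] = None
    ckd: Optional[bool] = None
    obesity: Optional[bool] = None
    ntprobnp_high: Optional[bool] = None
    hscrp_high: Optional[bool] = None
    af_detected: Optional[bool] = None
    af_status: Optional[str] = None


class CohortSpec(BaseModel):
    """Generative parameters for a synthetic screening cohort.

    ``outcome_mode`` selects how the two outcomes are drawn:

    * ``"saf_first"`` (default): silent AF comes from a logistic model with
      the silent-AF odds ratios calibrated to ``target_saf_prevalence``;
      symptomatic AF is then drawn among the remaining subjects from the
      overall-AF odds ratios, calibrated so total AF hits
      ``target_af_prevalence``.  Silent-AF effect sizes are then exactly the
      specified ones, which is what score derivation exercises.
    * ``"af_first"``: overall AF comes from the overall-AF model; silent
      status among AF subjects is drawn from a symptom model in CHD, obesity
      and thyroid disease (the factors that predict overall but not silent
      AF), calibrated so the silent fraction of AF equals
      ``target_saf_prevalence / target_af_prevalence``.
    """

    n_subjects: int = Field(default=3014, ge=1)
    age_mean: float = 77.5
    age_sd: float = Field(default=7.9, gt=0)
    age_min: float = 65.0
    covariate_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    af_log_ors: dict[str, float] = Field(
        default_factory=lambda: {k: math.log(v) for k, v in DEFAULT_AF_ORS.items()}
    )
    saf_log_ors: dict[str, float] = Field(
        default_factory=lambda: {k: math.log(v) for k, v in DEFAULT_SAF_ORS.items()}
    )
    target_af_prevalence: float = Field(default=0.226, gt=0, lt=1)
    target_saf_prevalence: float = Field(default=0.093, gt=0, lt=1)
    outcome_mode: Literal["saf_first", "af_first"] = "saf_first"
    lab_distributions: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAB_DISTRIBUTIONS.items()}
    )
    # log-odds of AF symptoms given AF, used in "af_first" mode
    symptom_log_ors: dict[str, float] = Field(
        default_factory=lambda: {
            "chd": math.log(1.30), "obesity": math.log(1.43), "thyroid": math.log(1.44)
        }
    )
    # effective monitoring time: lognormal, median 23 d 10 h 26 min
    monitoring_median_s: float = Field(default=23 * 86400 + 10 * 3600 + 26 * 60, gt=0)
    monitoring_log_sd: float = Field(default=0.35, ge=0)
    monitoring_min_s: float = Field(default=720.0, gt=0)
    # fraction of AF-negative subjects carrying only sub-30-s episodes
    short_episode_rate: float = Field(default=0.08, ge=0, le=1)
    # symptom prevalence among subjects without AF (symptoms alone are not AF)
    background_symptom_rate: float = Field(default=0.05, ge=0, le=1)
    # optional Gaussian-copula latent correlations: (factor_a, factor_b, rho)
    copula_corr: list[tuple[str, str, float]] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name} outside [0,1]: {p}")
        if self.target_saf_prevalence >= self.target_af_prevalence:
            raise ValueError("silent-AF prevalence must be below overall AF prevalence")
        if self.age_min > self.age_mean:
            raise ValueError("age_min must not exceed age_mean")
        for side in (self.af_log_ors, self.saf_log_ors):
            for name in side:
                if name != "age5" and name not in self.covariate_prevalences:
                    raise ValueError(f"factor {name!r} has no generation rule")
        for a, b, rho in self.copula_corr:
            if a not in self.covariate_prevalences or b not in self.covariate_prevalences:
                raise ValueError(f"copula pair ({a}, {b}) not among generated covariates")
            if not -1.0 < rho < 1.0:
                raise ValueError("copula correlation must be in (-1, 1)")
        return self


class CalibrationError(RuntimeError):
    """Target prevalence cannot be reached by shifting the intercept."""


def calibrate_intercept(
    covariates: np.ndarray,
    log_ors: np.ndarray,
    target_prevalence: float,
    tol: float = 1e-10,
) -> float:
    """Intercept b0 with mean_i logistic(b0 + x_i . beta) = target.

    The mean predicted probability is strictly increasing in b0, so the root
    is found by bisection (Brent) on an expanding bracket.  Solved far below
    the 0.002 contract so calibration error never contributes to downstream
    prevalence checks.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise CalibrationError(f"target prevalence {target_prevalence} not in (0,1)")
    eta = np.asarray(covariates, dtype=float) @ np.asarray(log_ors, dtype=float)

    def mean_prev(b0: float) -> float:
        return float(np.mean(special.expit(b0 + eta)))

    lo, hi = -20.0, 20.0
    while mean_prev(lo) > target_prevalence:
        lo *= 2
        if lo < -1e6:  # pragma: no cover - defensive
            raise CalibrationError("target below achievable range")
    while mean_prev(hi) < target_prevalence:
        hi *= 2
        if hi > 1e6:  # pragma: no cover - defensive
            raise CalibrationError("target above achievable range")
    return float(
        optimize.brentq(lambda b: mean_prev(b) - target_prevalence, lo, hi, xtol=tol)
    )


def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lo: float = -np.inf,
    hi: float = np.inf,
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_lognorm(
    rng: np.random.Generator,
    logmean: float,
    logsd: float,
    size: int,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    log_lo = -np.inf if lo <= 0 else math.log(lo)
    log_hi = np.inf if math.isinf(hi) else math.log(hi)
    return np.exp(_truncnorm(rng, logmean, logsd, size, log_lo, log_hi))


def _draw_binary_covariates(spec: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Threshold a latent Gaussian copula at the normal quantile of each prevalence."""
    names = list(BINARY_FACTORS)
    extra = [k for k in spec.covariate_prevalences if k not in names]
    names += extra
    k = len(names)
    corr = np.eye(k)
    for a, b, rho in spec.copula_corr:
        ia, ib = names.index(a), names.index(b)
        corr[ia, ib] = corr[ib, ia] = rho
    n = spec.n_subjects
    if spec.copula_corr:
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, k)) @ chol.T
    else:
        z = rng.standard_normal((n, k))
    out = {}
    for j, name in enumerate(names):
        p = spec.covariate_prevalences.get(name, 0.0)
        out[name] = z[:, j] < stats.norm.ppf(p)
    return out


def _design_matrix(age5: np.ndarray, flags: dict[str, np.ndarray],
                   factor_names: Sequence[str]) -> np.ndarray:
    cols = []
    for name in factor_names:
        cols.append(age5 if name == "age5" else flags[name].astype(float))
    return np.column_stack(cols)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a cohort of :class:`SubjectRecord`; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = _truncnorm(rng, spec.age_mean, spec.age_sd, n, lo=spec.age_min)
    age5 = (age - 65.0) / 5.0
    flags = _draw_binary_covariates(spec, rng)

    factor_names = [k for k in MODEL_FACTORS if k in spec.saf_log_ors or k in spec.af_log_ors]
    X = _design_matrix(age5, flags, factor_names)
    beta_af = np.array([spec.af_log_ors.get(f, 0.0) for f in factor_names])
    beta_saf = np.array([spec.saf_log_ors.get(f, 0.0) for f in factor_names])

    if spec.outcome_mode == "saf_first":
        b0 = calibrate_intercept(X, beta_saf, spec.target_saf_prevalence)
        saf = rng.random(n) < special.expit(b0 + X @ beta_saf)
        # symptomatic AF among the rest, so that total AF hits its target
        rest = ~saf
        sympt_af = np.zeros(n, dtype=bool)
        if rest.any():
            want = spec.target_af_prevalence - spec.target_saf_prevalence
            sub_target = min(max(want * n / rest.sum(), 1e-9), 1 - 1e-9)
            b0s = calibrate_intercept(X[rest], beta_af, sub_target)
            sympt_af[rest] = rng.random(rest.sum()) < special.expit(b0s + X[rest] @ beta_af)
        latent_af = saf | sympt_af
    else:  # af_first
        b0 = calibrate_intercept(X, beta_af, spec.target_af_prevalence)
        latent_af = rng.random(n) < special.expit(b0 + X @ beta_af)
        sympt_af = np.zeros(n, dtype=bool)
        if latent_af.any():
            sympt_names = list(spec.symptom_log_ors)
            Xs = _design_matrix(age5[latent_af],
                                {k: v[latent_af] for k, v in flags.items()}, sympt_names)
            gamma = np.array([spec.symptom_log_ors[f] for f in sympt_names])
            sympt_frac = 1.0 - spec.target_saf_prevalence / spec.target_af_prevalence
            c0 = calibrate_intercept(Xs, gamma, sympt_frac)
            sympt_af[latent_af] = rng.random(latent_af.sum()) < special.expit(c0 + Xs @ gamma)
        saf = latent_af & ~sympt_af

    symptomatic = sympt_af.copy()
    no_af = ~latent_af
    symptomatic[no_af] = rng.random(no_af.sum()) < spec.background_symptom_rate

    labs = _draw_labs(spec, rng, age, flags)
    monitoring = np.maximum(
        np.exp(rng.normal(math.log(spec.monitoring_median_s), spec.monitoring_log_sd, n)),
        spec.monitoring_min_s,
    )
    episodes = _draw_episodes(spec, rng, latent_af, monitoring)

    region = rng.choice(len(REGIONS), size=n, p=REGION_PROBS)
    urban = rng.random(n) < URBAN_PROB

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(SubjectRecord.model_construct(
            id=f"S{i + 1:0{width}d}",
            age=float(age[i]),
            sex="male" if flags["male"][i] else "female",
            region=REGIONS[region[i]],
            environment="urban" if urban[i] else "rural",
            mi=bool(flags["mi"][i]),
            chd=bool(flags["chd"][i]),
            thyroid=bool(flags["thyroid"][i]),
            pulmonary=bool(flags["pulmonary"][i]),
            thromboembolism=bool(flags["thromboembolism"][i]),
            lead=bool(flags["lead"][i]),
            ics_tia=bool(flags["ics_tia"][i]),
            pci_cabg=bool(flags["pci_cabg"][i]),
            heart_failure=bool(flags["heart_failure"][i]),
            physical_activity=bool(flags["physical_activity"][i]),
            antihypertensive=bool(labs["antihypertensive"][i]),
            glucose_lowering=bool(labs["glucose_lowering"][i]),
            creatinine_mg_dl=float(labs["creatinine"][i]),
            acr_mg_g=float(labs["acr"][i]),
            hba1c_pct=float(labs["hba1c"][i]),
            ntprobnp_pg_ml=float(labs["ntprobnp"][i]),
            hscrp_mg_l=float(labs["hscrp"][i]),
            bmi=float(labs["bmi"][i]),
            sbp_mmhg=float(labs["sbp"][i]),
            dbp_mmhg=float(labs["dbp"][i]),
            episodes=episodes[i],
            effective_monitoring_s=float(monitoring[i]),
            symptomatic=bool(symptomatic[i]),
            latent_af=bool(latent_af[i]),
            egfr=None, ha=None, dm=None, ckd=None, obesity=None,
            ntprobnp_high=None, hscrp_high=None, af_detected=None, af_status=None,
        ))
    return records


def _draw_labs(
    spec: CohortSpec,
    rng: np.random.Generator,
    age: np.ndarray,
    flags: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Labs conditional on the latent condition flags.

    Each lab is truncated at its diagnostic cut-point on the side the flag
    dictates, so guideline phenotyping recovers the latent flags exactly and
    the flag prevalences land on their specified marginals.
    """
    n = spec.n_subjects
    L = spec.lab_distributions
    out: dict[str, np.ndarray] = {}

    # --- diabetes: HbA1c mixture + glucose-lowering treatment
    p = L["hba1c"]
    dm = flags["dm"]
    treated = dm & (rng.random(n) < p["treated_frac"])
    hba1c = _truncnorm(rng, p["nondm_mean"], p["nondm_sd"], n,
                       lo=p["nondm_lo"], hi=p["nondm_hi"])
    if treated.any():  # treated diabetics: HbA1c may be controlled below 6.5
        hba1c[treated] = _truncnorm(rng, p["dm_mean"], p["dm_sd"], treated.sum(),
                                    lo=p["dm_lo"], hi=p["dm_hi"])
    untreated_dm = dm & ~treated
    if untreated_dm.any():  # flag must come from the HbA1c criterion
        hba1c[untreated_dm] = _truncnorm(rng, p["dm_mean"], p["dm_sd"],
                                         untreated_dm.sum(), lo=6.5, hi=p["dm_hi"])
    out["hba1c"] = hba1c
    out["glucose_lowering"] = treated

    # --- hypertension: office BP + antihypertensive treatment
    p = L["bp"]
    ha = flags["ha"]
    on_drugs = ha & (rng.random(n) < p["treated_frac"])
    sbp = _truncnorm(rng, p["normo_sbp_mean"], p["normo_sbp_sd"], n, lo=85.0, hi=139.9)
    dbp = _truncnorm(rng, p["normo_dbp_mean"], p["normo_dbp_sd"], n, lo=45.0, hi=89.9)
    if on_drugs.any():
        m = on_drugs.sum()
        sbp[on_drugs] = _truncnorm(rng, p["treated_sbp_mean"], p["treated_sbp_sd"], m, lo=85.0)
        dbp[on_drugs] = _truncnorm(rng, p["treated_dbp_mean"], p["treated_dbp_sd"], m, lo=45.0)
    untreated_ha = ha & ~on_drugs
    if untreated_ha.any():  # flag must come from the BP criterion
        m = untreated_ha.sum()
        sbp[untreated_ha] = _truncnorm(rng, p["untreated_sbp_mean"],
                                       p["untreated_sbp_sd"], m, lo=140.0)
        dbp[untreated_ha] = _truncnorm(rng, p["untreated_dbp_mean"],
                                       p["untreated_dbp_sd"], m, lo=45.0)
    out["sbp"], out["dbp"] = sbp, dbp
    out["antihypertensive"] = on_drugs

    # --- kidney: target eGFR inverted through CKD-EPI to creatinine, plus ACR
    p = L["kidney"]
    ckd = flags["ckd"]
    low_egfr = ckd & (rng.random(n) < p["low_egfr_frac"])
    alb_only = ckd & ~low_egfr
    egfr_target = rng.uniform(p["nonckd_egfr_lo"], p["nonckd_egfr_hi"], n)
    egfr_target[low_egfr] = rng.uniform(p["ckd_egfr_lo"], p["ckd_egfr_hi"], low_egfr.sum())
    egfr_target[alb_only] = rng.uniform(p["alb_egfr_lo"], p["alb_egfr_hi"], alb_only.sum())
    male = flags["male"]
    creatinine = np.array([
        creatinine_for_egfr(egfr_target[i], age[i], "male" if male[i] else "female")
        for i in range(n)
    ])
    acr = _trunc_lognorm(rng, p["acr_norm_logmean"], p["acr_norm_logsd"], n, hi=29.9)
    if alb_only.any():  # flag must come from the albuminuria criterion
        acr[alb_only] = _trunc_lognorm(rng, p["acr_high_logmean"], p["acr_high_logsd"],
                                       alb_only.sum(), lo=30.0)
    if low_egfr.any():  # ACR unconstrained when eGFR already qualifies
        acr[low_egfr] = _trunc_lognorm(rng, p["acr_high_logmean"], p["acr_high_logsd"],
                                       low_egfr.sum())
    out["creatinine"], out["acr"] = creatinine, acr

    # --- BMI, biomarkers: truncated at the cut-point per flag
    p = L["bmi"]
    obese = flags["obesity"]
    bmi = _truncnorm(rng, p["nonobese_mean"], p["nonobese_sd"], n,
                     lo=p["nonobese_lo"], hi=29.9)
    if obese.any():
        bmi[obese] = _truncnorm(rng, p["obese_mean"], p["obese_sd"], obese.sum(),
                                lo=30.0, hi=p["obese_hi"])
    out["bmi"] = bmi

    for lab, flag_name, cut in (("ntprobnp", "ntprobnp_high", 125.0),
                                ("hscrp", "hscrp_high", 5.0)):
        p = L[lab]
        hi_flag = flags[flag_name]
        vals = _trunc_lognorm(rng, p["low_logmean"], p["low_logsd"], n, hi=cut)
        if hi_flag.any():  # strict ">" cut: nudge the lower truncation bound up
            vals[hi_flag] = _trunc_lognorm(rng, p["high_logmean"], p["high_logsd"],
                                           hi_flag.sum(), lo=cut * (1 + 1e-9))
        out[lab] = vals
    return out


def _draw_episodes(
    spec: CohortSpec,
    rng: np.random.Generator,
    latent_af: np.ndarray,
    monitoring: np.ndarray,
) -> list[list[EcgEpisode]]:
    """Episode lists: AF subjects get >=1 episode >30 s; a configurable
    fraction of AF-negative subjects get only sub-30-s episodes."""
    n = spec.n_subjects
    episodes: list[list[EcgEpisode]] = [[] for _ in range(n)]
    decoys = (~latent_af) & (rng.random(n) < spec.short_episode_rate)
    for i in range(n):
        subject_eps: list[EcgEpisode] = []
        if latent_af[i]:
            n_long = 1 + rng.poisson(1.5)
            durations = 30.0 + np.exp(rng.normal(math.log(240.0), 1.0, n_long))
            n_short = rng.poisson(0.7)
            if n_short:
                durations = np.concatenate([durations, rng.uniform(3.0, 30.0, n_short)])
        elif decoys[i]:
            durations = rng.uniform(3.0, 30.0, 1 + rng.poisson(0.5))
        else:
            continue
        for d in durations:
            d = float(min(d, monitoring[i] * 0.5))
            start = float(rng.uniform(0.0, max(monitoring[i] - d, 1.0)))
            subject_eps.append(EcgEpisode(start_offset=start, duration=d))
        episodes[i] = subject_eps
    return episodes


# ---------------------------------------------------------------------------
# serialization: CSV with a JSON episodes column, plus a JSON spec sidecar

_BOOL_COLS = [
    "mi", "chd", "thyroid", "pulmonary", "thromboembolism", "lead", "ics_tia",
    "pci_cabg", "heart_failure", "physical_activity", "antihypertensive",
    "glucose_lowering", "symptomatic", "latent_af",
]
_DERIVED_BOOL_COLS = ["ha", "dm", "ckd", "obesity", "ntprobnp_high",
                      "hscrp_high", "af_detected"]


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame; episodes become a JSON-encoded column."""
    rows = []
    for s in subjects:
        row = s.model_dump(exclude={"episodes"})
        row["episodes"] = json.dumps(
            [[e.start_offset, e.duration] for e in s.episodes]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for row in frame.to_dict("records"):
        eps = row.pop("episodes", "[]")
        if isinstance(eps, str):
            eps = json.loads(eps)
        row["episodes"] = [EcgEpisode(start_offset=a, duration=d) for a, d in eps]
        for col in _BOOL_COLS:
            if col in row and row[col] is not None and not pd.isna(row[col]):
                row[col] = bool(row[col])
        for col in _DERIVED_BOOL_COLS:
            if col in row:
                row[col] = None if pd.isna(row[col]) else bool(row[col])
        if "af_status" in row and pd.isna(row["af_status"]):
            row["af_status"] = None
        for col, val in row.items():
            if isinstance(val, float) and math.isnan(val):
                row[col] = None
        records.append(SubjectRecord(**row))
    return records


def write_cohort(
    subjects: Sequence[SubjectRecord],
    path: str | pathlib.Path,
    spec: CohortSpec | None = None,
) -> None:
    """Write ``cohort.csv`` plus, when a spec is given, a ``.spec.json`` sidecar."""
    path = pathlib.Path(path)
    cohort_to_frame(subjects).to_csv(path, index=False)
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(spec.model_dump_json(indent=2))


def read_cohort(path: str | pathlib.Path) -> tuple[list[SubjectRecord], CohortSpec | None]:
    path = pathlib.Path(path)
    frame = pd.read_csv(path)
    spec = None
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    if sidecar.exists():
        spec = CohortSpec.model_validate_json(sidecar.read_text())
    return frame_to_cohort(frame), spec
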