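"""Guideline-based clinical phenotyping.

Derives the condition flags used throughout the analysis from raw subject
fields: hypertension (office blood pressure or treatment), diabetes (HbA1c or
glucose-lowering treatment), chronic kidney disease (CKD-EPI 2009 eGFR or
albuminuria), obesity, biomarker elevation flags, and atrial-fibrillation
status from the list of confirmed ECG episodes.

AF positivity follows the ESC convention used in long-term screening studies:
a subject is AF-positive if and only if at least one confirmed episode lasts
strictly longer than 30 seconds.  Silent AF is detected AF in a subject
without AF symptoms.
"""

from __future__ import annotations

import enum
import math
from typing import TYPE_CHECKING, Iterable, Sequence

from pydantic import BaseModel, field_validator

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import EcgEpisode, SubjectRecord

__all__ = [
    "AfStatus",
    "PhenotypeThresholds",
    "egfr_ckd_epi_2009",
    "creatinine_for_egfr",
    "detect_af",
    "classify_saf",
    "classify_conditions",
    "phenotype_cohort",
]


class AfStatus(str, enum.Enum):
    """Exhaustive, mutually exclusive AF classification."""

    NO_AF = "no_af"
    SYMPTOMATIC_AF = "symptomatic_af"
    SILENT_AF = "silent_af"


class PhenotypeThresholds(BaseModel):
    """Clinical cut-points for the condition flags.

    Defaults are the guideline values used in the analysis: office BP
    140/90 mmHg, HbA1c 6.5 %, eGFR 60 mL/min/1.73 m2, ACR 30 mg/g,
    BMI 30 kg/m2, NT-proBNP 125 pg/mL, hsCRP 5 mg/L, and the 30 s minimum
    ECG episode duration for AF.  ``age_score_cut`` (75 years) is the
    dichotomization used by the risk score, kept here so every clinical
    cut-point lives in one place.

    Boundary semantics differ by flag and are preserved exactly:
    BP/HbA1c/ACR/BMI use ">=", eGFR uses "<", NT-proBNP and hsCRP use a
    strict ">", and the AF episode rule is strictly "longer than 30 s".
    """

    af_min_episode_s: float = 30.0
    sbp_mmhg: float = 140.0
    dbp_mmhg: float = 90.0
    hba1c_pct: float = 6.5
    egfr_ckd: float = 60.0
    acr_mg_g: float = 30.0
    bmi_obese: float = 30.0
    ntprobnp_pg_ml: float = 125.0
    hscrp_mg_l: float = 5.0
    age_score_cut: float = 75.0
    # CKD-EPI race coefficient; 1.0 for the population studied here.
    egfr_race_coefficient: float = 1.0

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be strictly positive")
        return v


def egfr_ckd_epi_2009(
    creatinine_mg_dl: float,
    age_years: float,
    sex: str,
    race_coefficient: float = 1.0,
) -> float:
    """Estimated GFR (mL/min/1.73 m2) by the CKD-EPI 2009 creatinine equation.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [if female] * race_coefficient

    with k = 0.7 (female) / 0.9 (male) and a = -0.329 (female) / -0.411
    (male).  The race coefficient defaults to 1.
    """
    if creatinine_mg_dl <= 0:
        raise ValueError(f"creatinine must be positive, got {creatinine_mg_dl}")
    if age_years < 18:
        raise ValueError("eGFR equation is defined for adults (age >= 18)")
    female = _is_female(sex)
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = creatinine_mg_dl / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
        * (1.018 if female else 1.0)
        * race_coefficient
    )
    return egfr


def creatinine_for_egfr(
    egfr: float, age_years: float, sex: str, race_coefficient: float = 1.0
) -> float:
    """Invert CKD-EPI 2009: the serum creatinine giving a target eGFR.

    The equation is piecewise in Scr with a breakpoint at Scr = k, strictly
    decreasing on each piece, so the inverse is closed-form.  Used by the
    cohort generator to produce creatinine values consistent with a target
    kidney-function profile.
    """
    if egfr <= 0:
        raise ValueError("target eGFR must be positive")
    female = _is_female(sex)
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    base = 141.0 * 0.993**age_years * (1.018 if female else 1.0) * race_coefficient
    ratio = egfr / base  # value of the power terms at the solution
    if ratio >= 1.0:  # Scr <= kappa branch
        return kappa * ratio ** (1.0 / alpha)
    return kappa * ratio ** (1.0 / -1.209)


def _is_female(sex: str) -> bool:
    s = str(sex).lower()
    if s in ("female", "f"):
        return True
    if s in ("male", "m"):
        return False
    raise ValueError(f"unrecognized sex {sex!r}")


def detect_af(
    episodes: Iterable["EcgEpisode"], thr: PhenotypeThresholds | None = None
) -> bool:
    """True iff any confirmed episode lasts strictly longer than 30 s.

    Durations are compared exactly as stored; an episode of exactly 30.0 s
    does not qualify.  An empty episode list is AF-negative.
    """
    thr = thr or PhenotypeThresholds()
    return any(ep.duration > thr.af_min_episode_s for ep in episodes)


def classify_saf(af_detected: bool, symptomatic: bool) -> AfStatus:
    """Silent AF is detected AF without symptoms; symptoms alone are not AF."""
    if af_detected:
        return AfStatus.SYMPTOMATIC_AF if symptomatic else AfStatus.SILENT_AF
    return AfStatus.NO_AF


_REQUIRED_LABS = (
    "sbp_mmhg",
    "dbp_mmhg",
    "hba1c_pct",
    "creatinine_mg_dl",
    "acr_mg_g",
    "bmi",
    "ntprobnp_pg_ml",
    "hscrp_mg_l",
)


class MissingFieldError(ValueError):
    """A lab required for phenotyping is absent (complete-case analysis)."""

    def __init__(self, subject_id: str, field: str):
        self.subject_id = subject_id
        self.field = field
        super().__init__(f"subject {subject_id}: missing {field}")


def classify_conditions(
    subject: "SubjectRecord", thr: PhenotypeThresholds | None = None
) -> "SubjectRecord":
    """Fill every derived phenotype on a copy of the subject record.

    Flags:
      HA       mean SBP >= 140 or mean DBP >= 90 or antihypertensive treatment
      DM       HbA1c >= 6.5 % or glucose-lowering treatment
      CKD      eGFR < 60 or ACR >= 30 mg/g (CKD-EPI 2009 eGFR)
      obesity  BMI >= 30
      NT-proBNP / hsCRP elevation use strict ">" at 125 pg/mL and 5 mg/L
      af_detected / af_status from the episode list and symptom flag

    Raises :class:`MissingFieldError` for any absent required lab; cohort-level
    wrappers turn this into a complete-case exclusion with a logged reason.
    """
    thr = thr or PhenotypeThresholds()
    for field in _REQUIRED_LABS:
        value = getattr(subject, field)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingFieldError(subject.id, field)

    out = subject.model_copy(deep=True)
    out.egfr = egfr_ckd_epi_2009(
        subject.creatinine_mg_dl, subject.age, subject.sex, thr.egfr_race_coefficient
    )
    out.ha = (
        subject.sbp_mmhg >= thr.sbp_mmhg
        or subject.dbp_mmhg >= thr.dbp_mmhg
        or subject.antihypertensive
    )
    out.dm = subject.hba1c_pct >= thr.hba1c_pct or subject.glucose_lowering
    out.ckd = out.egfr < thr.egfr_ckd or subject.acr_mg_g >= thr.acr_mg_g
    out.obesity = subject.bmi >= thr.bmi_obese
    out.ntprobnp_high = subject.ntprobnp_pg_ml > thr.ntprobnp_pg_ml
    out.hscrp_high = subject.hscrp_mg_l > thr.hscrp_mg_l
    out.af_detected = detect_af(subject.episodes, thr)
    out.af_status = classify_saf(out.af_detected, subject.symptomatic).value
    return out


def phenotype_cohort(
    subjects: Sequence["SubjectRecord"], thr: PhenotypeThresholds | None = None
) -> tuple[list["SubjectRecord"], list[tuple[str, str]]]:
    """Phenotype every subject; complete-case exclusion with a reason log.

    Returns ``(phenotyped, exclusions)`` where ``exclusions`` is a list of
    ``(subject_id, missing_field)`` pairs for subjects dropped because a
    required lab was absent.
    """
    thr = thr or PhenotypeThresholds()
    kept: list[SubjectRecord] = []
    excluded: list[tuple[str, str]] = []
    for subject in subjects:
        try:
            kept.append(classify_conditions(subject, thr))
        except MissingFieldError as err:
            excluded.append((err.subject_id, err.field))
    return kept, excluded
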