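"""Clinical definitions: CKD-EPI eGFR, condition flags, the >30 s AF rule."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mrdash.cohort import EcgEpisode, SubjectRecord
from mrdash.phenotyping import (
    AfStatus,
    MissingFieldError,
    PhenotypeThresholds,
    classify_conditions,
    classify_saf,
    creatinine_for_egfr,
    detect_af,
    egfr_ckd_epi_2009,
    phenotype_cohort,
)


def make_subject(**overrides) -> SubjectRecord:
    base = dict(
        id="X1", age=70.0, sex="male",
        creatinine_mg_dl=1.0, acr_mg_g=10.0, hba1c_pct=5.5,
        ntprobnp_pg_ml=100.0, hscrp_mg_l=1.0, bmi=25.0,
        sbp_mmhg=120.0, dbp_mmhg=75.0,
    )
    base.update(overrides)
    return SubjectRecord(**base)


class TestEgfr:
    # independently evaluated from the closed-form equation
    @pytest.mark.parametrize("creatinine,age,sex,expected", [
        (1.2, 70, "male", 60.9),
        (0.7, 65, "female", 90.9),
        (0.9, 65, "male", 89.3),   # Scr at the male knot: power terms vanish
        (2.0, 80, "female", 23.0),
        (0.5, 75, "male", 106.0),
    ])
    def test_matches_independent_evaluation(self, creatinine, age, sex, expected):
        assert egfr_ckd_epi_2009(creatinine, age, sex) == pytest.approx(
            expected, abs=0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.3, 5.0), st.floats(0.05, 1.0), st.floats(65, 95),
           st.sampled_from(["male", "female"]))
    def test_strictly_decreasing_in_creatinine(self, scr, delta, age, sex):
        assert egfr_ckd_epi_2009(scr + delta, age, sex) < egfr_ckd_epi_2009(
            scr, age, sex)

    def test_decreasing_in_age(self):
        assert egfr_ckd_epi_2009(1.0, 80, "male") < egfr_ckd_epi_2009(1.0, 70, "male")

    def test_female_factor_when_knot_ratios_coincide(self):
        # with Scr/knot > 1 both sexes share the -1.209 exponent, so the
        # only difference is the 1.018 multiplier
        ratio = 1.5
        female = egfr_ckd_epi_2009(0.7 * ratio, 72, "female")
        male = egfr_ckd_epi_2009(0.9 * ratio, 72, "male")
        assert female / male == pytest.approx(1.018, rel=1e-12)

    def test_race_coefficient_scales_linearly(self):
        assert egfr_ckd_epi_2009(1.1, 70, "male", race_coefficient=1.159) == (
            pytest.approx(1.159 * egfr_ckd_epi_2009(1.1, 70, "male"), rel=1e-12))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(15, 130), st.floats(65, 95), st.sampled_from(["male", "female"]))
    def test_inverse_round_trip(self, target, age, sex):
        scr = creatinine_for_egfr(target, age, sex)
        assert egfr_ckd_epi_2009(scr, age, sex) == pytest.approx(target, rel=1e-9)

    def test_rejects_nonpositive_creatinine(self):
        with pytest.raises(ValueError):
            egfr_ckd_epi_2009(0.0, 70, "male")


class TestDetectAf:
    def test_empty_episode_list_is_negative(self):
        assert detect_af([]) is False

    def test_thirty_seconds_exactly_does_not_qualify(self):
        eps = [EcgEpisode(start_offset=0, duration=25.0),
               EcgEpisode(start_offset=100, duration=30.0)]
        assert detect_af(eps) is False

    def test_single_qualifying_episode_suffices(self):
        eps = [EcgEpisode(start_offset=0, duration=29.0),
               EcgEpisode(start_offset=100, duration=31.0)]
        assert detect_af(eps) is True

    def test_duration_compared_exactly_no_rounding(self):
        assert detect_af([EcgEpisode(start_offset=0, duration=30.0000001)]) is True
        assert detect_af([EcgEpisode(start_offset=0, duration=29.9999999)]) is False


class TestClassifySaf:
    @pytest.mark.parametrize("af,sympt,expected", [
        (True, False, AfStatus.SILENT_AF),
        (True, True, AfStatus.SYMPTOMATIC_AF),
        (False, True, AfStatus.NO_AF),
        (False, False, AfStatus.NO_AF),
    ])
    def test_definition(self, af, sympt, expected):
        assert classify_saf(af, sympt) is expected

    def test_statuses_partition_cohort(self, default_cohort):
        counts = {s: 0 for s in AfStatus}
        for subject in default_cohort:
            counts[AfStatus(subject.af_status)] += 1
        assert sum(counts.values()) == len(default_cohort)
        assert all(v > 0 for v in counts.values())


class TestConditionFlags:
    def test_hypertension_requires_threshold_or_treatment(self):
        below = classify_conditions(make_subject(sbp_mmhg=139.0, dbp_mmhg=89.0))
        assert below.ha is False
        treated = classify_conditions(
            make_subject(sbp_mmhg=139.0, dbp_mmhg=89.0, antihypertensive=True))
        assert treated.ha is True
        assert classify_conditions(make_subject(sbp_mmhg=140.0)).ha is True
        assert classify_conditions(make_subject(dbp_mmhg=90.0)).ha is True

    def test_diabetes_hba1c_boundary_and_treatment(self):
        assert classify_conditions(make_subject(hba1c_pct=6.5)).dm is True
        assert classify_conditions(make_subject(hba1c_pct=6.49)).dm is False
        assert classify_conditions(
            make_subject(hba1c_pct=5.0, glucose_lowering=True)).dm is True

    def test_ckd_albuminuria_branch_at_preserved_egfr(self):
        # creatinine tuned so eGFR lands just above 60: CKD must then be
        # decided by the ACR >= 30 branch alone
        scr = creatinine_for_egfr(60.5, 70, "male")
        with_alb = classify_conditions(
            make_subject(creatinine_mg_dl=scr, acr_mg_g=30.0))
        assert with_alb.egfr >= 60.0
        assert with_alb.ckd is True
        without = classify_conditions(
            make_subject(creatinine_mg_dl=scr, acr_mg_g=29.0))
        assert without.ckd is False

    def test_ckd_low_egfr_branch(self):
        scr = creatinine_for_egfr(59.0, 70, "male")
        assert classify_conditions(
            make_subject(creatinine_mg_dl=scr, acr_mg_g=5.0)).ckd is True

    def test_obesity_bmi_boundary_inclusive(self):
        assert classify_conditions(make_subject(bmi=30.0)).obesity is True
        assert classify_conditions(make_subject(bmi=29.99)).obesity is False

    def test_biomarker_flags_are_strict_inequalities(self):
        at_cut = classify_conditions(
            make_subject(ntprobnp_pg_ml=125.0, hscrp_mg_l=5.0))
        assert at_cut.ntprobnp_high is False
        assert at_cut.hscrp_high is False
        above = classify_conditions(
            make_subject(ntprobnp_pg_ml=125.01, hscrp_mg_l=5.01))
        assert above.ntprobnp_high is True
        assert above.hscrp_high is True

    def test_af_status_filled_from_episodes_and_symptoms(self):
        eps = [EcgEpisode(start_offset=0, duration=60.0)]
        silent = classify_conditions(make_subject(episodes=eps, symptomatic=False))
        assert silent.af_detected is True
        assert silent.af_status == AfStatus.SILENT_AF.value
        overt = classify_conditions(make_subject(episodes=eps, symptomatic=True))
        assert overt.af_status == AfStatus.SYMPTOMATIC_AF.value


class TestCompleteCase:
    def test_missing_lab_raises_with_field_name(self):
        with pytest.raises(MissingFieldError, match="hba1c_pct"):
            classify_conditions(make_subject(hba1c_pct=None))

    def test_cohort_wrapper_logs_exclusions(self):
        subjects = [make_subject(id="A"),
                    make_subject(id="B", creatinine_mg_dl=None),
                    make_subject(id="C", bmi=float("nan"))]
        kept, excluded = phenotype_cohort(subjects)
        assert [s.id for s in kept] == ["A"]
        assert ("B", "creatinine_mg_dl") in excluded
        assert ("C", "bmi") in excluded

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeThresholds(sbp_mmhg=0)
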