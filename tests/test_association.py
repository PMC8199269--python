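"""Association surface: 2x2 ORs, group tests, logistic fits, weights."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrdash.association import (
    FitError, WeightSpec, contingency_or, fit_logistic, group_tests, poststratify,
)


def _random_2x2(rng, n=400):
    """A 2x2 dataset with no zero cells."""
    while True:
        x = rng.random(n) < rng.uniform(0.2, 0.8)
        p = np.where(x, rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8))
        y = rng.random(n) < p
        a = int((x & y).sum()); b = int((~x & y).sum())
        c = int((x & ~y).sum()); d = int((~x & ~y).sum())
        if min(a, b, c, d) > 0:
            return x, y, (a, b, c, d)


class TestContingencyOr:
    def test_study_male_gender_counts(self):
        # male/female split of the AF and no-AF groups in the study
        est = contingency_or(413, 267, 1122, 1212)
        assert est.odds_ratio == pytest.approx(1.67, abs=0.01)
        assert est.p_value < 0.001
        assert est.ci_low < est.odds_ratio < est.ci_high

    def test_balanced_table_is_null(self):
        est = contingency_or(10, 10, 10, 10)
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_swapping_exposure_inverts_or(self):
        a = contingency_or(30, 20, 15, 40)
        b = contingency_or(20, 30, 40, 15)
        assert b.odds_ratio == pytest.approx(1 / a.odds_ratio, rel=1e-12)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-12)

    def test_zero_cell_triggers_flagged_continuity_correction(self):
        est = contingency_or(0, 10, 10, 10)
        assert est.continuity_corrected is True
        assert est.odds_ratio == pytest.approx(0.5 * 10.5 / (10.5 * 10.5), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_or(-1, 5, 5, 5)

    def test_wald_se_formula(self):
        a, b, c, d = 40, 25, 30, 55
        est = contingency_or(a, b, c, d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(a * d / (b * c)) - 1.959963984540054 * se)
        assert est.ci_low == pytest.approx(lo, rel=1e-9)


def _status_frame(n_pos_male, n_pos, n_neg_male, n_neg):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n_pos):
        rows.append({"age": rng.normal(80, 7), "male": i < n_pos_male,
                     "af_status": "silent_af"})
    for i in range(n_neg):
        rows.append({"age": rng.normal(77, 8), "male": i < n_neg_male,
                     "af_status": "no_af"})
    return pd.DataFrame(rows)


class TestGroupTests:
    def test_identical_proportions_give_null_chi2(self):
        frame = _status_frame(50, 100, 100, 200)
        out = group_tests(frame, "saf", factors=["male"])
        row = out[out["factor"] == "male"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_study_male_gender_split_highly_significant(self):
        # 413/680 male among AF vs 1122/2334 among AF-negative
        frame = _status_frame(413, 680, 1122, 2334)
        out = group_tests(frame, "saf", factors=["male"])
        assert out[out["factor"] == "male"].iloc[0]["p_value"] < 0.001

    def test_chi2_equals_squared_two_proportion_z(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n1, n2 = rng.integers(30, 200, 2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            frame = _status_frame(int(k1), int(n1), int(k2), int(n2))
            chi2 = group_tests(frame, "saf", factors=["male"]).iloc[1]["statistic"]
            p1, p2 = k1 / n1, k2 / n2
            pooled = (k1 + k2) / (n1 + n2)
            z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            assert chi2 == pytest.approx(z**2, rel=1e-9)

    def test_age_t_test_pooled_matches_scipy(self):
        frame = _status_frame(40, 80, 100, 220)
        row = group_tests(frame, "saf", factors=[]).iloc[0]
        pos = frame[frame.af_status == "silent_af"]["age"]
        neg = frame[frame.af_status == "no_af"]["age"]
        t, p = stats.ttest_ind(pos, neg)
        assert row["statistic"] == pytest.approx(t)
        assert row["p_value"] == pytest.approx(p)

    def test_small_expected_cell_is_annotated(self):
        frame = _status_frame(1, 4, 2, 400)
        out = group_tests(frame, "saf", factors=["male"])
        assert out[out["factor"] == "male"].iloc[0]["warning"] == "expected cell < 1"


class TestFitLogistic:
    def test_single_binary_predictor_equals_cross_product_or(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, y, (a, b, c, d) = _random_2x2(rng)
            fitted = fit_logistic(pd.DataFrame({"x": x.astype(float)}), y)[0]
            table = contingency_or(a, b, c, d)
            assert fitted.odds_ratio == pytest.approx(table.odds_ratio, abs=1e-6)
            assert fitted.p_value == pytest.approx(table.p_value, abs=1e-6)

    def test_unit_weights_equal_unweighted_fit(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        y = rng.random(500) < 0.3
        plain = fit_logistic(X, y)
        weighted = fit_logistic(X, y, weights=np.ones(500))
        for e1, e2 in zip(plain, weighted):
            assert math.log(e2.odds_ratio) == pytest.approx(
                math.log(e1.odds_ratio), abs=1e-10)

    def test_null_outcome_gives_small_effects(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({f"x{i}": (rng.random(10_000) < 0.3).astype(float)
                          for i in range(5)})
        y = rng.random(10_000) < 0.2
        for est in fit_logistic(X, y):
            assert abs(math.log(est.odds_ratio)) < 0.25

    def test_frequency_weights_equal_row_duplication(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": (rng.random(200) < 0.5).astype(float)})
        y = rng.random(200) < 0.35
        w = rng.integers(1, 4, 200)
        dup_idx = np.repeat(np.arange(200), w)
        weighted = fit_logistic(X, y, weights=w.astype(float))[0]
        duplicated = fit_logistic(X.iloc[dup_idx].reset_index(drop=True), y[dup_idx])[0]
        assert weighted.odds_ratio == pytest.approx(duplicated.odds_ratio, rel=1e-8)

    def test_separation_failure_names_predictor(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        y = x > 0.5
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"noise": rng.normal(size=100), "culprit": x})
        with pytest.raises(FitError, match="culprit"):
            fit_logistic(X, y)

    def test_rank_deficiency_lists_collinear_columns(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=200)})
        y = rng.random(200) < 0.4
        with pytest.raises(FitError, match="b"):
            fit_logistic(X, y)

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"x": np.arange(20, dtype=float)})
        with pytest.raises(FitError):
            fit_logistic(X, np.zeros(20, dtype=bool))


class TestPoststratify:
    def test_matching_shares_give_unit_weights(self):
        frame = pd.DataFrame({"sex": ["male"] * 50 + ["female"] * 50})
        spec = WeightSpec(strata=["sex"], target_shares={"male": 0.5, "female": 0.5})
        assert np.allclose(poststratify(frame, spec), 1.0)

    def test_two_cell_ratio(self):
        frame = pd.DataFrame({"sex": ["male"] * 50 + ["female"] * 50})
        spec = WeightSpec(strata=["sex"], target_shares={"male": 0.6, "female": 0.4})
        w = poststratify(frame, spec)
        assert np.allclose(w[:50], 1.2) and np.allclose(w[50:], 0.8)

    def test_weighted_share_equals_target(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({"env": rng.choice(["urban", "rural"], 300, p=[0.7, 0.3])})
        spec = WeightSpec(strata=["env"], target_shares={"urban": 0.55, "rural": 0.45})
        w = poststratify(frame, spec)
        urban_share = w[(frame["env"] == "urban").to_numpy()].sum() / w.sum()
        assert urban_share == pytest.approx(0.55, abs=1e-12)

    def test_unmatched_sample_cell_fails(self):
        frame = pd.DataFrame({"env": ["urban", "rural"]})
        spec = WeightSpec(strata=["env"], target_shares={"urban": 1.0})
        with pytest.raises(ValueError, match="rural"):
            poststratify(frame, spec)

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WeightSpec(strata=["env"], target_shares={"urban": 0.5, "rural": 0.4})
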