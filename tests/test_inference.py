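"""Group inference: LME adjustment, contrasts, demographics, amyloid, ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.formula.api as smf

from fctopo.atlas import MACROAREAS, load_macroarea_table, macroarea_assign
from fctopo.inference import (
    adjusted_sex_contrast,
    attach_nearest_pet,
    chi_square_2x2,
    classify_amyloid,
    filter_eligibility,
    fit_lme_adjust,
    groupwise_regression_slope_test,
    sex_ttest,
    ttest_from_summary,
    two_way_anova,
)

warnings.filterwarnings("ignore", message=".*convergence.*")


def _covariates(rng, n, sex=None):
    return pd.DataFrame(
        {
            "sex": sex if sex is not None else rng.choice(["M", "F"], n),
            "age": rng.normal(72, 4, n),
            "education": rng.normal(16, 2, n),
            "handedness": rng.choice(["R", "L"], n, p=[0.9, 0.1]),
            "apoe4": rng.choice([0, 1], n, p=[0.7, 0.3]),
        }
    )


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ([[12, 36], [27, 47]], 0.18),   # APOE4 carriers by sex
            ([[43, 5], [63, 11]], 0.48),    # handedness by sex
            ([[25, 43], [44, 72]], 0.87),   # amyloid status by sex
        ],
    )
    def test_demographic_tables_round_to_published_values(self, table, expected_p):
        _, p = chi_square_2x2(table)
        assert round(p, 2) == expected_p

    def test_perfect_independence(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 7]])

    def test_textbook_closed_form(self):
        # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 12, 36, 27, 47
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        assert stat == pytest.approx(expected, abs=1e-10)


class TestTTestFromSummary:
    def test_age_row_reproduces_published_p(self):
        _, p = ttest_from_summary(72.2, 4.3, 77, 72.6, 4.5, 130)
        assert round(p, 2) == 0.53

    def test_equal_means_give_p_one(self):
        _, p = ttest_from_summary(5.0, 1.0, 20, 5.0, 2.0, 30)
        assert p == pytest.approx(1.0)

    def test_agrees_with_raw_data_ttest(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 55)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_sum, p_sum = ttest_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)


class TestLMEAdjust:
    def test_null_covariates_leave_values_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        n = 400
        cov = _covariates(rng, n)
        y = rng.standard_normal(n)
        adj = fit_lme_adjust(y, cov, np.arange(n))
        assert np.abs(adj.adjusted.to_numpy() - y).max() < 0.25

    def test_age_effect_is_removed(self):
        rng = np.random.default_rng(2)
        n_subj = 150
        n_sess = rng.choice([1, 2], n_subj)
        subj = np.repeat(np.arange(n_subj), n_sess)
        n = len(subj)
        cov = _covariates(rng, n_subj).iloc[subj].reset_index(drop=True)
        age_c = cov["age"] - cov["age"].mean()
        u = rng.normal(0, 0.5, n_subj)[subj]
        y = 2.0 * age_c + u + 0.3 * (cov["sex"] == "F") + rng.normal(0, 1, n)
        adj = fit_lme_adjust(y.to_numpy(), cov, subj)
        fit = stats.linregress(cov["age"][adj.adjusted.index],
                               adj.adjusted.to_numpy())
        assert abs(fit.slope) < 3 * fit.stderr

    def test_subject_variance_detected_from_duplicated_sessions(self):
        rng = np.random.default_rng(3)
        n_subj = 40
        subj = np.repeat(np.arange(n_subj), 2)
        cov = _covariates(rng, n_subj).iloc[subj].reset_index(drop=True)
        y = rng.normal(0, 1.0, n_subj)[subj] + rng.normal(0, 0.1, 2 * n_subj)
        adj = fit_lme_adjust(y, cov, subj)
        assert adj.var_subject > 5 * adj.var_residual
        # with BLUPs removed the within-subject pairs nearly coincide
        resid = adj.adjusted.to_numpy()
        assert np.std(resid) < 0.5 * np.std(y)

    def test_idempotence_on_adjusted_values(self):
        rng = np.random.default_rng(4)
        n = 300
        cov = _covariates(rng, n)
        y = 1.5 * (cov["age"] - cov["age"].mean()) + rng.standard_normal(n)
        once = fit_lme_adjust(y.to_numpy(), cov, np.arange(n))
        twice = fit_lme_adjust(once.adjusted.to_numpy(), cov, np.arange(n))
        assert np.abs(twice.adjusted.to_numpy()
                      - once.adjusted.to_numpy()).max() < 0.05


class TestSexTTest:
    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        sex = np.array(["M"] * 200 + ["F"] * 200)
        res = sex_ttest(vals, sex, n_comparisons=94)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p * 94))
        assert res.p_bonferroni >= res.p

    def test_women_lower_gives_negative_t(self):
        rng = np.random.default_rng(6)
        men = rng.normal(1.0, 1, 300)
        women = rng.normal(0.2, 1, 300)
        res = sex_ttest(np.concatenate([men, women]),
                        np.array(["M"] * 300 + ["F"] * 300))
        assert res.t < 0
        assert res.mean_women < res.mean_men

    def test_corrected_p_example(self):
        # raw p = 0.0005 over 94 comparisons -> 0.047
        assert min(1.0, 0.0005 * 94) == pytest.approx(0.047)

    def test_subject_level_collapse(self):
        vals = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        sex = np.array(["M", "M", "M", "F", "F", "F"])
        subj = np.array(["a", "a", "b", "c", "c", "d"])
        res = sex_ttest(vals, sex, subject_ids=subj, level="subject")
        # subject means: a=2, b=5 vs c=3, d=6
        assert res.n_men == 2 and res.n_women == 2
        assert res.mean_men == pytest.approx(3.5)
        assert res.mean_women == pytest.approx(4.5)


class TestAmyloidClassification:
    def _sessions(self, suvr, gap_days):
        return pd.DataFrame(
            {
                "session_id": [f"s{i}" for i in range(len(suvr))],
                "mri_date": pd.Timestamp("2013-06-01"),
                "pet_date": [
                    pd.Timestamp("2013-06-01") + pd.Timedelta(days=g)
                    if g is not None else pd.NaT
                    for g in gap_days
                ],
                "suvr": suvr,
            }
        )

    def test_positive_negative_unknown_boundaries(self):
        sess = self._sessions([1.20, 1.11, 1.30, 1.05, np.nan],
                              [100, -30, 400, 365, None])
        status = classify_amyloid(sess)
        assert list(status) == ["positive", "negative", "unknown", "negative",
                                "unknown"]

    def test_negative_suvr_is_a_data_error(self):
        sess = self._sessions([-0.5], [10])
        with pytest.raises(ValueError, match="negative SUVR"):
            classify_amyloid(sess)

    def test_nearest_pet_wins(self):
        sessions = pd.DataFrame(
            {"session_id": ["s1"], "subject_id": ["p1"],
             "mri_date": [pd.Timestamp("2013-06-01")]}
        )
        pets = pd.DataFrame(
            {"subject_id": ["p1", "p1"],
             "pet_date": [pd.Timestamp("2013-01-01"), pd.Timestamp("2013-07-01")],
             "suvr": [1.30, 1.05]}
        )
        out = attach_nearest_pet(sessions, pets)
        assert out.loc[0, "suvr"] == 1.05  # July scan is 30 days away
        assert classify_amyloid(out).iloc[0] == "negative"


class TestEligibility:
    def test_cutoffs_are_strict(self):
        sess = pd.DataFrame(
            {"age": [81, 80, 72, 75], "adas_cog": [5, 10, 11, 5]}
        )
        kept, log = filter_eligibility(sess)
        assert list(kept.index) == [1, 3]  # age 80 and ADAS 10 retained
        assert log["age_gt_cutoff"] == 1
        assert log["adas_gt_cutoff"] == 1
        assert log["retained"] == 2


class TestTwoWayAnova:
    def test_balanced_design_type2_equals_type1(self):
        rng = np.random.default_rng(7)
        a = np.repeat(["x", "y"], 40)
        b = np.tile(np.repeat(["u", "v"], 20), 2)
        y = rng.standard_normal(80)
        t2 = two_way_anova(y, a, b)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
        import statsmodels.api as sm

        t1 = sm.stats.anova_lm(fit, typ=1)
        np.testing.assert_allclose(t2["sum_sq"][:3], t1["sum_sq"][:3], atol=1e-8)

    def test_sex_only_effect_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            a = rng.choice(["M", "F"], 200)
            b = rng.choice(["pos", "neg"], 200)
            y = 1.0 * (a == "F") + rng.standard_normal(200)
            tab = two_way_anova(y, a, b)
            if (tab.loc["factor_a", "PR(>F)"] < 0.01
                    and tab.loc["factor_b", "PR(>F)"] > 0.05
                    and tab.loc["interaction", "PR(>F)"] > 0.05):
                hits += 1
        assert hits >= 0.9 * 20 * 0.8  # >= 90% nominal with binomial slack

    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(9)
        ps = []
        for rep in range(200):
            a = rng.choice(["M", "F"], 60)
            b = rng.choice(["pos", "neg"], 60)
            y = rng.standard_normal(60)
            try:
                tab = two_way_anova(y, a, b)
            except ValueError:
                continue
            ps.append(tab.loc["factor_a", "PR(>F)"])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= rate <= 0.11

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1.0, 2.0], ["x", "x"], ["u", "v"])


class TestSlopeComparison:
    def test_generated_slope_difference_is_detected(self):
        rng = np.random.default_rng(10)
        n = 200
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        g = np.array(["w"] * n + ["m"] * n)
        y = np.where(g == "w", -1.0, 1.0) * x + rng.normal(0, 0.3, 2 * n)
        res = groupwise_regression_slope_test(x, y, g)
        assert res.p_diff < 1e-3
        assert res.groups["w"].slope < 0 < res.groups["m"].slope

    def test_matches_pooled_interaction_model(self):
        rng = np.random.default_rng(11)
        n = 300
        x = rng.normal(0, 1, 2 * n)
        g = np.array(["a"] * n + ["b"] * n)
        y = 0.5 * x + 0.4 * (g == "b") * x + rng.normal(0, 1, 2 * n)
        res = groupwise_regression_slope_test(x, y, g)
        df = pd.DataFrame({"x": x, "y": y, "g": g})
        fit = smf.ols("y ~ x * C(g)", data=df).fit()
        t_int = fit.tvalues["x:C(g)[T.b]"]
        assert abs(res.t_diff) == pytest.approx(abs(t_int), rel=0.05)

    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 400)
        y = 0.7 * x + rng.normal(0, 1, 400)
        g = np.array(["a", "b"] * 200)
        res = groupwise_regression_slope_test(x, y, g)
        assert res.p_diff > 0.05

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            groupwise_regression_slope_test(
                [1, 1, 1, 0, 1, 2], [1, 2, 3, 4, 5, 6],
                ["a", "a", "a", "b", "b", "b"],
            )


class TestMacroareas:
    def test_partition_covers_all_94_regions(self):
        table = load_macroarea_table()
        labels = table["region_label"].tolist()
        assert len(labels) == 94
        assigned = macroarea_assign(labels)
        assert len(assigned) == 94
        assert set(assigned) == set(MACROAREAS)
        assert assigned.value_counts().sum() == 94

    def test_missing_region_raises_with_name(self):
        with pytest.raises(KeyError, match="Atlantis"):
            macroarea_assign(["Atlantis"], {"Precentral_L": "other_frontal"})


class TestAdjustedSexContrast:
    def test_implanted_shift_detected_with_direction(self):
        rng = np.random.default_rng(13)
        n_subj = 80
        n_sess = rng.choice([1, 2], n_subj)
        subj = np.repeat(np.arange(n_subj), n_sess)
        sex = np.repeat(np.where(np.arange(n_subj) < 40, "M", "F"), n_sess)
        cov = _covariates(rng, n_subj).iloc[subj].reset_index(drop=True)
        cov["sex"] = sex
        y = rng.normal(0, 0.8, len(subj)) - 0.8 * (sex == "F")
        res, adj = adjusted_sex_contrast(y, cov, subj)
        assert res.p < 0.01
        assert res.t < 0  # women lower
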