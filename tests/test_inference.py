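"""Routed tests, exact tests, FDR, and the outcome models."""

import math
from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from doceeg import inference, synthetic
from doceeg.errors import InvalidInputError, InvalidParameterError


class TestShapiroRoute:
    def test_gaussian_samples_route_to_t(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            if inference.shapiro_route(r.normal(size=17),
                                       r.normal(size=17)) == "t_test":
                hits += 1
        assert hits >= 32  # nominal 1 - (1 - 0.95^2) ~ 0.90

    def test_skewed_samples_route_to_mann_whitney(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = np.exp(r.normal(size=17) * 2)
            b = np.exp(r.normal(size=17) * 2)
            if inference.shapiro_route(a, b) == "mann_whitney":
                hits += 1
        assert hits >= 18

    def test_too_few_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            inference.shapiro_route([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTwoSampleT:
    def test_crsr_row_from_summary_stats(self):
        # baseline CRS-R summary comparison, propofol - esketamine orientation
        res = inference.two_sample_t_from_stats(6.47, 2.10, 17, 7.65, 1.84, 17)
        assert res.statistic == pytest.approx(-1.7426, abs=1e-3)
        assert res.p_raw == pytest.approx(0.091, abs=0.001)

    def test_raw_data_equals_summary_path(self, rng):
        a = rng.normal(5, 2, 20)
        b = rng.normal(6, 2, 25)
        raw = inference.two_sample_t(a, b)
        summ = inference.two_sample_t_from_stats(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_raw == pytest.approx(summ.p_raw, abs=1e-12)

    def test_pooled_formula_closed_form(self):
        # |t| by the pooled formula for the respiratory-recovery means/SDs
        res = inference.two_sample_t_from_stats(12.02, 3.88, 17, 17.42, 4.62, 17)
        assert abs(res.statistic) == pytest.approx(3.69, abs=0.01)

    def test_identical_groups(self):
        res = inference.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)
        assert res.effect_size == 0.0

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.raises(InvalidInputError):
            inference.two_sample_t([2.0, 2.0], [3.0, 3.0])

    def test_cohens_d_sign_follows_orientation(self, rng):
        a = rng.normal(10, 1, 30)
        b = rng.normal(8, 1, 30)
        assert inference.two_sample_t(a, b).effect_size > 0
        assert inference.two_sample_t(b, a).effect_size < 0


class TestMannWhitney:
    def test_complete_separation(self):
        res = inference.mann_whitney([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == 9.0  # U for first group; U for second = 0
        assert abs(res.effect_size) == pytest.approx(1.0)

    def test_identical_groups_zero_effect(self):
        res = inference.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.effect_size == pytest.approx(0.0)

    def test_exact_p_matches_label_enumeration(self, rng):
        # brute force over all C(8,4) labelings of pooled distinct values
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        res = inference.mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        obs_u = ranks[:4].sum() - 4 * 5 / 2
        count = 0
        total = 0
        for idx in combinations(range(8), 4):
            u = ranks[list(idx)].sum() - 4 * 5 / 2
            # two-sided: as or more extreme in either direction
            if abs(u - 8) >= abs(obs_u - 8) - 1e-9:
                count += 1
            total += 1
        assert res.p_raw == pytest.approx(count / total, abs=1e-9)


def fisher_two_sided_oracle(table):
    """Enumerate all tables with fixed margins; sum p of those <= observed."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_k = hypergeom.pmf(k, n, col1, row1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return total


class TestFisherExact:
    def test_vasopressor_table_equals_enumeration(self):
        res = inference.fisher_exact([[3, 14], [9, 8]])
        assert res.p_raw == pytest.approx(
            fisher_two_sided_oracle([[3, 14], [9, 8]]), abs=1e-10)
        assert res.p_raw == pytest.approx(0.0705, abs=0.001)

    def test_balanced_table_p_one(self):
        assert inference.fisher_exact([[5, 5], [5, 5]]).p_raw == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        res = inference.fisher_exact([[10, 0], [0, 10]])
        assert res.p_raw == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert res.effect_size == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidInputError):
            inference.fisher_exact([[0, 0], [3, 4]])

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            res = inference.fisher_exact(t)
            assert res.p_raw == pytest.approx(fisher_two_sided_oracle(t),
                                              abs=1e-9)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(inference.benjamini_hochberg([0.03]), [0.03])

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            inference.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(inference.benjamini_hochberg([1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.random(20)
        q = inference.benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        # monotone in the order statistics
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            inference.benjamini_hochberg([0.5, 1.2])


class TestLogisticModel:
    def test_group_effect_recovery_moderate_n(self):
        coh = synthetic.generate_cohort(synthetic.default_cohort_params(800),
                                        seed=21)
        fit = inference.fit_logistic(coh)
        aor = float(fit.params.loc["group_esketamine", "or"])
        assert 4.5 < aor < 10.0
        assert fit.converged and not fit.separation

    def test_all_true_outcome_flagged_as_separation(self, small_cohort):
        coh = small_cohort.copy()
        coh["improved"] = True
        fit = inference.fit_logistic(coh)
        assert fit.separation
        assert fit.params["coef"].isna().all()

    def test_wald_ci_brackets_point(self):
        coh = synthetic.generate_cohort(synthetic.default_cohort_params(400),
                                        seed=5)
        fit = inference.fit_logistic(coh)
        p = fit.params
        assert (p["ci_low"] <= p["coef"]).all()
        assert (p["coef"] <= p["ci_high"]).all()
        assert (p["or"] > 0).all()


class TestLinearModel:
    def test_group_effect_recovery(self):
        coh = synthetic.generate_cohort(synthetic.default_cohort_params(800),
                                        seed=22)
        fit = inference.fit_linear(coh)
        assert fit.coef("group_esketamine") == pytest.approx(-5.4, abs=1.0)

    def test_rank_deficiency_names_columns(self, small_cohort):
        coh = small_cohort.copy()
        coh["dup"] = 1.0  # collides with the intercept
        with pytest.raises(InvalidInputError, match="dup"):
            inference.fit_linear(coh, covariates=("group", "age"),
                                 extra_covariates=("dup",))

    def test_null_outcome_ci_covers_zero_mostly(self):
        covered = 0
        for seed in range(30):
            coh = synthetic.generate_cohort(
                synthetic.default_cohort_params(60), seed=seed)
            rng = np.random.default_rng(seed + 1000)
            coh["noise_outcome"] = rng.normal(size=len(coh))
            fit = inference.fit_linear(coh, outcome="noise_outcome")
            row = fit.params.loc["group_esketamine"]
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert covered >= 25


class TestLikelihoodRatio:
    def _fit(self, ll, covs, n=100):
        return inference.ModelFit(outcome="y", kind="logistic",
                                  params=pd.DataFrame(), loglike=ll, n=n,
                                  covariates=covs)

    def test_identical_models_chi2_zero(self):
        full = self._fit(-10.0, ("a", "b"))
        res = inference.likelihood_ratio(self._fit(-10.0, ("a", "b", "c")), full)
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_df2_closed_form(self):
        # chi2_2 survival function is exp(-x/2)
        full = self._fit(-8.0, ("a", "b", "c"))
        red = self._fit(-10.0, ("a",))
        res = inference.likelihood_ratio(full, red)
        assert res.statistic == pytest.approx(4.0)
        assert res.p_raw == pytest.approx(math.exp(-2.0), rel=1e-9)

    def test_gaussian_nested_closed_form(self, rng):
        # OLS loglike difference equals n/2 log(RSS_red/RSS_full)
        n = 120
        x = rng.normal(size=n)
        y = 2.0 + 0.5 * x + rng.normal(size=n)
        coh = pd.DataFrame({"group": ["esketamine"] * (n // 2) + ["propofol"] * (n // 2),
                            "age": x, "y": y})
        full = inference.fit_linear(coh, outcome="y", covariates=("group", "age"))
        red = inference.fit_linear(coh, outcome="y", covariates=("group",))
        res = inference.likelihood_ratio(full, red)
        import statsmodels.api as sm
        xf = sm.add_constant(pd.DataFrame({
            "g": (coh["group"] == "esketamine").astype(float), "age": x}))
        xr = sm.add_constant(pd.DataFrame({
            "g": (coh["group"] == "esketamine").astype(float)}))
        rss_f = sm.OLS(y, xf).fit().ssr
        rss_r = sm.OLS(y, xr).fit().ssr
        assert res.statistic == pytest.approx(n * math.log(rss_r / rss_f),
                                              rel=1e-9)

    def test_non_nested_rejected(self):
        with pytest.raises(InvalidInputError):
            inference.likelihood_ratio(self._fit(-5.0, ("a",)),
                                       self._fit(-6.0, ("b",)))


class TestTableOne:
    def test_percent_formatting(self):
        assert inference._pct(3, 17) == "3 (17.65%)"
        assert inference._pct(9, 17) == "9 (52.94%)"
        assert inference._pct(0, 17) == "0 (0.00%)"

    def test_structure_and_orientation(self, small_cohort):
        tab = inference.table_one(small_cohort)
        assert set(tab["variable"]) >= {"Age (years)", "CRS-R score",
                                        "Norepinephrine = yes"}
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidInputError):
            inference.table_one(pd.DataFrame())


class TestOrdinalContrast:
    def test_direction_favors_improved_group(self):
        coh = synthetic.generate_cohort(synthetic.default_cohort_params(300),
                                        seed=8)
        res = inference.ordinal_state_contrast(coh)
        assert res.statistic < 0  # propofol - esketamine: esketamine higher

    def test_mark_improved_matches_generator_flag(self, small_cohort):
        np.testing.assert_array_equal(
            inference.mark_improved(small_cohort).to_numpy(),
            small_cohort["improved"].to_numpy())
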