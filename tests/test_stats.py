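"""Regression layer: FDR oracle equivalence, VIF, power formula, gates."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from tauspread import (
    beta_strem2_association,
    collinearity_check,
    fdr_bh,
    generate_cohort,
    minimum_n_for_power,
    normality_gate,
    power_check,
    regionwise_models,
)
from conftest import small_config


def brute_force_bh(p, alpha=0.05):
    """Independent step-up implementation used as the oracle."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    q = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, ranked[i] * m / (i + 1))
        q[order[i]] = prev
    return q, reject


class TestNormalityGate:
    def test_normal_sample_passes_untouched(self, rng):
        x = rng.normal(10, 2, 500)
        out, flag = normality_gate(x)
        assert not flag
        np.testing.assert_array_equal(out, x)

    def test_lognormal_sample_log_transformed_then_passes(self, rng):
        x = rng.lognormal(8, 0.5, 500)
        out, flag = normality_gate(x)
        assert flag
        np.testing.assert_allclose(out, np.log(x))
        _, flag2 = normality_gate(out)
        assert not flag2

    def test_constant_sample_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            normality_gate(np.full(50, 3.0))

    def test_nonpositive_values_with_transform_indicated_name_offenders(self, rng):
        x = pd.Series(rng.lognormal(1, 1, 100))
        x.iloc[3] = -1.0
        with pytest.raises(ValueError, match="3"):
            normality_gate(x)


class TestFDR:
    def test_hand_worked_step_up(self):
        q, rej = fdr_bh([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert rej.tolist() == [True, True, True, False]

    def test_uniform_small_p_all_significant(self):
        q, rej = fdr_bh([0.001] * 7)
        assert rej.all()
        np.testing.assert_allclose(q, 0.001)

    def test_matches_brute_force_oracle_on_random_draws(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 200))
            q, rej = fdr_bh(p)
            q0, rej0 = brute_force_bh(p)
            np.testing.assert_allclose(q, q0, atol=1e-12)
            np.testing.assert_array_equal(rej, rej0)

    def test_mask_invariant_to_input_order(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        _, rej = fdr_bh(p)
        _, rej_p = fdr_bh(p[perm])
        np.testing.assert_array_equal(rej[perm], rej_p)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=60))
    def test_q_values_dominate_p_and_stay_in_unit_interval(self, p):
        q, rej = fdr_bh(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all((q >= 0) & (q <= 1))
        q0, rej0 = brute_force_bh(p)
        np.testing.assert_allclose(q, q0, atol=1e-12)

    def test_empty_and_invalid_inputs(self):
        q, rej = fdr_bh([])
        assert q.size == 0 and rej.size == 0
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestCollinearity:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        vif = collinearity_check(X)
        np.testing.assert_allclose(vif["vif"], 1.0, atol=1e-12)

    def test_duplicated_predictor_reported_above_bound(self, rng):
        a = rng.normal(size=50)
        vif = collinearity_check(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(vif["vif"]).all()
        assert vif["exceeds_bound"].all()

    def test_correlated_pair_matches_closed_form(self, rng):
        n = 200_000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        vif = collinearity_check(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(vif["vif"], 1 / (1 - 0.64), atol=0.05)


class TestRegionwiseModels:
    @staticmethod
    def _frames(rng, n=400, beta=0.3, noise=None):
        # unit-variance outcome: standardized coefficient converges to beta
        if noise is None:
            noise = np.sqrt(1.0 - beta**2)
        ab = rng.normal(size=n)
        y = beta * (ab - ab.mean()) / ab.std(ddof=1) + rng.normal(0, noise, n)
        ids = [f"s{i}" for i in range(n)]
        slopes = pd.DataFrame({0: y}, index=ids)
        regional_ab = pd.DataFrame({0: ab}, index=ids)
        strem2 = pd.Series(rng.lognormal(8, 0.5, n), index=ids)
        baseline = pd.DataFrame({0: rng.normal(1.2, 0.1, n)}, index=ids)
        cov = pd.DataFrame({"age": rng.normal(70, 5, n),
                            "sex_female": rng.integers(0, 2, n)}, index=ids)
        return slopes, regional_ab, strem2, baseline, cov

    def test_planted_standardized_coefficient_recovered(self, rng):
        slopes, ab, s2, bt, cov = self._frames(rng, n=20_000)
        out = regionwise_models(slopes, ab, np.log(s2), bt, cov, spec=1)
        b = out.loc[out["predictor"] == "regional_ab", "beta"].iloc[0]
        assert b == pytest.approx(0.3, abs=0.02)

    def test_single_predictor_beta_equals_pearson_r(self, rng):
        slopes, ab, s2, bt, _ = self._frames(rng, noise=1.0)
        cov = pd.DataFrame(index=slopes.index)  # no covariates
        out = regionwise_models(slopes, ab, np.log(s2), bt, cov, spec=1)
        b = out.loc[out["predictor"] == "regional_ab", "beta"].iloc[0]
        r = sps.pearsonr(ab[0], slopes[0])[0]
        assert abs(b - r) < 1e-12

    def test_permuted_predictor_type_one_error_near_nominal(self, rng):
        n, m = 150, 300
        ids = [f"s{i}" for i in range(n)]
        slopes = pd.DataFrame(rng.normal(size=(n, m)), index=ids)
        ab = pd.DataFrame(rng.normal(size=(n, m)), index=ids)
        s2 = pd.Series(rng.lognormal(8, 0.5, n), index=ids)
        bt = pd.DataFrame(rng.normal(1.2, 0.1, (n, m)), index=ids)
        cov = pd.DataFrame({"age": rng.normal(70, 5, n),
                            "sex_female": rng.integers(0, 2, n)}, index=ids)
        out = regionwise_models(slopes, ab, s2, bt, cov, spec=1)
        rate = (out["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < 4 * se

    def test_planted_attenuation_gives_negative_regional_strem2_coefficients(self):
        cfg = small_config(stratum_sizes=(0, 60, 0, 0), seed=17,
                          strem2_attenuation_gamma=0.5)
        tables, truth = generate_cohort(cfg)
        parts = tables.participants.set_index("id")
        slopes = truth.true_slopes  # isolate the regression from slope noise
        ab = tables.ab_baseline.pivot_table(index="id", columns="parcel",
                                            values="suvr")
        bt = slopes * 0 + 1.2
        cov = pd.DataFrame({"age": parts["age"],
                            "sex_female": (parts["sex"] == "F").astype(float)})
        strem2 = pd.Series(np.log(parts["strem2"]), index=parts.index)
        out = regionwise_models(slopes, ab, strem2, bt, cov, spec=3)
        med = out.loc[out["predictor"] == "strem2", "beta"].median()
        assert med < 0

    def test_unknown_spec_rejected(self, rng):
        slopes, ab, s2, bt, cov = self._frames(rng)
        with pytest.raises(ValueError):
            regionwise_models(slopes, ab, s2, bt, cov, spec=9)


class TestBetaStrem2Association:
    def test_constant_beta_plus_noise_gives_null_coefficient(self, rng):
        n = 400
        ids = [f"s{i}" for i in range(n)]
        betas = pd.Series(-0.2 + rng.normal(0, 0.05, n), index=ids)
        strem2 = pd.Series(rng.lognormal(8, 0.5, n), index=ids)
        cov = pd.DataFrame(index=ids)
        assoc = beta_strem2_association(betas, strem2, cov)
        assert abs(assoc.coefficient) < 0.1
        assert assoc.n == n

    def test_requires_minimum_sample_and_variance(self, rng):
        ids = list("abcdef")
        with pytest.raises(ValueError):
            beta_strem2_association(pd.Series(0.1, index=ids),
                                    pd.Series(1000.0, index=ids),
                                    pd.DataFrame(index=ids))


class TestPower:
    def test_printed_design_thresholds(self):
        # smallest n certified at 80% power for rho=0.3, alpha=0.05
        assert minimum_n_for_power(0.8, 0.3, 0.05) == 85
        assert power_check(85) >= 0.8
        assert power_check(84) < 0.8

    def test_monotone_in_n_and_effect_size(self):
        powers = [power_check(n) for n in (20, 50, 100, 400)]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert power_check(100, 0.5) > power_check(100, 0.3)

    def test_limits(self):
        assert power_check(100_000) > 0.9999
        # one-tail approximation at rho=0 leaves alpha/2
        assert power_check(100, effect_size=0.0) == pytest.approx(0.025, abs=1e-9)
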