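"""Template building and the spreading statistic: scrubbing, density, distance."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tauspread import (
    ConnectivityTemplate,
    build_template,
    distance_to_epicentres,
    group_level_spread,
    scrub_and_fc,
    spreading_beta,
    template_from_z,
)
from tauspread.connectome import SubjectFC


def _fc(z):
    return SubjectFC(z=np.asarray(z, float), censored_fraction=0.0, retained=True)


class TestScrubbing:
    def test_half_censored_subject_not_retained(self, rng):
        sig = rng.normal(size=(4, 100))
        fd = np.where(np.arange(100) % 2 == 0, 1.0, 0.1)
        fc = scrub_and_fc(sig, fd, fd_threshold=0.5)
        assert fc.censored_fraction == pytest.approx(0.5)
        assert not fc.retained

    def test_identical_signals_capped_at_finite_z(self, rng):
        a = rng.normal(size=200)
        sig = np.stack([a, a, rng.normal(size=200)])
        fc = scrub_and_fc(sig, np.zeros(200))
        assert np.isfinite(fc.z[0, 1])
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_long_series_recovers_fisher_z_of_true_correlation(self, rng):
        n = 60_000
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        fc = scrub_and_fc(np.stack([x, y]), np.zeros(n))
        assert abs(fc.z[0, 1] - np.arctanh(0.6)) < 0.03

    def test_constant_parcel_reported_missing(self, rng):
        sig = np.stack([np.ones(100), rng.normal(size=100)])
        fc = scrub_and_fc(sig, np.zeros(100))
        assert np.isnan(fc.z[0, 1])

    def test_raising_threshold_never_decreases_retained_frames(self, rng):
        sig = rng.normal(size=(3, 300))
        fd = rng.exponential(0.3, 300)
        counts = [scrub_and_fc(sig, fd, fd_threshold=t).n_frames_used
                  for t in (0.2, 0.5, 0.8, 1.2)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestTemplate:
    def test_default_density_retains_30_percent_of_edges(self, rng):
        z = rng.normal(0.3, 0.2, (200, 200))
        z = (z + z.T) / 2
        tpl = template_from_z(z, density=0.30)
        assert tpl.mask[np.triu_indices(200, 1)].sum() == round(0.30 * 19_900)
        assert tpl.density == pytest.approx(0.30, abs=1e-9)

    def test_full_density_distance_reverses_z_ordering(self, rng):
        z = rng.normal(0.3, 0.2, (20, 20))
        z = (z + z.T) / 2
        tpl = template_from_z(z, density=1.0)
        iu = np.triu_indices(20, 1)
        order_z = np.argsort(z[iu])
        order_d = np.argsort(-tpl.distance[iu])
        np.testing.assert_array_equal(order_z, order_d)

    def test_three_parcel_toy_matches_hand_computation(self):
        z = np.array([[0.0, 0.9, 0.5], [0.9, 0.0, 0.1], [0.5, 0.1, 0.0]])
        tpl = template_from_z(z, density=2 / 3)
        # two strongest edges retained; minmax puts them at distances 0 and 1
        assert tpl.mask[0, 1] and tpl.mask[0, 2] and not tpl.mask[1, 2]
        assert tpl.distance[0, 1] == pytest.approx(0.0)
        assert tpl.distance[0, 2] == pytest.approx(1.0)
        assert tpl.distance[1, 2] == 1.0
        assert np.all(np.diag(tpl.distance) == 0.0)

    def test_template_invariant_to_subject_order(self, rng):
        zs = [rng.normal(0.2, 0.3, (8, 8)) for _ in range(4)]
        zs = [(z + z.T) / 2 for z in zs]
        t1 = build_template([_fc(z) for z in zs], density=0.5)
        t2 = build_template([_fc(z) for z in reversed(zs)], density=0.5)
        np.testing.assert_allclose(t1.distance, t2.distance, atol=1e-12)

    def test_non_retained_subjects_ignored_and_empty_template_refused(self, rng):
        z = (lambda m: (m + m.T) / 2)(rng.normal(size=(5, 5)))
        bad = SubjectFC(z * 100, 0.9, retained=False)
        tpl = build_template([_fc(z), bad], density=0.5)
        np.testing.assert_allclose(tpl.mean_z, z, atol=1e-12)
        with pytest.raises(ValueError):
            build_template([bad], density=0.5)

    @pytest.mark.parametrize("density", [0.0, -0.2, 1.5])
    def test_invalid_density_refused(self, density, rng):
        z = np.zeros((4, 4))
        with pytest.raises(ValueError):
            template_from_z(z, density=density)


class TestDistanceToEpicentres:
    def _tpl(self, d):
        d = np.asarray(d, float)
        return ConnectivityTemplate(np.zeros_like(d), d < 1, d, 0.3)

    def test_trivial_and_mean_cases(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.2
        d[0, 2] = d[2, 0] = 0.4
        out = distance_to_epicentres(self._tpl(d), [1, 2])
        assert out[0] == pytest.approx(0.3)  # mean of 0.2 and 0.4

    def test_matches_brute_force_loop(self, rng):
        d = rng.random((15, 15))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        epis = [2, 7, 11]
        out = distance_to_epicentres(self._tpl(d), epis)
        for r in range(15):
            assert out[r] == pytest.approx(np.mean([d[r, e] for e in epis]))

    def test_empty_or_out_of_atlas_epicentres_refused(self):
        tpl = self._tpl(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            distance_to_epicentres(tpl, [])
        with pytest.raises(ValueError):
            distance_to_epicentres(tpl, [9])


class TestSpreadingBeta:
    def test_noiseless_anti_association_gives_minus_one(self, rng):
        d = pd.Series(rng.random(60))
        slopes = -0.1 * d
        stat = spreading_beta(slopes, d, epicentres=[])
        assert stat.beta == pytest.approx(-1.0, abs=1e-12)
        assert stat.n_regions == 60

    def test_beta_equals_pearson_r_to_machine_precision(self, rng):
        s = pd.Series(rng.normal(size=120))
        d = pd.Series(rng.normal(size=120))
        stat = spreading_beta(s, d, epicentres=[])
        r, p = sps.pearsonr(s, d)
        assert abs(stat.beta - r) < 1e-12
        assert abs(stat.p_value - p) < 1e-12

    def test_permuted_slopes_fall_in_null_band(self, rng):
        d = pd.Series(rng.random(190))
        betas = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(d.to_numpy()), index=d.index)
            betas.append(spreading_beta(perm, d, epicentres=[]).beta)
        # mean of permutation betas ~ 0 with SE ~ 1/sqrt(190*200)
        assert abs(np.mean(betas)) < 4 / np.sqrt(190 * 200)
        assert np.quantile(np.abs(betas), 0.5) < 2 / np.sqrt(190)

    def test_default_atlas_and_k_use_190_regions(self, rng):
        slopes = pd.Series(rng.normal(size=200))
        d = pd.Series(rng.random(200))
        stat = spreading_beta(slopes, d, epicentres=list(range(10)))
        assert stat.n_regions == 190

    def test_degenerate_variance_flagged(self):
        s = pd.Series(np.zeros(30))
        d = pd.Series(np.linspace(0, 1, 30))
        stat = spreading_beta(s, d, epicentres=[])
        assert stat.flagged and np.isnan(stat.beta)

    def test_too_few_regions_refused(self):
        s = pd.Series(np.arange(5.0))
        with pytest.raises(ValueError):
            spreading_beta(s, s * 2, epicentres=[])


class TestGroupLevel:
    def test_group_epicentres_are_top_mean_scores_and_regression_excludes_them(self, rng):
        n = 40
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tpl = ConnectivityTemplate(np.zeros_like(d), d < 1, d, 0.3)
        scores = pd.DataFrame(rng.random((6, n)), index=[f"s{i}" for i in range(6)])
        slopes = pd.DataFrame(rng.normal(size=(6, n)), index=scores.index)
        stat, scatter = group_level_spread(slopes, tpl, scores, k=5)
        expected = set(scores.mean(0).sort_values(ascending=False).index[:5])
        assert set(stat.epicentres) == set(int(i) for i in expected)
        assert stat.n_regions == n - 5
        assert len(scatter) == n - 5
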