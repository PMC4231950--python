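import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import binmix as bm


def random_pmf(rng, x_max):
    raw = rng.random(x_max + 1)
    tail = rng.random() * 0.1
    probs = raw / raw.sum() * (1 - tail)
    return bm.Pmf(support=np.arange(x_max + 1), probabilities=probs, tail_mass=tail)


class TestEmpiricalPmf:
    def test_simple_frequencies(self):
        p = bm.empirical_pmf(bm.CountVector(np.array([0, 0, 1, 1])))
        assert p.probabilities.tolist() == [0.5, 0.5]
        assert p.tail_mass == 0.0

    def test_single_observation(self):
        p = bm.empirical_pmf(bm.CountVector(np.array([5])))
        assert p.probabilities.tolist() == [0, 0, 0, 0, 0, 1]

    def test_normalization(self, gamma_counts_5k):
        p = bm.empirical_pmf(gamma_counts_5k)
        assert abs(p.probabilities.sum() - 1.0) <= 1e-12


class TestRecoverPmf:
    def test_point_mass_recovers_poisson(self):
        mix = bm.DiscreteMixture(theta=np.array([3.0]), pi=np.array([1.0]))
        p = bm.recover_pmf(mix, 20)
        assert np.allclose(p.probabilities, stats.poisson.pmf(np.arange(21), 3.0), rtol=1e-12)

    def test_two_point_formula_at_zero(self):
        mix = bm.DiscreteMixture(theta=np.array([1.0, 10.0]), pi=np.array([0.5, 0.5]))
        p = bm.recover_pmf(mix, 5)
        assert np.isclose(p.probabilities[0], 0.5 * np.exp(-1) + 0.5 * np.exp(-10), rtol=1e-12)

    def test_recovery_tv_shrinks_with_sample_size(self):
        spec = bm.MixingSpec.gamma(2.0, 0.5)
        tvs = []
        for n, seed in [(1000, 1), (100_000, 2)]:
            cv = bm.simulate_counts(spec, n, seed=seed)
            res = bm.cnm_fit(cv)
            emp = bm.empirical_pmf(cv)
            tvs.append(bm.tv_distance(bm.recover_pmf(res.mixture, emp.x_max), emp))
        assert tvs[1] < tvs[0]
        assert tvs[1] < 0.01


class TestTvDistance:
    def test_identical_pmfs(self):
        p = bm.empirical_pmf(bm.CountVector(np.array([0, 1, 2])))
        assert bm.tv_distance(p, p) == 0.0

    def test_disjoint_point_masses(self):
        f = bm.Pmf(np.arange(1), np.array([1.0]))
        g = bm.Pmf(np.arange(2), np.array([0.0, 1.0]))
        assert bm.tv_distance(f, g) == 1.0

    def test_matches_direct_summation(self):
        x = np.arange(51)
        f = bm.Pmf(x, stats.poisson.pmf(x, 1.0), tail_mass=float(stats.poisson.sf(50, 1.0)))
        g = bm.Pmf(x, stats.poisson.pmf(x, 2.0), tail_mass=float(stats.poisson.sf(50, 2.0)))
        direct = 0.5 * (
            np.abs(stats.poisson.pmf(x, 1.0) - stats.poisson.pmf(x, 2.0)).sum()
            + abs(stats.poisson.sf(50, 1.0) - stats.poisson.sf(50, 2.0))
        )
        assert abs(bm.tv_distance(f, g) - direct) <= 1e-10

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        f, g, h = (random_pmf(rng, rng.integers(1, 15)) for _ in range(3))
        dfg = bm.tv_distance(f, g)
        assert 0.0 <= dfg <= 1.0
        assert dfg == bm.tv_distance(g, f)
        assert bm.tv_distance(f, f) == 0.0
        assert dfg <= bm.tv_distance(f, h) + bm.tv_distance(h, g) + 1e-12


class TestCdfBounds:
    def test_single_point(self):
        mix = bm.DiscreteMixture(theta=np.array([2.0]), pi=np.array([1.0]))
        b = bm.cdf_bounds(mix)
        assert b.lower.tolist() == [0.0]
        assert b.upper.tolist() == [1.0]

    def test_cumulative_rows(self):
        mix = bm.DiscreteMixture(theta=np.array([1.0, 5.0, 20.0]), pi=np.array([0.5, 0.3, 0.2]))
        b = bm.cdf_bounds(mix)
        assert np.allclose(b.lower, [0.0, 0.5, 0.8])
        assert np.allclose(b.upper, [0.5, 0.8, 1.0])

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_telescoping(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.integers(1, 8)
        pi = rng.dirichlet(np.ones(L))
        keep = pi > 1e-9
        pi = pi[keep] / pi[keep].sum()
        theta = np.sort(rng.random(pi.size)) * 10 + np.arange(pi.size) * 1e-3
        mix = bm.DiscreteMixture(theta=theta, pi=pi)
        b = bm.cdf_bounds(mix)
        assert b.lower[0] == 0.0
        assert np.allclose(b.lower[1:], b.upper[:-1], atol=1e-15)
        assert abs((b.upper - b.lower).sum() - 1.0) <= 1e-12


class TestCheckMixingFit:
    def test_generating_gamma_passes_bounds(self, gamma_counts_5k):
        res = bm.cnm_fit(gamma_counts_5k)
        bounds = bm.cdf_bounds(res.mixture)
        # generating mixing distribution: gamma(shape=2, rate=0.5) = NB(mu=4, r=2)
        report = bm.check_mixing_fit(bm.NBParams(mu=4.0, r=2.0), bounds)
        assert report.n_violations <= 1

    def test_point_mass_fails_on_overdispersed_data(self, gamma_counts_5k):
        res = bm.cnm_fit(gamma_counts_5k)
        bounds = bm.cdf_bounds(res.mixture)
        mu = float(gamma_counts_5k.counts.mean())
        report = bm.check_mixing_fit(bm.PoissonParams(mu=mu), bounds)
        assert report.n_violations >= 1
        assert report.first_violation is not None

    def test_own_cdf_hits_upper_bound_and_fails_half_open(self):
        # the discrete mixture's right-continuous CDF at theta_i equals the
        # upper bound, which the strict [lower, upper) convention rejects
        mix = bm.DiscreteMixture(theta=np.array([1.0, 5.0]), pi=np.array([0.6, 0.4]))
        b = bm.cdf_bounds(mix)
        F = np.asarray(mix.cdf(b.theta))
        assert np.allclose(F, b.upper)
        assert not np.any((b.lower <= F) & (F < b.upper))


class TestZeroScan:
    def test_rho_zero_reproduces_unadjusted_fit(self, gamma_counts_5k):
        res = bm.zero_scan(gamma_counts_5k, [0.0], model_names=("nb",), seed=0)
        fit = bm.fit_nb(gamma_counts_5k)
        emp = bm.empirical_pmf(gamma_counts_5k)
        expected = bm.tv_distance(bm.model_pmf(fit.params, emp.x_max), emp)
        assert res.table.loc[0, "d_tv"] == expected

    def test_rho_above_one_rejected(self, gamma_counts_5k):
        with pytest.raises(ValueError):
            bm.zero_scan(gamma_counts_5k, [1.5], model_names=("nb",), seed=0)

    def test_reproducible(self, gamma_counts_5k):
        grid = [-0.2, 0.0, 0.4]
        a = bm.zero_scan(gamma_counts_5k, grid, model_names=("poisson", "nb"), seed=1)
        b = bm.zero_scan(gamma_counts_5k, grid, model_names=("poisson", "nb"), seed=1)
        assert a.table.equals(b.table)

    def test_zero_inflated_nb_detected(self):
        # ZI-NB(nu=0.3, mu=5, r=2): the NB model fits best once the share of
        # zeros attributable to inflation has been removed
        nu, mu, r = 0.3, 5.0, 2.0
        cv = bm.simulate_counts(
            bm.nb_mixing_spec(mu, r), 20_000, bm.ZeroInflationConfig(nu=nu), seed=21
        )
        grid = np.linspace(-0.3, 0.9, 13)
        res = bm.zero_scan(cv, grid, model_names=("nb",), seed=0)
        p_zero_nb = (r / (r + mu)) ** r
        rho_true = nu / (nu + (1 - nu) * p_zero_nb)  # inflated share of all zeros
        step = grid[1] - grid[0]
        assert abs(res.optimum("nb") - rho_true) <= step + 1e-9


class TestClassifyBins:
    def test_tau_zero_gives_zero_posteriors(self):
        fit = bm.NBNBParams(tau=0.0, comp1=bm.NBParams(2, 5), comp2=bm.NBParams(20, 1))
        post, regions = bm.classify_bins(fit, bm.CountVector(np.array([0, 5, 50])))
        assert np.all(post == 0.0)
        assert len(regions) == 0

    def test_matches_direct_bayes_rule(self, nbnb_fit_50k):
        p = nbnb_fit_50k.params
        x = np.arange(0, 200)
        cv = bm.CountVector(x)
        post, _ = bm.classify_bins(p, cv)
        f1 = np.asarray(bm.pmf(p.comp1, x))
        f2 = np.asarray(bm.pmf(p.comp2, x))
        direct = p.tau * f2 / (p.tau * f2 + (1 - p.tau) * f1)
        assert np.allclose(post, direct, atol=1e-12, rtol=0)

    def test_posterior_monotone_under_mlr(self):
        # with equal dispersions and mu2 > mu1 component 2 dominates in
        # likelihood ratio, so the posterior must be non-decreasing in x
        fit = bm.NBNBParams(tau=0.1, comp1=bm.NBParams(3, 2), comp2=bm.NBParams(30, 2))
        x = np.arange(0, 501)
        post, _ = bm.classify_bins(fit, bm.CountVector(x))
        assert np.all(np.diff(post) >= -1e-12)

    def test_blacklist_merges_adjacent_bins(self):
        fit = bm.NBNBParams(tau=0.2, comp1=bm.NBParams(2, 10), comp2=bm.NBParams(50, 2))
        cv = bm.CountVector(
            np.array([1, 60, 55, 2, 70]),
            bin_width=100,
            chrom="chr1",
            bin_starts=np.array([0, 100, 200, 300, 400]),
        )
        _, regions = bm.classify_bins(fit, cv, threshold=0.5)
        assert regions.intervals == (("chr1", 100, 300), ("chr1", 400, 500))

    def test_missing_coordinates_warns_and_returns_empty_regions(self, caplog):
        fit = bm.NBNBParams(tau=0.2, comp1=bm.NBParams(2, 10), comp2=bm.NBParams(50, 2))
        with caplog.at_level("WARNING", logger="binmix"):
            post, regions = bm.classify_bins(fit, bm.CountVector(np.array([1, 60])))
        assert post.size == 2
        assert len(regions) == 0
        assert "coordinates" in caplog.text

    def test_unordered_fit_rejected(self):
        fit = bm.NBNBParams(tau=0.2, comp1=bm.NBParams(50, 2), comp2=bm.NBParams(2, 10))
        with pytest.raises(ValueError):
            bm.classify_bins(fit, bm.CountVector(np.array([1])))
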