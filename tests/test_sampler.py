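"""Region sampler: marginal-likelihood oracles, enumeration equivalence,
convergence diagnostics and chain validity."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import kstest, multivariate_normal

from regionbvs.sampler import (
    BVSConfig,
    BVSModelState,
    BVSPriors,
    SamplerError,
    gelman_rubin,
    log_marginal_likelihood,
    mcmc_step,
    run_bvs,
)

from conftest import make_G


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

class TestLogMarginalLikelihood:
    w = np.array([0.3, -1.2, 0.7, 2.0, -0.4])
    x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])

    def test_empty_model_reduces_to_intercept_only_form(self):
        Sigma = np.eye(5) + 100.0 * np.ones((5, 5))
        direct = multivariate_normal.logpdf(self.w, np.zeros(5), Sigma)
        assert log_marginal_likelihood(self.w, None, 0.5, None) == pytest.approx(
            direct, abs=1e-10
        )

    def test_one_snp_matches_quadrature(self):
        h = 0.005
        s2 = np.array([np.var(self.x, ddof=1)])
        siga2 = h / ((1 - h) * s2.sum())
        norm_const = (2 * np.pi) ** 3.5 * np.sqrt(siga2 * 100.0)

        def integrand(beta, mu):
            r = self.w - mu - self.x * beta
            return (
                np.exp(-0.5 * (r @ r) - 0.5 * beta**2 / siga2 - 0.5 * mu**2 / 100.0)
                / norm_const
            )

        val, err = integrate.dblquad(
            integrand, -80, 80, -3, 3, epsabs=1e-16, epsrel=1e-12
        )
        assert err < 1e-12
        assert log_marginal_likelihood(self.w, self.x, h, s2) == pytest.approx(
            math.log(val), abs=1e-6
        )

    def test_scale_invariance_of_dosage_units(self):
        base = log_marginal_likelihood(
            self.w, self.x, 0.01, np.array([np.var(self.x, ddof=1)])
        )
        c = 3.7
        scaled = log_marginal_likelihood(
            self.w, c * self.x, 0.01, np.array([c**2 * np.var(self.x, ddof=1)])
        )
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_invalid_h_rejected(self):
        with pytest.raises(SamplerError):
            log_marginal_likelihood(self.w, self.x, 1.5, np.array([1.0]))

    def test_zero_variance_snp_rejected(self):
        with pytest.raises(SamplerError):
            log_marginal_likelihood(self.w, self.x, 0.01, np.array([0.0]))


# ---------------------------------------------------------------------------
# single-sweep validity
# ---------------------------------------------------------------------------

class TestMcmcStep:
    @pytest.fixture
    def instance(self, rng):
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        y = rng.permutation(np.repeat([0, 1], 15))
        return X, y

    def test_model_size_never_exceeds_cap(self, instance):
        X, y = instance
        priors = BVSPriors(max_model_size=2)
        state = BVSModelState(gamma=[0, 3], h=0.005, log10_pi=-0.5)
        for seed in range(60):
            state = mcmc_step(state, (X, y), priors, seed=seed)
            assert len(state.gamma) <= 2
            assert priors.h_min <= state.h <= priors.h_max

    def test_empty_model_remains_valid(self, instance):
        X, y = instance
        priors = BVSPriors()
        state = BVSModelState(gamma=[], h=0.005, log10_pi=-0.5)
        sizes = []
        for seed in range(60):
            state = mcmc_step(state, (X, y), priors, seed=seed)
            sizes.append(len(state.gamma))
            assert np.isfinite(state.log_ml)
        assert min(sizes) >= 0

    def test_latent_liability_signs_match_labels(self, instance):
        X, y = instance
        state = BVSModelState(gamma=[1], h=0.005, log10_pi=-0.5)
        state = mcmc_step(state, (X, y), BVSPriors(), seed=11)
        assert np.all((state.z > 0) == (np.asarray(y) == 1))


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_posterior_pips(X, y, h_grid, pi, max_k):
    """Exact PIPs by summing over all models x h-grid points."""
    n, p = X.shape
    s2 = np.var(X, axis=0, ddof=1)
    logps, models = [], []
    for k in range(max_k + 1):
        for gam in itertools.combinations(range(p), k):
            cols = list(gam)
            for h in h_grid:
                lm = log_marginal_likelihood(
                    y, X[:, cols] if k else None, h, s2[cols] if k else None
                )
                logps.append(lm + k * np.log(pi) + (p - k) * np.log(1 - pi))
                models.append(gam)
    logps = np.asarray(logps)
    post = np.exp(logps - logps.max())
    post /= post.sum()
    pip = np.zeros(p)
    for gam, q in zip(models, post):
        for j in gam:
            pip[j] += q
    return pip


class TestEnumerationEquivalence:
    def test_small_instance_pips_match_enumeration(self, rng):
        n, p = 200, 8
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = 0.35 * (X[:, 2] - X[:, 2].mean()) + rng.normal(size=n)
        grid = [0.05, 0.2, 0.5]
        priors = BVSPriors(
            h_min=1e-4, h_max=0.9, target_size_min=2.0, target_size_max=2.0,
            max_model_size=2, h_grid=grid,
        )
        exact = enumerate_posterior_pips(X, y, grid, pi=2.0 / p, max_k=2)
        res = run_bvs(
            X, y, priors,
            BVSConfig(n_iter=500_000, trait_mode="continuous", seed=17),
        )
        np.testing.assert_allclose(res.pip, exact, atol=0.03)

    def test_detailed_balance_on_three_snps(self, rng):
        # fixed h, fixed pi: long-run model frequencies = exact posterior
        n, p = 20, 3
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        y = 0.8 * X[:, 0] + rng.normal(size=n)
        grid = [0.3]
        priors = BVSPriors(
            h_min=1e-4, h_max=0.9, target_size_min=1.5, target_size_max=1.5,
            max_model_size=3, h_grid=grid,
        )
        exact = enumerate_posterior_pips(X, y, grid, pi=1.5 / p, max_k=3)
        res = run_bvs(
            X, y, priors,
            BVSConfig(n_iter=400_000, trait_mode="continuous", seed=23),
        )
        np.testing.assert_allclose(res.pip, exact, atol=0.02)


# ---------------------------------------------------------------------------
# run_bvs behaviour
# ---------------------------------------------------------------------------

class TestRunBvs:
    def test_seeded_determinism(self, rng):
        X = rng.integers(0, 3, size=(60, 10)).astype(float)
        y = rng.permutation(np.repeat([0, 1], 30))
        cfg = BVSConfig(n_iter=5000, seed=5)
        a = run_bvs(X, y, BVSPriors(), cfg)
        b = run_bvs(X, y, BVSPriors(), cfg)
        np.testing.assert_array_equal(a.pip, b.pip)
        np.testing.assert_array_equal(a.traces["h"], b.traces["h"])
        c = run_bvs(X, y, BVSPriors(), BVSConfig(n_iter=5000, seed=6))
        assert not np.array_equal(a.traces["h"], c.traces["h"])

    def test_pip_bounds_and_sum_cap(self, rng):
        X = rng.integers(0, 3, size=(80, 30)).astype(float)
        y = rng.permutation(np.repeat([0, 1], 40))
        res = run_bvs(X, y, BVSPriors(max_model_size=5), BVSConfig(n_iter=5000, seed=1))
        assert np.all((res.pip >= 0) & (res.pip <= 1))
        assert res.sum_pip <= 5.0 + 1e-12
        assert res.sum_pip == pytest.approx(res.pip.sum())
        assert res.mean_pip == pytest.approx(res.sum_pip / 30)

    def test_null_regions_have_prior_dominated_sum(self, rng):
        sums = []
        for i in range(20):
            X = rng.integers(0, 3, size=(60, 25)).astype(float)
            y = rng.permutation(np.repeat([0, 1], 30))
            res = run_bvs(X, y, BVSPriors(), BVSConfig(n_iter=2000, seed=i))
            sums.append(res.sum_pip)
        assert np.median(sums) < 5.0

    def test_causal_snp_recovery_binary(self, rng):
        hits = 0
        for rep in range(10):
            X = rng.binomial(2, 0.3, size=(500, 8)).astype(float)
            liab = 0.65 * (X[:, 4] - X[:, 4].mean()) / X[:, 4].std() + rng.normal(size=500)
            y = (liab > np.median(liab)).astype(int)
            res = run_bvs(
                X, y, BVSPriors(h_max=0.5), BVSConfig(n_iter=20_000, seed=rep)
            )
            hits += int(res.pip.argmax() == 4)
        assert hits >= 9

    def test_prior_recovery_with_constant_response(self):
        # an information-free response leaves h at its uniform prior
        X = np.random.default_rng(0).integers(0, 3, size=(50, 5)).astype(float)
        y = np.zeros(50)
        priors = BVSPriors(h_min=0.001, h_max=0.01)
        res = run_bvs(
            X, y, priors, BVSConfig(n_iter=200_000, trait_mode="continuous", seed=3)
        )
        h = res.traces["h"][0, res.n_kept_burn :]
        stat = kstest(h, "uniform", args=(0.001, 0.009)).statistic
        assert stat < 0.1

    def test_monomorphic_columns_get_zero_pip(self, rng):
        X = rng.integers(0, 3, size=(50, 4)).astype(float)
        X[:, 2] = 1.0
        y = rng.permutation(np.repeat([0, 1], 25))
        res = run_bvs(X, y, BVSPriors(), BVSConfig(n_iter=2000, seed=0))
        assert res.pip[2] == 0.0

    def test_constant_binary_phenotype_rejected(self, rng):
        X = rng.integers(0, 3, size=(20, 4)).astype(float)
        with pytest.raises(SamplerError):
            run_bvs(X, np.ones(20, dtype=int), BVSPriors(), BVSConfig(n_iter=1000))

    def test_empty_region_rejected(self):
        with pytest.raises(SamplerError):
            run_bvs(np.empty((10, 0)), np.repeat([0, 1], 5), BVSPriors(),
                    BVSConfig(n_iter=1000))

    def test_missing_dosages_rejected(self, rng):
        G = make_G(np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 0.0], [2.0, 2.0]]))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(SamplerError, match="impute"):
            run_bvs(G, y, BVSPriors(), BVSConfig(n_iter=1000))


# ---------------------------------------------------------------------------
# Gelman-Rubin diagnostic
# ---------------------------------------------------------------------------

class TestGelmanRubin:
    def test_identical_chains_give_subunit_value(self):
        chain = np.random.default_rng(1).normal(size=500)
        val = gelman_rubin(np.vstack([chain, chain]))
        assert val == pytest.approx(math.sqrt(499 / 500))

    def test_shifted_chains_flagged_and_match_formula(self):
        r = np.random.default_rng(2)
        a = r.normal(size=1000)
        b = r.normal(loc=5.0, size=1000)
        arr = np.vstack([a, b])
        n = 1000
        W = arr.var(axis=1, ddof=1).mean()
        B = n * arr.mean(axis=1).var(ddof=1)
        expected = math.sqrt((n - 1) / n + B / (n * W))
        val = gelman_rubin(arr)
        assert val == pytest.approx(expected)
        assert val > 1.04

    def test_zero_variance_chain_warns(self):
        arr = np.vstack([np.zeros(50), np.ones(50)])
        with pytest.warns(UserWarning):
            assert gelman_rubin(arr) == math.inf

    def test_converged_sampler_beats_bound(self, rng):
        X = rng.integers(0, 3, size=(100, 15)).astype(float)
        y = rng.permutation(np.repeat([0, 1], 50))
        res = run_bvs(X, y, BVSPriors(), BVSConfig(n_iter=20_000, n_chains=2, seed=9))
        assert res.gelman_rubin["h"] < 1.04
        assert res.gelman_rubin["log_joint"] < 1.04
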