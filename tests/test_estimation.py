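"""GLS, likelihood evaluation, and REML/ML fitting."""

import math

import numpy as np
import pytest
from scipy import optimize

import streamnet as sn
from streamnet.covariance import CovarianceComponent, CovarianceParams
from streamnet.distance import (
    downstream_distance_matrix,
    euclidean_distance_matrix,
    tailup_weights,
)
from streamnet.errors import RankError, SingularError
from streamnet.estimation import _CovCache, build_design, neg2_loglik

from conftest import random_network, random_sites

_LOG_2PI = math.log(2 * math.pi)


def _iid_dataset(n=60, seed=0, beta=(3.0, 1.5), sd=1.0):
    """Sites on a random network with iid Gaussian responses."""
    net = random_network(seed, n_edges=30)
    sites = random_sites(net, n, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    for s in sites:
        s.response = float(
            beta[0] + beta[1] * s.covariates["x1"] + rng.normal(0, sd)
        )
    return sn.SSNDataset(network=net, obs=sites)


class TestGlsBeta:
    def test_identity_sigma_equals_ols(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.normal(size=30)
        beta, vcov = sn.gls_beta(X, y, np.eye(30))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta, ols, atol=1e-10)
        assert np.allclose(vcov, np.linalg.inv(X.T @ X), atol=1e-10)

    def test_precision_weighted_mean(self):
        X = np.ones((2, 1))
        y = np.array([1.0, 5.0])
        sigma = np.diag([1.0, 4.0])
        beta, _ = sn.gls_beta(X, y, sigma)
        assert beta[0] == pytest.approx((1 / 1 + 5 / 4) / (1 + 1 / 4))  # 1.8

    def test_duplicate_column_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, x])
        with pytest.raises(RankError):
            sn.gls_beta(X, rng.normal(size=20), np.eye(20))


class TestNeg2Loglik:
    def _cache(self, ds, spec):
        return _CovCache(ds.obs, ds.network, spec)

    def test_single_point_ml(self):
        ds = _iid_dataset(n=1)
        spec = sn.ModelSpec("response ~ 1", estmethod="ml")
        X = np.ones((1, 1))
        y = np.array([ds.obs[0].response])
        cache = self._cache(sn.SSNDataset(network=ds.network, obs=ds.obs[:1]), spec)
        m2 = neg2_loglik(CovarianceParams(nugget=1.0), X, y, cache, "ml")
        # single standard-normal point at its mean: -2l = log 2pi
        assert m2 == pytest.approx(_LOG_2PI + 0.0, abs=1e-10)

    def test_variance_doubling_changes_logdet(self):
        ds = _iid_dataset(n=25)
        spec = sn.ModelSpec("response ~ x1", estmethod="ml")
        X, y, _ = build_design(ds.obs, spec)
        cache = self._cache(ds, spec)
        n = len(y)
        m1 = neg2_loglik(CovarianceParams(nugget=1.0), X, y, cache, "ml")
        m2 = neg2_loglik(CovarianceParams(nugget=2.0), X, y, cache, "ml")
        # -2l = log|Sigma| + r'S^-1 r + n log 2pi: doubling Sigma adds
        # n log 2 to the determinant and halves the quadratic form
        quad1 = m1 - n * _LOG_2PI  # log|I| = 0 so this is the quadratic
        assert m2 == pytest.approx(n * math.log(2) + quad1 / 2 + n * _LOG_2PI)

    def test_iid_reml_grid_oracle(self):
        """The REML objective over sigma2 on a grid is minimized at the
        n-1 divisor sample variance (intercept-only model)."""
        ds = _iid_dataset(n=40, beta=(2.0, 0.0))
        spec = sn.ModelSpec("response ~ 1")
        X, y, _ = build_design(ds.obs, spec)
        cache = self._cache(ds, spec)
        s2_hat = float(np.var(y, ddof=1))
        grid = np.linspace(0.3 * s2_hat, 3 * s2_hat, 801)
        vals = [
            neg2_loglik(CovarianceParams(nugget=float(v)), X, y, cache, "reml")
            for v in grid
        ]
        assert grid[int(np.argmin(vals))] == pytest.approx(s2_hat, rel=0.01)

    def test_reml_translation_invariance(self):
        """REML depends on y only through error contrasts: adding Xc to y
        leaves the objective unchanged."""
        ds = _iid_dataset(n=30)
        spec = sn.ModelSpec("response ~ x1")
        X, y, _ = build_design(ds.obs, spec)
        cache = self._cache(ds, spec)
        params = CovarianceParams(nugget=1.3)
        m1 = neg2_loglik(params, X, y, cache, "reml")
        m2 = neg2_loglik(params, X, y + X @ np.array([4.0, -2.0]), cache, "reml")
        assert m2 == pytest.approx(m1, abs=1e-8)


class TestFit:
    def test_all_none_reproduces_ols_and_iid_variance(self):
        ds = _iid_dataset(n=80, seed=3)
        spec = sn.ModelSpec("response ~ x1")
        res = sn.fit(spec, ds)
        X, y, _ = build_design(ds.obs, spec)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ ols
        s2 = float(resid @ resid) / (len(y) - 2)
        assert np.allclose(res.beta_hat, ols, atol=1e-6)
        assert res.theta_hat.nugget == pytest.approx(s2, abs=1e-6)

    def test_intercept_only_reml_variance_is_sample_variance(self):
        ds = _iid_dataset(n=50, seed=9, beta=(4.0, 0.0))
        spec = sn.ModelSpec("response ~ 1")
        res = sn.fit(spec, ds)
        y = np.array([s.response for s in ds.obs])
        assert res.theta_hat.nugget == pytest.approx(float(np.var(y, ddof=1)),
                                                     rel=1e-10)
        assert res.beta_hat[0] == pytest.approx(float(np.mean(y)), rel=1e-10)

    def test_loglik_consistent_with_neg2_loglik(self):
        ds = _iid_dataset(n=40, seed=7)
        spec = sn.ModelSpec(
            "response ~ x1", taildown_type="exponential", euclid_type="none"
        )
        res = sn.fit(spec, ds)
        cache = _CovCache(ds.obs, ds.network, spec)
        X, y, _ = build_design(ds.obs, spec)
        m2 = neg2_loglik(res.theta_hat, X, y, cache, "reml")
        assert m2 == pytest.approx(-2 * res.loglik, abs=1e-10)
        assert res.aic == pytest.approx(m2 + 2 * res.q)

    def test_profiling_identity(self):
        """With correlation parameters fixed, the analytically profiled
        overall variance equals the numerically optimized one."""
        ds = _iid_dataset(n=40, seed=11)
        spec = sn.ModelSpec("response ~ x1", taildown_type="exponential")
        X, y, _ = build_design(ds.obs, spec)
        cache = _CovCache(ds.obs, ds.network, spec)
        n, p = X.shape

        def m2(v):
            params = CovarianceParams(
                taildown=CovarianceComponent("exponential", 0.6 * v, 3.0),
                nugget=0.4 * v,
            )
            return neg2_loglik(params, X, y, cache, "reml")

        res = optimize.minimize_scalar(
            m2, bounds=(1e-3, 50.0), method="bounded",
            options={"xatol": 1e-10},
        )
        # analytic profile: v = r' R^-1 r / (n - p) at the same correlation
        base = CovarianceParams(
            taildown=CovarianceComponent("exponential", 0.6, 3.0), nugget=0.4
        )
        sigma = cache.sigma(base)
        beta, _ = sn.gls_beta(X, y, sigma)
        r = y - X @ beta
        v_analytic = float(r @ np.linalg.solve(sigma, r)) / (n - p)
        assert res.x == pytest.approx(v_analytic, rel=1e-6)

    def test_rank_deficient_design_raises(self):
        ds = _iid_dataset(n=30)
        for s in ds.obs:
            s.covariates["x2"] = s.covariates["x1"]
        spec = sn.ModelSpec("response ~ x1 + x2")
        with pytest.raises(SingularError):
            sn.fit(spec, ds)

    def test_nugget_only_parameter_recovery(self):
        """Closed-form iid fits across seeds recover the generating values."""
        sig_hats, beta_hats = [], []
        for seed in range(30):
            ds = _iid_dataset(n=150, seed=100 + seed, beta=(0.0, 0.0), sd=1.0)
            res = sn.fit(sn.ModelSpec("response ~ 1"), ds)
            sig_hats.append(res.theta_hat.nugget)
            beta_hats.append(res.beta_hat[0])
        assert abs(np.median(sig_hats) - 1.0) < 0.2
        assert abs(np.median(beta_hats)) < 0.15

    def test_optimum_at_least_as_good_as_truth(self, reference_params):
        """The optimizer is never beaten by the generating parameters."""
        net = random_network(21, n_edges=60)
        sites = random_sites(net, 60, seed=22)
        sim = sn.SimulationConfig(
            params=reference_params, beta=[1.0, 0.5], covariates=["x1"],
            seed=23, n_sim=5,
        )
        Y = sn.simulate_gaussian(sim, net, sites)
        spec = sn.ModelSpec(
            "response ~ x1", tailup_type="exponential",
            taildown_type="spherical", euclid_type="gaussian",
            additive="additive_attr",
        )
        wins = 0
        for r in range(Y.shape[0]):
            for s, v in zip(sites, Y[r]):
                s.response = float(v)
            ds = sn.SSNDataset(network=net, obs=sites)
            res = sn.fit(spec, ds)
            cache = _CovCache(ds.obs, net, spec)
            X, y, _ = build_design(ds.obs, spec)
            m2_true = neg2_loglik(reference_params, X, y, cache, "reml")
            wins += (-2 * res.loglik) <= m2_true + 1e-6
        assert wins == Y.shape[0]

    def test_ml_versus_reml_distinct(self):
        ds = _iid_dataset(n=40, seed=13)
        r1 = sn.fit(sn.ModelSpec("response ~ x1", estmethod="reml"), ds)
        r2 = sn.fit(sn.ModelSpec("response ~ x1", estmethod="ml"), ds)
        n, p = r1.n, r1.p
        # iid closed forms: REML divides by n-p, ML by n
        assert r1.theta_hat.nugget == pytest.approx(
            r2.theta_hat.nugget * n / (n - p), rel=1e-8
        )


class TestModelSpec:
    def test_formula_parsing(self):
        spec = sn.ModelSpec("temp ~ elev + precip")
        assert spec.response == "temp"
        assert spec.covariates == ["elev", "precip"]
        assert sn.ModelSpec("y ~ 1").covariates == []

    def test_tailup_requires_additive(self):
        with pytest.raises(ValueError, match="additive"):
            sn.ModelSpec("y ~ x", tailup_type="exponential")

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="tailup_type"):
            sn.ModelSpec("y ~ x", tailup_type="matern")
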