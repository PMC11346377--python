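"""Gaussian stream-network linear model fitting by REML or ML.

The model is ``y = X beta + z_tu + z_td + z_e + eps`` with independent
zero-mean Gaussian error processes: tail-up, tail-down and Euclidean spatial
components plus an iid nugget.  Fixed effects are profiled out by GLS, and
the overall variance scale is profiled analytically, so the numerical search
runs only over variance proportions (log-ratios against the nugget) and
ranges.  Restricted maximum likelihood (REML) is the default; maximum
likelihood (ML) is available via ``estmethod="ml"``.

Objective (natural parameters theta, r = y - X beta_hat(theta)):

* ML:   -2l = log|Sigma| + r' Sigma^-1 r + n log 2 pi
* REML: -2l = log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r + (n-p) log 2 pi
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numba
import numpy as np
from scipy import linalg, optimize

from .covariance import (
    EUCLID_TYPES,
    TAILDOWN_TYPES,
    TAILUP_TYPES,
    CovarianceComponent,
    CovarianceParams,
)
from .distance import (
    HydroDistances,
    downstream_distance_matrix,
    euclidean_distance_matrix,
    tailup_weights,
)
from .errors import ConvergenceWarning, NotPDError, RankError, SingularError
from .network import Site, StreamNetwork

__all__ = ["ModelSpec", "FitResult", "gls_beta", "neg2_loglik", "fit", "fit_with_params"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: mean formula, covariance types, estimation method.

    ``formula`` follows the ``"response ~ cov1 + cov2"`` convention with an
    implicit intercept; ``"response ~ 1"`` is intercept-only.  ``additive``
    names the additive variable behind the AFVs and is required whenever a
    tail-up component is requested.
    """

    formula: str
    tailup_type: str = "none"
    taildown_type: str = "none"
    euclid_type: str = "none"
    additive: Optional[str] = None
    estmethod: str = "reml"

    def __post_init__(self):
        if self.tailup_type not in TAILUP_TYPES:
            raise ValueError(
                f"tailup_type {self.tailup_type!r} not in {TAILUP_TYPES}"
            )
        if self.taildown_type not in TAILDOWN_TYPES:
            raise ValueError(
                f"taildown_type {self.taildown_type!r} not in {TAILDOWN_TYPES}"
            )
        if self.euclid_type not in EUCLID_TYPES:
            raise ValueError(
                f"euclid_type {self.euclid_type!r} not in {EUCLID_TYPES}"
            )
        if self.estmethod not in ("reml", "ml"):
            raise ValueError("estmethod must be 'reml' or 'ml'")
        if self.tailup_type != "none" and not self.additive:
            raise ValueError(
                "an additive variable is required when modeling the tail-up "
                "covariance"
            )
        # force a parse error early
        self.response, self.covariates  # noqa: B018

    @property
    def response(self) -> str:
        return self._parse()[0]

    @property
    def covariates(self) -> list[str]:
        return self._parse()[1]

    def _parse(self) -> tuple[str, list[str]]:
        if "~" not in self.formula:
            raise ValueError(f"formula {self.formula!r} must contain '~'")
        lhs, rhs = self.formula.split("~", 1)
        resp = lhs.strip()
        if not resp:
            raise ValueError("formula must name a response")
        terms = [t.strip() for t in rhs.split("+")]
        covs = [t for t in terms if t and t != "1"]
        return resp, covs


@dataclass
class FitResult:
    """Everything a fitted stream-network model exposes or needs downstream."""

    spec: ModelSpec
    beta_hat: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    theta_hat: CovarianceParams
    loglik: float
    n: int
    p: int
    q: int  # estimated covariance parameters
    aic: float
    converged: bool
    n_iter: int
    message: str = ""
    # prediction machinery (populated by fit)
    network: Optional[StreamNetwork] = None
    obs_sites: Optional[list[Site]] = None
    X: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    sigma_chol: Optional[np.ndarray] = None  # lower factor
    sigma_inv_resid: Optional[np.ndarray] = None

    def coef(self) -> dict[str, float]:
        return dict(zip(self.beta_names, self.beta_hat))

    def fitted_mean(self) -> np.ndarray:
        """GLS mean X beta_hat at the observed sites."""
        return self.X @ self.beta_hat

    def residuals(self) -> np.ndarray:
        """Marginal (response) residuals y - X beta_hat."""
        return self.y - self.fitted_mean()

    @property
    def AIC(self) -> float:
        return self.aic


def build_design(
    sites: Sequence[Site], spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (with intercept), response vector, and term names."""
    n = len(sites)
    names = ["(Intercept)"] + list(spec.covariates)
    X = np.ones((n, 1 + len(spec.covariates)))
    for j, cov in enumerate(spec.covariates):
        for i, s in enumerate(sites):
            if cov not in s.covariates:
                raise KeyError(f"site {s.site_id} lacks covariate {cov!r}")
            X[i, 1 + j] = s.covariates[cov]
    y = np.empty(n)
    for i, s in enumerate(sites):
        if s.response is None:
            raise ValueError(f"site {s.site_id} has no response value")
        y[i] = s.response
    return X, y, names


def _chol_jitter(sigma: np.ndarray):
    """Lower Cholesky with escalating diagonal jitter; None if hopeless.

    Policy: add 1e-10 x mean diagonal, escalate tenfold up to 1e-6, then
    give up (the caller maps that to +inf or raises).
    """
    try:
        return linalg.cholesky(sigma, lower=True, check_finite=False)
    except linalg.LinAlgError:
        pass
    base = float(np.mean(np.diag(sigma)))
    eye = np.eye(sigma.shape[0])
    for mult in (1e-10, 1e-9, 1e-8, 1e-7, 1e-6):
        try:
            return linalg.cholesky(
                sigma + mult * base * eye, lower=True, check_finite=False
            )
        except linalg.LinAlgError:
            continue
    return None


def gls_beta(
    X: np.ndarray, y: np.ndarray, sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least squares via Cholesky whitening.

    beta = (X' Sigma^-1 X)^-1 X' Sigma^-1 y with vcov (X' Sigma^-1 X)^-1.
    """
    L = _chol_jitter(sigma)
    if L is None:
        raise NotPDError("covariance matrix is not positive definite")
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    try:
        c = linalg.cholesky(xtx, lower=True)
    except linalg.LinAlgError:
        raise RankError("X' Sigma^-1 X is singular (rank-deficient design)")
    # an exactly collinear design leaves a pivot at sqrt(eps) level
    d = np.diag(c)
    if d.min() <= 1e-7 * d.max():
        raise RankError("X' Sigma^-1 X is numerically singular")
    beta = linalg.cho_solve((c, True), Xw.T @ yw)
    vcov = linalg.cho_solve((c, True), np.eye(X.shape[1]))
    vcov = 0.5 * (vcov + vcov.T)
    return beta, vcov


# The likelihood search evaluates the covariance thousands of times, so the
# component fills are JIT-compiled single passes over precomputed compact
# index arrays.  They implement exactly the closed forms of
# streamnet.covariance (kind codes: 0 exponential, 1 linear_sill, 2
# spherical; Euclidean: 0 exponential, 1 gaussian, 2 spherical) and the test
# suite asserts equality with the generic assembly.

_KIND = {"exponential": 0, "linear_sill": 1, "spherical": 2}
_EKIND = {"exponential": 0, "gaussian": 1, "spherical": 2}


@numba.njit(cache=False)
def _fill_stream(flat, idx, h, w, use_w, sill, rng, kind):
    for t in range(idx.size):
        x = h[t] / rng
        if kind == 0:
            rho = math.exp(-x)
        elif kind == 1:
            rho = 1.0 - x if x < 1.0 else 0.0
        else:
            rho = 1.0 - 1.5 * x + 0.5 * x**3 if x <= 1.0 else 0.0
        v = sill * rho
        if use_w:
            v *= w[t]
        flat[idx[t]] += v


@numba.njit(cache=False)
def _fill_taildown_fu(flat, idx, a, b, sill, rng, kind):
    for t in range(idx.size):
        ta = a[t] / rng
        tb = b[t] / rng
        if kind == 0:
            v = math.exp(-(ta + tb))
        elif kind == 1:
            v = 1.0 - ta if ta < 1.0 else 0.0
        else:
            v = (1.0 - ta) ** 2 * (1.0 + 0.5 * ta - 1.5 * tb) if ta <= 1.0 else 0.0
        flat[idx[t]] += sill * v


@numba.njit(cache=False)
def _fill_euclid(sig, d, sill, rng, kind):
    n, m = sig.shape
    for i in range(n):
        for j in range(m):
            x = d[i, j] / rng
            if kind == 0:
                rho = math.exp(-x)
            elif kind == 1:
                rho = math.exp(-(x * x))
            else:
                rho = 1.0 - 1.5 * x + 0.5 * x**3 if x <= 1.0 else 0.0
            sig[i, j] += sill * rho


class _CovCache:
    """Precomputed distance/weight structures reused across objective calls.

    Also pre-extracts compact flow-connected / flow-unconnected index arrays
    so the per-iteration covariance assembly touches only the entries each
    component can affect; ``sigma(params)`` is numerically identical to
    :func:`streamnet.covariance.assemble_sigma` on the cached matrices.
    """

    def __init__(
        self,
        sites: Sequence[Site],
        network: StreamNetwork,
        spec: ModelSpec,
        dists: HydroDistances | None = None,
        W: np.ndarray | None = None,
        euclid_d: np.ndarray | None = None,
    ):
        need_stream = spec.tailup_type != "none" or spec.taildown_type != "none"
        if dists is None and need_stream:
            dists = downstream_distance_matrix(sites, sites, network)
        if dists is None:
            # placeholder zero distances for pure-Euclidean/iid models
            n = len(sites)
            dists = HydroDistances(np.zeros((n, n)), np.zeros((n, n)))
        self.dists = dists
        if W is None and spec.tailup_type != "none":
            W = tailup_weights(sites, sites, network, dists)
        self.W = W
        if euclid_d is None and spec.euclid_type != "none":
            euclid_d = euclidean_distance_matrix(sites, sites)
        self.euclid_d = euclid_d

        self.n = dists.d_rows.shape[0]
        fc = dists.flow_connected
        fin = dists.same_network
        self._fc_idx = np.flatnonzero(fc.ravel())
        self._fu_idx = np.flatnonzero((~fc & fin).ravel())
        self._h_fc = dists.h.ravel()[self._fc_idx]
        self._a_fu = dists.a.ravel()[self._fu_idx]
        self._b_fu = dists.b.ravel()[self._fu_idx]
        self._w_fc = W.ravel()[self._fc_idx] if W is not None else None

    def sigma(self, params: CovarianceParams) -> np.ndarray:
        """Model covariance under ``params`` using the cached structures."""
        n = self.n
        flat = np.zeros(n * n)
        if params.tailup.active:
            _fill_stream(
                flat, self._fc_idx, self._h_fc, self._w_fc, True,
                params.tailup.partial_sill, params.tailup.range,
                _KIND[params.tailup.type],
            )
        if params.taildown.active:
            td = params.taildown
            _fill_stream(
                flat, self._fc_idx, self._h_fc, self._h_fc, False,
                td.partial_sill, td.range, _KIND[td.type],
            )
            _fill_taildown_fu(
                flat, self._fu_idx, self._a_fu, self._b_fu,
                td.partial_sill, td.range, _KIND[td.type],
            )
        sig = flat.reshape(n, n)
        if params.euclid.active:
            _fill_euclid(
                sig, self.euclid_d, params.euclid.partial_sill,
                params.euclid.range, _EKIND[params.euclid.type],
            )
        if params.nugget > 0:
            sig[np.diag_indices(n)] += params.nugget
        return sig


def neg2_loglik(
    params: CovarianceParams,
    X: np.ndarray,
    y: np.ndarray,
    cache: _CovCache,
    estmethod: str = "reml",
) -> float:
    """-2 log likelihood (REML or ML) at the given covariance parameters.

    Returns +inf when the implied covariance cannot be factorized even after
    the jitter policy.
    """
    n, p = X.shape
    sigma = cache.sigma(params)
    L = _chol_jitter(sigma)
    if L is None:
        return math.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    xtx = Xw.T @ Xw
    try:
        c = linalg.cholesky(xtx, lower=True)
    except linalg.LinAlgError:
        return math.inf
    beta = linalg.cho_solve((c, True), Xw.T @ yw)
    rw = yw - Xw @ beta
    quad = float(rw @ rw)
    if estmethod == "ml":
        return logdet + quad + n * _LOG_2PI
    logdet_xtx = 2.0 * float(np.sum(np.log(np.diag(c))))
    return logdet + logdet_xtx + quad + (n - p) * _LOG_2PI


# ---------------------------------------------------------------------------
# parameter packing for the profiled objective


class _ParamStructure:
    """Free parameters: log variance ratios vs nugget + log ranges.

    The overall variance scale is profiled analytically, so a model with k
    variance components (spatial + nugget) and m active ranges has
    (k - 1) + m free parameters; the nugget-only model has none.
    """

    def __init__(self, spec: ModelSpec, log_range_caps: dict | None = None):
        self.components = [
            name
            for name, t in (
                ("tailup", spec.tailup_type),
                ("taildown", spec.taildown_type),
                ("euclid", spec.euclid_type),
            )
            if t != "none"
        ]
        self.types = {
            "tailup": spec.tailup_type,
            "taildown": spec.taildown_type,
            "euclid": spec.euclid_type,
        }
        self.n_free = 2 * len(self.components)
        # ranges beyond a few times the data extent are indistinguishable
        # from a constant component, so the search is capped there
        self.log_range_caps = log_range_caps or {}

    def unpack(self, theta: np.ndarray, scale: float = 1.0) -> CovarianceParams:
        """Map free parameters + overall scale to CovarianceParams.

        Proportions: nugget weight 1, component i weight exp(theta_i); all
        normalized to sum to `scale`.
        """
        k = len(self.components)
        ratios = np.exp(np.clip(theta[:k], -40.0, 40.0))
        log_ranges = np.clip(theta[k:], -40.0, 40.0)
        for i, name in enumerate(self.components):
            cap = self.log_range_caps.get(name)
            if cap is not None and log_ranges[i] > cap:
                log_ranges[i] = cap
        ranges = np.exp(log_ranges)
        total = 1.0 + ratios.sum()
        sills = scale * ratios / total
        nugget = scale * 1.0 / total
        kwargs = {}
        for i, name in enumerate(self.components):
            kwargs[name] = CovarianceComponent(
                type=self.types[name], partial_sill=float(sills[i]),
                range=float(ranges[i]),
            )
        return CovarianceParams(nugget=float(nugget), **kwargs)


def _profiled_objective(
    theta: np.ndarray,
    struct: _ParamStructure,
    X: np.ndarray,
    y: np.ndarray,
    cache: _CovCache,
    estmethod: str,
) -> float:
    """-2 log likelihood with the overall variance profiled out."""
    n, p = X.shape
    params = struct.unpack(theta, scale=1.0)
    R = cache.sigma(params)
    L = _chol_jitter(R)
    if L is None:
        return math.inf
    logdet_R = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    xtx = Xw.T @ Xw
    try:
        c = linalg.cholesky(xtx, lower=True)
    except linalg.LinAlgError:
        return math.inf
    beta = linalg.cho_solve((c, True), Xw.T @ yw)
    rw = yw - Xw @ beta
    Q = max(float(rw @ rw), 1e-300)
    if estmethod == "ml":
        v = Q / n
        return n * math.log(v) + logdet_R + n + n * _LOG_2PI
    logdet_xtx = 2.0 * float(np.sum(np.log(np.diag(c))))
    v = Q / (n - p)
    return (
        (n - p) * math.log(v)
        + logdet_R
        + logdet_xtx
        + (n - p)
        + (n - p) * _LOG_2PI
    )


def _profiled_scale(
    theta: np.ndarray,
    struct: _ParamStructure,
    X: np.ndarray,
    y: np.ndarray,
    cache: _CovCache,
    estmethod: str,
) -> float:
    """The analytically optimal overall variance at the given free params."""
    n, p = X.shape
    params = struct.unpack(theta, scale=1.0)
    R = cache.sigma(params)
    L = _chol_jitter(R)
    if L is None:
        raise NotPDError("correlation matrix not positive definite")
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _ = np.linalg.lstsq(Xw, yw, rcond=None)[:2]
    rw = yw - Xw @ beta
    Q = float(rw @ rw)
    return Q / (n - p) if estmethod == "reml" else Q / n


def _initial_free_params(
    struct: _ParamStructure,
    X: np.ndarray,
    y: np.ndarray,
    cache: _CovCache,
) -> np.ndarray:
    """Equal variance split (log-ratios 0); ranges at half the median
    nonzero pairwise distance of the relevant metric."""
    k = len(struct.components)
    theta = np.zeros(2 * k)
    h = cache.dists.h
    finite_h = h[np.isfinite(h) & (h > 0)]
    med_h = float(np.median(finite_h)) if finite_h.size else 1.0
    for i, name in enumerate(struct.components):
        if name == "euclid":
            d = cache.euclid_d
            nz = d[d > 0]
            med = float(np.median(nz)) if nz.size else 1.0
        else:
            med = med_h
        theta[k + i] = math.log(max(0.5 * med, 1e-8))
    return theta


def fit(
    spec: ModelSpec,
    dataset,
    dists: HydroDistances | None = None,
    W: np.ndarray | None = None,
    euclid_d: np.ndarray | None = None,
    maxiter: int = 2000,
    n_restarts: int = 2,
) -> FitResult:
    """Fit the stream-network linear model.

    Parameters
    ----------
    spec
        Model specification (formula, covariance types, REML/ML).
    dataset
        Any object with ``network`` (StreamNetwork) and ``obs`` (sequence of
        located Sites) attributes, e.g. :class:`streamnet.io.SSNDataset`.
    dists, W, euclid_d
        Optional precomputed observed-by-observed hydrologic distances,
        tail-up weights, and Euclidean distances (recomputed when absent).

    The optimizer is Nelder-Mead on log-scale free parameters with two
    restarts from deterministically perturbed initials; the overall variance
    is profiled analytically at every step.
    """
    sites: list[Site] = list(dataset.obs)
    network: StreamNetwork = dataset.network
    X, y, names = build_design(sites, spec)
    n, p = X.shape
    if n <= p:
        raise SingularError(f"need more sites ({n}) than fixed effects ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise SingularError("design matrix is rank deficient")

    cache = _CovCache(sites, network, spec, dists, W, euclid_d)
    h = cache.dists.h
    finite_h = h[np.isfinite(h)]
    max_h = float(finite_h.max()) if finite_h.size else 1.0
    max_e = float(cache.euclid_d.max()) if cache.euclid_d is not None else 1.0
    caps = {
        "tailup": math.log(max(2.0 * max_h, 1e-8)),
        "taildown": math.log(max(2.0 * max_h, 1e-8)),
        "euclid": math.log(max(2.0 * max_e, 1e-8)),
    }
    struct = _ParamStructure(spec, log_range_caps=caps)

    theta0 = _initial_free_params(struct, X, y, cache)
    total_iters = 0
    converged = True
    message = ""
    if struct.n_free == 0:
        best_theta = theta0
        best_val = _profiled_objective(theta0, struct, X, y, cache, spec.estmethod)
    else:
        rng = np.random.default_rng(202401)
        starts = [theta0]
        for _ in range(n_restarts):
            starts.append(theta0 + rng.normal(0.0, 0.4, size=theta0.size))
        best_theta, best_val = None, math.inf
        for s in starts:
            res = optimize.minimize(
                _profiled_objective,
                s,
                args=(struct, X, y, cache, spec.estmethod),
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "fatol": 1e-6,
                    "xatol": 1e-4,
                    "adaptive": True,
                },
            )
            total_iters += res.nit
            if res.fun < best_val:
                best_theta, best_val = res.x, res.fun
                if not res.success:
                    converged = False
                    message = res.message
                else:
                    converged = True
                    message = ""
        if not converged:
            warnings.warn(
                f"optimizer iteration cap reached: {message}", ConvergenceWarning
            )

    scale = _profiled_scale(best_theta, struct, X, y, cache, spec.estmethod)
    params = struct.unpack(best_theta, scale=scale)

    sigma = cache.sigma(params)
    L = _chol_jitter(sigma)
    if L is None:
        raise NotPDError("fitted covariance matrix is not positive definite")
    beta, vcov = gls_beta(X, y, sigma)
    resid = y - X @ beta
    rw = linalg.solve_triangular(L, resid, lower=True)
    alpha = linalg.solve_triangular(L.T, rw, lower=False)

    m2ll = neg2_loglik(params, X, y, cache, spec.estmethod)
    q = len(struct.components) * 2 + 1  # sills + ranges + nugget
    aic = m2ll + 2 * (q if spec.estmethod == "reml" else q + p)

    return FitResult(
        spec=spec,
        beta_hat=beta,
        beta_names=names,
        vcov_beta=vcov,
        theta_hat=params,
        loglik=-0.5 * m2ll,
        n=n,
        p=p,
        q=q,
        aic=aic,
        converged=converged,
        n_iter=total_iters,
        message=message,
        network=network,
        obs_sites=sites,
        X=X,
        y=y,
        sigma=sigma,
        sigma_chol=L,
        sigma_inv_resid=alpha,
    )


def fit_with_params(
    spec: ModelSpec,
    dataset,
    params: CovarianceParams,
    dists: HydroDistances | None = None,
    W: np.ndarray | None = None,
    euclid_d: np.ndarray | None = None,
) -> FitResult:
    """GLS fit holding the covariance parameters fixed (no optimization).

    Useful for evaluating a model at known parameters, e.g. when kriging
    from simulated data with the generating covariance.  Singular but
    positive-semidefinite covariances (such as a zero nugget with co-located
    sites) follow the usual jitter policy.
    """
    sites: list[Site] = list(dataset.obs)
    network: StreamNetwork = dataset.network
    X, y, names = build_design(sites, spec)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise SingularError("design matrix is rank deficient")
    cache = _CovCache(sites, network, spec, dists, W, euclid_d)
    sigma = cache.sigma(params)
    L = _chol_jitter(sigma)
    if L is None:
        raise NotPDError("covariance matrix is not positive definite")
    beta, vcov = gls_beta(X, y, sigma)
    resid = y - X @ beta
    rw = linalg.solve_triangular(L, resid, lower=True)
    alpha = linalg.solve_triangular(L.T, rw, lower=False)
    m2ll = neg2_loglik(params, X, y, cache, spec.estmethod)
    struct = _ParamStructure(spec)
    q = len(struct.components) * 2 + 1
    aic = m2ll + 2 * (q if spec.estmethod == "reml" else q + p)
    return FitResult(
        spec=spec, beta_hat=beta, beta_names=names, vcov_beta=vcov,
        theta_hat=params, loglik=-0.5 * m2ll, n=n, p=p, q=q, aic=aic,
        converged=True, n_iter=0, network=network, obs_sites=sites,
        X=X, y=y, sigma=sigma, sigma_chol=L, sigma_inv_resid=alpha,
    )
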