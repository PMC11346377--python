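"""Universal kriging on the stream network, and leave-one-out validation.

Point prediction at an unobserved site p:

    fitted = x_p' beta_hat + c_p' Sigma^-1 (y - X beta_hat)

with prediction variance

    se^2 = sigma2_tot - c_p' Sigma^-1 c_p + m_p' (X' Sigma^-1 X)^-1 m_p,
    m_p = x_p - X' Sigma^-1 c_p,

where ``c_p`` is the cross-covariance between p and the observed sites
(spatial components only; the nugget never correlates distinct
measurements) and ``sigma2_tot`` is the full marginal variance including
the nugget, so intervals are prediction intervals for a new noisy
observation, not confidence intervals for the noiseless surface.  The
fixed-effect term accounts for beta having been estimated.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .covariance import assemble_sigma
from .distance import (
    HydroDistances,
    downstream_distance_matrix,
    euclidean_distance_matrix,
    tailup_weights,
)
from .errors import DimensionError, NotFittedError
from .estimation import FitResult, gls_beta
from .network import Site

__all__ = ["krige", "loocv"]


def _pred_design(pred_sites: Sequence[Site], fit: FitResult) -> np.ndarray:
    Xp = np.ones((len(pred_sites), fit.p))
    for j, cov in enumerate(fit.spec.covariates):
        for i, s in enumerate(pred_sites):
            if cov not in s.covariates:
                raise KeyError(f"prediction site {s.site_id} lacks covariate {cov!r}")
            Xp[i, 1 + j] = s.covariates[cov]
    return Xp


def _cross_covariance(
    fit: FitResult,
    pred_sites: Sequence[Site],
    cross_dists: Optional[HydroDistances] = None,
    cross_W: Optional[np.ndarray] = None,
    cross_euclid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """n_obs x n_pred spatial cross-covariance (no nugget)."""
    spec = fit.spec
    obs = fit.obs_sites
    need_stream = spec.tailup_type != "none" or spec.taildown_type != "none"
    if cross_dists is None and need_stream:
        cross_dists = downstream_distance_matrix(obs, pred_sites, fit.network)
    if cross_dists is None:
        z = np.zeros((len(obs), len(pred_sites)))
        cross_dists = HydroDistances(z, z.copy())
    if cross_W is None and spec.tailup_type != "none":
        cross_W = tailup_weights(obs, pred_sites, fit.network, cross_dists)
    if cross_euclid is None and spec.euclid_type != "none":
        cross_euclid = euclidean_distance_matrix(obs, pred_sites)
    return assemble_sigma(
        cross_dists, cross_W, cross_euclid, fit.theta_hat,
        include_nugget_on_diagonal=False,
    )


def krige(
    fit: FitResult,
    pred_sites: Sequence[Site],
    cross_dists: Optional[HydroDistances] = None,
    cross_W: Optional[np.ndarray] = None,
    cross_euclid: Optional[np.ndarray] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Universal kriging predictions with prediction intervals.

    Returns a DataFrame with columns ``site_id, x, y, .fitted, .se,
    .lower, .upper`` (interval at the Gaussian quantile for ``level``).
    Distances and weights between observed and prediction sites are
    recomputed transparently when not supplied.
    """
    if fit.sigma_chol is None or fit.obs_sites is None:
        raise NotFittedError("krige requires a fitted model with stored data")
    if len(pred_sites) == 0:
        return pd.DataFrame(
            columns=["site_id", "x", "y", ".fitted", ".se", ".lower", ".upper"]
        )
    C = _cross_covariance(fit, pred_sites, cross_dists, cross_W, cross_euclid)
    if C.shape != (len(fit.obs_sites), len(pred_sites)):
        raise DimensionError(
            f"cross-covariance shape {C.shape} does not match "
            f"({len(fit.obs_sites)}, {len(pred_sites)})"
        )
    Xp = _pred_design(pred_sites, fit)
    L = fit.sigma_chol
    # Sigma^-1 C via two triangular solves
    Cw = linalg.solve_triangular(L, C, lower=True)
    SiC = linalg.solve_triangular(L.T, Cw, lower=False)
    fitted = Xp @ fit.beta_hat + C.T @ fit.sigma_inv_resid
    sigma2_tot = fit.theta_hat.total_variance
    var_spatial = sigma2_tot - np.sum(C * SiC, axis=0)
    M = Xp.T - fit.X.T @ SiC  # p x m
    var_beta = np.sum(M * (fit.vcov_beta @ M), axis=0)
    se2 = var_spatial + var_beta
    if np.any(se2 < -1e-10 * max(sigma2_tot, 1.0)):
        warnings.warn(
            "negative kriging variance beyond numerical noise; clamped to 0",
            RuntimeWarning,
        )
    se = np.sqrt(np.maximum(se2, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in pred_sites],
            "x": [s.x for s in pred_sites],
            "y": [s.y for s in pred_sites],
            ".fitted": fitted,
            ".se": se,
            ".lower": fitted - z * se,
            ".upper": fitted + z * se,
        }
    )


def loocv(fit: FitResult, level: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Leave-one-out cross-validation holding the covariance estimate fixed.

    Each site is predicted from the other n-1 by universal kriging under
    ``theta_hat`` (fixed effects re-estimated from the reduced data each
    time; no covariance refit).  Returns the per-site table and summary
    statistics: bias, RMSPE, and empirical coverage of the
    ``level`` prediction intervals.
    """
    if fit.sigma is None:
        raise NotFittedError("loocv requires a fitted model with stored data")
    n = fit.n
    sigma = fit.sigma
    X, y = fit.X, fit.y
    sigma2_tot = fit.theta_hat.total_variance
    z = stats.norm.ppf(0.5 + level / 2.0)
    preds = np.empty(n)
    ses = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        S = sigma[np.ix_(keep, keep)]
        # off-diagonal row of Sigma = spatial cross-covariance (no nugget)
        c = sigma[keep, i]
        Xi, yi = X[keep], y[keep]
        beta, vcov = gls_beta(Xi, yi, S)
        L = linalg.cholesky(S, lower=True)
        cw = linalg.solve_triangular(L, c, lower=True)
        Sic = linalg.solve_triangular(L.T, cw, lower=False)
        r = yi - Xi @ beta
        rw = linalg.solve_triangular(L, r, lower=True)
        alpha = linalg.solve_triangular(L.T, rw, lower=False)
        preds[i] = X[i] @ beta + c @ alpha
        m = X[i] - Xi.T @ Sic
        se2 = sigma2_tot - c @ Sic + m @ vcov @ m
        ses[i] = np.sqrt(max(se2, 0.0))
    resid = y - preds
    table = pd.DataFrame(
        {
            "site_id": [s.site_id for s in fit.obs_sites],
            "observed": y,
            ".fitted": preds,
            ".se": ses,
            ".lower": preds - z * ses,
            ".upper": preds + z * ses,
        }
    )
    covered = (y >= table[".lower"].to_numpy()) & (y <= table[".upper"].to_numpy())
    summary = {
        "bias": float(np.mean(preds - y)),
        "RMSPE": float(np.sqrt(np.mean(resid**2))),
        "coverage": float(np.mean(covered)),
        "level": level,
    }
    return table, summary
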