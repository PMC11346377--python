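"""Model summaries in the tidy/glance/augment idiom."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import NotFittedError
from .estimation import FitResult
from .network import Site
from .prediction import krige

__all__ = ["tidy", "glance", "augment", "summary_text"]


def _check(fit: FitResult) -> None:
    if fit is None or fit.X is None:
        raise NotFittedError("a fitted model is required")


def tidy(fit: FitResult) -> pd.DataFrame:
    """One row per fixed effect: estimate, std_error, z statistic, p value.

    p values use the standard-normal reference, the usual asymptotic
    convention for spatial mixed models.
    """
    _check(fit)
    est = fit.beta_hat
    se = np.sqrt(np.diag(fit.vcov_beta))
    stat = est / se
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "term": fit.beta_names,
            "estimate": est,
            "std_error": se,
            "statistic": stat,
            "p_value": pval,
        }
    )


def pseudo_r2(fit: FitResult) -> float:
    """Squared Pearson correlation between y and the GLS fitted means.

    One of several generalized-R2 conventions; returns 0 for a constant
    mean surface (intercept-only).
    """
    _check(fit)
    mu = fit.fitted_mean()
    if np.allclose(mu, mu[0]):
        return 0.0
    r = np.corrcoef(fit.y, mu)[0, 1]
    return float(r**2)


def glance(fit: FitResult) -> pd.DataFrame:
    """One-row model summary: n, p, npar, loglik, AIC, pseudo_r2."""
    _check(fit)
    return pd.DataFrame(
        {
            "n": [fit.n],
            "p": [fit.p],
            "npar": [fit.q],
            "loglik": [fit.loglik],
            "AIC": [fit.aic],
            "pseudo_r2": [pseudo_r2(fit)],
        }
    )


def augment(
    fit: FitResult,
    newdata: Optional[Sequence[Site]] = None,
    standardized: bool = False,
    level: float = 0.95,
) -> pd.DataFrame:
    """Site table with fitted values and residuals or prediction intervals.

    Without ``newdata``: the observed sites with ``.fitted`` (GLS means) and
    ``.resid`` (marginal residuals y - x'beta); ``standardized=True`` adds
    ``.std_resid``, the Cholesky-whitened residuals.  With ``newdata``:
    delegates to :func:`streamnet.prediction.krige` (``.fitted``, ``.se``,
    ``.lower``, ``.upper``).
    """
    _check(fit)
    if newdata is not None:
        return krige(fit, list(newdata), level=level)
    mu = fit.fitted_mean()
    resid = fit.y - mu
    out = pd.DataFrame(
        {
            "site_id": [s.site_id for s in fit.obs_sites],
            "x": [s.x for s in fit.obs_sites],
            "y": [s.y for s in fit.obs_sites],
            "response": fit.y,
            ".fitted": mu,
            ".resid": resid,
        }
    )
    if standardized:
        out[".std_resid"] = linalg.solve_triangular(
            fit.sigma_chol, resid, lower=True
        )
    return out


def _fmt_comp(name: str, comp) -> str:
    if comp.type == "none":
        return f"  {name:<9} none"
    return (
        f"  {name:<9} {comp.type:<12} partial sill {comp.partial_sill:10.4g}"
        f"   range {comp.range:10.4g}"
    )


def summary_text(fit: FitResult) -> str:
    """Console-style fit summary: coefficients and covariance parameters."""
    _check(fit)
    rows = tidy(fit)
    lines = [
        f"Stream-network linear model ({fit.spec.estmethod.upper()})",
        f"formula: {fit.spec.formula}",
        "",
        "Coefficients:",
        f"  {'term':<16}{'estimate':>12}{'std_error':>12}{'statistic':>12}{'p_value':>12}",
    ]
    for _, r in rows.iterrows():
        lines.append(
            f"  {r['term']:<16}{r['estimate']:>12.5g}{r['std_error']:>12.5g}"
            f"{r['statistic']:>12.3f}{r['p_value']:>12.4g}"
        )
    th = fit.theta_hat
    lines += [
        "",
        "Covariance parameters:",
        _fmt_comp("tailup", th.tailup),
        _fmt_comp("taildown", th.taildown),
        _fmt_comp("euclid", th.euclid),
        f"  {'nugget':<9} {th.nugget:10.4g}",
        "",
        f"n = {fit.n}, p = {fit.p}, covariance parameters = {fit.q}",
        f"loglik = {fit.loglik:.4f}, AIC = {fit.aic:.4f}, "
        f"pseudo-R2 = {pseudo_r2(fit):.4f}",
        f"converged: {fit.converged} ({fit.n_iter} iterations)",
    ]
    return "\n".join(lines)
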