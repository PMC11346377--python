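"""Gaussian simulation on a stream network.

Draws ``y = X beta + L z`` with ``L`` the lower Cholesky factor of the
model covariance assembled from the true parameters and ``z`` iid standard
normal from a seeded generator.  Every replicate uses independent ``z``;
the same seed reproduces the same replicates bit for bit on one platform.
This is also the engine behind the package's parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .covariance import CovarianceParams, assemble_sigma
from .distance import (
    downstream_distance_matrix,
    euclidean_distance_matrix,
    tailup_weights,
    HydroDistances,
)
from .errors import NotPDError
from .network import Site, StreamNetwork

__all__ = ["SimulationConfig", "simulate_gaussian", "build_sigma_for_sites"]


@dataclass
class SimulationConfig:
    """Ground truth for a simulation study.

    ``beta`` pairs with ``covariates``: the design is an intercept column
    followed by the named site covariates, so ``len(beta) ==
    1 + len(covariates)``.
    """

    params: CovarianceParams
    beta: Sequence[float] = (0.0,)
    covariates: Sequence[str] = ()
    seed: int = 0
    n_sim: int = 1

    def __post_init__(self):
        if len(self.beta) != 1 + len(self.covariates):
            raise ValueError(
                "beta must have one entry per covariate plus the intercept"
            )


def build_sigma_for_sites(
    params: CovarianceParams,
    network: StreamNetwork,
    sites: Sequence[Site],
    dists: Optional[HydroDistances] = None,
) -> np.ndarray:
    """Model covariance among a set of sites under the given parameters."""
    need_stream = params.tailup.active or params.taildown.active
    if dists is None and need_stream:
        dists = downstream_distance_matrix(sites, sites, network)
    if dists is None:
        n = len(sites)
        dists = HydroDistances(np.zeros((n, n)), np.zeros((n, n)))
    W = tailup_weights(sites, sites, network, dists) if params.tailup.active else None
    d_e = euclidean_distance_matrix(sites, sites) if params.euclid.active else None
    return assemble_sigma(dists, W, d_e, params, include_nugget_on_diagonal=True)


def simulate_gaussian(
    config: SimulationConfig,
    network: StreamNetwork,
    sites: Sequence[Site],
    dists: Optional[HydroDistances] = None,
) -> np.ndarray:
    """Simulate ``config.n_sim`` response vectors at the given sites.

    Returns an (n_sim, n_sites) array.  Raises :class:`NotPDError` if the
    covariance cannot be factorized even after a small diagonal jitter.
    """
    sigma = build_sigma_for_sites(config.params, network, sites, dists)
    n = sigma.shape[0]
    try:
        L = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        # singular but PSD covariances (e.g., co-located sites with zero
        # nugget) get an exact eigendecomposition square root so perfectly
        # correlated sites simulate identically
        evals, evecs = linalg.eigh(sigma)
        if evals[-1] <= 0 or evals[0] < -1e-8 * evals[-1]:
            raise NotPDError("simulation covariance is not positive definite")
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))

    X = np.ones((n, 1 + len(config.covariates)))
    for j, cov in enumerate(config.covariates):
        for i, s in enumerate(sites):
            X[i, 1 + j] = s.covariates[cov]
    mean = X @ np.asarray(config.beta, dtype=float)

    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_sim, n))
    return mean[None, :] + z @ L.T
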