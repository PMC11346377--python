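# Methods

## The model

`streamnet` fits Gaussian linear models to data observed on dendritic stream
networks:

    y = X beta + z_tu + z_td + z_e + eps

where the three latent fields and the iid noise `eps` are mutually
independent, zero-mean Gaussian processes:

* **tail-up** `z_tu`: a moving-average construction pointing upstream.  Its
  covariance is nonzero only between *flow-connected* sites (water flows
  from one to the other) and is attenuated by spatial weights that account
  for branching;
* **tail-down** `z_td`: a moving-average construction pointing downstream,
  covering both flow-connected and flow-unconnected pairs (sites sharing a
  downstream junction without flow between them);
* **Euclidean** `z_e`: ordinary geostatistical dependence on straight-line
  distance, capturing drivers (geology, climate) not confined to the
  channel;
* **nugget** `eps`: spatially independent measurement/micro-scale variance
  `sigma2_0`.

Each spatial component has a partial sill (its variance) and a range.  The
marginal variance is the sum `sigma2_tu + sigma2_td + sigma2_e + sigma2_0`.

### Distances and flow-connectivity

Positions are encoded as (edge, ratio) with ratio measured from the
**downstream** node of the edge (0 = downstream end).  `up_dist` is the
along-network distance from the outlet.  For a pair of sites, `a >= b` are
the two distances to their closest common downstream point; the total
stream distance is `h = a + b`, and the pair is flow-connected exactly when
`b = 0`.  Sites on different networks (different `net_id`) have infinite
stream distance: tail-up and tail-down covariances are identically zero
across networks while the Euclidean component still applies.

### Additive function values and tail-up weights

AFVs are computed from a strictly positive additive attribute (cumulative
watershed area in real data; accumulated upstream channel length in the
synthetic generator).  The outlet edge has AFV 1; at each junction every
upstream edge gets the segment weight `omega = attr / sum(attr of
siblings)` and `afv(up) = afv(down) * omega`.  Junctions with more than two
upstream edges are allowed.  The tail-up weight between flow-connected
sites is `sqrt(afv_upstream / afv_downstream)`, which equals the square
root of the product of the segment weights crossed on the connecting path.
Edges with a zero or negative additive attribute are rejected rather than
imputed.

### Covariance forms

With `t = h/alpha` (flow-connected, and tail-up) and `ta = a/alpha`,
`tb = b/alpha` (tail-down, flow-unconnected):

| form         | flow-connected rho(t)              | flow-unconnected rho(a, b)                     |
|--------------|------------------------------------|------------------------------------------------|
| exponential  | exp(-t)                            | exp(-(ta + tb))                                |
| linear_sill  | (1 - t)+                           | (1 - ta)+                                      |
| spherical    | 1 - 3t/2 + t^3/2 on t <= 1         | (1 - ta)^2 (1 + ta/2 - 3 tb/2) on ta <= 1      |

Euclidean forms: exponential `exp(-d/alpha)`, gaussian `exp(-(d/alpha)^2)`,
spherical as above in `d/alpha`.

**Range convention.**  `alpha` is the natural scale of each form: the
e-folding distance for exponential/gaussian and the exact support for
spherical and linear-with-sill.  No effective-range factor (such as 3) is
applied anywhere; conventions differ across software, so check this before
comparing fitted ranges with other packages.

All stream forms derive from unilateral moving-average kernels
(exponential, indicator, triangular — all with kernel range equal to the
closed form's `alpha`).  `moving_average_oracle` recomputes every
correlation as `int g(x+a) g(x+b) dx / int g(x)^2 dx` by adaptive
quadrature; the test suite asserts agreement with the closed forms to 1e-6
over a grid of more than 200 `(a, b, alpha)` combinations.  This guards the
algebra, including the identity `(1-t)^2 (1+t/2) = 1 - 3t/2 + t^3/2` that
makes the spherical flow-unconnected form continuous at `b = 0`.

## Estimation

REML is the default (`estmethod="reml"`), ML optional:

* ML:   `-2l = log|Sigma| + r' Sigma^-1 r + n log 2pi`
* REML: `-2l = log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r + (n - p) log 2pi`

with `r = y - X beta_hat(theta)` and `beta_hat` the GLS estimate, always
computed through Cholesky factors (never an explicit inverse).

### Numerical strategy

* **Profiling.**  Fixed effects are profiled by GLS, and the overall
  variance scale is profiled analytically: writing `Sigma = v R`, the
  optimal `v` is `r' R^-1 r / (n - p)` (REML; `/n` for ML).  The numerical
  search therefore runs only over log variance *ratios* (each spatial
  component against the nugget) and log ranges.  A nugget-only model has no
  free parameters at all and is solved in closed form, which is why the
  degenerate iid model reproduces the `n-1`-divisor variance exactly.
* **Optimizer.**  Nelder–Mead on the log-scale free parameters, objective
  tolerance 1e-6, iteration cap 2000, plus two restarts from perturbed
  initial values (the restarts found better optima in roughly half of pilot
  replicates).  Initial values: the OLS residual variance split equally
  across active variance components; each range starts at half the median
  nonzero pairwise distance of its metric.
* **Range caps.**  Log-ranges are capped at twice the maximum pairwise
  distance of the relevant metric.  Beyond the data extent a range is not
  identifiable (the component degenerates toward a constant confounded with
  the intercept) and uncapped searches wander; the cap changes no
  identifiable optimum.
* **Cholesky jitter.**  If factorization fails, `1e-10 x mean(diag)` is
  added to the diagonal, escalating tenfold to `1e-6`; past that the
  objective returns +inf (optimization) or raises (final fit).
* **Hot path.**  The covariance is reassembled thousands of times per fit,
  so the component fills are JIT-compiled single passes over precomputed
  flow-connected / flow-unconnected index arrays.  They are tested for
  exact (1e-15) agreement with the plain numpy assembly.

### Information criteria and inference

`AIC = -2 loglik + 2q` with `q` the number of covariance parameters (sills,
ranges, nugget) under REML; under ML the fixed effects are added to the
count.  Coefficient p-values use the standard-normal reference with no
degrees-of-freedom adjustment, the usual asymptotic convention.  Covariance
parameter standard errors are not reported.  `pseudo_r2` is the squared
Pearson correlation between the response and the GLS fitted means — one of
several conventions, chosen for simplicity.

## Prediction

Universal kriging at site p:

    fitted = x_p' beta + c_p' Sigma^-1 (y - X beta)
    se^2   = sigma2_tot - c_p' Sigma^-1 c_p + m_p' (X' Sigma^-1 X)^-1 m_p
    m_p    = x_p - X' Sigma^-1 c_p

`c_p` contains only the spatial components (the nugget never correlates
distinct measurements), while `sigma2_tot` includes the nugget: intervals
are **prediction intervals** for a new noisy observation at the default
Gaussian 95% level.  The `m_p` term propagates the uncertainty of the
estimated fixed effects.  Consequences worth knowing: with a zero nugget,
kriging interpolates the observations exactly; with a positive nugget, a
prediction co-located with an observation does *not* collapse onto it and
keeps a positive standard error.  Tiny negative prediction variances from
floating-point cancellation are clamped at zero; anything beyond `-1e-10 x
sigma2_tot` triggers a warning.

Leave-one-out cross-validation holds the covariance estimate fixed (no
refit) and re-solves the kriging system for each held-out site, with fixed
effects re-estimated from the remaining `n - 1` sites.  It reports bias,
RMSPE, and empirical coverage of the prediction intervals.

## Simulation

`simulate_gaussian` draws `y = X beta + L z` with `L` the lower Cholesky
factor of the assembled covariance and `z` from `numpy.random.default_rng`
seeded by the configuration; replicates use independent draws and the same
seed is bit-reproducible on a platform.  Singular but PSD covariances
(e.g., co-located sites with no nugget) fall back to an eigendecomposition
square root so perfectly correlated sites simulate identically.

## The synthetic generator

`generate_network` grows a dendritic tree upstream from the outlet: each new
edge attaches to a random tip, or (with probability `branching_prob`) to an
edge that already has one upstream neighbor, giving predominantly binary
junctions.  Edge lengths are log-normal (default median 1 unit, sigma 0.5 on
the log scale; a 200-edge network then spans roughly 19 units along-stream
and 15 planar units).  The additive attribute is accumulated upstream
channel length — a crude watershed-area proxy; real watershed delineation is
out of scope.  The planar embedding draws each edge at a jittered heading
from its downstream node and may self-intersect; only network and point
distances enter the model, so this is accepted.

Observed sites are uniform over total channel length.  Prediction sites are
systematic: on each edge, positions every `pred_spacing` from the downstream
node (`floor(length/spacing)` sites per edge) plus the outlet itself, so at
least one prediction site always exists.  Covariates are `x1` (standard
normal) and `elev` (increasing in `up_dist` with noise, an elevation-like
gradient).

**What the generator does not emulate:** real network geometry and sinuosity,
non-Gaussian responses, preferential (non-uniform) sampling designs,
covariate measurement error, and discontinuities at confluences beyond what
the AFV weights encode.  Passing the simulation studies therefore certifies
the estimator and predictor under a correctly specified Gaussian model, not
robustness to the mis-specification found in field data.

## Reference study conditions

The parameter-recovery and interval-calibration studies use one 200-edge
network, 300 observed sites, and 50 simulated response replicates from

    tail-up  exponential: partial sill 2.0, range 6
    tail-down spherical:  partial sill 2.0, range 6
    euclidean gaussian:   partial sill 1.0, range 5
    nugget                0.5
    beta = (10, 1) on intercept + x1

Ranges are about one third of the network extent — long enough for spatial
structure to matter, short enough for sills and ranges to be separable at
n = 300.  Problem sizes (50 replicates, n = 300; leave-one-out calibration
pooled over 3 replicates; 10,000 replicates at 10 sites for simulation
fidelity) were chosen so the full suite runs comfortably on a single CPU.

## Known limitations

* Gaussian responses only; no GLM families, no nonspatial random effects,
  no Euclidean anisotropy.
* Variance-component estimates at moderate n are noisy and right-skewed —
  individual replicates can misattribute variance between the tail-down and
  Euclidean components even when medians are accurate.
* Coordinates must be planar (projected); no geodesic distances.
* The shapefile `.ssn` reader requires optional geospatial dependencies and
  is a stub without them; the CSV/GeoJSON layout is the native format.
* Block (segment-averaged) prediction is not implemented.
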