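# Methods

This note records the statistical model, the conventions, and the numerical
choices behind `corstab`, in enough detail to re-derive every number the
package produces.

## 1. Data-generating process

Each simulated cell is defined by a population correlation `rho`. A
*trajectory* is one sequentially growing sample: observations
`(x_i, y_i), i = 1..n_max` drawn once, with estimates computed on every
prefix `(x_1..x_n, y_1..y_n)` for `n = n_min..n_max`. Nested prefixes are
the point: they reproduce the "evolution of the estimate as data accumulate"
that a sequential study would see, and they make frequentist and Bayesian
estimates paired (same data) at every `n`.

Populations are standard bivariate normal with correlation `rho`, built from
independent standard normals via `y = rho·z0 + sqrt(1 − rho²)·z1`. Two
sampling modes:

- `iid` (default): each observation is a fresh draw.
- `finite_population`: a fixed pool of `pop_size = 1,000,000` members is
  materialized per cell and trajectories sample it without replacement.
  At `n_max = 500 ≪ 10^6` the finite-population correction is negligible;
  a Kolmogorov–Smirnov test in the suite confirms the two modes are
  statistically indistinguishable at these sizes. `iid` is the default
  because it is faster and exactly matches the stated model.

**Seeding.** All randomness derives from one `master_seed` through
`numpy.random.SeedSequence` hierarchies: the population seed is
`SeedSequence([master, key(rho), 0])` and replication `r`'s sampling seed is
`SeedSequence([master, key(rho), 1, r])`, with `key(rho)` a fixed integer
encoding. Consequences: runs are bit-for-bit reproducible, cells for
different `rho` are independent, and adding replications never changes
earlier ones. A `SeedLedger` with a SHA-256 digest of the seed tree is
written into every run manifest.

Default scales: 10,000 replications per frequentist cell, `n` from 10 to
500 (every integer for frequentist fits; a coarsened grid for Bayesian
fits — every `n` to 100, every 5th to 250, every 10th to 500). Scaled-down
Bayesian cells use 2,000 replications; with proportion SE ≈ 0.009 and
nearly flat proportion curves near a threshold, the first-crossing `n` then
carries a Monte Carlo SE of roughly 5–7 samples, which is the resolution we
report at.

## 2. Frequentist estimation

Prefix Pearson correlations are computed from cumulative sums of
`x, y, x², y², xy`, vectorized over all replications and all `n`
simultaneously; the suite verifies agreement with `scipy.stats.pearsonr`
to 1e−12. A zero-variance prefix yields NaN with a warning and is excluded
from proportion curves.

Confidence intervals use the Fisher z-transformation:
`tanh(atanh(r) ± z_{(1+L)/2} / sqrt(n − 3))` at levels 0.66, 0.90, 0.95.
Empirical coverage is tested against nominal within Monte Carlo error.

## 3. Bayesian estimation

The model treats the correlation as the slope of a standardized regression:

```
y_i ~ Normal(a + b·x_i, s²)
(b + 1)/2 ~ Beta(alpha, beta)        # so b is supported on (−1, 1)
a ~ Normal(0, 2.5)
s ~ Half-Cauchy(0, 1)
```

With unit-variance simulated data the slope `b` equals the population
correlation, so the Beta prior is a prior on the correlation itself.
Prior families:

- **weak**: `Beta(2, 2)` — symmetric, mildly regularizing toward 0.
- **moderate / high**: mode-centered at a chosen correlation `rho_c` with
  concentration `kappa` (10 and 50 respectively), via
  `alpha = m(kappa − 2) + 1`, `beta = (1 − m)(kappa − 2) + 1`,
  `m = (rho_c + 1)/2`. This is the standard mode/concentration
  parameterization of the Beta; only the prior's mode and spread are
  specified, so any pair with the same mode and concentration is
  equivalent.

The reported point estimate is the posterior mean of `b`; intervals are
central percentile intervals of the `b` posterior.

### Collapsed-grid posterior (primary fitter)

The intercept is integrated out analytically: conditional on `(b, s)`, the
`a`-integral is Gaussian, contributing `−½·log A + S_r²/(2 A s⁴)` with
`A = n/s² + 1/tau²` and `S_r = Σy − b·Σx`. The remaining 2-D posterior over
`(b, s)` is evaluated on a fixed grid — 401 equispaced `b` points on
(−0.999, 0.999) × 200 geometrically spaced `s` points on (0.05, 5) — using
only the sufficient statistics `(n, Σx, Σy, Σx², Σy², Σxy)`, so one fit
costs O(grid) regardless of `n`. Marginal means come from trapezoid
quadrature and quantiles from interpolating the normalized cumulative
marginal. The hot loop accumulates the grid cube in float32 with a float64
log-sum-exp reduction; the suite shows agreement with a brute-force 3-D
quadrature (dense `a × b × s` grid, float64) to ~1e−3 on means and with
MCMC within Monte Carlo SE. Typical cost ≈ 1 ms per fit; batches
parallelize over replication chunks with deterministic assembly (serial and
parallel results are bit-identical).

### MCMC cross-check

A self-contained random-walk Metropolis sampler on `(a, b, log s)` (4
chains, OLS-based initialization, step scale `2.4/sqrt(3)` of the rough
posterior scale) provides an independent check of the grid fitter; arviz
supplies R-hat and effective-sample-size diagnostics. It is not used in
batch runs — only for validation — because the grid fitter is two orders of
magnitude faster at this model size.

## 4. Stability criteria and required n

For each cell, model and `n`, the proportion of replications satisfying:

1. `sign_correct` — the point estimate has the sign of `rho`.
2. `robust_nonzero` — the interval at level `L` excludes 0 on the correct
   side (lower bound > 0 for positive `rho`).
3. `estimate_in_cos` — the point estimate lies inside the corridor of
   stability.
4. `interval_in_cos` — the entire interval at level `L` lies inside the
   corridor.

**Corridor convention.** The corridor of half-width `w` is `rho ± w` on the
raw correlation scale (clipped to (−1, 1)); this is the package default. A
z-scale variant `tanh(atanh(rho) ± w)` — an asymmetric band when
`rho ≠ 0` — is available via `cos_scale="z"`. The raw scale is the default
because, in high-precision fixed-`n` studies run during development, it is
the convention whose required-`n` values match the standard
corridor-of-stability results for these criteria; the choice is exposed as
a config field so either convention can be requested.

**Required n.** The reported required sample size is the *first* `n` on the
grid where the proportion reaches the threshold `P` (`rule="first"`); a
stricter `rule="sustained"` (threshold met at every later grid point) is
available. Crossings at the smallest grid point are reported as
`< n_min`, never-reached thresholds as `> n_max` (left/right censoring,
mirroring how such tables are usually printed). Each crossing carries the
binomial standard error of the proportion at that `n`. Because proportion
curves are nearly flat near high thresholds, small Monte Carlo wiggles in
the curve translate into several-sample wiggles in the crossing; the
binomial SE at the crossing is the honest uncertainty summary.

Tables add the percent change of each model's required `n` relative to the
frequentist reference in the same cell.

## 5. What the generator emulates vs. real data

The generator produces idealized bivariate-normal sequential samples:
no measurement error model, no missingness, no non-normal marginals, no
drift in the population over time. Conclusions about required sample sizes
therefore apply to the best case; heavier tails or attenuation would shift
the curves right. The `finite_population` mode emulates sampling from a
large fixed cohort rather than an infinite population, which matters only
when `n_max` approaches the pool size.

## 6. Limitations

- The moderate/high prior families are specified by mode and concentration
  only; results for them are covered by qualitative/property checks
  (shrinkage monotone in `kappa`, prior-consistency of the point estimate),
  not by numeric replication targets.
- The grid posterior's `b` resolution is 0.005; quantile interpolation
  refines this below grid spacing, but intervals are not exact beyond
  ~1e−3.
- Required-`n` values inherit Monte Carlo noise from both the proportion
  estimate and the grid spacing of `n`; at 10,000 replications the
  first-crossing SE is a few samples, at 2,000 replications roughly 5–7.
- The MCMC sampler is a validation tool, not a production sampler; it uses
  a simple random-walk kernel and would be inefficient for larger models.
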