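# Methods

This note records the statistical conventions and numerical choices the
package implements, in enough detail to reproduce every number it
prints.

## The classification problem

Lot quality assurance sampling (LQAS) classifies a supervision area by
comparing the number of successes `X` among `n` sampled subjects to a
decision rule `d`: the area is classified *low* (coverage below
standard) when `X <= d`. Given a threshold couplet `p_l < p_u`, the two
misclassification risks are

```
alpha = P(X <= d | p = p_u)     (provider risk)
beta  = P(X >  d | p = p_l)     (population risk)
```

A design `(n, d)` is *feasible* when `alpha <= a` and `beta <= b` for
the chosen caps (default `.1/.1`). Both risks are monotone in `d`
(alpha non-decreasing, beta non-increasing), so the feasible rules at a
given `n` form a contiguous interval; searches report its lower end and
attach the full interval.

Some applications state the rule on the failure-count scale ("classify
acceptable iff failures <= d_fail", e.g. malnutrition case counts).
That rule equals "successes > n - d_fail - 1", so the success-scale rule
is `d = n - d_fail - 1`; reports show both scales.

## Clustering and its two parameterizations

Field surveys draw `k` clusters of `m` subjects. Let `p_j` be the true
coverage of cluster `j`, with mean `p` and standard deviation `sigma`
across clusters. The intraclass correlation is

```
rho = sigma^2 / (p (1 - p))
```

so fixing `sigma` across coverage levels and fixing `rho` are different
modeling choices: a fixed `sigma = .1` implies `rho` rising from .04 at
`p = .55` to .21 at `p = .95`, while a fixed `rho = .1` implies `sigma`
falling from .16 to .07 over the same range. `ClusteringSpec` carries
either convention, or a coverage-dependent `rho(p)` given as a callable
or an interpolated `(p, rho)` grid, and resolves whichever parameter a
model needs at the coverage where a risk is evaluated. Every risk
computation resolves the clustering *at its own threshold*: `alpha`
uses the spec at `p_u` and `beta` the spec at `p_l`.

## The three cluster models

**Binomial-scaled (`pezzoli`).** The latent cluster coverage is
`p_j = Binomial(eta, p) / eta` with the integer mixing index
`eta = round(p (1 - p) / sigma^2)` (equivalently `round(1 / rho)`), so
`SD(p_j) ~ sigma`. The cluster count given `p_j` is `Binomial(m, p_j)`.
Because `p_j` has only `eta + 1` support points, the cluster-count pmf
is an exact finite mixture, and the survey total's pmf follows by
`k`-fold convolution — the simulation historically used for this model
is replaced by a closed form (and kept available as a seeded
cross-check).

**Beta-binomial (`hedt`).** `p_j ~ Beta(a, b)` with
`a = p (1 - rho) / rho`, `b = (1 - p)(1 - rho) / rho`, i.e. mean `p` and
intraclass correlation `rho`; cluster counts are beta-binomial and the
total is again an exact `k`-fold convolution. `rho = 0` degenerates to
the binomial and `rho = 1` to the two-point mixture on `{0, m}`.

**Effective sample size (`hund`).** An overdispersed (quasi-binomial)
count with design effect `D = 1 + (m - 1) rho` is approximated by the
effective binomial `X* ~ Binomial(n*, p)` with `n* = round(n / D)`, and
the rule is mapped to `d* = round(d / D)`. Risks are binomial tails on
the effective scale, with `D` recomputed at each threshold's `rho`.

All three models share mean `n p`; the two latent-coverage models also
share total variance `n p (1 - p) (1 + (m - 1) rho)` up to the integer
rounding of `eta`, and in practice produce nearly identical risks. The
effective-sample-size model differs mainly through rounding at small
effective sizes.

## Rounding conventions

These conventions were reverse-engineered to reproduce the published
benchmark designs exactly and are applied consistently:

1. **Effective counts round half away from zero.** `round(x) =
   floor(x + .5)` for `n / D`, `d / D`, and `eta`. Example: `n = 80`,
   `d = 66`, `rho = .11`, `m = 10` gives `D = 1.99` and effective design
   `(40, 33)` — identical to the SRS design for the same couplet.
2. **The design search back-transforms the minimal effective rule with
   ties to even.** The search finds the smallest feasible effective rule
   `d*` and reports the original-scale `d = round(d* x D)` under the
   banker's rounding of the standard library. The two conventions
   differ only at exact halves: `d* = 175`, `D = 1.9` yields
   `332.5 -> 332`. The smallest feasible original-scale `d` can be one
   unit lower than this back-transform (its whole feasible interval is
   attached to the returned design).
3. **The Monte-Carlo evaluator for the effective-scale model compares on
   the continuous scale.** A draw is classified low when `D * X* <= d`,
   with the product compared in floating point. This mirrors the
   historical simulation workflow, including its boundary behavior: when
   `d / D` is an exact integer in real arithmetic, floating-point dust in
   `D` can exclude the boundary point (e.g. `D = 1 + 9 x .11` is
   slightly above `1.99`, so `D * 33 <= 66` is false even though
   `66 / 1.99 = 33` after rounding). The deterministic evaluator
   (`model_risks`) instead uses convention 1; the two can differ by one
   effective unit at such boundaries, and both are exposed on purpose.
4. **Failure-scale rules round on the failure scale.** For a case-count
   rule, the effective threshold is `round(d_fail / D)` applied to the
   failure-count binomial, not the success-scale `round(d / D)`; the two
   orders of operations differ when rounding breaks differently.

## Estimating `sigma^2` from published summaries

Reports typically give, per area, the estimated coverage `p_hat`
(mean of estimated cluster coverages), the SD `s` of those estimated
cluster coverages (or the standard error `se = s / sqrt(k)`), and the
geometry `(k, m)`. Since each cluster estimate carries within-cluster
binomial noise, `s^2` overstates `sigma^2`; the method-of-moments
correction is

```
sigma2_hat = (m s^2 - p_hat (1 - p_hat)) / (m - 1),   truncated at 0.
```

The estimator is unbiased for `sigma^2` *before* truncation; the
truncated version is non-negative by construction and carries a small
positive-part bias near `sigma^2 = 0` (flagged per row so downstream
users can see how often it binds). The implied
`rho_hat = sigma2_hat / (p_hat (1 - p_hat))` is attached when defined.

## Design searches

Sample size grows by whole clusters at fixed `m` (the costly unit in the
field is the cluster visit), or by subjects per cluster at fixed `k`.
Feasibility is re-evaluated exactly at each candidate size; note that
feasibility is *not* monotone in `n` for the effective-scale model
(rounding can destroy a rule that a smaller `n` admitted), so the scan
does not early-out on infeasibility. A cost-based variant scans a grid
of `m` values and minimizes `k x cost_per_cluster + n x
cost_per_subject`. Heavy clustering can make a fixed-`k` target
infeasible at any `m` — the design effect grows as fast as the
information — which is reported as an explicit infeasibility error
rather than a cap-sized design.

## Numerical choices

- Beta-binomial pmfs come from `scipy.stats.betabinom`; binomial tails
  from `scipy.stats.binom`; convolution via `numpy.convolve` (direct,
  not FFT — supports up to `n ~ 10^4` are exact to machine precision).
- Below `rho = 1e-10` the beta-binomial is evaluated as a plain
  binomial: the design effect is within `1e-8` of 1 there, while the
  beta shapes `~ 1/rho` overflow the special functions.
- Special-function pmfs can mis-state total mass by `~1e-6` at extreme
  shapes; `convolve_iid` renormalizes its base pmf (after validating the
  mass is within `1e-5` of 1) so the drift does not compound `k`-fold.
- All samplers take a `numpy.random.Generator` or integer seed; every
  simulation-derived number is reported with its Monte-Carlo standard
  error and the seed that produced it.

## Limitations

- Clusters are assumed equal-sized and independent, with a common `m`;
  unequal cluster sizes and finite-population corrections are out of
  scope.
- The effective-sample-size model is an approximation by construction;
  its risks are sensitive to rounding at small `n / D`, which is the
  main practical difference from the latent-coverage models.
- The `sigma^2` estimator needs `m >= 2` and `k >= 2`, and its
  truncation bias matters when true clustering is near zero.
- Published benchmark risks for the latent-coverage designs were
  produced by 10,000-draw simulation; exact values agree with them
  within Monte-Carlo error but not digit-for-digit.
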