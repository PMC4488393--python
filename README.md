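# clusterlqas

Design and evaluate LQAS classification surveys under two-stage cluster
sampling.

## The problem

Lot quality assurance sampling (LQAS) gives program managers a cheap
verdict on a supervision area: sample `n` subjects, count successes
`X` (vaccinated children, households with adequate nutrition, ...), and
classify the area *low* when `X <= d`. The design `(n, d)` is chosen so
that two error probabilities stay below caps:

- **provider risk** `alpha = P(X <= d | p = p_u)` — a well-performing
  area (coverage at the upper threshold `p_u`) is condemned;
- **population risk** `beta = P(X > d | p = p_l)` — a failing area
  (coverage at the lower threshold `p_l`) is cleared.

The classical design assumes `X ~ Binomial(n, p)`. Field LQAS surveys,
however, sample `k` clusters of `m` subjects, and subjects within a
cluster are correlated: if cluster coverages `p_j` vary with standard
deviation `sigma` (equivalently intraclass correlation
`rho = sigma^2 / (p(1-p))`), the variance of `X` is inflated by the
design effect `1 + (m-1) rho` and the binomial design quietly exceeds
both risk caps. This package implements, compares, and inverts the
three corrections in use:

| method    | model for the survey total                                            |
|-----------|-----------------------------------------------------------------------|
| `pezzoli` | cluster coverage `Binomial(eta, p)/eta`, `eta = round(p(1-p)/sigma^2)` |
| `hedt`    | beta-binomial cluster counts with intraclass correlation `rho`         |
| `hund`    | effective binomial: `n* = round(n/D)`, `d* = round(d/D)`, `D = 1+(m-1)rho` |

For the two latent-coverage models the survey total's distribution is
computed **exactly** by `k`-fold convolution of the finite cluster pmf —
no simulation needed — and seeded Monte-Carlo samplers are provided as
cross-checks. The package also converts between the `sigma` and `rho`
parameterizations (they are *not* interchangeable across coverage
levels), estimates `sigma^2` from the summary statistics surveys
actually publish, and draws operating-characteristic curves, including
with coverage-dependent clustering. See `docs/methods.md` for the full
conventions.

## Worked example

How many clusters of 10 are needed to classify against a 75%/90%
couplet with both risks capped at .1, when cluster coverages have
SD `sigma = .1`?

```python
from clusterlqas import ClusteringSpec, DesignTargets, compare_designs

table = compare_designs(
    targets_list=[DesignTargets(0.75, 0.90)],
    m=10,
    clustering_spec_list=[ClusteringSpec.from_sigma(0.1)],
    methods=["srs", "pezzoli", "hund", "hedt"],
)
print(table.round({"alpha": 3, "beta": 3}).to_string(index=False))
```

prints (risks are exact, not simulated):

```
 couplet  method clustering  n  d   k    m  alpha  beta
0.75-0.9     srs            40 33 NaN  NaN  0.100 0.096
0.75-0.9 pezzoli  sigma=0.1 80 66 8.0 10.0  0.084 0.078
0.75-0.9    hund rho_l=0.05 70 58 7.0 10.0  0.093 0.071
0.75-0.9    hund rho_u=0.11 80 66 8.0 10.0  0.100 0.096
0.75-0.9    hedt rho_l=0.05 70 58 7.0 10.0  0.080 0.081
0.75-0.9    hedt rho_u=0.11 90 75 9.0 10.0  0.095 0.078
```

Ignoring clustering calls for 40 subjects; accounting for it roughly
doubles the sample. The `rho_l`/`rho_u` rows show the same fixed
`sigma` converted to `rho` at each threshold — the choice of
parameterization changes the design.

The same search is available from the shell:

```sh
$ clusterlqas design --method hedt --p-l 0.75 --p-u 0.90 --rho 0.1 -m 10
# clusterlqas 0.1.0
# config: {"alpha": 0.1, "beta": 0.1, "clustering": "rho=0.1", "k": null, "m": 10, "method": "hedt", "mode": "exact", "n_sims": 10000, "p_l": 0.75, "p_u": 0.9, "seed": null, "subcommand": "design"}
method  n  d  k  m    alpha     beta  rho_l  rho_u  sigma_l  sigma_u  d_fail
  hedt 90 75  9 10 0.090322 0.072395    0.1    0.1 0.136931 0.094868      14
```

Other subcommands: `risks` (exact risks of a given design, success- or
failure-scale rules), `simulate` (seeded Monte Carlo with standard
errors), `oc` (operating-characteristic curves, optional plot),
`estimate` (per-area `sigma^2` from a survey-summary CSV), `fixture`
(synthetic survey-summary generator), `compare` (tables as above).
Every run embeds its version, seed, and resolved configuration in the
output header.

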