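"""Survey-total distributions under the four cluster-LQAS models.

An LQAS survey classifies an area by comparing the number of successes
``X`` in a sample of ``n = k * m`` subjects (``k`` clusters, ``m`` per
cluster) to a decision rule ``d``: the area is classified low (coverage
below standard) when ``X <= d``.  The misclassification risks are

    ``alpha = P(X <= d | p = p_u)``   (provider risk),
    ``beta  = P(X >  d | p = p_l)``   (population risk),

evaluated at the coverage thresholds under one of four models for ``X``:

``srs``
    plain ``Binomial(n, p)`` -- clustering ignored;
``hedt``
    per-cluster counts are beta-binomial: the cluster coverage ``p_j`` is
    Beta-distributed with mean ``p`` and intraclass correlation ``rho``;
``pezzoli``
    binomial-scaled: ``p_j = Binomial(eta, p) / eta`` with integer mixing
    index ``eta ~ p(1-p)/sigma^2``, so ``p_j`` has ``eta + 1`` support
    points with SD close to ``sigma``;
``hund``
    overdispersed (quasi-)binomial with design effect
    ``D = 1 + (m - 1) rho``, evaluated on the effective scale
    ``X* ~ Binomial(round(n / D), p)`` against the effective rule
    ``round(d / D)``.

For the two latent-coverage models the per-cluster mass function has a
small finite description, so the distribution of the survey total is
computed *exactly* by k-fold convolution rather than by simulation.
Seeded samplers for all four models are provided alongside for
simulation-fidelity checks and Monte-Carlo studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import betabinom, binom

from .params import ClusteringSpec, DesignTargets, design_effect, round_half_away

__all__ = [
    "TotalPMF",
    "ClusterSample",
    "binomial_risks",
    "betabinomial_pmf",
    "binomial_scaled_pmf",
    "cluster_pmf",
    "convolve_iid",
    "total_pmf",
    "hund_effective",
    "model_risks",
    "sample_totals",
    "sample_total",
    "failure_rule_to_success",
    "METHODS",
]

METHODS = ("srs", "pezzoli", "hedt", "hund")

_NORMALIZATION_TOL = 1e-9
_RENORM_DRIFT = 1e-12
# below this, rho is numerically indistinguishable from no clustering
_RHO_BINOMIAL_THRESHOLD = 1e-10


@dataclass(frozen=True)
class TotalPMF:
    """Exact probability mass function of a survey total on support 0..n."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a non-empty 1-d array")
        if np.any(probs < -1e-15):
            raise ValueError("pmf has negative mass")
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            raise ValueError(f"pmf mass {total} deviates from 1 beyond tolerance")
        if abs(total - 1.0) > _RENORM_DRIFT:
            probs = probs / total
        object.__setattr__(self, "probs", probs)

    @property
    def n(self) -> int:
        return self.probs.size - 1

    def cdf(self, d: int) -> float:
        """P(X <= d)."""
        if d < 0:
            return 0.0
        return float(self.probs[: min(d, self.n) + 1].sum())

    def sf(self, d: int) -> float:
        """P(X > d)."""
        return 1.0 - self.cdf(d)

    def mean(self) -> float:
        return float(np.arange(self.n + 1) @ self.probs)

    def var(self) -> float:
        x = np.arange(self.n + 1)
        mu = self.mean()
        return float(((x - mu) ** 2) @ self.probs)

    def to_array(self) -> np.ndarray:
        return self.probs.copy()


@dataclass(frozen=True)
class ClusterSample:
    """One simulated survey: per-cluster success counts and latent coverages."""

    counts: np.ndarray
    latent_coverages: Optional[np.ndarray] = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def binomial_risks(
    n: int, d: int, p_l: float, p_u: float
) -> Tuple[float, float]:
    """Exact (alpha, beta) for the plain binomial model at sample size ``n``.

    ``alpha = P(X <= d | p_u)`` and ``beta = P(X > d | p_l)`` with
    ``X ~ Binomial(n, p)``, the risks evaluated at the threshold
    coverages where they are largest.
    """
    if not 0 <= d <= n:
        raise ValueError(f"decision rule d={d} outside support 0..{n}")
    alpha = float(binom.cdf(d, n, p_u))
    beta = float(binom.sf(d, n, p_l))
    return alpha, beta


def betabinomial_pmf(m: int, p: float, rho: float) -> np.ndarray:
    """Beta-binomial pmf of one cluster's success count on 0..m.

    The cluster coverage is Beta with mean ``p`` and intraclass
    correlation ``rho``, i.e. shape parameters ``a = p (1 - rho) / rho``
    and ``b = (1 - p)(1 - rho) / rho``; the count given the coverage is
    binomial.  ``rho = 0`` degenerates to ``Binomial(m, p)`` and
    ``rho = 1`` to the two-point mixture on {0, m}.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    x = np.arange(m + 1)
    if rho < _RHO_BINOMIAL_THRESHOLD:
        # beta shapes ~ 1/rho overflow the beta-binomial evaluation long
        # before the design effect 1 + (m-1) rho differs measurably from 1
        return binom.pmf(x, m, p)
    if rho == 1.0:
        pmf = np.zeros(m + 1)
        pmf[0] = 1.0 - p
        pmf[m] += p
        return pmf
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return betabinom.pmf(x, m, a, b)


def binomial_scaled_pmf(m: int, p: float, eta: int) -> np.ndarray:
    """Binomial-scaled pmf of one cluster's success count on 0..m.

    The cluster coverage takes the values ``j / eta`` with
    ``Binomial(eta, p)`` weights, so the count is the exact finite
    mixture ``sum_j P(eta, p)(j) * Binomial(m, j/eta)``.  This closed
    form replaces the simulation traditionally used for this model.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if eta < 1 or eta != int(eta):
        raise ValueError(f"eta must be a positive integer, got {eta}")
    eta = int(eta)
    j = np.arange(eta + 1)
    weights = binom.pmf(j, eta, p)
    x = np.arange(m + 1)
    # rows: coverage support points j/eta; columns: count 0..m
    component = binom.pmf(x[None, :], m, (j / eta)[:, None])
    return weights @ component


def cluster_pmf(
    method: str, m: int, p: float, clustering: ClusteringSpec
) -> np.ndarray:
    """Per-cluster success-count pmf for a latent-coverage model.

    Dispatches to the beta-binomial (``hedt``) or binomial-scaled
    (``pezzoli``) pmf with the clustering spec resolved at coverage
    ``p``; ``srs`` returns the plain binomial pmf.
    """
    if method == "hedt":
        return betabinomial_pmf(m, p, clustering.rho_at(p))
    if method == "pezzoli":
        return binomial_scaled_pmf(m, p, clustering.eta_at(p))
    if method == "srs":
        return binom.pmf(np.arange(m + 1), m, p)
    raise ValueError(
        f"no exact cluster pmf for method {method!r}; expected one of "
        "'srs', 'pezzoli', 'hedt'"
    )


def convolve_iid(pmf: np.ndarray | TotalPMF, k: int) -> TotalPMF:
    """Exact distribution of the sum of ``k`` iid cluster counts.

    Iterated direct convolution; supports up to ``k * m ~ 1e4`` are
    handled comfortably without FFT.
    """
    if k < 1:
        raise ValueError(f"cluster count k must be >= 1, got {k}")
    base = pmf.probs if isinstance(pmf, TotalPMF) else np.asarray(pmf, float)
    total = base.sum()
    # extreme shape parameters can cost the special functions ~1e-6 in mass
    if abs(total - 1.0) > 1e-5:
        raise ValueError(f"base pmf mass {total} deviates from 1 beyond tolerance")
    # renormalize away the few-ulp mass drift of special-function pmfs so
    # it does not compound k-fold in the convolution
    base = base / total
    out = np.array([1.0])
    for _ in range(k):
        out = np.convolve(out, base)
    return TotalPMF(out)


def total_pmf(
    method: str, k: int, m: int, p: float, clustering: ClusteringSpec
) -> TotalPMF:
    """Exact pmf of the survey total ``X`` for an exactly-computable model."""
    return convolve_iid(cluster_pmf(method, m, p, clustering), k)


def hund_effective(
    n: int, d: int, m: int, rho: float
) -> Tuple[int, int, float]:
    """Effective sample size and rule under the design-effect model.

    Returns ``(n_star, d_star, D)`` where ``D = 1 + (m - 1) rho`` and the
    effective counts are nearest-integer ``n / D`` and ``d / D``.
    """
    D = design_effect(m, rho)
    return round_half_away(n / D), round_half_away(d / D), D


def failure_rule_to_success(n: int, d_fail: int) -> int:
    """Convert a failure-count rule to the success scale.

    A rule "classify acceptable iff failures <= d_fail" is equivalent to
    "successes > n - d_fail - 1", so the success-scale decision rule is
    ``d = n - d_fail - 1``.
    """
    if not 0 <= d_fail <= n - 1:
        raise ValueError(f"failure rule {d_fail} outside 0..{n - 1}")
    return n - d_fail - 1


def model_risks(
    method: str,
    k: int,
    m: int,
    d: int,
    targets: DesignTargets,
    clustering: Optional[ClusteringSpec] = None,
    rule_scale: str = "success",
) -> Tuple[float, float]:
    """Exact (alpha, beta) of a ``k x m`` design with rule ``d`` under a model.

    ``alpha`` is evaluated at ``p_u`` and ``beta`` at ``p_l``, each with
    the clustering spec resolved at that threshold (a sigma-fixed spec
    yields different ``rho`` at the two thresholds, and vice versa for
    the binomial-scaled mixing index).

    ``rule_scale`` matters only for the ``hund`` model, whose effective
    counts are rounded on the scale the rule was stated on: ``"success"``
    rounds ``d / D`` directly, while ``"failure"`` (used e.g. by
    malnutrition case-count rules) rounds the failure threshold
    ``(n - d - 1) / D`` and evaluates the failure-count binomial.  ``d``
    is always given on the success scale; use
    :func:`failure_rule_to_success` to convert a case-count rule first.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if rule_scale not in ("success", "failure"):
        raise ValueError(f"rule_scale must be 'success' or 'failure', got {rule_scale!r}")
    n = k * m
    if not 0 <= d <= n:
        raise ValueError(f"decision rule d={d} outside support 0..{n}")
    if method == "srs":
        return binomial_risks(n, d, targets.p_l, targets.p_u)
    if clustering is None:
        raise ValueError(f"method {method!r} requires a clustering spec")
    if method == "hund":
        rho_l = clustering.rho_at(targets.p_l)
        rho_u = clustering.rho_at(targets.p_u)
        if rule_scale == "success":
            n_u, d_u, _ = hund_effective(n, d, m, rho_u)
            n_l, d_l, _ = hund_effective(n, d, m, rho_l)
            alpha = float(binom.cdf(d_u, n_u, targets.p_u))
            beta = float(binom.sf(d_l, n_l, targets.p_l))
        else:
            f = n - d - 1  # failure-count threshold
            n_u, f_u, _ = hund_effective(n, f, m, rho_u)
            n_l, f_l, _ = hund_effective(n, f, m, rho_l)
            # classify acceptable iff failures <= f*; failure prob is 1 - p
            alpha = float(binom.sf(f_u, n_u, 1.0 - targets.p_u))
            beta = float(binom.cdf(f_l, n_l, 1.0 - targets.p_l))
        return alpha, beta
    pmf_u = total_pmf(method, k, m, targets.p_u, clustering)
    pmf_l = total_pmf(method, k, m, targets.p_l, clustering)
    return pmf_u.cdf(d), pmf_l.sf(d)


def sample_totals(
    method: str,
    k: int,
    m: int,
    p: float,
    clustering: Optional[ClusteringSpec],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized draws of the survey total ``X`` under a model.

    * ``srs``: ``Binomial(km, p)``.
    * ``hedt``: cluster coverages from the Beta distribution, then
      binomial counts, summed over clusters.
    * ``pezzoli``: cluster coverages ``Binomial(eta, p) / eta``, then
      binomial counts.
    * ``hund``: an effective-scale binomial draw rescaled by the design
      effect and rounded to the nearest integer,
      ``round(D * Binomial(round(n/D), p))``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    n = k * m
    if method == "srs":
        return rng.binomial(n, p, size=size)
    if clustering is None:
        raise ValueError(f"method {method!r} requires a clustering spec")
    if method == "hedt":
        rho = clustering.rho_at(p)
        if rho < _RHO_BINOMIAL_THRESHOLD:
            return rng.binomial(n, p, size=size)
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        pj = rng.beta(a, b, size=(size, k))
        return rng.binomial(m, pj).sum(axis=1)
    if method == "pezzoli":
        eta = clustering.eta_at(p)
        pj = rng.binomial(eta, p, size=(size, k)) / eta
        return rng.binomial(m, pj).sum(axis=1)
    # hund: rescaled effective-scale draws
    D = design_effect(m, clustering.rho_at(p))
    n_star = round_half_away(n / D)
    x_star = rng.binomial(n_star, p, size=size)
    return np.floor(D * x_star + 0.5).astype(np.int64)


def sample_total(
    method: str,
    k: int,
    m: int,
    p: float,
    clustering: Optional[ClusteringSpec],
    rng: np.random.Generator | int,
    return_clusters: bool = False,
):
    """One draw of the survey total (optionally with per-cluster detail).

    ``rng`` may be a :class:`numpy.random.Generator` or an integer seed.
    With ``return_clusters=True`` (latent-coverage models only) a
    :class:`ClusterSample` is returned instead of a bare integer.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not return_clusters:
        return int(sample_totals(method, k, m, p, clustering, 1, rng)[0])
    if method == "hedt":
        rho = clustering.rho_at(p)
        if rho < _RHO_BINOMIAL_THRESHOLD:
            pj = np.full(k, p)
        else:
            a = p * (1.0 - rho) / rho
            b = (1.0 - p) * (1.0 - rho) / rho
            pj = rng.beta(a, b, size=k)
    elif method == "pezzoli":
        eta = clustering.eta_at(p)
        pj = rng.binomial(eta, p, size=k) / eta
    else:
        raise ValueError(
            f"per-cluster detail is only defined for latent-coverage models, "
            f"not {method!r}"
        )
    counts = rng.binomial(m, pj)
    return ClusterSample(counts=counts, latent_coverages=pj)
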