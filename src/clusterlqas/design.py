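"""Decision-rule and sample-size searches for cluster-LQAS designs.

All searches enforce the two risk constraints

    ``P(X <= d | p = p_u) <= alpha``  and  ``P(X > d | p = p_l) <= beta``

exactly, using the exact total-count distributions from
:mod:`clusterlqas.models`.  Sample size is grown by whole clusters at a
fixed per-cluster size ``m`` (or by subjects per cluster at a fixed
``k``), mirroring field practice where the costly unit is the cluster
visit.  The alpha constraint is non-decreasing and the beta constraint
non-increasing in ``d``, so the feasible rules at a given size form a
contiguous interval; searches return its lower end (with the full
interval attached) except for the effective-sample-size construction,
which back-transforms the minimal effective rule (see
:func:`hund_design`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .errors import InfeasibleDesignError
from .models import (
    TotalPMF,
    binomial_risks,
    cluster_pmf,
    model_risks,
    sample_totals,
)
from .params import (
    ClusteringSpec,
    DesignTargets,
    design_effect,
    round_half_away,
)

__all__ = [
    "FeasibleRules",
    "ClusterDesign",
    "SRSDesign",
    "find_feasible_d",
    "find_srs_design",
    "find_cluster_design",
    "find_cluster_design_fixed_k",
    "hund_design",
    "pezzoli_design",
    "cost_optimal_design",
    "DEFAULT_N_CAP",
    "DEFAULT_K_CAP",
    "DEFAULT_M_CAP",
]

DEFAULT_N_CAP = 10_000
DEFAULT_K_CAP = 2_000
DEFAULT_M_CAP = 500


@dataclass(frozen=True)
class FeasibleRules:
    """The contiguous interval of decision rules meeting both risk caps."""

    d_min: int
    d_max: int
    alpha_at_min: float
    beta_at_min: float

    @property
    def d(self) -> int:
        """The returned rule (lower end of the feasible interval)."""
        return self.d_min


@dataclass(frozen=True)
class SRSDesign:
    """A simple-random-sampling LQAS design (n, d) with achieved risks."""

    n: int
    d: int
    alpha_hat: float
    beta_hat: float
    feasible: Optional[FeasibleRules] = None


@dataclass(frozen=True)
class ClusterDesign:
    """A two-stage cluster LQAS design with its achieved risks.

    ``clustering_used`` records the parameters actually resolved at each
    threshold (``rho_l``/``rho_u``, ``sigma_l``/``sigma_u``, and for the
    binomial-scaled model the mixing indices ``eta_l``/``eta_u``; for
    the effective-sample-size construction also ``D_l``/``D_u`` and
    ``n_star``/``d_star``).
    """

    method: str
    k: int
    m: int
    d: int
    alpha_hat: float
    beta_hat: float
    clustering_used: Dict[str, float] = field(default_factory=dict)
    feasible: Optional[FeasibleRules] = None
    warnings: Tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.k * self.m

    def to_record(self) -> Dict[str, object]:
        """Flat record mirroring the published comparison-table columns."""
        rec: Dict[str, object] = {
            "method": self.method,
            "n": self.n,
            "d": self.d,
            "k": self.k,
            "m": self.m,
            "alpha": self.alpha_hat,
            "beta": self.beta_hat,
        }
        rec.update(self.clustering_used)
        return rec


def _feasible_from_risk_arrays(
    alpha: np.ndarray, beta: np.ndarray, targets: DesignTargets
) -> Optional[FeasibleRules]:
    ok = (alpha <= targets.alpha) & (beta <= targets.beta)
    if not ok.any():
        return None
    idx = np.flatnonzero(ok)
    d_min, d_max = int(idx[0]), int(idx[-1])
    return FeasibleRules(
        d_min=d_min,
        d_max=d_max,
        alpha_at_min=float(alpha[d_min]),
        beta_at_min=float(beta[d_min]),
    )


def find_feasible_d(
    total_pmf_at_pl: TotalPMF,
    total_pmf_at_pu: TotalPMF,
    targets: DesignTargets,
) -> Optional[FeasibleRules]:
    """Smallest decision rule meeting both risk caps, or ``None``.

    ``alpha(d)`` is the upper-threshold CDF and ``beta(d)`` the
    lower-threshold survival function of the candidate rule; monotone in
    ``d``, so the feasible set is an interval, returned in full.
    """
    if total_pmf_at_pl.n != total_pmf_at_pu.n:
        raise ValueError(
            "the two total pmfs must share the same support "
            f"(got 0..{total_pmf_at_pl.n} and 0..{total_pmf_at_pu.n})"
        )
    alpha = np.cumsum(total_pmf_at_pu.probs)
    beta = 1.0 - np.cumsum(total_pmf_at_pl.probs)
    return _feasible_from_risk_arrays(alpha, beta, targets)


def _binomial_feasible(
    n: int, targets: DesignTargets
) -> Optional[FeasibleRules]:
    d = np.arange(n + 1)
    alpha = binom.cdf(d, n, targets.p_u)
    beta = binom.sf(d, n, targets.p_l)
    return _feasible_from_risk_arrays(alpha, beta, targets)


def find_srs_design(
    targets: DesignTargets, n_max: int = DEFAULT_N_CAP
) -> SRSDesign:
    """Smallest binomial sample size admitting a feasible decision rule."""
    for n in range(1, n_max + 1):
        rules = _binomial_feasible(n, targets)
        if rules is not None:
            return SRSDesign(
                n=n,
                d=rules.d,
                alpha_hat=rules.alpha_at_min,
                beta_hat=rules.beta_at_min,
                feasible=rules,
            )
    raise InfeasibleDesignError(
        f"no SRS design with n <= {n_max} satisfies "
        f"alpha <= {targets.alpha}, beta <= {targets.beta}"
    )


def _clustering_record(
    method: str, clustering: ClusteringSpec, targets: DesignTargets, m: int
) -> Dict[str, float]:
    rec = {
        "rho_l": clustering.rho_at(targets.p_l),
        "rho_u": clustering.rho_at(targets.p_u),
        "sigma_l": clustering.sigma_at(targets.p_l),
        "sigma_u": clustering.sigma_at(targets.p_u),
    }
    if method == "pezzoli":
        rec["eta_l"] = clustering.eta_at(targets.p_l)
        rec["eta_u"] = clustering.eta_at(targets.p_u)
    if method == "hund":
        rec["D_l"] = design_effect(m, rec["rho_l"])
        rec["D_u"] = design_effect(m, rec["rho_u"])
    return rec


def _exact_design_at(
    method: str,
    targets: DesignTargets,
    clustering: ClusteringSpec,
    k: int,
    m: int,
) -> Optional[FeasibleRules]:
    """Feasible rules of a k x m design under an exactly-computable model."""
    from .models import total_pmf  # local import avoids cycle at module load

    pmf_l = total_pmf(method, k, m, targets.p_l, clustering)
    pmf_u = total_pmf(method, k, m, targets.p_u, clustering)
    return find_feasible_d(pmf_l, pmf_u, targets)


def _hund_feasible(
    n: int, m: int, targets: DesignTargets, clustering: ClusteringSpec
) -> Optional[Tuple[FeasibleRules, Dict[str, float]]]:
    """Feasible *effective-scale* rules for a Hund design of total size n.

    Both risks are evaluated with the clustering resolved at the
    respective threshold; the rule interval is on the effective scale of
    the upper threshold's design effect (the one the alpha constraint
    rounds with), and candidate original-scale rules are screened with
    the exact per-threshold evaluation.
    """
    rho_l = clustering.rho_at(targets.p_l)
    rho_u = clustering.rho_at(targets.p_u)
    D_l = design_effect(m, rho_l)
    D_u = design_effect(m, rho_u)
    n_l = round_half_away(n / D_l)
    n_u = round_half_away(n / D_u)
    d = np.arange(n + 1)
    d_eff_u = np.floor(d / D_u + 0.5).astype(int)
    d_eff_l = np.floor(d / D_l + 0.5).astype(int)
    alpha = binom.cdf(np.minimum(d_eff_u, n_u), n_u, targets.p_u)
    beta = binom.sf(np.minimum(d_eff_l, n_l), n_l, targets.p_l)
    rules = _feasible_from_risk_arrays(alpha, beta, targets)
    if rules is None:
        return None
    info = {
        "rho_l": rho_l,
        "rho_u": rho_u,
        "D_l": D_l,
        "D_u": D_u,
        "n_star_l": n_l,
        "n_star_u": n_u,
    }
    return rules, info


def hund_design(
    targets: DesignTargets,
    clustering: ClusteringSpec,
    m: int,
    k_max: int = DEFAULT_K_CAP,
) -> ClusterDesign:
    """Minimal-cluster design under the effective-sample-size construction.

    Clusters are added until the effective binomial (size
    ``round(n / D)``) admits a feasible effective rule ``d*``.  The
    reported original-scale rule is the nearest integer to
    ``d*_min x D_u`` with ties to even, the back-transform convention of
    the published designs; the full feasible interval of original-scale
    rules remains available on the returned design.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    for k in range(1, k_max + 1):
        n = k * m
        found = _hund_feasible(n, m, targets, clustering)
        if found is None:
            continue
        rules, info = found
        D_u = info["D_u"]
        d_star = round_half_away(rules.d_min / D_u)
        # Back-transform with half-to-even; snap into the feasible interval
        # in the rare case FP rounding lands one unit outside it.
        d = int(round(round(d_star * D_u, 9)))
        d = min(max(d, rules.d_min), rules.d_max)
        info["d_star"] = d_star
        alpha, beta = model_risks("hund", k, m, d, targets, clustering)
        warnings = ("k=1: a single-cluster survey cannot estimate clustering",) if k == 1 else ()
        return ClusterDesign(
            method="hund",
            k=k,
            m=m,
            d=d,
            alpha_hat=alpha,
            beta_hat=beta,
            clustering_used=info,
            feasible=rules,
            warnings=warnings,
        )
    raise InfeasibleDesignError(
        f"no hund design with k <= {k_max} clusters of size m={m} meets the risk caps"
    )


def find_cluster_design(
    method: str,
    targets: DesignTargets,
    clustering: ClusteringSpec,
    m: int,
    k_max: int = DEFAULT_K_CAP,
) -> ClusterDesign:
    """Smallest number of clusters (at fixed ``m``) admitting a feasible rule.

    The beta-binomial and binomial-scaled models are evaluated through
    their exact convolved total pmfs; the effective-sample-size model is
    delegated to :func:`hund_design`.
    """
    if method == "hund":
        return hund_design(targets, clustering, m, k_max=k_max)
    if method not in ("hedt", "pezzoli", "srs"):
        raise ValueError(f"unknown design method {method!r}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    # grow the total pmfs one cluster at a time
    unit_l = cluster_pmf(method, m, targets.p_l, clustering) if method != "srs" else None
    unit_u = cluster_pmf(method, m, targets.p_u, clustering) if method != "srs" else None
    acc_l = np.array([1.0])
    acc_u = np.array([1.0])
    for k in range(1, k_max + 1):
        n = k * m
        if method == "srs":
            rules = _binomial_feasible(n, targets)
        else:
            acc_l = np.convolve(acc_l, unit_l)
            acc_u = np.convolve(acc_u, unit_u)
            alpha = np.cumsum(acc_u)
            beta = 1.0 - np.cumsum(acc_l)
            rules = _feasible_from_risk_arrays(alpha, beta, targets)
        if rules is None:
            continue
        warnings = ("k=1: a single-cluster survey cannot estimate clustering",) if k == 1 else ()
        return ClusterDesign(
            method=method,
            k=k,
            m=m,
            d=rules.d,
            alpha_hat=rules.alpha_at_min,
            beta_hat=rules.beta_at_min,
            clustering_used=_clustering_record(method, clustering, targets, m)
            if method != "srs"
            else {},
            feasible=rules,
            warnings=warnings,
        )
    raise InfeasibleDesignError(
        f"no {method} design with k <= {k_max} clusters of size m={m} meets the risk caps"
    )


def find_cluster_design_fixed_k(
    method: str,
    targets: DesignTargets,
    clustering: ClusteringSpec,
    k: int,
    m_max: int = DEFAULT_M_CAP,
) -> ClusterDesign:
    """Smallest per-cluster size (at fixed ``k``) admitting a feasible rule.

    The design effect grows with ``m``, so feasibility is re-evaluated
    model-exactly at every candidate ``m``; heavy clustering can make a
    fixed-``k`` target genuinely infeasible at any ``m``, in which case
    an :class:`InfeasibleDesignError` is raised once the cap is reached.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    for m in range(1, m_max + 1):
        if method == "hund":
            found = _hund_feasible(k * m, m, targets, clustering)
            if found is None:
                continue
            rules, info = found
            d_star = round_half_away(rules.d_min / info["D_u"])
            d = int(round(round(d_star * info["D_u"], 9)))
            d = min(max(d, rules.d_min), rules.d_max)
            info["d_star"] = d_star
            alpha, beta = model_risks("hund", k, m, d, targets, clustering)
            return ClusterDesign(
                method=method, k=k, m=m, d=d, alpha_hat=alpha, beta_hat=beta,
                clustering_used=info, feasible=rules,
            )
        rules = (
            _binomial_feasible(k * m, targets)
            if method == "srs"
            else _exact_design_at(method, targets, clustering, k, m)
        )
        if rules is None:
            continue
        return ClusterDesign(
            method=method,
            k=k,
            m=m,
            d=rules.d,
            alpha_hat=rules.alpha_at_min,
            beta_hat=rules.beta_at_min,
            clustering_used=_clustering_record(method, clustering, targets, m)
            if method != "srs"
            else {},
            feasible=rules,
        )
    raise InfeasibleDesignError(
        f"no {method} design with m <= {m_max} subjects in k={k} clusters meets the risk caps"
    )


def pezzoli_design(
    targets: DesignTargets,
    clustering: ClusteringSpec,
    m: int,
    mode: str = "exact",
    n_sims: int = 10_000,
    seed: Optional[int] = None,
    k_max: int = DEFAULT_K_CAP,
) -> ClusterDesign:
    """Binomial-scaled design by exact mixture pmfs or by seeded simulation.

    ``mode="exact"`` (default) evaluates the finite-mixture total pmf
    exactly, which is possible because the latent coverage has only
    ``eta + 1`` support points.  ``mode="simulate"`` reproduces the
    historical workflow: at each candidate ``k``, ``n_sims`` survey
    totals are drawn independently at each threshold and the empirical
    risk curves searched for a feasible rule.
    """
    if mode == "exact":
        return find_cluster_design("pezzoli", targets, clustering, m, k_max=k_max)
    if mode != "simulate":
        raise ValueError(f"mode must be 'exact' or 'simulate', got {mode!r}")
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    rng = np.random.default_rng(seed)
    for k in range(1, k_max + 1):
        n = k * m
        draws_l = sample_totals("pezzoli", k, m, targets.p_l, clustering, n_sims, rng)
        draws_u = sample_totals("pezzoli", k, m, targets.p_u, clustering, n_sims, rng)
        counts_l = np.bincount(draws_l, minlength=n + 1)
        counts_u = np.bincount(draws_u, minlength=n + 1)
        alpha = np.cumsum(counts_u) / n_sims
        beta = 1.0 - np.cumsum(counts_l) / n_sims
        rules = _feasible_from_risk_arrays(alpha, beta, targets)
        if rules is None:
            continue
        return ClusterDesign(
            method="pezzoli",
            k=k,
            m=m,
            d=rules.d,
            alpha_hat=rules.alpha_at_min,
            beta_hat=rules.beta_at_min,
            clustering_used=_clustering_record("pezzoli", clustering, targets, m),
            feasible=rules,
            warnings=(f"risks are simulation estimates ({n_sims} draws, seed={seed})",),
        )
    raise InfeasibleDesignError(
        f"no pezzoli design with k <= {k_max} clusters of size m={m} meets the risk caps"
    )


def cost_optimal_design(
    method: str,
    targets: DesignTargets,
    clustering: ClusteringSpec,
    cost_per_cluster: float,
    cost_per_subject: float,
    m_grid: Sequence[int],
    k_max: int = DEFAULT_K_CAP,
) -> ClusterDesign:
    """Cheapest design over a grid of per-cluster sizes.

    For each ``m`` in the grid the minimal-cluster design is found and
    its total cost ``k * cost_per_cluster + n * cost_per_subject``
    computed; the cheapest is returned, ties broken by smaller ``n``,
    then smaller ``m``.  This realizes the recommended cost-based design
    procedure: fix the risk targets and clustering, then iterate over
    cluster geometries to minimize field cost.
    """
    if cost_per_cluster < 0 or cost_per_subject < 0:
        raise ValueError("costs must be non-negative")
    if len(m_grid) == 0:
        raise ValueError("m_grid must be non-empty")
    best: Optional[Tuple[float, int, int, ClusterDesign]] = None
    for m in m_grid:
        try:
            cand = find_cluster_design(method, targets, clustering, int(m), k_max=k_max)
        except InfeasibleDesignError:
            continue
        cost = cand.k * cost_per_cluster + cand.n * cost_per_subject
        key = (cost, cand.n, cand.m)
        if best is None or key < best[:3]:
            best = (cost, cand.n, cand.m, cand)
    if best is None:
        raise InfeasibleDesignError(
            f"no feasible {method} design for any m in {list(m_grid)}"
        )
    return best[3]
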