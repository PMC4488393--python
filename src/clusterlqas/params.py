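"""Design targets, clustering parameterizations, and summary-statistic estimators.

Two equivalent descriptions of between-cluster heterogeneity are used for
two-stage cluster surveys.  Let ``p_j`` be the true indicator coverage of
cluster ``j``, with mean ``p`` across clusters.  Then

* ``sigma`` is the standard deviation of the ``p_j``, and
* ``rho = sigma^2 / (p (1 - p))`` is the intraclass correlation,

so either one determines the other at a given coverage level.  Classical
design-effect calculations fix ``rho`` across coverage levels; the
binomial-scaled survey-design tradition fixes ``sigma`` instead.  The
:class:`ClusteringSpec` type carries either convention (or a
coverage-dependent function) and resolves whichever parameter a model
needs at the coverage level where a risk is being evaluated.

Also provided here is a method-of-moments estimator of ``sigma^2`` from
published survey summaries (estimated coverage, SD of estimated cluster
coverages, and cluster geometry), which corrects the naive use of the SD
of *estimated* cluster coverages for the within-cluster binomial noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateClusteringError,
    InvalidClusteringError,
    UndefinedEstimatorError,
)

__all__ = [
    "DesignTargets",
    "ClusteringSpec",
    "SurveySummary",
    "Sigma2Estimate",
    "round_half_away",
    "rho_from_sigma",
    "sigma_from_rho",
    "design_effect",
    "effective_count",
    "eta_from_clustering",
    "estimate_sigma2",
]


def round_half_away(x: float) -> int:
    """Round a non-negative real to the nearest integer, halves away from zero.

    This is the rounding convention used for every effective-count and
    mixing-index calculation in the package (``round(0.5) -> 1``), as
    opposed to Python's built-in half-to-even rule.
    """
    if x < 0:
        raise ValueError(f"round_half_away expects a non-negative value, got {x}")
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DesignTargets:
    """Coverage thresholds and misclassification risk caps for an LQAS design.

    An area with true coverage at or above ``p_u`` should rarely be
    classified low (probability at most ``alpha``, the provider risk);
    an area at or below ``p_l`` should rarely be classified high
    (probability at most ``beta``, the population risk).  Risks are
    unconstrained in the grey region between the thresholds.
    """

    p_l: float
    p_u: float
    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_l < self.p_u < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < p_l < p_u < 1, got "
                f"p_l={self.p_l}, p_u={self.p_u}"
            )
        for name in ("alpha", "beta"):
            r = getattr(self, name)
            if not (0.0 < r < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {r}")


def rho_from_sigma(sigma: float, p: float) -> float:
    """Intraclass correlation implied by a cluster-coverage SD at coverage ``p``.

    ``rho = sigma^2 / (p (1 - p))``.  Raises
    :class:`InvalidClusteringError` when ``sigma^2 > p (1 - p)``, which
    would imply ``rho > 1``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage p must lie in (0, 1), got {p}")
    if sigma < 0.0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    denom = p * (1.0 - p)
    rho = sigma * sigma / denom
    if rho > 1.0:
        raise InvalidClusteringError(
            f"sigma={sigma} implies intraclass correlation {rho:.4f} > 1 "
            f"at coverage p={p} (requires sigma^2 <= p(1-p) = {denom:.4f})"
        )
    return rho


def sigma_from_rho(rho: float, p: float) -> float:
    """Cluster-coverage SD implied by an intraclass correlation at coverage ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"coverage p must lie in (0, 1), got {p}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return math.sqrt(rho * p * (1.0 - p))


def design_effect(m: int, rho: float) -> float:
    """Variance inflation of a two-stage cluster sample relative to SRS.

    ``D = 1 + (m - 1) rho`` for ``m`` subjects per cluster; the total
    sample size divided by ``D`` is the effective sample size.
    """
    if m < 1:
        raise ValueError(f"per-cluster size m must be >= 1, got {m}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return 1.0 + (m - 1) * rho


def effective_count(x: float, D: float) -> int:
    """Nearest-integer effective count ``x / D`` (ties away from zero)."""
    if x < 0:
        raise ValueError(f"count must be non-negative, got {x}")
    if D < 1.0:
        raise ValueError(f"design effect must be >= 1, got {D}")
    return round_half_away(x / D)


class ClusteringSpec:
    """Between-cluster heterogeneity, under one of three conventions.

    Construct with exactly one of:

    * :meth:`from_sigma` -- the SD of true cluster coverages is held fixed
      across coverage levels (the binomial-scaled survey tradition);
    * :meth:`from_rho` -- the intraclass correlation is held fixed (the
      design-effect tradition);
    * :meth:`from_rho_function` / :meth:`from_rho_grid` -- ``rho`` varies
      with coverage, given as a callable or as a tabulated ``(p, rho)``
      grid interpolated linearly (flat beyond the grid ends).

    The accessors resolve whichever parameter a model needs at a given
    coverage level, applying the ``rho``/``sigma`` conversion on the fly.
    """

    __slots__ = ("mode", "sigma", "rho", "_rho_fn")

    def __init__(
        self,
        *,
        mode: str,
        sigma: Optional[float] = None,
        rho: Optional[float] = None,
        rho_fn: Optional[Callable[[float], float]] = None,
    ) -> None:
        if mode not in ("sigma_fixed", "rho_fixed", "function_of_p"):
            raise ValueError(f"unknown clustering mode {mode!r}")
        populated = sum(v is not None for v in (sigma, rho, rho_fn))
        if populated != 1:
            raise ValueError("exactly one of sigma, rho, rho_fn must be given")
        if mode == "sigma_fixed" and sigma is None:
            raise ValueError("sigma_fixed mode requires sigma")
        if mode == "rho_fixed" and rho is None:
            raise ValueError("rho_fixed mode requires rho")
        if mode == "function_of_p" and rho_fn is None:
            raise ValueError("function_of_p mode requires rho_fn")
        if sigma is not None and sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {sigma}")
        if rho is not None and not 0.0 <= rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {rho}")
        self.mode = mode
        self.sigma = sigma
        self.rho = rho
        self._rho_fn = rho_fn

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_sigma(cls, sigma: float) -> "ClusteringSpec":
        return cls(mode="sigma_fixed", sigma=float(sigma))

    @classmethod
    def from_rho(cls, rho: float) -> "ClusteringSpec":
        return cls(mode="rho_fixed", rho=float(rho))

    @classmethod
    def from_rho_function(cls, fn: Callable[[float], float]) -> "ClusteringSpec":
        return cls(mode="function_of_p", rho_fn=fn)

    @classmethod
    def from_rho_grid(
        cls, p_grid: Sequence[float], rho_grid: Sequence[float]
    ) -> "ClusteringSpec":
        p_arr = np.asarray(p_grid, dtype=float)
        r_arr = np.asarray(rho_grid, dtype=float)
        if p_arr.ndim != 1 or p_arr.shape != r_arr.shape or p_arr.size < 2:
            raise ValueError("grids must be 1-d, equal length, and of size >= 2")
        if np.any(np.diff(p_arr) <= 0):
            raise ValueError("p grid must be strictly increasing")
        if np.any((r_arr < 0) | (r_arr >= 1)):
            raise ValueError("rho grid values must lie in [0, 1)")

        def fn(p: float, _p=p_arr, _r=r_arr) -> float:
            # np.interp clamps outside the grid: flat extrapolation.
            return float(np.interp(p, _p, _r))

        return cls(mode="function_of_p", rho_fn=fn)

    # ---- accessors ----------------------------------------------------

    def rho_at(self, p: float) -> float:
        """Intraclass correlation at coverage ``p``."""
        if self.mode == "rho_fixed":
            return self.rho  # type: ignore[return-value]
        if self.mode == "sigma_fixed":
            return rho_from_sigma(self.sigma, p)  # type: ignore[arg-type]
        rho = self._rho_fn(p)  # type: ignore[misc]
        if not 0.0 <= rho < 1.0:
            raise InvalidClusteringError(
                f"clustering function returned rho={rho} at p={p}, "
                "outside [0, 1)"
            )
        return rho

    def sigma_at(self, p: float) -> float:
        """Cluster-coverage SD at coverage ``p``."""
        if self.mode == "sigma_fixed":
            # Validate that the fixed sigma is attainable at this p.
            rho_from_sigma(self.sigma, p)  # type: ignore[arg-type]
            return self.sigma  # type: ignore[return-value]
        return sigma_from_rho(self.rho_at(p), p)

    def eta_at(self, p: float) -> int:
        """Integer mixing index for the binomial-scaled model at coverage ``p``.

        ``eta`` is the nearest integer to ``p (1 - p) / sigma^2``
        (equivalently ``1 / rho``); with it, a Binomial(eta, p)/eta draw
        for the cluster coverage has SD approximately ``sigma``.
        """
        return eta_from_clustering(self, p)

    def design_effect_at(self, p: float, m: int) -> float:
        return design_effect(m, self.rho_at(p))

    def describe(self) -> str:
        if self.mode == "sigma_fixed":
            return f"sigma={self.sigma:g}"
        if self.mode == "rho_fixed":
            return f"rho={self.rho:g}"
        return "rho=f(p)"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ClusteringSpec({self.describe()})"


def eta_from_clustering(spec: ClusteringSpec, p: float) -> int:
    """Nearest-integer mixing index ``p(1-p)/sigma^2`` for coverage ``p``.

    Raises :class:`DegenerateClusteringError` when the spec implies no
    clustering at ``p`` (``sigma = 0``); the plain binomial model should
    be used in that case.
    """
    sigma = spec.sigma_at(p)
    if sigma <= 0.0:
        raise DegenerateClusteringError(
            f"sigma=0 at p={p}: the binomial-scaled model is undefined; "
            "use the plain binomial (SRS) model instead"
        )
    eta = round_half_away(p * (1.0 - p) / (sigma * sigma))
    return max(eta, 1)


@dataclass(frozen=True)
class SurveySummary:
    """Published summaries of one area's two-stage cluster survey.

    ``s`` is the standard deviation of the *estimated* cluster coverages
    (counts divided by ``m``), which overstates the between-cluster SD
    ``sigma`` because each cluster estimate carries binomial noise.  When
    a report gives a standard error of the overall coverage estimate
    instead, use :meth:`from_standard_error` (``s = se * sqrt(k)``).
    """

    area_id: str
    p_hat: float
    s: float
    k: int
    m: int
    rho_hat: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError(f"p_hat must lie in [0, 1], got {self.p_hat}")
        if self.s < 0.0:
            raise ValueError(f"s must be non-negative, got {self.s}")
        if self.k < 2:
            raise ValueError(f"cluster count k must be >= 2, got {self.k}")
        if self.m < 1:
            raise ValueError(f"per-cluster size m must be >= 1, got {self.m}")

    @classmethod
    def from_standard_error(
        cls,
        area_id: str,
        p_hat: float,
        se: float,
        k: int,
        m: int,
        rho_hat: Optional[float] = None,
    ) -> "SurveySummary":
        """Build a summary from a reported standard error of ``p_hat``.

        Under the cluster-mean estimator, ``se = s / sqrt(k)``, so the SD
        of estimated cluster coverages is recovered as ``se * sqrt(k)``.
        """
        return cls(
            area_id=area_id,
            p_hat=p_hat,
            s=se * math.sqrt(k),
            k=k,
            m=m,
            rho_hat=rho_hat,
        )


@dataclass(frozen=True)
class Sigma2Estimate:
    """Between-cluster variance estimate with derived quantities.

    ``truncated`` marks estimates clipped at zero (within-cluster noise
    exceeded the observed between-cluster spread), distinguishing "no
    clustering observed" from a genuinely zero point estimate.
    """

    sigma2: float
    sigma: float
    rho: Optional[float]
    truncated: bool


def estimate_sigma2(summary: SurveySummary) -> Sigma2Estimate:
    """Method-of-moments estimate of the between-cluster variance ``sigma^2``.

    The variance of an estimated cluster coverage decomposes into the
    between-cluster variance plus the average within-cluster binomial
    variance over ``m``; solving the decomposition for ``sigma^2`` gives

        ``sigma2_hat = (m s^2 - p_hat (1 - p_hat)) / (m - 1)``,

    truncated at zero when negative.  The estimator is unbiased for
    ``sigma^2`` as ``m``, ``k``, or ``mk`` grows.  The implied intraclass
    correlation ``sigma2_hat / (p_hat (1 - p_hat))`` is attached whenever
    ``0 < p_hat < 1``.
    """
    m = summary.m
    if m < 2:
        raise UndefinedEstimatorError(
            f"sigma^2 estimation requires m >= 2 subjects per cluster, got m={m}"
        )
    pq = summary.p_hat * (1.0 - summary.p_hat)
    raw = (m * summary.s**2 - pq) / (m - 1)
    truncated = raw < 0.0 or math.isclose(raw, 0.0, abs_tol=1e-15)
    sigma2 = max(raw, 0.0)
    rho = sigma2 / pq if pq > 0.0 else None
    return Sigma2Estimate(
        sigma2=sigma2, sigma=math.sqrt(sigma2), rho=rho, truncated=truncated
    )
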