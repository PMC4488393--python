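"""Survey-summary CSV ingestion, estimation tables, and synthetic fixtures.

The between-cluster variance estimator in :mod:`clusterlqas.params`
needs only the summary statistics routinely published for two-stage
cluster surveys: per area, the estimated coverage ``p_hat``, the SD of
estimated cluster coverages ``s`` (or a standard error plus the cluster
count), and the geometry ``(k, m)``.  This module reads such tables
from CSV, applies the estimator row by row, and can generate synthetic
summary tables by simulating the two-stage models — the tool used for
estimator-recovery studies in place of external survey datasets.

CSV schema (header row required, UTF-8, ``.`` decimal separator)::

    area_id, p_hat, s, se, k, m, rho_hat

Exactly one of ``s``/``se`` must be non-empty per row; ``rho_hat`` is
optional.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .models import sample_total
from .params import ClusteringSpec, SurveySummary, estimate_sigma2

__all__ = [
    "SUMMARY_COLUMNS",
    "read_survey_summaries",
    "write_survey_summaries",
    "estimate_table",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["area_id", "p_hat", "s", "se", "k", "m", "rho_hat"]
_REQUIRED_COLUMNS = ["area_id", "p_hat", "s", "se", "k", "m"]


def read_survey_summaries(
    path: Union[str, Path],
) -> Tuple[List[SurveySummary], List[str]]:
    """Parse a survey-summary CSV into :class:`SurveySummary` records.

    Returns ``(summaries, problems)`` where ``problems`` lists malformed
    rows (reported with their line number and reason, logged, and
    skipped).  Missing required columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"area_id": str}, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"survey-summary file {path} is missing required columns: {missing}"
        )
    summaries: List[SurveySummary] = []
    problems: List[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        has_s = pd.notna(row["s"])
        has_se = pd.notna(row["se"])
        try:
            if has_s == has_se:
                raise ValueError("exactly one of s/se must be provided")
            rho_hat = (
                float(row["rho_hat"])
                if "rho_hat" in df.columns and pd.notna(row.get("rho_hat"))
                else None
            )
            common = dict(
                area_id=str(row["area_id"]),
                p_hat=float(row["p_hat"]),
                k=int(row["k"]),
                m=int(row["m"]),
                rho_hat=rho_hat,
            )
            if has_s:
                summaries.append(SurveySummary(s=float(row["s"]), **common))
            else:
                summaries.append(
                    SurveySummary.from_standard_error(se=float(row["se"]), **common)
                )
        except (ValueError, TypeError) as err:
            msg = f"line {line_no}: {err}"
            problems.append(msg)
            logger.warning("skipping malformed survey-summary row, %s", msg)
    return summaries, problems


def write_survey_summaries(
    summaries: Sequence[SurveySummary], path: Union[str, Path]
) -> None:
    """Write summaries back out in the standard CSV schema (``s`` column)."""
    df = pd.DataFrame(
        {
            "area_id": [s.area_id for s in summaries],
            "p_hat": [s.p_hat for s in summaries],
            "s": [s.s for s in summaries],
            "se": [None] * len(summaries),
            "k": [s.k for s in summaries],
            "m": [s.m for s in summaries],
            "rho_hat": [s.rho_hat for s in summaries],
        }
    )
    df.to_csv(path, index=False)


def estimate_table(summaries: Sequence[SurveySummary]) -> pd.DataFrame:
    """Apply the between-cluster variance estimator to each area.

    One output row per summary: the truncated ``sigma2_hat`` estimate,
    its square root, the implied intraclass correlation, and a flag
    marking rows where truncation at zero occurred.
    """
    rows = []
    for s in summaries:
        est = estimate_sigma2(s)
        rows.append(
            {
                "area_id": s.area_id,
                "p_hat": s.p_hat,
                "s": s.s,
                "k": s.k,
                "m": s.m,
                "sigma2_hat": est.sigma2,
                "sigma_hat": est.sigma,
                "rho_hat": est.rho,
                "truncated": est.truncated,
            }
        )
    return pd.DataFrame(rows)


def generate_fixture(
    method: str,
    true_p: float,
    clustering: ClusteringSpec,
    n_areas: int,
    k: int,
    m: int,
    seed: int,
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Simulate a survey-summary table from a two-stage cluster model.

    Each of the ``n_areas`` areas is surveyed with ``k`` clusters of
    ``m`` subjects under the chosen latent-coverage model (``hedt`` or
    ``pezzoli``; ``srs`` for a no-clustering control); the published-style
    summaries ``p_hat`` (mean of estimated cluster coverages) and ``s``
    (their SD, ``ddof=1``) are computed per area.  Deterministic for a
    given seed; written to ``path`` when given (schema-conformant CSV).
    """
    if n_areas < 1:
        raise ValueError(f"n_areas must be >= 1, got {n_areas}")
    if k < 2:
        raise ValueError(f"k must be >= 2 to define a per-area SD, got {k}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_areas):
        if method == "srs":
            counts = rng.binomial(m, true_p, size=k)
        else:
            counts = sample_total(
                method, k, m, true_p, clustering, rng, return_clusters=True
            ).counts
        phat_j = counts / m
        rows.append(
            {
                "area_id": f"area{i + 1:04d}",
                "p_hat": float(np.mean(phat_j)),
                "s": float(np.std(phat_j, ddof=1)),
                "se": None,
                "k": k,
                "m": m,
                "rho_hat": None,
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df
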