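"""Robust Rank Aggregation (RRA) of gene-eigenvectors across a homology map.

Each gene's normalized ranks across the input lists are compared against
order statistics of the uniform distribution: with ranks sorted ascending
r_(1) <= ... <= r_(m), the rho score is the minimum over j of
Beta(j, m-j+1).cdf(r_(j)) — how surprisingly well the gene is ranked by its
best j lists.  A Bonferroni bound over the m order statistics gives the
p-value min(1, m * rho), which is conservative under the uniform null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HomologyMap

__all__ = ["rra_rho", "rra_pvalue", "aggregate_eigenvectors"]


def rra_rho(normalized_ranks: np.ndarray, m: int | None = None) -> float:
    """Rho score of one gene's normalized ranks (each in (0, 1]).

    ``rho = min_j BetaCDF(r_(j); j, m-j+1)`` over the ascending-sorted
    ranks.  A single list degenerates to the uniform CDF, rho = r.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if m is None:
        m = len(r)
    if len(r) != m:
        raise ValueError(f"expected {m} ranks, got {len(r)}")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, m + 1)
    return float(np.min(stats.beta.cdf(r, j, m - j + 1)))


def rra_pvalue(rho: float, m: int) -> float:
    """Bonferroni-bound p-value for a rho score from m lists."""
    if not (0 < rho <= 1):
        raise ValueError("rho must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, m * rho))


def _rho_two_lists(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Vectorized rho for m=2: min(1-(1-r_(1))^2, r_(2)^2)."""
    lo = np.minimum(r1, r2)
    hi = np.maximum(r1, r2)
    return np.minimum(1.0 - (1.0 - lo) ** 2, hi ** 2)


def _ranks_by_loading(loadings: pd.Series, pole: str) -> pd.Series:
    """Competition-free ranks 1..n, descending for "up", ascending for "down".

    Ties in loadings are broken by gene id so outputs are deterministic.
    """
    sign = -1.0 if pole == "up" else 1.0
    order = sorted(loadings.index, key=lambda g: (sign * loadings[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order).loc[loadings.index]


def aggregate_eigenvectors(
    vA: pd.Series,
    vB: pd.Series,
    hmap: HomologyMap,
    pole: str = "up",
) -> pd.DataFrame:
    """Aggregate two polarized gene-eigenvectors into one ranked homolog list.

    Both vectors are gene-id -> loading Series (already polarized so that
    the pole of interest is positive).  Genes are restricted to the
    homolog map; within each species list the homologs are ranked by
    loading (descending for ``pole="up"``: large positive loadings first;
    ascending for ``"down"``), ranks normalized by the homolog count, and
    each gene scored by rho with Bonferroni p = min(1, 2*rho).  The output
    is sorted by rho ascending (aggregate rank 1 = most consistently
    top-ranked) and indexed by the species-A gene id, carrying both
    species' ids, per-species homolog-restricted ranks and, for reference,
    full-genome ranks.

    Raises if no homolog pair is present in both vectors.
    """
    if pole not in ("up", "down"):
        raise ValueError("pole must be 'up' or 'down'")
    hmap = hmap.restrict(set(vA.index), set(vB.index))
    if len(hmap) == 0:
        raise ValueError("no homolog pairs present in both gene-eigenvectors")
    a_ids, b_ids = hmap.a_ids, hmap.b_ids
    # full-genome ranks before restriction, for annotation only
    full_rank_A = _ranks_by_loading(vA, pole)
    full_rank_B = _ranks_by_loading(vB, pole)
    subA, subB = vA.loc[a_ids], vB.loc[b_ids]
    rank_A = _ranks_by_loading(subA, pole)
    rank_B = _ranks_by_loading(subB, pole).values  # aligned with b_ids order
    n = len(hmap)
    rA = rank_A.values / n
    rB = rank_B / n
    rho = _rho_two_lists(rA, rB)
    p = np.minimum(1.0, 2.0 * rho)
    df = pd.DataFrame(
        {
            "gene_a": a_ids,
            "gene_b": b_ids,
            "rank_a": rank_A.values,
            "rank_b": rank_B,
            "norm_rank_a": rA,
            "norm_rank_b": rB,
            "rho": rho,
            "p": p,
            "full_rank_a": full_rank_A.loc[a_ids].values,
            "full_rank_b": full_rank_B.loc[b_ids].values,
            "pole": pole,
        }
    )
    df = df.sort_values(["rho", "gene_a"], kind="stable").reset_index(drop=True)
    df["aggregate_rank"] = np.arange(1, n + 1)
    return df
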