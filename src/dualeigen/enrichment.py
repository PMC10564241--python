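"""Rank-based (Wilcoxon scoring) gene-set enrichment.

A gene set is scored by the rank-sum of its members' positions when all
genes in the universe are ranked by their values (gene-eigenvector
loadings, aggregated ranks, or per-timepoint log differences).  The z-score
standardizes the rank-sum W by its null mean m(N+1)/2 and variance
m(N-m)(N+1)/12; a positive z means the set concentrates at the positive
pole (high values).  Being rank-based, the score is invariant to any
monotone transform of the values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCatalog

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "wilcoxon_score", "enrich_catalog"]


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set on one ranked gene vector."""

    set_name: str
    set_size_used: int
    rank_sum: float
    z: float
    p: float                      # two-sided
    p_one_sided: float            # toward the observed pole
    direction: str                # "positive" | "negative" pole
    p_adjusted: float | None = None


def wilcoxon_score(
    values: pd.Series | np.ndarray,
    gene_set: set[str],
    universe: list[str] | None = None,
    set_name: str = "",
    min_members: int = 3,
) -> EnrichmentResult | None:
    """Score one gene set against per-gene values by the rank-sum method.

    ``values`` maps gene id -> value (a pandas Series, or an array paired
    with ``universe`` as the gene id list).  Ranks use average ties.  The
    two-sided p comes from the normal z unless the problem is small
    (m <= 10, N <= 30) and tie-free, where the exact rank-sum null is
    enumerated instead.  Sets with fewer than 3 usable members are skipped
    (returns None with a warning).
    """
    if not isinstance(values, pd.Series):
        if universe is None:
            raise ValueError("array values need an explicit universe of gene ids")
        values = pd.Series(np.asarray(values, dtype=float), index=list(universe))
    vals = values.values.astype(float)
    N = len(vals)
    member = values.index.isin(gene_set)
    m = int(member.sum())
    if m < min_members:
        logger.warning(
            "gene set %r has %d usable members (<%d); skipped", set_name, m, min_members
        )
        return None
    ranks = stats.rankdata(vals)  # average ties
    W = float(ranks[member].sum())
    mean_W = m * (N + 1) / 2.0
    var_W = m * (N - m) * (N + 1) / 12.0
    if var_W == 0:  # set == universe
        z = 0.0
        p_two, p_one = 1.0, 1.0
    else:
        z = (W - mean_W) / np.sqrt(var_W)
        tie_free = len(np.unique(vals)) == N
        if m <= 10 and N <= 30 and tie_free:
            inside, outside = vals[member], vals[~member]
            p_two = float(stats.mannwhitneyu(inside, outside, alternative="two-sided",
                                             method="exact").pvalue)
            alt = "greater" if z > 0 else "less"
            p_one = float(stats.mannwhitneyu(inside, outside, alternative=alt,
                                             method="exact").pvalue)
        else:
            p_two = float(2 * stats.norm.sf(abs(z)))
            p_one = float(stats.norm.sf(abs(z)))
    return EnrichmentResult(
        set_name=set_name,
        set_size_used=m,
        rank_sum=W,
        z=float(z),
        p=p_two,
        p_one_sided=p_one,
        direction="positive" if z > 0 else "negative",
    )


def enrich_catalog(
    values: pd.Series,
    catalog: GeneSetCatalog,
    adjust_method: str = "bh",
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Enrich every usable catalog set on one ranked gene vector.

    Sets are intersected with the value universe and filtered by
    ``min_size``/``max_size``; two-sided p-values are adjusted across the
    catalog by Benjamini-Hochberg (``adjust_method="bh"``, default),
    Bonferroni (``"bonferroni"``) or left raw (``"none"``).  Rows are
    sorted by p ascending.
    """
    results = []
    gene_index = set(values.index)
    for name, members in catalog.sets.items():
        used = members & gene_index
        if not (min_size <= len(used) <= max_size):
            continue
        res = wilcoxon_score(values, used, set_name=name)
        if res is not None:
            results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["set_name", "set_size_used", "rank_sum", "z", "p",
                     "p_one_sided", "direction", "p_adjusted"]
        )
    df = pd.DataFrame([vars(r) for r in results])
    if adjust_method == "bh":
        df["p_adjusted"] = stats.false_discovery_control(df["p"], method="bh")
    elif adjust_method == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p"] * len(df), 1.0)
    elif adjust_method == "none":
        df["p_adjusted"] = df["p"]
    else:
        raise ValueError(f"unknown adjust_method {adjust_method!r}")
    return df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
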