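"""SVD dual eigen-analysis: baseline, polarization, contrasts, accounting.

The log-expression matrix E (samples x genes) is decomposed as
``E = sum_{k=0}^{s-1} lambda_k u_k v_k^T`` with decreasing positive singular
values.  Component 0 is the baseline: after good between-sample
normalization its sample loadings are nearly constant (u_{0,i} ~ 1/sqrt(s)),
so by orthogonality every later sample-eigenvector sums to ~0 — an
"empirical contrast" defined by the data themselves.  Each contrast u_k is
interpreted jointly with its dual gene-eigenvector v_k after polarization
(sign fixed so a designated reference group sits at the positive pole,
loadings sorted).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    EigenDecomposition,
    ExpressionProfile,
    PolarizedComponent,
    SumOfSquaresTable,
)

__all__ = [
    "decompose",
    "baseline_cv",
    "empirical_contrast_gap",
    "polarize",
    "contrast_test",
    "sum_of_squares",
    "timecourse_differential",
    "stratify",
]

# Singular values below this relative threshold are numerically zero and dropped.
_RANK_RTOL = 1e-12


def decompose(
    profile: ExpressionProfile | np.ndarray,
    *,
    index_origin: int = 0,
    provenance: str = "",
) -> EigenDecomposition:
    """Full SVD of a profile, numerically-zero components dropped.

    Signs are fixed deterministically: the baseline pair (u_0, v_0) is
    oriented so that u_0 has positive mean; every other pair so that the
    largest-magnitude gene loading is positive.  Either choice flips u_k and
    v_k together, leaving the outer products unchanged.
    """
    if isinstance(profile, ExpressionProfile):
        E = profile.matrix
        sample_ids, gene_ids = profile.sample_ids, profile.gene_ids
        provenance = provenance or profile.species
    else:
        E = np.asarray(profile, dtype=float)
        sample_ids = [f"s{i}" for i in range(E.shape[0])]
        gene_ids = [f"g{j}" for j in range(E.shape[1])]
    if not np.all(np.isfinite(E)):
        raise ValueError("cannot decompose: non-finite values in matrix")
    s, g = E.shape
    if s < 2:
        raise ValueError("need at least 2 samples")
    U, lam, Vt = np.linalg.svd(E, full_matrices=False)
    keep = lam > (lam[0] * _RANK_RTOL if lam[0] > 0 else 0)
    U, lam, Vt = U[:, keep], lam[keep], Vt[keep]
    for k in range(len(lam)):
        if k == 0 and index_origin == 0:
            flip = U[:, 0].mean() < 0
        else:
            j = np.argmax(np.abs(Vt[k]))
            flip = Vt[k, j] < 0
        if flip:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    return EigenDecomposition(
        singular_values=lam,
        sample_eigenvectors=U.T.copy(),
        gene_eigenvectors=Vt.copy(),
        sample_ids=list(sample_ids),
        gene_ids=list(gene_ids),
        provenance=provenance,
        index_origin=index_origin,
    )


def baseline_cv(decomp: EigenDecomposition, constant_threshold: float = 2.0) -> tuple[float, bool]:
    """Coefficient of variation of the baseline sample loadings, in percent.

    Returns ``(cv_percent, nearly_constant)`` where the flag marks
    ``u_{0,i} ~ 1/sqrt(s)`` (CV below ``constant_threshold`` percent).
    Well-normalized profiles sit well under 1%.
    """
    if decomp.index_origin != 0:
        raise ValueError("baseline CV needs a decomposition that retains component 0")
    u0 = decomp.u(0)
    if u0.mean() < 0:
        u0 = -u0
    m = u0.mean()
    if abs(m) < 1e-12:
        raise ValueError("baseline loadings have near-zero mean; not a baseline")
    cv = float(u0.std(ddof=0) / m * 100.0)
    return cv, cv < constant_threshold


def empirical_contrast_gap(decomp: EigenDecomposition, k: int) -> float:
    """|sum_i u_{k,i}| — how far u_k is from an exact contrast.

    Zero when the baseline loadings are exactly constant (orthogonality);
    small when normalization is good.
    """
    if k == 0 and decomp.index_origin == 0:
        raise ValueError("component 0 is the baseline, not a contrast")
    return float(abs(decomp.u(k).sum()))


def polarize(
    decomp: EigenDecomposition,
    k: int,
    reference_group: np.ndarray | list[bool] | list[str],
    *,
    metadata: pd.DataFrame | None = None,
    group_name: str = "reference",
) -> PolarizedComponent:
    """Fix the sign of component k so the reference group's mean loading > 0.

    ``reference_group`` is a boolean membership vector over samples (or a
    list of sample ids).  u_k and v_k are negated together when the
    reference mean loading is negative, leaving lambda_k u_k v_k^T intact;
    a zero reference mean keeps the decomposition sign with a warning.
    """
    if isinstance(reference_group, (list, tuple)) and reference_group and isinstance(
        reference_group[0], str
    ):
        member = np.array([sid in set(reference_group) for sid in decomp.sample_ids])
    else:
        member = np.asarray(reference_group, dtype=bool)
    if member.shape != (len(decomp.sample_ids),):
        raise ValueError("reference_group length must match sample count")
    if not member.any():
        raise ValueError("reference group is empty")
    u, v, lam = decomp.u(k).copy(), decomp.v(k).copy(), decomp.lam(k)
    ref_mean = u[member].mean()
    flipped = False
    if ref_mean < 0:
        u, v = -u, -v
        flipped = True
    elif ref_mean == 0:
        warnings.warn("reference mean loading is exactly 0; keeping decomposition sign")
    order = np.argsort(-u, kind="stable")
    sorted_loadings = pd.DataFrame(
        {"sample_id": np.array(decomp.sample_ids)[order], "loading": u[order],
         "in_reference": member[order]}
    )
    if metadata is not None:
        sorted_loadings = sorted_loadings.join(
            metadata.reset_index(drop=True).iloc[order].reset_index(drop=True)
        )
    gorder = np.argsort(-v, kind="stable")
    gene_table = pd.DataFrame(
        {"gene_id": np.array(decomp.gene_ids)[gorder], "loading": v[gorder],
         "rank": np.arange(1, len(v) + 1)}
    )
    return PolarizedComponent(
        k=k, lam=lam, u=u, v=v,
        sample_ids=list(decomp.sample_ids), gene_ids=list(decomp.gene_ids),
        flipped=flipped, reference_group=group_name,
        sorted_loadings=sorted_loadings, gene_table=gene_table,
    )


def contrast_test(
    loadings: np.ndarray,
    binary_labels: np.ndarray,
    sided: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum p-value for a loading contrast between two groups.

    Exact null enumeration when total n <= 50 and the loadings are tie-free
    (scipy's shift algorithm); otherwise the normal approximation with
    continuity correction and average ranks on ties.  ``sided`` is
    ``"two-sided"``, ``"greater"`` (labeled group high) or ``"less"``.
    """
    loadings = np.asarray(loadings, dtype=float)
    labels = np.asarray(binary_labels, dtype=bool)
    x, y = loadings[labels], loadings[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(loadings)
    has_ties = len(np.unique(loadings)) < n
    method = "exact" if (n <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=sided, method=method)
    return float(res.pvalue)


def sum_of_squares(decomp: EigenDecomposition, E1: np.ndarray | None = None) -> SumOfSquaresTable:
    """Contrast sum-of-squares accounting after baseline extraction.

    For each k >= 1: lambda_k^2 and its proportion of the contrast total
    ``sum_{k>=1} lambda_k^2 = ||E^(1)||_F^2``.  Also emits the proportion of
    the baseline-included total and the per-gene induced squares
    ``SS_j^(1) = (sum_i u_{1,i} E^(1)_{i,j})^2`` whose sum is lambda_1^2.
    ``E1`` (the baseline-removed matrix) is recomputed from the
    decomposition when not supplied.
    """
    if decomp.index_origin == 0:
        ks = range(1, decomp.n_components)
        if E1 is None:
            E1 = decomp.reconstruct() - decomp.lam(0) * np.outer(decomp.u(0), decomp.v(0))
    else:
        ks = range(decomp.index_origin, decomp.index_origin + decomp.n_components)
        if E1 is None:
            E1 = decomp.reconstruct()
    ks = list(ks)
    lam2 = np.array([decomp.lam(k) ** 2 for k in ks])
    total = lam2.sum()
    total_incl = float((decomp.singular_values ** 2).sum())
    table = pd.DataFrame(
        {
            "component": ks,
            "lambda_sq": lam2,
            "proportion": lam2 / total,
            "proportion_incl_baseline": lam2 / total_incl,
        }
    )
    k1 = ks[0]
    per_gene = (decomp.u(k1) @ E1) ** 2
    return SumOfSquaresTable(
        table=table,
        frobenius_sq=float((E1 ** 2).sum()),
        per_gene_ss1=pd.Series(per_gene, index=decomp.gene_ids, name="SS1"),
    )


def timecourse_differential(
    profile: ExpressionProfile,
    group_labels: np.ndarray | pd.Series,
    timepoints: np.ndarray | pd.Series,
    group_order: tuple | None = None,
) -> pd.DataFrame:
    """Per-timepoint gene difference vectors between two groups.

    At each timepoint the replicates of each group are averaged and the
    difference (group 1 mean − group 2 mean, log scale) is taken per gene.
    Returns a genes x timepoints DataFrame; a missing group/timepoint cell
    is an error naming the cell.
    """
    groups = pd.Series(np.asarray(group_labels), index=profile.sample_ids)
    times = pd.Series(np.asarray(timepoints), index=profile.sample_ids)
    levels = group_order if group_order is not None else sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g1, g2 = levels
    out = {}
    for tp in sorted(times.unique()):
        cols = {}
        for grp in (g1, g2):
            sel = (groups == grp) & (times == tp)
            if not sel.any():
                raise ValueError(f"no samples for group {grp!r} at timepoint {tp!r}")
            cols[grp] = profile.matrix[sel.values].mean(axis=0)
        out[tp] = cols[g1] - cols[g2]
    return pd.DataFrame(out, index=profile.gene_ids)


def stratify(
    loadings_1: np.ndarray,
    loadings_2: np.ndarray,
    threshold_x: float,
    threshold_y: float,
    flags: np.ndarray | None = None,
    covariate: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> dict:
    """Stratify samples on the plane of two sample-loading coordinates.

    Regions by thresholds (t_x, t_y): I: x > t_x & y > t_y; II: x <= t_x &
    y > t_y; III: x > t_x & y <= t_y; IV: x <= t_x & y <= t_y.  ``flags``
    marks samples of interest (e.g. abnormal-HbA1c donors); the union
    statistic is the proportion of flagged samples outside region IV, i.e.
    with x > t_x or y > t_y — invariant to the II/III numbering convention.
    Returns a dict with the per-sample table and per-region summaries.
    """
    x = np.asarray(loadings_1, dtype=float)
    y = np.asarray(loadings_2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    n = len(x)
    gx, gy = x > threshold_x, y > threshold_y
    region = np.where(gx & gy, "I", np.where(~gx & gy, "II", np.where(gx & ~gy, "III", "IV")))
    table = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
            "loading_1": x,
            "loading_2": y,
            "region": region,
        }
    )
    if flags is not None:
        table["flagged"] = np.asarray(flags, dtype=bool)
    if covariate is not None:
        table["covariate"] = np.asarray(covariate, dtype=float)
    summary = {}
    for r in ("I", "II", "III", "IV"):
        sel = table["region"] == r
        row = {"count": int(sel.sum())}
        if flags is not None and sel.any():
            row["flagged_proportion"] = float(table.loc[sel, "flagged"].mean())
        if covariate is not None and sel.any():
            row["covariate_mean"] = float(table.loc[sel, "covariate"].mean())
        summary[r] = row
    result = {
        "table": table,
        "summary": summary,
        "thresholds": {"x": threshold_x, "y": threshold_y},
    }
    if flags is not None:
        flagged = table["flagged"].values
        if flagged.any():
            result["flagged_outside_IV"] = float(
                (flagged & (region != "IV")).sum() / flagged.sum()
            )
        else:
            result["flagged_outside_IV"] = float("nan")
    return result
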