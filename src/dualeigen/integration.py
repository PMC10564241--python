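"""Unified SVD of the concatenated two-species expression profile.

Each species' profile is restricted to the shared homologs, its baseline
(top SVD component) removed, optionally scaled to unit Frobenius norm so
both species contribute equal variation, and the two blocks are stacked
over the sample dimension.  The SVD of the concatenated matrix then yields
sample-eigenvectors that partition into a species-A part and a species-B
part, each of which is polarized and contrast-tested against its own
sample labels.  Because the baselines are removed before concatenation, no
baseline component remains and components are indexed from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import EigenDecomposition, ExpressionProfile, HomologyMap, PolarizedComponent
from .eigen import contrast_test, decompose, polarize

__all__ = ["remove_baseline", "concatenate", "unified_dual_eigen", "ConcatenatedProfile"]


def remove_baseline(
    profile: ExpressionProfile, decomp: EigenDecomposition | None = None
) -> np.ndarray:
    """Baseline-removed matrix ``E^(1) = E - lambda_0 u_0 v_0^T``.

    The result is orthogonal to the baseline: ``||u_0^T E^(1)||`` vanishes
    relative to ``||E||_F``.
    """
    if decomp is None:
        decomp = decompose(profile)
    E = profile.matrix if isinstance(profile, ExpressionProfile) else np.asarray(profile)
    return E - decomp.lam(0) * np.outer(decomp.u(0), decomp.v(0))


@dataclass
class ConcatenatedProfile:
    """Two baseline-removed species blocks sharing one homolog column order."""

    block_a: np.ndarray              # (s_a, g_bar)
    block_b: np.ndarray              # (s_b, g_bar)
    homologs: HomologyMap            # column order: homolog pairs
    sample_ids_a: list[str]
    sample_ids_b: list[str]
    equalized: bool
    frobenius_a: float               # norms before equalization
    frobenius_b: float

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([self.block_a, self.block_b])

    @property
    def n_a(self) -> int:
        return self.block_a.shape[0]


def concatenate(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    hmap: HomologyMap,
    equalize: bool = True,
    baseline: str = "homolog-restricted",
) -> ConcatenatedProfile:
    """Align homolog columns, remove per-species baselines, stack blocks.

    ``baseline="homolog-restricted"`` (default) recomputes each species'
    baseline on the homolog-restricted matrix before removing it;
    ``"genome-wide"`` removes the baseline computed on the full gene set
    first and restricts columns afterwards.  With ``equalize`` each block
    is divided by its Frobenius norm so both species contribute equal
    variation to the unified SVD.
    """
    hmap = hmap.restrict(set(profile_a.gene_ids), set(profile_b.gene_ids))
    if len(hmap) == 0:
        raise ValueError("homology map shares no genes with the two profiles")
    if baseline == "homolog-restricted":
        sub_a = profile_a.subset_genes(hmap.a_ids)
        sub_b = profile_b.subset_genes(hmap.b_ids)
        A1 = remove_baseline(sub_a)
        B1 = remove_baseline(sub_b)
    elif baseline == "genome-wide":
        A1_full = remove_baseline(profile_a)
        B1_full = remove_baseline(profile_b)
        ia = profile_a.gene_index()
        ib = profile_b.gene_index()
        A1 = A1_full[:, [ia[g] for g in hmap.a_ids]]
        B1 = B1_full[:, [ib[g] for g in hmap.b_ids]]
    else:
        raise ValueError(f"unknown baseline policy {baseline!r}")
    fa = float(np.linalg.norm(A1))
    fb = float(np.linalg.norm(B1))
    if equalize:
        if fa == 0 or fb == 0:
            raise ValueError("cannot equalize a zero-variation block")
        A1, B1 = A1 / fa, B1 / fb
    return ConcatenatedProfile(
        block_a=A1, block_b=B1, homologs=hmap,
        sample_ids_a=list(profile_a.sample_ids),
        sample_ids_b=list(profile_b.sample_ids),
        equalized=equalize, frobenius_a=fa, frobenius_b=fb,
    )


def unified_dual_eigen(
    concat: ConcatenatedProfile,
    groups_a: np.ndarray | None = None,
    groups_b: np.ndarray | None = None,
    components: tuple[int, ...] = (1,),
    sided: str = "two-sided",
) -> dict:
    """SVD of the concatenated matrix with per-species dual eigen-analysis.

    Components are indexed from 1 (both baselines were removed before
    concatenation, so no baseline component remains).  For each requested
    component the sample-eigenvector is split into its species-A and
    species-B partitions; each partition is polarized against its own
    reference group (boolean membership vectors ``groups_a``/``groups_b``)
    and Wilcoxon rank-sum contrast-tested.

    Returns a dict with the decomposition and, per component, the two
    PolarizedComponent halves and contrast p-values.
    """
    if concat.n_a < 2 or concat.block_b.shape[0] < 2:
        raise ValueError("each species block needs at least 2 samples")
    sample_ids = [f"A:{x}" for x in concat.sample_ids_a] + [
        f"B:{x}" for x in concat.sample_ids_b
    ]
    decomp = decompose(concat.matrix, index_origin=1, provenance="concatenated")
    decomp.sample_ids = sample_ids
    decomp.gene_ids = [f"{a}|{b}" for a, b in concat.homologs.pairs]
    n_a = concat.n_a
    per_component: dict[int, dict] = {}
    for k in components:
        u = decomp.u(k)
        v = decomp.v(k)
        lam = decomp.lam(k)
        entry: dict = {"lambda": lam, "u_a": u[:n_a], "u_b": u[n_a:], "v": v}
        for part, (u_part, ids, groups) in {
            "a": (u[:n_a], concat.sample_ids_a, groups_a),
            "b": (u[n_a:], concat.sample_ids_b, groups_b),
        }.items():
            if groups is None:
                continue
            groups = np.asarray(groups, dtype=bool)
            part_decomp = EigenDecomposition(
                singular_values=np.array([lam]),
                sample_eigenvectors=u_part[None, :],
                gene_eigenvectors=v[None, :],
                sample_ids=list(ids),
                gene_ids=decomp.gene_ids,
                provenance=f"concatenated:{part}",
                index_origin=k,
            )
            pol: PolarizedComponent = polarize(part_decomp, k, groups)
            p = contrast_test(pol.u, groups, sided=sided)
            entry[f"polarized_{part}"] = pol
            entry[f"contrast_p_{part}"] = p
        per_component[k] = entry
    return {"decomposition": decomp, "components": per_component}
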