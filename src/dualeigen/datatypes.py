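"""Core containers shared by all pipeline stages.

The internal matrix convention is samples x genes: sample index i runs over
rows, gene index j over columns, so the SVD's left singular vectors are the
sample-eigenvectors u_k (length s) and the right singular vectors are the
gene-eigenvectors v_k (length g).  On-disk expression tables use the common
genes-as-rows dialect; the readers in :mod:`dualeigen.io` transpose on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "HomologyMap",
    "GeneSetCatalog",
    "EigenDecomposition",
    "PolarizedComponent",
    "SumOfSquaresTable",
]


@dataclass
class ExpressionProfile:
    """A log-scale expression profile with identifiers and sample metadata.

    Parameters
    ----------
    matrix
        Array of shape (s, g): samples in rows, genes in columns, log scale.
    gene_ids, sample_ids
        Unique identifier lists matching the matrix dimensions.
    species
        Free-form species tag, e.g. ``"rat"`` or ``"human"``.
    metadata
        Optional per-sample table indexed by sample id (group label,
        timepoint, replicate, continuous covariates such as HbA1c).
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    species: str = ""
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        s, g = self.matrix.shape
        if s != len(self.sample_ids):
            raise ValueError(
                f"matrix has {s} rows but {len(self.sample_ids)} sample ids"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"matrix has {g} columns but {len(self.gene_ids)} gene ids"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        if self.metadata is not None:
            missing = set(self.sample_ids) - set(self.metadata.index.astype(str))
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
            self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {gid: j for j, gid in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionProfile":
        idx = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [idx[sid] for sid in sample_ids]
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return ExpressionProfile(
            self.matrix[rows], self.gene_ids, list(sample_ids), self.species, meta
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionProfile":
        idx = self.gene_index()
        cols = [idx[gid] for gid in gene_ids]
        return ExpressionProfile(
            self.matrix[:, cols], list(gene_ids), self.sample_ids, self.species,
            self.metadata,
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class HomologyMap:
    """One-to-one pairs (species-A gene id, species-B gene id)."""

    pairs: list[tuple[str, str]]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        for side, ids in (("A", a_ids), ("B", b_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"homology map not one-to-one on side {side}: {dup!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def b_ids(self) -> list[str]:
        return [b for _, b in self.pairs]

    def restrict(self, a_present: set[str], b_present: set[str]) -> "HomologyMap":
        """Keep only pairs whose both members are present; count the drops."""
        kept = [(a, b) for a, b in self.pairs if a in a_present and b in b_present]
        return HomologyMap(kept, n_dropped=self.n_dropped + len(self.pairs) - len(kept))


@dataclass
class GeneSetCatalog:
    """Named gene sets over a gene universe (typically read from GMT)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sets = {str(k): set(v) for k, v in self.sets.items()}
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EigenDecomposition:
    """SVD of an expression profile, baseline component at index 0.

    ``E = sum_k lambda_k u_k v_k^T`` with singular values decreasing and
    strictly positive (numerically zero components are dropped).  Index 0 is
    the baseline: its sample loadings are nearly constant ~ 1/sqrt(s) after
    good normalization, so every later u_k is an empirical contrast.
    """

    singular_values: np.ndarray          # (r,) decreasing, > 0
    sample_eigenvectors: np.ndarray      # (r, s), row k is u_k
    gene_eigenvectors: np.ndarray        # (r, g), row k is v_k
    sample_ids: list[str]
    gene_ids: list[str]
    provenance: str = ""
    index_origin: int = 0                # 0: baseline kept; 1: baseline-removed input

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def u(self, k: int) -> np.ndarray:
        return self.sample_eigenvectors[self._pos(k)]

    def v(self, k: int) -> np.ndarray:
        return self.gene_eigenvectors[self._pos(k)]

    def lam(self, k: int) -> float:
        return float(self.singular_values[self._pos(k)])

    def _pos(self, k: int) -> int:
        pos = k - self.index_origin
        if pos < 0 or pos >= self.n_components:
            raise IndexError(f"component {k} not available")
        return pos

    def reconstruct(self) -> np.ndarray:
        return (self.sample_eigenvectors.T * self.singular_values) @ self.gene_eigenvectors


@dataclass
class PolarizedComponent:
    """One eigen-component with its sign fixed and loadings sorted.

    The sign of (u_k, v_k) is flipped together so that the designated
    reference group's mean sample loading is positive; the outer product
    lambda_k u_k v_k^T is unchanged.  ``sorted_loadings`` is a per-sample
    table sorted by loading descending (the polarized bar plot order);
    ``gene_table`` ranks genes by loading descending.
    """

    k: int
    lam: float
    u: np.ndarray
    v: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    flipped: bool
    reference_group: str
    sorted_loadings: pd.DataFrame
    gene_table: pd.DataFrame


@dataclass
class SumOfSquaresTable:
    """Per-contrast sum-of-squares accounting after baseline extraction.

    ``proportion`` is over the contrast total sum of squares
    ``sum_{k>=1} lambda_k^2 = ||E^(1)||_F^2`` (canonical); a column over the
    baseline-included total is also emitted.  ``per_gene_ss1`` holds
    SS_j^(1) = (sum_i u_{1,i} E^(1)_{i,j})^2, which sums to lambda_1^2.
    """

    table: pd.DataFrame
    frobenius_sq: float
    per_gene_ss1: pd.Series

    def top_proportion(self, n: int) -> float:
        """Summed contrast-SS proportion of the top-n components (k=1..n)."""
        return float(self.table["proportion"].iloc[:n].sum())
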