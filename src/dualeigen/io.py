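"""Readers and writers for the on-disk formats.

Expression tables are tab-delimited with genes as rows (the common
transcriptomics dialect) and are transposed on load into the internal
samples x genes convention.  Gene sets use GMT, homology maps a two-column
TSV, masks any single-channel image binarized at > 0.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import ExpressionProfile, GeneSetCatalog, HomologyMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_homology",
    "write_homology",
    "read_mask",
    "write_mask",
    "read_truth",
    "write_truth",
]


def read_expression(
    path: str | Path,
    species: str = "",
    metadata: pd.DataFrame | None = None,
    orientation: str = "genes_as_rows",
) -> ExpressionProfile:
    """Load a tab-delimited log-expression table into an ExpressionProfile.

    The first column holds gene ids, remaining column headers are sample
    ids (``orientation="genes_as_rows"``, the default file dialect); pass
    ``"samples_as_rows"`` for the transposed dialect.  Duplicated ids and
    non-numeric or missing cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate row id in {path.name}: {dup[0]!r}")
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate column id in {path.name}: {dup[0]!r}")
    try:
        values = df.astype(float)
    except ValueError:
        bad = _locate_non_numeric(df)
        raise ValueError(
            f"non-numeric cell in {path.name} at row {bad[0]!r}, column {bad[1]!r}: {bad[2]!r}"
        ) from None
    if values.isna().any().any():
        j, i = np.argwhere(values.isna().values)[0]
        raise ValueError(
            f"missing value in {path.name} at row {values.index[j]!r}, "
            f"column {values.columns[i]!r}"
        )
    if orientation == "genes_as_rows":
        matrix = values.values.T
        gene_ids, sample_ids = list(values.index), list(values.columns)
    elif orientation == "samples_as_rows":
        matrix = values.values
        gene_ids, sample_ids = list(values.columns), list(values.index)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    logger.info(
        "read %s: %d genes x %d samples", path.name, len(gene_ids), len(sample_ids)
    )
    return ExpressionProfile(matrix, gene_ids, sample_ids, species, metadata)


def _locate_non_numeric(df: pd.DataFrame) -> tuple[str, str, str]:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.values.argmax()]
            return str(row), str(col), str(df.loc[row, col])
    return "?", "?", "?"


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    """Write genes-as-rows TSV at full float precision (repr round-trip)."""
    df = pd.DataFrame(
        profile.matrix.T, index=profile.gene_ids, columns=profile.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Parse a GMT catalog: set name, description, tab-separated members.

    Empty sets are dropped with a warning rather than failing the load.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if not members:
            logger.warning("dropping empty gene set %r", name)
            continue
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCatalog(sets, descriptions)


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = []
    for name, members in catalog.sets.items():
        desc = catalog.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_homology(path: str | Path) -> HomologyMap:
    """Read a two-column homolog TSV; keep the first occurrence per id.

    Many-to-many rows violate the one-to-one requirement downstream; the
    first pair per id on either side is retained and the drop count logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("homology file needs two columns")
    pairs: list[tuple[str, str]] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    dropped = 0
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a in seen_a or b in seen_b:
            dropped += 1
            continue
        seen_a.add(a)
        seen_b.add(b)
        pairs.append((a, b))
    if dropped:
        logger.info("homology map: dropped %d many-to-many rows", dropped)
    return HomologyMap(pairs, n_dropped=dropped)


def write_homology(
    hmap: HomologyMap, path: str | Path, columns: tuple[str, str] = ("gene_a", "gene_b")
) -> None:
    pd.DataFrame(hmap.pairs, columns=list(columns)).to_csv(path, sep="\t", index=False)


def write_truth(truth, path: str | Path) -> None:
    """Write a SyntheticTruth sidecar as JSON (arrays as lists)."""
    import json

    payload = {
        "programs": truth.programs,
        "patterns_a": {k: list(map(float, v)) for k, v in truth.patterns_a.items()},
        "patterns_b": {k: list(map(float, v)) for k, v in truth.patterns_b.items()},
        "covariate_b": list(map(float, truth.covariate_b)),
        "infiltration": truth.infiltration,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path: str | Path):
    """Read a SyntheticTruth sidecar written by :func:`write_truth`."""
    import json

    from .synthetic import SyntheticTruth

    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        programs=payload["programs"],
        patterns_a={k: np.array(v) for k, v in payload["patterns_a"].items()},
        patterns_b={k: np.array(v) for k, v in payload["patterns_b"].items()},
        covariate_b=np.array(payload["covariate_b"]),
        infiltration=payload["infiltration"],
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Read any single-channel image as a boolean mask (binarized at > 0)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    mask = img > 0
    if not mask.any():
        raise ValueError(f"empty mask: {Path(path).name}")
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
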