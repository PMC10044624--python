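"""Readers, writers and preprocessing for spatial expression inputs.

Supported inputs: a 10x-style MatrixMarket triplet (``matrix.mtx`` plus
``features.tsv`` and ``barcodes.tsv``), or a single dense CSV/TSV with
gene rows and cell columns; a coordinate CSV with ``barcode, u, v``
columns; gene sets in GMT format; and an optional external per-cell
phenotype CSV.

Preprocessing mirrors the standard preparation of spatial RNA-seq counts
for the linear-combination test, in this order:

1. ``filter_genes`` — keep genes whose mean raw expression across cells
   is strictly greater than a threshold (default 1);
2. ``jitter_zeros`` — replace exact zero counts by a small uniform
   jitter about zero, so downstream rank-based transforms see no massive
   ties at zero;
3. ``normalize_genes`` — per-gene rank-based inverse-normal transform,
   giving each gene an approximately standard normal marginal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .datasets import GeneSetCollection, SpatialExpressionDataset

__all__ = [
    "read_expression",
    "write_expression",
    "read_coordinates",
    "read_gmt",
    "write_gmt",
    "filter_genes",
    "jitter_zeros",
    "normalize_genes",
    "extract_phenotype",
    "preprocess",
    "assemble_dataset",
]

logger = logging.getLogger("gwlct")


class FormatError(ValueError):
    """Raised when an input file is malformed or internally inconsistent."""


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    matrix_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Read a genes x cells matrix from MTX triplet files or a dense CSV/TSV.

    With ``features_path``/``barcodes_path`` given, ``matrix_path`` is a
    MatrixMarket file whose rows are genes and columns are cells; the id
    files are headerless TSVs whose first column holds the identifier.
    Otherwise ``matrix_path`` is a dense CSV (or TSV, by extension) with
    gene ids in the first column and cell barcodes as the header.

    Returns ``(matrix, gene_ids, barcodes)`` with a dense float matrix.
    """
    matrix_path = Path(matrix_path)
    if features_path is not None or barcodes_path is not None:
        if features_path is None or barcodes_path is None:
            raise FormatError("features and barcodes files must be given together")
        try:
            mat = mmread(str(matrix_path))
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
        mat = np.asarray(mat.todense(), dtype=float) if hasattr(mat, "todense") else np.asarray(mat, float)
        genes = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} but features file has "
                f"{len(genes)} ids and barcodes file has {len(cells)} ids"
            )
    else:
        sep = "\t" if matrix_path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        genes = df.index.astype(str).to_numpy()
        cells = df.columns.astype(str).to_numpy()
    if len(set(genes)) != len(genes):
        raise FormatError("duplicate gene identifiers in expression input")
    return mat, np.asarray(genes, object), np.asarray(cells, object)


def write_expression(
    matrix: np.ndarray,
    gene_ids,
    barcodes,
    matrix_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> None:
    """Write a genes x cells matrix as an MTX triplet or a dense CSV/TSV."""
    matrix_path = Path(matrix_path)
    matrix = np.asarray(matrix, dtype=float)
    if features_path is not None:
        mmwrite(str(matrix_path), coo_matrix(matrix))
        pd.Series(list(gene_ids)).to_csv(features_path, sep="\t", header=False, index=False)
        pd.Series(list(barcodes)).to_csv(barcodes_path, sep="\t", header=False, index=False)
    else:
        sep = "\t" if matrix_path.suffix.lower() in (".tsv", ".txt") else ","
        pd.DataFrame(matrix, index=list(gene_ids), columns=list(barcodes)).to_csv(
            matrix_path, sep=sep
        )


def read_coordinates(
    path: str | Path,
    barcodes: np.ndarray | None = None,
    barcode_col: str = "barcode",
    u_col: str = "u",
    v_col: str = "v",
) -> tuple[np.ndarray, np.ndarray]:
    """Read per-cell planar coordinates and align them to expression barcodes.

    Returns ``(coords, kept_barcodes)``: coordinates in the order of the
    expression barcodes that were found in the file.  Cells without a
    coordinate row are dropped with a warning; fewer than 50% matches is
    treated as a file mismatch and raises.
    """
    df = pd.read_csv(path)
    for col in (barcode_col, u_col, v_col):
        if col not in df.columns:
            raise FormatError(f"coordinate file lacks required column {col!r}")
    df = df.drop_duplicates(subset=barcode_col, keep="first")
    table = df.set_index(df[barcode_col].astype(str))
    if barcodes is None:
        coords = table[[u_col, v_col]].to_numpy(dtype=float)
        return coords, table.index.to_numpy(dtype=object)
    barcodes = np.asarray([str(b) for b in barcodes], dtype=object)
    present = np.array([b in table.index for b in barcodes])
    if present.mean() < 0.5:
        raise FormatError(
            f"only {int(present.sum())} of {len(barcodes)} expression barcodes "
            "have coordinates; wrong coordinate file?"
        )
    if not present.all():
        logger.warning(
            "%d cell(s) lack coordinates and were dropped", int((~present).sum())
        )
    kept = barcodes[present]
    coords = table.loc[kept, [u_col, v_col]].to_numpy(dtype=float)
    return coords, kept


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, member genes...).

    Preserves file order; duplicate members within a set are deduplicated
    with a warning; sets with no members are skipped with a warning;
    duplicate set names are a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                logger.warning("gene set %r has no members; skipped", name)
                continue
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning("gene set %r contains duplicate members; deduplicated", name)
            sets[name] = deduped
    if not sets:
        raise FormatError(f"{path}: no usable gene sets")
    return GeneSetCollection(sets)


def write_gmt(genesets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    """Write a gene-set collection in GMT format."""
    with open(path, "w") as fh:
        for name in genesets.names:
            fh.write("\t".join([name, description, *genesets[name]]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing


def filter_genes(
    matrix: np.ndarray, gene_ids, threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Keep genes whose mean expression across cells is strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    matrix = np.asarray(matrix, dtype=float)
    keep = matrix.mean(axis=1) > threshold
    if not keep.any():
        raise ValueError("no genes pass the mean-expression filter")
    return matrix[keep], np.asarray(gene_ids, object)[keep]


def jitter_zeros(matrix: np.ndarray, jitter_scale: float | None = None, seed: int = 0) -> np.ndarray:
    """Replace exact zeros by a small uniform jitter in ``(-scale, scale) \\ {0}``.

    The default scale is ``1e-6`` times the smallest nonzero absolute
    value in the matrix, so the jitter cannot reorder any nonzero entry.
    Nonzero entries are untouched; deterministic given the seed.
    """
    matrix = np.asarray(matrix, dtype=float).copy()
    zeros = matrix == 0
    if not zeros.any():
        return matrix
    if jitter_scale is None:
        nz = np.abs(matrix[~zeros])
        jitter_scale = 1e-6 * (nz.min() if nz.size else 1.0)
    if jitter_scale <= 0:
        raise ValueError("jitter_scale must be positive")
    rng = np.random.default_rng(seed)
    n = int(zeros.sum())
    draws = rng.uniform(-jitter_scale, jitter_scale, size=n)
    while np.any(draws == 0):  # pragma: no cover - measure-zero event
        draws[draws == 0] = rng.uniform(-jitter_scale, jitter_scale, size=int((draws == 0).sum()))
    matrix[zeros] = draws
    return matrix


def normalize_genes(matrix: np.ndarray) -> np.ndarray:
    """Per-gene rank-based inverse-normal transform (Blom offsets).

    Each gene's values are replaced by ``Phi^{-1}((r - 3/8) / (n + 1/4))``
    of their ranks (ties averaged), giving approximately standard normal
    marginals with mean 0.  Constant genes map to all zeros with a
    warning.  Run after ``jitter_zeros``: ranking raw counts would put
    all zeros in one massive tie.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    out = np.empty_like(matrix)
    for i in range(matrix.shape[0]):
        row = matrix[i]
        if np.all(row == row[0]):
            logger.warning("gene row %d is constant; normalized to zeros", i)
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def preprocess(
    matrix: np.ndarray,
    gene_ids,
    threshold: float = 1.0,
    jitter_scale: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter, jitter and normalize a raw genes x cells matrix, in that order."""
    filtered, kept = filter_genes(matrix, gene_ids, threshold)
    jittered = jitter_zeros(filtered, jitter_scale, seed)
    return normalize_genes(jittered), kept


# ---------------------------------------------------------------------------
# phenotype extraction


def extract_phenotype(
    dataset: SpatialExpressionDataset,
    marker: str | None = None,
    csv_path: str | Path | None = None,
    genesets: GeneSetCollection | None = None,
    exclude_marker: bool = True,
) -> tuple[np.ndarray, GeneSetCollection | None]:
    """Per-cell phenotype from a marker gene's expression or an external CSV.

    When a marker gene supplies the phenotype and ``exclude_marker`` is
    true (default), the marker is removed from every tested gene set —
    otherwise any set containing it would be trivially self-associated.
    Returns ``(phenotype, genesets)`` with the possibly pruned sets.
    """
    if (marker is None) == (csv_path is None):
        raise ValueError("give exactly one of marker or csv_path")
    if marker is not None:
        idx = dataset.gene_indices([marker])
        if idx.size == 0:
            pool = [str(g) for g in dataset.gene_ids]
            near = [g for g in pool if marker.lower() in g.lower() or g.lower() in marker.lower()]
            raise KeyError(
                f"marker gene {marker!r} not in the dataset; near matches: {near[:5]}"
            )
        y = dataset.expression[idx[0]].copy()
        if genesets is not None and exclude_marker:
            before = {name: len(genesets[name]) for name in genesets.names}
            genesets = genesets.drop_gene(marker)
            for name, size in before.items():
                if name in genesets.sets and len(genesets[name]) != size:
                    logger.warning(
                        "marker %s removed from gene set %s", marker, name
                    )
        return y, genesets
    df = pd.read_csv(csv_path)
    if df.shape[1] < 2:
        raise FormatError("phenotype CSV needs a barcode column and a value column")
    table = df.set_index(df.columns[0])
    if dataset.barcodes is None:
        raise ValueError("dataset has no barcodes to align the phenotype CSV against")
    missing = [b for b in dataset.barcodes if str(b) not in table.index.astype(str)]
    if missing:
        raise FormatError(f"{len(missing)} dataset barcode(s) missing from phenotype CSV")
    table.index = table.index.astype(str)
    y = table.loc[[str(b) for b in dataset.barcodes]].iloc[:, 0].to_numpy(dtype=float)
    return y, genesets


def assemble_dataset(
    matrix_path: str | Path,
    coords_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    threshold: float = 1.0,
    seed: int = 0,
) -> SpatialExpressionDataset:
    """Read, align and preprocess the full expression + coordinate input."""
    raw, genes, cells = read_expression(matrix_path, features_path, barcodes_path)
    coords, kept = read_coordinates(coords_path, cells)
    pos = {str(b): j for j, b in enumerate(cells)}
    col_idx = [pos[str(b)] for b in kept]
    norm, kept_genes = preprocess(raw[:, col_idx], genes, threshold=threshold, seed=seed)
    return SpatialExpressionDataset(
        expression=norm, gene_ids=kept_genes, coords=coords, barcodes=kept
    )
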