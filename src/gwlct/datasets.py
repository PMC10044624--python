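"""In-memory containers for spatial expression data and gene-set catalogues."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SpatialExpressionDataset", "GeneSetCollection"]


@dataclass
class SpatialExpressionDataset:
    """A genes-by-cells expression matrix with planar cell coordinates.

    Parameters
    ----------
    expression
        ``(g, n)`` array of expression values, one row per gene, one
        column per cell; on the normalized (approximately standard
        normal) scale for testing.
    gene_ids
        Unique gene identifiers, length ``g``.
    coords
        ``(n, 2)`` planar Cartesian ``(u, v)`` coordinates per cell.
    phenotype
        Optional length-``n`` continuous per-cell phenotype ``Y``.
    barcodes
        Optional cell identifiers, length ``n``.
    """

    expression: np.ndarray
    gene_ids: np.ndarray
    coords: np.ndarray
    phenotype: np.ndarray | None = None
    barcodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D genes x cells matrix")
        g, n = self.expression.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != gene count {g}"
            )
        if len(set(map(str, self.gene_ids))) != g:
            raise ValueError("gene_ids must be unique")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with {n} cells"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (n,):
                raise ValueError("phenotype length must equal the cell count")
        if self.barcodes is not None:
            self.barcodes = np.asarray(self.barcodes, dtype=object)
            if len(self.barcodes) != n:
                raise ValueError("barcodes length must equal the cell count")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        self._gene_index = {str(gid): i for i, gid in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def gene_indices(self, names: Iterable[str], missing: str = "drop") -> np.ndarray:
        """Row indices of the named genes.

        ``missing='drop'`` silently skips names absent from the matrix;
        ``missing='error'`` raises instead.
        """
        idx = []
        absent = []
        for name in names:
            i = self._gene_index.get(str(name))
            if i is None:
                absent.append(str(name))
            else:
                idx.append(i)
        if absent and missing == "error":
            raise KeyError(f"genes not in dataset: {absent[:10]}")
        return np.asarray(idx, dtype=int)

    def diameter(self) -> float:
        """Largest pairwise distance between cells (bounding scale for bandwidths)."""
        from scipy.spatial.distance import pdist

        if self.n_cells < 2:
            return 0.0
        return float(pdist(self.coords).max())


class GeneSetCollection:
    """An ordered catalogue of named gene sets (a parsed GMT file)."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        if len(sets) < 1:
            raise ValueError("at least one gene set is required")
        self.sets: dict[str, list[str]] = {}
        for name, members in sets.items():
            members = list(dict.fromkeys(map(str, members)))  # dedupe, keep order
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[str(name)] = members

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def membership_matrix(self, universe: Sequence[str]) -> pd.DataFrame:
        """K x g 0/1 indicator DataFrame over a gene universe."""
        universe = [str(u) for u in universe]
        mat = np.zeros((len(self.sets), len(universe)), dtype=int)
        pos = {u: j for j, u in enumerate(universe)}
        for i, members in enumerate(self.sets.values()):
            for m in members:
                j = pos.get(m)
                if j is not None:
                    mat[i, j] = 1
        return pd.DataFrame(mat, index=self.names, columns=universe)

    def drop_gene(self, gene: str) -> "GeneSetCollection":
        """Collection with one gene removed everywhere (phenotype-leakage guard).

        Sets reduced to zero members are dropped.
        """
        pruned = {}
        for name, members in self.sets.items():
            kept = [m for m in members if m != str(gene)]
            if kept:
                pruned[name] = kept
        if not pruned:
            raise ValueError("removing the marker gene emptied every set")
        return GeneSetCollection(pruned)
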