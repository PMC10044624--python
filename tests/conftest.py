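import numpy as np
import pytest

from gwlct.datasets import GeneSetCollection, SpatialExpressionDataset


def make_dataset(n_cells=15, n_genes=5, seed=0, signal_gene=None, side=None):
    """Small synthetic dataset with smooth-ish expression surfaces.

    ``signal_gene``: if given, the phenotype equals that gene's row plus
    mild noise; otherwise the phenotype is independent noise.
    """
    rng = np.random.default_rng(seed)
    if side is None:
        coords = rng.uniform(0, 10, size=(n_cells, 2))
    else:
        ax = np.arange(side, dtype=float)
        uu, vv = np.meshgrid(ax, ax)
        coords = np.column_stack([uu.ravel(), vv.ravel()])
        n_cells = coords.shape[0]
    # smooth component + noise so local fits have structure
    expr = np.empty((n_genes, n_cells))
    for g in range(n_genes):
        a, b = rng.normal(size=2)
        expr[g] = a * coords[:, 0] / 10 + b * coords[:, 1] / 10 + rng.normal(
            scale=1.0, size=n_cells
        )
    if signal_gene is None:
        pheno = rng.normal(size=n_cells)
    else:
        pheno = expr[signal_gene] + 0.2 * rng.normal(size=n_cells)
    gene_ids = np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    return SpatialExpressionDataset(
        expression=expr, gene_ids=gene_ids, coords=coords, phenotype=pheno
    )


@pytest.fixture
def small_dataset():
    return make_dataset(n_cells=15, n_genes=5, seed=3)


@pytest.fixture
def two_sets():
    return GeneSetCollection({"setA": ["g0", "g1", "g2"], "setB": ["g2", "g3", "g4"]})
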