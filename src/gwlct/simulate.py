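"""Geostatistical simulation of spatial expression data and the power study.

Synthetic data follow a variogram-parameterized Gaussian random field
model.  A field over planar coordinates has covariance

    C(d) = partial_sill * rho(d / range) + nugget * 1{d = 0},

with ``rho`` an isotropic correlation family (exponential by default;
Gaussian and spherical are available).  Fields are drawn by exact
Cholesky factorization of the full covariance matrix — affordable up to
roughly 10^4 points — so the simulated covariance is exact, with no
neighbourhood approximation.  The default variogram is
``partial_sill = 10, range = 3, nugget = 10``.

Scenario construction
---------------------
A scenario crosses six factors: kernel neighbour count (6 or 20), grid
side (10 or 100), gene count (100 or 1000), gene-set membership
probability (0.3 or 0.9), and two spatial-association levels each taking
variances {50, 5, 0.1} (higher variance = weaker association), yielding
the 144-cell factorial.  Genes share a common unit-variance spatial
field ``G`` plus an independent per-gene spatial field of variance
``v_gene`` (the gene-gene association level), so the cross-gene
correlation is ``1 / (1 + v_gene)``.  The phenotype is the standardized
mean of a designated "true" gene set plus an independent spatial noise
field of variance ``v_pheno`` (the phenotype-gene association level).
Gene-set membership is Bernoulli with the scenario's probability.

Power is the mean over Monte-Carlo replicates of the per-replicate
rejection measure: for GWLCT the fraction of locations whose
permutation p-value for the true set falls below ``alpha``; for the
aspatial LCT the 0/1 rejection of its single p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .core import global_lct, run_gwlct
from .datasets import GeneSetCollection, SpatialExpressionDataset
from .weights import KernelSpec

__all__ = [
    "VariogramSpec",
    "ScenarioSpec",
    "FieldSimulator",
    "simulate_gaussian_field",
    "simulate_genes",
    "generate_membership",
    "generate_phenotype",
    "grid_coords",
    "simulate_scenario_dataset",
    "scenario_grid",
    "estimate_power",
    "empirical_semivariogram",
    "model_semivariogram",
]

#: association-level variances: higher variance = weaker spatial association
ASSOC_VARIANCES = {"low": 50.0, "moderate": 5.0, "high": 0.1}


@dataclass(frozen=True)
class VariogramSpec:
    """Variogram parameters of a stationary isotropic Gaussian field."""

    partial_sill: float = 10.0
    range: float = 3.0
    nugget: float = 10.0
    model: str = "exponential"

    def __post_init__(self) -> None:
        if self.partial_sill < 0 or self.nugget < 0:
            raise ValueError("partial_sill and nugget must be nonnegative")
        if self.partial_sill + self.nugget <= 0:
            raise ValueError("total sill must be positive")
        if self.range <= 0:
            raise ValueError("range must be positive")
        if self.model not in ("exponential", "gaussian", "spherical"):
            raise ValueError(f"unknown correlation model: {self.model!r}")

    @property
    def sill(self) -> float:
        return self.partial_sill + self.nugget

    def correlation(self, d: np.ndarray) -> np.ndarray:
        """Correlation of the structured component at distance ``d``."""
        t = np.asarray(d, dtype=float) / self.range
        if self.model == "exponential":
            return np.exp(-t)
        if self.model == "gaussian":
            return np.exp(-(t**2))
        c = np.where(t < 1.0, 1.0 - 1.5 * t + 0.5 * t**3, 0.0)
        return c

    def covariance(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.partial_sill * self.correlation(d) + self.nugget * (d == 0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the 144-scenario factorial simulation design."""

    bandwidth: int  # adaptive neighbour count: 6 (low) or 20 (high)
    grid_side: int  # 10 (low) or 100 (high) points per axis
    n_genes: int  # 100 (low) or 1000 (high)
    geneset_prob: float  # Bernoulli membership probability: 0.3 or 0.9
    gene_assoc_variance: float  # 50 / 5 / 0.1 = low / moderate / high association
    pheno_assoc_variance: float  # same coding
    scenario_id: int = -1


class FieldSimulator:
    """Exact Gaussian-field sampler over a fixed coordinate set.

    Factorizes the covariance once so repeated draws (for example one
    per gene) cost a single matrix-vector product each.
    """

    def __init__(self, coords: np.ndarray, vspec: VariogramSpec):
        from scipy.spatial.distance import squareform, pdist

        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        self.coords = coords
        self.vspec = vspec
        n = coords.shape[0]
        D = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
        C = vspec.covariance(D)
        try:
            self._L = cholesky(C, lower=True)
        except np.linalg.LinAlgError:
            C = C + 1e-8 * vspec.sill * np.eye(n)
            self._L = cholesky(C, lower=True)

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """One realization (or ``size`` independent realizations, stacked rows)."""
        n = self.coords.shape[0]
        if size is None:
            return self._L @ rng.standard_normal(n)
        return (self._L @ rng.standard_normal((n, size))).T


def simulate_gaussian_field(coords, vspec: VariogramSpec, seed) -> np.ndarray:
    """One zero-mean Gaussian field realization with the given variogram.

    ``seed`` may be an integer, a ``SeedSequence`` or a ``Generator``;
    draws are deterministic given the seed.
    """
    sim = FieldSimulator(coords, vspec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sim.draw(rng)


def simulate_genes(coords, n_genes: int, vspec: VariogramSpec, seed: int) -> np.ndarray:
    """``n_genes`` independent field realizations, one row per gene.

    Per-gene seeds are split from the master seed with a counter-based
    spawn key, so enlarging ``n_genes`` leaves earlier genes' draws
    unchanged.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    sim = FieldSimulator(coords, vspec)
    out = np.empty((n_genes, sim.coords.shape[0]))
    for j in range(n_genes):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
        out[j] = sim.draw(rng)
    return out


def generate_membership(n_genes: int, K: int, prob: float, seed: int) -> np.ndarray:
    """K x n_genes Bernoulli(prob) gene-set membership indicator matrix.

    All-zero rows (possible at small ``prob``) are redrawn so no set is
    empty; ``prob = 0`` is rejected.
    """
    if not 0 < prob <= 1:
        raise ValueError("membership probability must lie in (0, 1]")
    if K < 1 or n_genes < 1:
        raise ValueError("K and n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x6D,)))
    M = (rng.random((K, n_genes)) < prob).astype(int)
    for i in range(K):
        while not M[i].any():
            M[i] = (rng.random(n_genes) < prob).astype(int)
    return M


def generate_phenotype(
    genes: np.ndarray,
    membership_row: np.ndarray,
    assoc_variance: float,
    vspec_noise: VariogramSpec,
    seed: int,
    coords: np.ndarray | None = None,
    mode: str = "alternative",
) -> np.ndarray:
    """Continuous phenotype tied to the true gene set.

    Under the alternative, ``Y`` is the standardized (zero-mean,
    unit-variance) mean expression of the member genes plus an
    independent spatially correlated Gaussian noise field scaled to
    marginal variance ``assoc_variance``; smaller variance means
    stronger phenotype-gene association.  Two null modes drop the signal
    term: ``"null-iid"`` draws iid standard normal values (cells
    exchangeable — the null model matched to the permutation test), and
    ``"null-spatial"`` keeps the spatially correlated noise field only.
    """
    genes = np.atleast_2d(np.asarray(genes, dtype=float))
    member = np.flatnonzero(np.asarray(membership_row))
    rng_master = np.random.SeedSequence(seed, spawn_key=(0x70,))
    rng = np.random.default_rng(rng_master)
    n = genes.shape[1]

    if mode == "null-iid":
        return rng.standard_normal(n)
    if coords is None:
        raise ValueError("coords are required for spatially correlated noise")
    noise_field = simulate_gaussian_field(coords, vspec_noise, rng)
    noise = noise_field / np.sqrt(vspec_noise.sill) * np.sqrt(assoc_variance)
    if mode == "null-spatial":
        return noise
    if mode != "alternative":
        raise ValueError(f"unknown phenotype mode: {mode!r}")
    if member.size == 0:
        raise ValueError("true gene set is empty under the alternative")
    signal = genes[member].mean(axis=0)
    sd = signal.std()
    if sd > 0:
        signal = (signal - signal.mean()) / sd
    return signal + noise


def grid_coords(side: int, spacing: float = 1.0) -> np.ndarray:
    """Regular ``side x side`` grid of planar coordinates."""
    ax = np.arange(side, dtype=float) * spacing
    uu, vv = np.meshgrid(ax, ax, indexing="xy")
    return np.column_stack([uu.ravel(), vv.ravel()])


def scenario_grid() -> list[ScenarioSpec]:
    """The full factorial simulation design in canonical order.

    Factors vary rightmost-fastest in the order: bandwidth (6, 20), grid
    side (10, 100), gene count (100, 1000), membership probability
    (0.3, 0.9), gene-gene association (low, moderate, high), and
    phenotype-gene association (low, moderate, high) — 144 scenarios.
    """
    levels = itertools.product(
        (6, 20),
        (10, 100),
        (100, 1000),
        (0.3, 0.9),
        (ASSOC_VARIANCES["low"], ASSOC_VARIANCES["moderate"], ASSOC_VARIANCES["high"]),
        (ASSOC_VARIANCES["low"], ASSOC_VARIANCES["moderate"], ASSOC_VARIANCES["high"]),
    )
    return [
        ScenarioSpec(bw, gs, ng, pr, ga, pa, scenario_id=i)
        for i, (bw, gs, ng, pr, ga, pa) in enumerate(levels)
    ]


def simulate_scenario_dataset(
    scenario: ScenarioSpec,
    seed: int,
    K: int = 2,
    vspec: VariogramSpec | None = None,
    phenotype_mode: str = "alternative",
) -> tuple[SpatialExpressionDataset, GeneSetCollection, int]:
    """Simulate one dataset under a scenario; returns (dataset, sets, true-set index).

    Gene ``j`` is ``G + eta_j`` with ``G`` a shared unit-variance field
    and ``eta_j`` an independent field of variance
    ``gene_assoc_variance``; the phenotype derives from gene set 0 (the
    "true" set) as described in :func:`generate_phenotype`.
    """
    if vspec is None:
        vspec = VariogramSpec()
    coords = grid_coords(scenario.grid_side)
    sim = FieldSimulator(coords, vspec)
    scale = np.sqrt(vspec.sill)

    rng_shared = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x47,)))
    G = sim.draw(rng_shared) / scale
    v_g = scenario.gene_assoc_variance
    X = np.empty((scenario.n_genes, coords.shape[0]))
    for j in range(scenario.n_genes):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, j)))
        X[j] = G + sim.draw(rng) / scale * np.sqrt(v_g)

    M = generate_membership(scenario.n_genes, K, scenario.geneset_prob, seed)
    gene_ids = np.array([f"g{j:04d}" for j in range(scenario.n_genes)], dtype=object)
    sets = GeneSetCollection(
        {f"set{i + 1}": [gene_ids[j] for j in np.flatnonzero(M[i])] for i in range(K)}
    )
    Y = generate_phenotype(
        X, M[0], scenario.pheno_assoc_variance, vspec, seed,
        coords=coords if phenotype_mode != "null-iid" else None,
        mode=phenotype_mode,
    )
    dataset = SpatialExpressionDataset(
        expression=X, gene_ids=gene_ids, coords=coords, phenotype=Y
    )
    return dataset, sets, 0


def estimate_power(
    scenario: ScenarioSpec,
    method: str = "gwlct",
    replicates: int = 50,
    B: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
    K: int = 2,
    phenotype_mode: str = "alternative",
) -> dict:
    """Monte-Carlo power (or, in a null mode, type-I error) of one method.

    Each replicate simulates a fresh dataset under the scenario, runs
    the method on the true gene set with the scenario's adaptive
    bisquare kernel, and records the rejection measure at level
    ``alpha``: the fraction of non-degenerate locations rejecting
    (GWLCT) or the 0/1 global rejection (aspatial LCT).  Returns the
    mean over replicates together with its Monte-Carlo standard error.
    """
    if replicates < 1 or B < 1:
        raise ValueError("replicates and B must be >= 1")
    if method not in ("gwlct", "global_lct"):
        raise ValueError(f"unknown method: {method!r}")
    vals = np.empty(replicates)
    for r in range(replicates):
        rep_seed = int(np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0] % (2**31))
        dataset, sets, true_idx = simulate_scenario_dataset(
            scenario, rep_seed, K=K, phenotype_mode=phenotype_mode
        )
        true_name = sets.names[true_idx]
        if method == "gwlct":
            spec = KernelSpec(family="bisquare", mode="adaptive", bandwidth=scenario.bandwidth)
            res = run_gwlct(
                dataset,
                GeneSetCollection({true_name: sets[true_name]}),
                spec=spec, B=B, seed=rep_seed, alpha=alpha,
            )
            ok = res[res["flag"] == "ok"]
            vals[r] = float((ok["p_value"] < alpha).mean()) if len(ok) else 0.0
        else:
            _, p = global_lct(dataset, sets[true_name], B=B, seed=rep_seed)
            vals[r] = float(p < alpha)
    power = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
    return {
        "scenario_id": scenario.scenario_id,
        "method": method,
        "power": power,
        "replicates": replicates,
        "se": se,
        "mode": phenotype_mode,
    }


# ---------------------------------------------------------------------------
# variogram diagnostics


def empirical_semivariogram(
    coords: np.ndarray, values: np.ndarray, bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical semivariogram ``gamma(d) = 0.5 E[(Z_i - Z_j)^2]``.

    Returns ``(bin_centers, gamma_hat)``; bins with no pairs yield NaN.
    """
    from scipy.spatial.distance import pdist

    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords)
    dz2 = pdist(values[:, None], metric="sqeuclidean")
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(d, bin_edges) - 1
    nb = len(bin_edges) - 1
    gamma = np.full(nb, np.nan)
    for b in range(nb):
        sel = which == b
        if sel.any():
            gamma[b] = 0.5 * dz2[sel].mean()
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return centers, gamma


def model_semivariogram(vspec: VariogramSpec, d: np.ndarray) -> np.ndarray:
    """Theoretical semivariogram ``psill * (1 - rho(d)) + nugget`` for ``d > 0``."""
    d = np.asarray(d, dtype=float)
    return np.where(
        d > 0, vspec.partial_sill * (1.0 - vspec.correlation(d)) + vspec.nugget, 0.0
    )
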