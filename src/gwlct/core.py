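"""The geographically weighted linear combination test (GWLCT).

At every calibration location the test finds the linear combination of a
gene set's expression values that is maximally correlated, under kernel
weights, with a continuous per-cell phenotype ``Y``.  Writing
``SCov(X,X)`` for the kernel-weighted, shrinkage-regularized covariance
of the set's genes and ``scov_xy`` for the weighted covariance of each
gene with ``Y``, the maximizing direction is

    beta* ∝ SCov(X,X)^{-1} scov_xy,

(the principal eigenvector of the rank-one matrix
``SCov(X,X)^{-1} scov_xy scov_xy'``) and the local statistic is

    rho = sqrt( scov_xy' SCov(X,X)^{-1} scov_xy / scov_yy ).

Without shrinkage and with at least as many weighted observations as
genes, ``rho`` is the maximal weighted correlation between ``Y`` and any
linear score of the set, so it lies in [0, 1].  When the local effective
sample size is smaller than the set size the unregularized maximum is
trivially 1; shrinkage keeps the statistic finite and informative, but it
is then a regularized association score that may exceed 1.  Its null
distribution is obtained by permuting ``Y`` across cells, so inference is
rank-based and needs no distributional calibration of ``rho`` itself.

Shrinkage follows the analytic (Schafer-Strimmer style) recipe on the
correlation scale: the weighted correlation matrix is shrunk toward the
identity with a data-driven intensity ``lambda`` and rescaled by the
weighted standard deviations, so the result is always positive definite.

The aspatial baseline (``global_lct``) is the identical computation with
all weights equal to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .datasets import GeneSetCollection, SpatialExpressionDataset
from .weights import KernelSpec, WeightVector, weight_matrix, weight_vector

__all__ = [
    "CovariancePair",
    "LocalModel",
    "LocalLCTResult",
    "DegenerateSupportError",
    "weighted_moments",
    "weighted_shrunken_cov",
    "max_linear_combination",
    "local_statistic",
    "permutation_pvalue",
    "run_gwlct",
    "global_lct",
]

#: floor applied to weighted gene variances so constant genes never yield
#: an exactly singular scale matrix
VARIANCE_FLOOR = 1e-12


class DegenerateSupportError(ValueError):
    """Raised when a weight vector leaves fewer than two effective cells."""


@dataclass
class CovariancePair:
    """Weighted shrunken covariance of a gene subset and its phenotype cross-terms."""

    scov_xx: np.ndarray
    scov_xy: np.ndarray
    scov_yy: float
    shrinkage_intensity: float


@dataclass
class LocalModel:
    """Fitted local linear-combination model at one calibration location."""

    beta_star: np.ndarray
    rho: float
    intercept: float
    slope: float
    sigma2: float


@dataclass
class LocalLCTResult:
    """Per-location, per-gene-set permutation test outcome."""

    location: int
    gene_set: str
    rho: float
    p_value: float
    bandwidth: float
    effective_n: float
    flag: str = "ok"


# ---------------------------------------------------------------------------
# weighted moment machinery


def _normalize_weights(weights: np.ndarray):
    """Split raw kernel weights into support, mean weights and covariance weights.

    Returns ``(keep, wn, wc, m)``: indices with positive weight, weights
    normalized to sum 1 (for means), weights normalized to sum ``m`` (the
    positive-weight cell count, for covariance sums with an ``m - 1``
    denominator so the uniform-weight case reduces exactly to the sample
    covariance), and ``m`` itself.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    keep = np.flatnonzero(w > 0)
    m = keep.size
    if m < 2:
        raise DegenerateSupportError(
            f"only {m} cell(s) carry positive weight; need at least 2"
        )
    wk = w[keep]
    wn = wk / wk.sum()
    wc = wn * m
    return keep, wn, wc, m


def weighted_moments(values, weights) -> tuple[float, float]:
    """Kernel-weighted mean and variance of a per-cell vector.

    Weights are renormalized to sum to the number of positive-weight
    cells ``m`` and the variance uses an ``m - 1`` denominator, so with
    uniform weights this reduces exactly to the ordinary sample mean and
    variance.
    """
    values = np.asarray(values, dtype=float)
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    keep, wn, wc, m = _normalize_weights(w)
    x = values[keep]
    mean = float(wn @ x)
    var = float(np.sum(wc * (x - mean) ** 2) / (m - 1))
    return mean, var


def _shrinkage_intensity(Xc: np.ndarray, wn: np.ndarray, d: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    ``Xc`` is the weighted-centered data (g x m), ``wn`` the weights
    normalized to sum 1, ``d`` the weighted variances.  The estimate is
    ``sum Var(r_ij) / sum r_ij^2`` over off-diagonal pairs, with the
    weighted-data moments of Schafer & Strimmer, clipped to [0, 1].
    """
    g = Xc.shape[0]
    if g < 2:
        return 0.0
    sw = float(np.sum(wn**2))
    if sw >= 1.0:  # single effective observation
        return 1.0
    h1 = 1.0 / (1.0 - sw)
    Xs = Xc / np.sqrt(d)[:, None]
    zbar = (Xs * wn) @ Xs.T
    z2bar = ((Xs**2) * wn) @ (Xs**2).T
    r = h1 * zbar
    var_r = sw * h1**3 * (z2bar - zbar**2)
    off = ~np.eye(g, dtype=bool)
    denom = float(np.sum(r[off] ** 2))
    if denom <= 0:
        return 1.0
    lam = float(np.sum(var_r[off]) / denom)
    return float(np.clip(lam, 0.0, 1.0))


def _cov_factors(
    X_subset: np.ndarray,
    y: np.ndarray | None,
    weights: np.ndarray,
    shrinkage: float | None = None,
):
    """Weighted shrunken covariance in factored form.

    Returns ``(L, sxy, syy, lam, wn, keep)`` where ``L`` is the lower
    Cholesky factor of the shrunken ``SCov(X,X)``.  ``sxy``/``syy`` are
    ``None`` when ``y`` is ``None``.
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    keep, wn, wc, m = _normalize_weights(weights)
    Xk = X_subset[:, keep]
    xbar = Xk @ wn
    Xc = Xk - xbar[:, None]
    d_raw = np.sum((Xc**2) * wc, axis=1) / (m - 1)
    d = np.maximum(d_raw, VARIANCE_FLOOR)

    lam = _shrinkage_intensity(Xc, wn, d) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")

    Sxx = (Xc * wc) @ Xc.T / (m - 1)
    sd = np.sqrt(d)
    R = Sxx / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    Rstar = (1.0 - lam) * R
    np.fill_diagonal(Rstar, 1.0)
    Sstar = Rstar * np.outer(sd, sd)
    try:
        L = cholesky(Sstar, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover - guarded by shrinkage
        L = cholesky(Sstar + 1e-10 * np.eye(Sstar.shape[0]), lower=True)

    sxy = syy = None
    if y is not None:
        yk = np.asarray(y, float)[keep]
        ybar = float(yk @ wn)
        sxy = (Xc * wc) @ yk / (m - 1)
        syy = float(np.sum(wc * (yk - ybar) ** 2) / (m - 1))
    return L, sxy, syy, lam, wn, keep


def weighted_shrunken_cov(
    X_subset: np.ndarray,
    y: np.ndarray,
    weights,
    shrinkage: float | None = None,
) -> CovariancePair:
    """Kernel-weighted, shrinkage-regularized covariance of a gene subset.

    ``shrinkage=None`` (default) estimates the intensity analytically;
    passing an explicit value in [0, 1] forces it (0 = raw weighted
    covariance, 1 = diagonal).
    """
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    L, sxy, syy, lam, _, _ = _cov_factors(X_subset, y, w, shrinkage)
    return CovariancePair(
        scov_xx=L @ L.T, scov_xy=sxy, scov_yy=syy, shrinkage_intensity=lam
    )


def max_linear_combination(cov: CovariancePair) -> LocalModel:
    """Direction maximizing the weighted association of ``Y`` with ``beta'X``.

    ``beta*`` is proportional to ``SCov(X,X)^{-1} scov_xy`` and is
    returned with unit Euclidean norm and its first nonzero component
    positive.  ``rho`` is ``sqrt(scov_xy' SCov(X,X)^{-1} scov_xy /
    scov_yy)``; see the module docstring for its range.
    """
    L = cholesky(cov.scov_xx, lower=True)
    q = solve_triangular(L, cov.scov_xy, lower=True)
    num = float(q @ q)
    syy = cov.scov_yy
    rho = float(np.sqrt(num / syy)) if syy > 0 else 0.0
    beta = cho_solve((L, True), cov.scov_xy)
    nrm = np.linalg.norm(beta)
    if nrm > 0:
        beta = beta / nrm
        nz = np.flatnonzero(beta)
        if nz.size and beta[nz[0]] < 0:
            beta = -beta
    else:
        beta = np.zeros_like(cov.scov_xy)
    # scale of the Y-on-Z regression (Z = beta*'X): slope and noise variance
    bSb = float(beta @ cov.scov_xx @ beta)
    bsxy = float(beta @ cov.scov_xy)
    slope = bsxy / bSb if bSb > 0 else 0.0
    sigma2 = max(syy - slope * bsxy, 0.0)
    return LocalModel(beta_star=beta, rho=rho, intercept=np.nan, slope=slope, sigma2=sigma2)


def local_statistic(
    dataset: SpatialExpressionDataset,
    geneset: list[str] | np.ndarray,
    center: int,
    spec: KernelSpec,
    shrinkage: float | None = None,
) -> LocalModel:
    """Fit the local linear-combination model at one calibration location."""
    idx = dataset.gene_indices(geneset)
    if idx.size == 0:
        raise ValueError("gene set has no genes present in the dataset")
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype vector")
    wv = weight_vector(dataset.coords, center, spec)
    cov = weighted_shrunken_cov(
        dataset.expression[idx], dataset.phenotype, wv, shrinkage
    )
    model = max_linear_combination(cov)
    # intercept of the Y-on-Z fit at this location
    keep, wn, _, _ = _normalize_weights(wv.values)
    z = model.beta_star @ dataset.expression[np.ix_(idx, keep)]
    ybar = float(dataset.phenotype[keep] @ wn)
    model.intercept = ybar - model.slope * float(z @ wn)
    return model


def _permutations(n: int, B: int, seed_seq: np.random.SeedSequence) -> np.ndarray:
    """(B, n) permutation index array, deterministic in the seed sequence."""
    rng = np.random.default_rng(seed_seq)
    return np.array([rng.permutation(n) for _ in range(B)])


def _rho_columns(Xs, Ymat, w, shrinkage=None):
    """rho for each column of ``Ymat`` against one gene subset under weights ``w``.

    The X-side factors (weighted covariance, shrinkage, Cholesky) do not
    depend on ``Y``, so one factorization serves the observed phenotype
    and every permutation.
    """
    L, _, _, lam, wn, keep = _cov_factors(Xs, None, w, shrinkage)
    m = keep.size
    wc = wn * m
    Xk = Xs[:, keep]
    xbar = Xk @ wn
    Xc = Xk - xbar[:, None]
    Yk = Ymat[keep]
    ybar = wn @ Yk
    Sxy = (Xc * wc) @ Yk / (m - 1)
    syy = (wc @ (Yk**2) - m * ybar**2) / (m - 1)
    Q = solve_triangular(L, Sxy, lower=True)
    num = np.sum(Q**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(syy > 0, np.sqrt(num / np.where(syy > 0, syy, 1.0)), 0.0)
    return rho, lam, float(np.sum(w))


def permutation_pvalue(
    dataset: SpatialExpressionDataset,
    geneset: list[str] | np.ndarray,
    center: int,
    spec: KernelSpec,
    B: int = 499,
    seed: int = 0,
    gene_set_name: str = "set",
    shrinkage: float | None = None,
) -> LocalLCTResult:
    """Permutation p-value of the local statistic at one location.

    The phenotype is permuted across all cells (expression and
    coordinates fixed) and the local statistic recomputed per relabeling;
    ``p = (1 + #{rho_perm >= rho_obs}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype vector")
    idx = dataset.gene_indices(geneset)
    n = dataset.n_cells
    perms = _permutations(n, B, np.random.SeedSequence(seed))
    Y = dataset.phenotype
    Ymat = np.column_stack([Y] + [Y[p] for p in perms])
    wv = weight_vector(dataset.coords, center, spec)
    rho, _, eff_n = _rho_columns(dataset.expression[idx], Ymat, wv.values, shrinkage)
    p = (1 + int(np.sum(rho[1:] >= rho[0]))) / (1 + B)
    return LocalLCTResult(
        location=center,
        gene_set=gene_set_name,
        rho=float(rho[0]),
        p_value=p,
        bandwidth=wv.bandwidth,
        effective_n=eff_n,
    )


def run_gwlct(
    dataset: SpatialExpressionDataset,
    genesets: GeneSetCollection,
    spec: KernelSpec | None = None,
    B: int = 499,
    seed: int = 0,
    alpha: float = 0.05,
    shrinkage: float | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Run the geographically weighted test at every cell for every gene set.

    Returns a long-format table with one row per (location, gene-set):
    ``location_index, u, v, gene_set, rho, p_value, bandwidth,
    effective_n, flag``.  Permutation indices are drawn once per gene set
    and shared across locations, so the spatial pattern of p-values for a
    set is computed against a common sequence of relabelings.  Locations
    whose weight vector leaves fewer than two cells are flagged
    ``degenerate`` with missing statistics rather than failing the run.
    Raw p-values are reported; ``adjust='bh'`` adds a ``p_adjusted``
    column with a Benjamini-Hochberg correction across locations within
    each gene set (off by default — maps use the raw ``alpha``
    threshold).
    """
    if adjust not in (None, "bh"):
        raise ValueError("adjust must be None or 'bh'")
    if spec is None:
        spec = KernelSpec()
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype vector")
    n = dataset.n_cells
    W, hs = weight_matrix(dataset.coords, spec)
    Y = dataset.phenotype
    root = np.random.SeedSequence(seed)
    rows = []
    for si, name in enumerate(genesets.names):
        idx = dataset.gene_indices(genesets.sets[name])
        if idx.size == 0:
            for l in range(n):
                rows.append((l, *dataset.coords[l], name, np.nan, np.nan, hs[l], np.nan, "empty_set"))
            continue
        Xs = dataset.expression[idx]
        perms = _permutations(n, B, np.random.SeedSequence(seed, spawn_key=(si,)))
        Ymat = np.column_stack([Y] + [Y[p] for p in perms])
        for l in range(n):
            try:
                rho, _, eff_n = _rho_columns(Xs, Ymat, W[l], shrinkage)
            except DegenerateSupportError:
                rows.append((l, *dataset.coords[l], name, np.nan, np.nan, hs[l], float(W[l].sum()), "degenerate"))
                continue
            p = (1 + int(np.sum(rho[1:] >= rho[0]))) / (1 + B)
            rows.append((l, *dataset.coords[l], name, float(rho[0]), p, hs[l], eff_n, "ok"))
    out = pd.DataFrame(
        rows,
        columns=[
            "location_index", "u", "v", "gene_set", "rho",
            "p_value", "bandwidth", "effective_n", "flag",
        ],
    )
    if adjust == "bh":
        from scipy.stats import false_discovery_control

        out["p_adjusted"] = np.nan
        for name in genesets.names:
            sel = (out["gene_set"] == name) & out["p_value"].notna()
            if sel.any():
                out.loc[sel, "p_adjusted"] = false_discovery_control(
                    out.loc[sel, "p_value"].to_numpy(), method="bh"
                )
    out.attrs["alpha"] = alpha
    out.attrs["permutations"] = B
    return out


def global_lct(
    dataset: SpatialExpressionDataset,
    geneset: list[str] | np.ndarray,
    B: int = 499,
    seed: int = 0,
    shrinkage: float | None = None,
) -> tuple[float, float]:
    """Aspatial linear combination test: all weights equal to one.

    Returns ``(rho, p_value)`` for the whole dataset.
    """
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    if dataset.phenotype is None:
        raise ValueError("dataset has no phenotype vector")
    idx = dataset.gene_indices(geneset)
    if idx.size == 0:
        raise ValueError("gene set has no genes present in the dataset")
    n = dataset.n_cells
    perms = _permutations(n, B, np.random.SeedSequence(seed))
    Y = dataset.phenotype
    Ymat = np.column_stack([Y] + [Y[p] for p in perms])
    rho, _, _ = _rho_columns(dataset.expression[idx], Ymat, np.ones(n), shrinkage)
    p = (1 + int(np.sum(rho[1:] >= rho[0]))) / (1 + B)
    return float(rho[0]), p
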