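"""Spatial kernel weighting for geographically weighted models.

Local models are calibrated at a focal cell by down-weighting distant
cells with a compact-support kernel.  Two kernel families are supported,

* bisquare: ``w = (1 - (d/h)^2)^2`` for ``d < h``, else 0,
* tricube:  ``w = (1 - (d/h)^3)^3`` for ``d < h``, else 0,

where ``d`` is the planar Euclidean distance to the focal cell and ``h``
the bandwidth.  The bandwidth is either a fixed distance or adaptive: the
distance from the focal cell to its k-th nearest neighbour, so that every
local window carries roughly the same number of cells regardless of local
point density.  The bandwidth (or the neighbour count k) can be chosen by
leave-one-out cross-validation over a candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "WeightVector",
    "BandwidthSelection",
    "euclidean_distance",
    "distance_matrix",
    "bisquare_weight",
    "tricube_weight",
    "adaptive_bandwidth",
    "weight_vector",
    "weight_matrix",
    "select_bandwidth_cv",
]

KernelFamily = Literal["bisquare", "tricube"]
BandwidthMode = Literal["fixed", "adaptive"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family, bandwidth mode and bandwidth value.

    In ``fixed`` mode ``bandwidth`` is a positive distance in coordinate
    units; in ``adaptive`` mode it is a positive integer neighbour count
    (the per-location bandwidth becomes the distance to the k-th nearest
    neighbour, the focal cell excluded).
    """

    family: KernelFamily = "bisquare"
    mode: BandwidthMode = "adaptive"
    bandwidth: float = 16

    def __post_init__(self) -> None:
        if self.family not in ("bisquare", "tricube"):
            raise ValueError(f"unknown kernel family: {self.family!r}")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown bandwidth mode: {self.mode!r}")
        if not np.isfinite(self.bandwidth) or self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive and finite")
        if self.mode == "adaptive" and int(self.bandwidth) != self.bandwidth:
            raise ValueError("adaptive bandwidth must be an integer neighbour count")


@dataclass
class WeightVector:
    """Per-cell kernel weights centred at one calibration location."""

    values: np.ndarray
    center: int
    bandwidth: float

    @property
    def support(self) -> np.ndarray:
        """Indices of cells with strictly positive weight."""
        return np.flatnonzero(self.values > 0)


@dataclass
class BandwidthSelection:
    """Outcome of cross-validated bandwidth selection."""

    candidates: list
    cv_scores: list = field(default_factory=list)
    selected: float = np.nan


def euclidean_distance(a, b) -> float:
    """Planar Euclidean distance between two ``(u, v)`` points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """All pairwise Euclidean distances for an ``(n, 2)`` coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return cdist(coords, coords)


def _check_dh(d, h) -> tuple[np.ndarray, float]:
    if h is None or not np.isfinite(h) or h <= 0:
        raise ValueError("bandwidth h must be positive and finite")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return d, float(h)


def bisquare_weight(d, h):
    """Bisquare kernel ``(1 - (d/h)^2)^2`` for ``d < h``, zero beyond."""
    d, h = _check_dh(d, h)
    t = d / h
    w = np.where(t < 1.0, (1.0 - t**2) ** 2, 0.0)
    return w if w.ndim else float(w)


def tricube_weight(d, h):
    """Tricube kernel ``(1 - (d/h)^3)^3`` for ``d < h``, zero beyond."""
    d, h = _check_dh(d, h)
    t = d / h
    w = np.where(t < 1.0, (1.0 - t**3) ** 3, 0.0)
    return w if w.ndim else float(w)


_KERNELS = {"bisquare": bisquare_weight, "tricube": tricube_weight}


def adaptive_bandwidth(coords: np.ndarray, center: int, k: int) -> float:
    """Distance from ``center`` to its k-th nearest neighbour (center excluded).

    Duplicated coordinates can make this 0 for small ``k``; callers must
    treat a zero bandwidth as degenerate (the weight vector collapses to a
    point mass at the center).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k = int(k)
    if not 1 <= k < n:
        raise ValueError(f"neighbour count k={k} out of range [1, {n - 1}]")
    d = np.hypot(*(coords - coords[center]).T)
    d = np.delete(d, center)
    return float(np.partition(d, k - 1)[k - 1])


def resolve_bandwidth(coords: np.ndarray, center: int, spec: KernelSpec) -> float:
    """Per-location bandwidth: the fixed value, or the adaptive k-NN distance."""
    if spec.mode == "fixed":
        return float(spec.bandwidth)
    return adaptive_bandwidth(coords, center, int(spec.bandwidth))


def weight_vector(coords: np.ndarray, center: int, spec: KernelSpec) -> WeightVector:
    """Kernel weights of every cell relative to the calibration location."""
    coords = np.asarray(coords, dtype=float)
    h = resolve_bandwidth(coords, center, spec)
    d = np.hypot(*(coords - coords[center]).T)
    if h <= 0:
        # degenerate adaptive bandwidth (duplicated points): point mass
        values = np.where(d == 0, 1.0, 0.0)
        return WeightVector(values=values, center=center, bandwidth=0.0)
    values = _KERNELS[spec.family](d, h)
    return WeightVector(values=np.asarray(values, float), center=center, bandwidth=h)


def weight_matrix(coords: np.ndarray, spec: KernelSpec):
    """Stack of weight vectors for every calibration location.

    Returns ``(W, h)`` where ``W[l]`` is the weight vector centred at cell
    ``l`` and ``h[l]`` its resolved bandwidth.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    D = distance_matrix(coords)
    if spec.mode == "fixed":
        h = np.full(n, float(spec.bandwidth))
    else:
        k = int(spec.bandwidth)
        if not 1 <= k < n:
            raise ValueError(f"neighbour count k={k} out of range [1, {n - 1}]")
        Doff = D + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
        h = np.partition(Doff, k - 1, axis=1)[:, k - 1]
    kern = _KERNELS[spec.family]
    W = np.zeros_like(D)
    for l in range(n):
        if h[l] > 0:
            W[l] = kern(D[l], h[l])
        else:
            W[l] = (D[l] == 0).astype(float)
    return W, h


def select_bandwidth_cv(
    dataset,
    genesets,
    candidates: Sequence[float],
    spec: KernelSpec | None = None,
) -> BandwidthSelection:
    """Choose a bandwidth by leave-one-out cross-validation.

    For each candidate bandwidth the score is the sum over gene-sets and
    cells of the squared error ``(Y_i - Yhat_{-i})^2``, where the held-out
    prediction at cell ``i`` comes from the local linear-combination model
    calibrated at ``i`` with cell ``i``'s own weight zeroed: the local
    direction ``beta*`` is estimated from the weighted shrunken covariances
    of the remaining cells, and ``Y`` is regressed on the combination score
    ``Z = beta*'X`` by weighted least squares.  A candidate is invalid at a
    location when fewer than ``g + 2`` cells carry positive weight (the
    pre-shrinkage covariance would be rank-deficient); such candidates
    score ``+inf``.  Ties are broken toward the smallest bandwidth, i.e.
    the most local model.
    """
    from .core import _cov_factors

    if spec is None:
        spec = KernelSpec()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must not be empty")

    coords = np.asarray(dataset.coords, float)
    n = coords.shape[0]
    Y = np.asarray(dataset.phenotype, float)
    D = distance_matrix(coords)
    kern = _KERNELS[spec.family]
    member_idx = [dataset.gene_indices(genesets.sets[name]) for name in genesets.names]

    scores = []
    for cand in candidates:
        total = 0.0
        for i in range(n):
            if spec.mode == "fixed":
                h = float(cand)
            else:
                doff = np.delete(D[i], i)
                k = int(cand)
                if not 1 <= k < n:
                    raise ValueError(f"neighbour count k={k} out of range")
                h = float(np.partition(doff, k - 1)[k - 1])
            if h <= 0:
                total = np.inf
                break
            w = np.asarray(kern(D[i], h), float)
            w[i] = 0.0  # hold out the focal cell
            for idx in member_idx:
                g = len(idx)
                if np.count_nonzero(w) < g + 2:
                    total = np.inf
                    break
                Xs = dataset.expression[idx]
                L, sxy, syy, _, wn, keep = _cov_factors(Xs, Y, w)
                beta = _solve_beta(L, sxy)
                z = beta @ (Xs[:, keep])
                zbar = float(wn @ z)
                ybar = float(wn @ Y[keep])
                szz = float(np.sum(wn * (z - zbar) ** 2))
                szy = float(np.sum(wn * (z - zbar) * (Y[keep] - ybar)))
                slope = szy / szz if szz > 0 else 0.0
                yhat = ybar + slope * (float(beta @ Xs[:, i]) - zbar)
                total += (Y[i] - yhat) ** 2
            if not np.isfinite(total):
                break
        scores.append(total)

    scores_arr = np.asarray(scores, float)
    if not np.any(np.isfinite(scores_arr)):
        raise ValueError("no valid bandwidth among the candidates")
    best = np.flatnonzero(scores_arr == scores_arr.min())
    # smallest bandwidth among ties
    sel = min(candidates[j] for j in best)
    return BandwidthSelection(candidates=candidates, cv_scores=scores, selected=sel)


def _solve_beta(L: np.ndarray, sxy: np.ndarray) -> np.ndarray:
    from scipy.linalg import cho_solve

    beta = cho_solve((L, True), sxy)
    nrm = np.linalg.norm(beta)
    if nrm > 0:
        beta = beta / nrm
        nz = np.flatnonzero(beta)
        if nz.size and beta[nz[0]] < 0:
            beta = -beta
    return beta
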