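"""Poisson scan statistic for spatial clusters of gene-set enrichment.

The per-location counts of significant gene sets are scanned with
Openshaw's Geographical Analysis Machine: circles of fixed radius are
centred on a regular grid over the bounding box, the observed count
``O`` inside each circle is compared with the expectation ``E`` under a
homogeneous Poisson baseline (the global mean count per location times
the number of locations covered), and circles whose Poisson upper-tail
probability ``P(N >= O)`` falls below a threshold are flagged.  The
reported cluster is the union of locations covered by at least one
flagged circle.  In the classic GAM spirit no multiplicity correction is
applied across the (heavily overlapping) circles; the flagged map is an
exploratory display, not a family-wise test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScanConfig", "poisson_upper_tail", "gam_scan", "cluster_mask"]


@dataclass
class ScanConfig:
    """Scan geometry and flagging threshold.

    ``radius`` is the scan-circle radius (defaults to 10% of the
    bounding-box diagonal when ``None``), ``grid_spacing`` the distance
    between circle centres (defaults to ``radius / 2``, the standard GAM
    overlap), ``alpha`` the Poisson tail threshold for flagging.
    """

    radius: float | None = None
    grid_spacing: float | None = None
    alpha: float = 0.002

    def __post_init__(self) -> None:
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.grid_spacing is not None and self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def poisson_upper_tail(observed: int, expected: float) -> float:
    """``P(N >= observed)`` for ``N ~ Poisson(expected)``."""
    if expected <= 0:
        raise ValueError("expected rate must be positive")
    observed = int(observed)
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def gam_scan(counts: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """Openshaw GAM scan over a table of per-location counts.

    ``counts`` must have columns ``u, v, count`` (the ``set_counts``
    table from the significance maps).  Returns one row per evaluated
    circle: ``center_u, center_v, radius, n_inside, observed, expected,
    p, flagged``.  Circles covering no locations are skipped.
    """
    if config is None:
        config = ScanConfig()
    u = counts["u"].to_numpy(dtype=float)
    v = counts["v"].to_numpy(dtype=float)
    c = counts["count"].to_numpy(dtype=float)
    if u.size == 0:
        raise ValueError("empty counts table")
    umin, umax, vmin, vmax = u.min(), u.max(), v.min(), v.max()
    diag = float(np.hypot(umax - umin, vmax - vmin))
    radius = config.radius if config.radius is not None else max(0.1 * diag, 1e-12)
    spacing = config.grid_spacing if config.grid_spacing is not None else radius / 2.0
    mean_count = float(c.mean())

    gu = np.arange(umin, umax + spacing / 2, spacing)
    gv = np.arange(vmin, vmax + spacing / 2, spacing)
    rows = []
    r2 = radius**2
    for cu in gu:
        du2 = (u - cu) ** 2
        for cv in gv:
            inside = du2 + (v - cv) ** 2 <= r2
            n_in = int(inside.sum())
            if n_in == 0:
                continue
            O = int(round(c[inside].sum()))
            E = mean_count * n_in
            if E <= 0:
                # all-zero count table: nothing can be flagged
                p, flagged = 1.0, False
            else:
                p = poisson_upper_tail(O, E)
                flagged = p < config.alpha
            rows.append((float(cu), float(cv), radius, n_in, O, E, p, flagged))
    return pd.DataFrame(
        rows,
        columns=["center_u", "center_v", "radius", "n_inside", "observed", "expected", "p", "flagged"],
    )


def cluster_mask(counts: pd.DataFrame, circles: pd.DataFrame) -> pd.DataFrame:
    """Locations covered by at least one flagged circle.

    Returns the ``counts`` coordinates with a boolean ``in_cluster``
    column — the demarcated spatial clusters of enrichment.
    """
    u = counts["u"].to_numpy(dtype=float)
    v = counts["v"].to_numpy(dtype=float)
    mask = np.zeros(u.size, dtype=bool)
    for _, row in circles.loc[circles["flagged"]].iterrows():
        mask |= (u - row["center_u"]) ** 2 + (v - row["center_v"]) ** 2 <= row["radius"] ** 2
    out = counts[["u", "v"]].copy()
    if "location_index" in counts:
        out.insert(0, "location_index", counts["location_index"])
    out["in_cluster"] = mask
    return out
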