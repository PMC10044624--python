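"""Combined significance across gene sets and phenotype-level stratification.

At each location the K per-gene-set permutation p-values are combined
with Fisher's method: ``X2 = -2 * sum(log p_k)`` is referred to a
chi-square distribution with ``2K`` degrees of freedom, giving a combined
p-value ``CP``, and the mapped combined-significance score is
``CS = -log(CP)`` (natural log; a flag switches to base 10 for display).
The per-set p-values at one location share permutations and genes, so CP
is a descriptive enrichment summary rather than a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CombinedSignificance",
    "fisher_combine",
    "combined_significance_map",
    "significant_set_counts",
    "stratify_phenotype_levels",
]


@dataclass
class CombinedSignificance:
    """Fisher combination of K p-values at one location."""

    x2: float
    df: int
    cp: float
    cs: float


def fisher_combine(pvalues: Sequence[float], log_base: float = np.e) -> CombinedSignificance:
    """Fisher's sum-of-logs combination of independent p-values.

    ``x2 = -2 sum(ln p_k)`` ~ chi-square with ``2K`` df under the global
    null; ``cp`` is its upper-tail probability and ``cs = -log(cp)`` in
    the requested base (natural log by default).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("at least one p-value is required")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    cp = float(stats.chi2.sf(x2, df))
    cp = max(cp, np.finfo(float).tiny)  # guard the log at extreme x2
    cs = float(-np.log(cp) / np.log(log_base))
    return CombinedSignificance(x2=x2, df=df, cp=cp, cs=cs)


def combined_significance_map(results: pd.DataFrame, log_base: float = np.e) -> pd.DataFrame:
    """Per-location Fisher combination of a GWLCT result table.

    Locations where any retained gene set is missing a p-value (for
    example a degenerate local fit) are flagged and excluded from the
    combined heatmap values.  Returns columns ``location_index, u, v, x2,
    cp, cs, n_sets, flag``.
    """
    if results is None or len(results) == 0:
        raise ValueError("empty result table")
    rows = []
    for (loc, u, v), grp in results.groupby(["location_index", "u", "v"], sort=True):
        p = grp["p_value"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)):
            rows.append((loc, u, v, np.nan, np.nan, np.nan, len(p), "missing"))
            continue
        c = fisher_combine(p, log_base=log_base)
        rows.append((loc, u, v, c.x2, c.cp, c.cs, len(p), "ok"))
    return pd.DataFrame(
        rows, columns=["location_index", "u", "v", "x2", "cp", "cs", "n_sets", "flag"]
    )


def significant_set_counts(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Count of gene sets with ``p < alpha`` at each location, with their names."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if results is None or len(results) == 0:
        raise ValueError("empty result table")
    rows = []
    for (loc, u, v), grp in results.groupby(["location_index", "u", "v"], sort=True):
        sig = grp.loc[grp["p_value"] < alpha, "gene_set"].tolist()
        rows.append((loc, u, v, len(sig), ",".join(sig)))
    return pd.DataFrame(rows, columns=["location_index", "u", "v", "count", "set_names"])


def stratify_phenotype_levels(phenotype, low: float = 0.5, high: float = 1.0) -> pd.DataFrame:
    """Three-way phenotype stratification on the normalized marker scale.

    ``Low`` for values below 0.5, ``Moderate`` for values in [0.5, 1]
    (both boundaries included), ``High`` for values above 1.
    """
    y = np.asarray(phenotype, dtype=float)
    labels = np.where(y < low, "Low", np.where(y <= high, "Moderate", "High"))
    return pd.DataFrame(
        {"cell": np.arange(y.size), "phenotype_value": y, "level": labels}
    )
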