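"""Non-spatial population readouts.

Marginal per-cell distributions (intensity normalized by cell area),
rank-based k-sample comparison via the Kruskal-Wallis test, and
percent-change summaries for ensemble readouts such as proliferation or
branch-point counts.  No multiplicity correction is applied across
conditions; significance tiers follow the convention
``*`` P<0.01, ``**`` P<0.001, ``***`` P<0.0001.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats


def area_normalize(total_intensity, cell_area):
    """Per-cell intensity divided by cell area (scalar or elementwise).

    Raises ValueError on non-positive areas or negative intensities.
    """
    intensity = np.asarray(total_intensity, dtype=float)
    area = np.asarray(cell_area, dtype=float)
    if (area <= 0).any():
        raise ValueError("cell_area must be positive")
    if (intensity < 0).any():
        raise ValueError("total_intensity must be non-negative")
    out = intensity / area
    return float(out) if out.ndim == 0 else out


def k_sample_rank_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p for k samples.

    Degenerate input where every pooled value is identical returns
    (H, p) = (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 values in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def percent_change(reference: float, treated: float) -> float:
    """100 * (treated - reference) / reference; reference must be positive."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (treated - reference) / reference


def significance_label(p: float) -> str:
    """Figure-caption significance tier for a p-value."""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


def marginal_quantiles(
    values: Sequence[float], qs: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95)
) -> pd.Series:
    v = np.asarray(values, dtype=float)
    return pd.Series(np.quantile(v, qs), index=[f"q{int(100 * q):02d}" for q in qs])

def marginal_histograms(
    groups: Mapping[str, Sequence[float]], n_bins: int = 50
) -> pd.DataFrame:
    """Density histograms with bin edges shared across all groups.

    Shared edges make vehicle/treated marginals directly comparable; each
    group's counts are normalized to integrate to 1.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    rows = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for name, v in groups.items():
        dens, _ = np.histogram(np.asarray(v, dtype=float), bins=edges, density=True)
        rows[str(name)] = dens
    return pd.DataFrame(rows)
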