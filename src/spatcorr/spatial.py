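"""Spatial correlation scoring of single cells.

The core statistic.  For each experimental condition:

1. **Null distribution** — repeatedly draw two distinct cells at random
   from the condition (position ignored) and record the Pearson correlation
   of their score vectors; 2000 draws by default.  The 95th percentile of
   these draws, ``q95``, is the classification threshold.
2. **Neighbor scoring** — for every cell, find its k = 20 nearest other
   cells by Euclidean centroid distance *within the same field of view*
   (FOVs do not overlap, so cross-FOV adjacency is undefined) and record
   the median Pearson correlation between the cell's score vector and each
   neighbor's.
3. **Classification** — a cell is *spatially correlated* when its median
   neighbor correlation strictly exceeds ``q95``; ties count as
   uncorrelated.

Because a median of 20 correlations rarely exceeds the 95th percentile of a
single-pair null, the classifier is conservative under the null: the
flagged fraction is expected well below 5%, not at 5%.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import FeatureTable

log = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_N_DRAWS = 2000
DEFAULT_PERCENTILE = 0.95
#: cells with fewer usable neighbors than this are left unscored
DEFAULT_MIN_NEIGHBORS = 5

_CONDITION_KEYS = ("cell_type", "treatment", "time_point")


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


class ConditionMismatchError(ValueError):
    """A null distribution was applied to cells from a different condition."""


# ----------------------------------------------------------------------
# correlation primitives
def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two vectors.

    Raises :class:`ZeroVarianceError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ZeroVarianceError("zero-variance vector")
    return float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))


def _unit_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit norm; rows with zero variance are
    zeroed and flagged False in the returned mask.  Dot products of the
    returned rows are Pearson correlations."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    U = np.zeros_like(Xc)
    U[ok] = Xc[ok] / norms[ok, None]
    return U, ok


def empirical_quantile(
    values: np.ndarray, q: float, method: str = "linear"
) -> float:
    """Empirical quantile with a declared convention.

    ``linear`` interpolates between order statistics (default);
    ``nearest-rank`` takes the smallest order statistic with cumulative
    probability >= q.
    """
    if method == "linear":
        return float(np.quantile(values, q, method="linear"))
    if method == "nearest-rank":
        return float(np.quantile(values, q, method="inverted_cdf"))
    raise ValueError(f"unknown percentile method: {method!r}")


# ----------------------------------------------------------------------
@dataclasses.dataclass
class NullDistribution:
    """Resampled pairwise-correlation null for one condition."""

    condition: tuple  # (cell_type, treatment, time_point)
    draws: np.ndarray
    n_draws: int
    q95: float
    median_r: float
    seed: int
    percentile: float = DEFAULT_PERCENTILE
    percentile_method: str = "linear"
    n_cells: int = 0
    n_excluded_zero_variance: int = 0


def build_null(
    scores: FeatureTable,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    percentile: float = DEFAULT_PERCENTILE,
    percentile_method: str = "linear",
) -> NullDistribution:
    """Build the random-pairing null for one condition.

    Pairs are drawn uniformly with replacement across draws; the two
    members of a pair are always distinct cells.  Spatial position plays no
    role.  The whole condition is pooled (pairs are not constrained within
    FOV).  Identical seed implies identical draws.
    """
    conds = scores.condition_tuples(_CONDITION_KEYS)
    if len(conds) != 1:
        raise ConditionMismatchError(f"expected one condition, got {conds}")
    U, ok = _unit_rows(scores.features)
    n_excl = int((~ok).sum())
    if n_excl:
        log.warning("null: excluding %d zero-variance cell(s)", n_excl)
    U = U[ok]
    n = len(U)
    if n < 2:
        raise ValueError("need at least 2 cells with non-constant score vectors")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_draws)
    j = rng.integers(0, n, size=n_draws)
    clash = i == j
    while clash.any():
        j[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = i == j
    draws = np.clip(np.einsum("ij,ij->i", U[i], U[j]), -1.0, 1.0)
    return NullDistribution(
        condition=conds[0],
        draws=draws,
        n_draws=n_draws,
        q95=empirical_quantile(draws, percentile, percentile_method),
        median_r=float(np.median(draws)),
        seed=seed,
        percentile=percentile,
        percentile_method=percentile_method,
        n_cells=n,
        n_excluded_zero_variance=n_excl,
    )


# ----------------------------------------------------------------------
def find_neighbors(
    fov: pd.DataFrame | FeatureTable, k: int = DEFAULT_K
) -> dict[str, list[str]]:
    """k nearest other cells per cell, within one FOV.

    Euclidean distance between centroids; distance ties broken by ascending
    cell_id.  If the FOV holds fewer than k other cells, all of them are
    returned.
    """
    df = fov.data if isinstance(fov, FeatureTable) else fov
    if df["fov_id"].nunique() > 1:
        raise ValueError("find_neighbors operates on a single FOV")
    n = len(df)
    if n < 2:
        raise ValueError("FOV must contain at least 2 cells")
    ids = df["cell_id"].to_numpy(dtype=object)
    xy = df[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # lexsort: last key is primary -> sort by distance, then cell_id
    id_rank = np.argsort(np.argsort(ids))
    out: dict[str, list[str]] = {}
    kk = min(k, n - 1)
    for i in range(n):
        order = np.lexsort((id_rank, d2[i]))[:kk]
        out[str(ids[i])] = [str(ids[j]) for j in order]
    return out


def neighbors_by_fov(
    table: FeatureTable, k: int = DEFAULT_K
) -> dict[str, list[str]]:
    """Neighbor lists for every FOV in a table; FOVs with <2 cells skipped."""
    out: dict[str, list[str]] = {}
    for _, sub in table.data.groupby("fov_id", sort=False):
        if len(sub) < 2:
            log.warning("skipping FOV with <2 cells: %s", sub["fov_id"].iloc[0])
            continue
        out.update(find_neighbors(sub, k))
    return out


def score_cells(
    scores: FeatureTable,
    neighbors: Mapping[str, Sequence[str]],
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
) -> pd.DataFrame:
    """Median neighbor correlation per cell.

    Neighbors with zero-variance score vectors are skipped (count logged);
    a cell with a zero-variance vector, no neighbor list, or fewer than
    ``min_neighbors`` usable neighbors is left unscored
    (``median_neighbor_r`` = NaN) and excluded from summaries.

    Returns a per-cell DataFrame carrying condition keys, fov_id and
    centroids through, with columns ``median_neighbor_r``,
    ``n_neighbors_used`` and ``scored``.
    """
    U, ok = _unit_rows(scores.features)
    ids = scores.data["cell_id"].to_numpy(dtype=object)
    row_of = {str(c): i for i, c in enumerate(ids)}
    n_bad_neighbors = 0
    med = np.full(len(ids), np.nan)
    used = np.zeros(len(ids), dtype=int)
    for i, cid in enumerate(ids):
        nbrs = neighbors.get(str(cid))
        if not nbrs or not ok[i]:
            continue
        rows = [row_of[nb] for nb in nbrs if nb in row_of]
        usable = [r for r in rows if ok[r]]
        n_bad_neighbors += len(rows) - len(usable)
        if len(usable) < min_neighbors:
            continue
        med[i] = np.median(U[usable] @ U[i])
        used[i] = len(usable)
    if n_bad_neighbors:
        log.warning("skipped %d zero-variance neighbor vector(s)", n_bad_neighbors)
    out = scores.data[
        ["cell_id", "cell_type", "treatment", "time_point", "replicate",
         "fov_id", "centroid_x", "centroid_y"]
    ].copy()
    out["median_neighbor_r"] = med
    out["n_neighbors_used"] = used
    out["scored"] = ~np.isnan(med)
    n_unscored = int((~out["scored"]).sum())
    if n_unscored:
        log.info("%d cell(s) left unscored", n_unscored)
    return out


def classify(score_table: pd.DataFrame, null: NullDistribution) -> pd.DataFrame:
    """Flag spatially correlated cells: median_neighbor_r strictly > q95.

    The score table must come from the null's condition.  Unscored cells
    get flag False but remain marked unscored.
    """
    conds = set(
        map(tuple, score_table[list(_CONDITION_KEYS)].drop_duplicates().itertuples(index=False))
    )
    if conds != {tuple(null.condition)}:
        raise ConditionMismatchError(
            f"score table condition(s) {conds} != null condition {null.condition}"
        )
    out = score_table.copy()
    out["correlated_flag"] = out["scored"] & (out["median_neighbor_r"] > null.q95)
    out["null_q95"] = null.q95
    return out


def percent_correlated(
    flagged: pd.DataFrame, keys: Sequence[str] = _CONDITION_KEYS
) -> pd.DataFrame:
    """Per-condition percentage of scored cells that are flagged."""
    scored = flagged.loc[flagged["scored"]]
    if scored.empty:
        log.warning("no scored cells; empty summary")
        return pd.DataFrame(
            columns=[*keys, "n_scored", "n_flagged", "percent_correlated"]
        )
    g = scored.groupby(list(keys), sort=False)
    out = g.agg(
        n_scored=("scored", "size"), n_flagged=("correlated_flag", "sum")
    ).reset_index()
    out["percent_correlated"] = 100.0 * out["n_flagged"] / out["n_scored"]
    return out


def confusion_against_truth(
    flagged: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity/specificity of the flag against ground-truth responders.

    Computed over scored cells only.  Reported for every synthetic run.
    """
    m = flagged.loc[flagged["scored"], ["cell_id", "correlated_flag"]].merge(
        truth[["cell_id", "responder"]], on="cell_id", how="inner"
    )
    tp = int((m.correlated_flag & m.responder).sum())
    fp = int((m.correlated_flag & ~m.responder).sum())
    fn = int((~m.correlated_flag & m.responder).sum())
    tn = int((~m.correlated_flag & ~m.responder).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
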