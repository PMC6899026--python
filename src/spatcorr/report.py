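"""Presentation surfaces: binary spatial maps and percent-correlated bars.

Every figure has a CSV twin, so no number exists only in a plot.  Output is
deterministic for fixed input (figure metadata that would embed timestamps
is suppressed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "spatcorr"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# figure-convention colors: uncorrelated purple / correlated green;
# vehicle blue / treated orange
UNCORRELATED_COLOR = "#7a28a8"
CORRELATED_COLOR = "#2e8b57"
MEDIA_COLORS = {"vehicle": "#1f77b4", "IGF-1": "#ff7f0e"}

_NO_DATE = {"Date": None, "Creator": None}


def _savefig(fig, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = _NO_DATE if path.suffix == ".svg" else None
    fig.savefig(path, metadata=meta)
    plt.close(fig)


def spatial_map(
    flagged: pd.DataFrame,
    path: str | Path,
    colors: tuple[str, str] = (UNCORRELATED_COLOR, CORRELATED_COLOR),
    point_size: float = 8.0,
) -> Path:
    """Scatter centroids colored by the correlated flag, one panel per FOV."""
    path = Path(path)
    scored = flagged.loc[flagged["scored"]] if "scored" in flagged else flagged
    fovs = list(dict.fromkeys(flagged["fov_id"]))
    if scored.empty:
        log.warning("spatial_map: no scored cells; emitting empty panel")
        fovs = fovs or ["(empty)"]
    ncol = min(5, max(1, len(fovs)))
    nrow = int(np.ceil(len(fovs) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False
    )
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, fov in zip(axes.ravel(), fovs):
        sub = scored.loc[scored["fov_id"] == fov] if not scored.empty else scored
        ax.set_axis_on()
        for flag, color, label in (
            (False, colors[0], "uncorrelated"),
            (True, colors[1], "correlated"),
        ):
            pts = sub.loc[sub["correlated_flag"] == flag] if len(sub) else sub
            if len(pts):
                ax.scatter(
                    pts["centroid_x"], pts["centroid_y"],
                    s=point_size, c=color, label=label, linewidths=0,
                )
        ax.set_title(str(fov), fontsize=8)
        ax.invert_yaxis()  # image convention: y grows downward
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    _savefig(fig, path)
    # CSV twin: the plotted cells and flags
    twin_cols = [c for c in ("cell_id", "fov_id", "centroid_x", "centroid_y",
                             "median_neighbor_r", "correlated_flag") if c in flagged]
    twin = scored[twin_cols].copy()
    if "correlated_flag" in twin:
        twin["correlated_flag"] = twin["correlated_flag"].astype(int)
    twin.to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")
    return path


def summary_report(
    summary: pd.DataFrame,
    path: str | Path,
    csv_path: str | Path | None = None,
    colors: dict[str, str] | None = None,
) -> tuple[Path, Path]:
    """Grouped bars of percent correlated by time point, paired by treatment.

    Writes the plotted table verbatim to the CSV twin and returns both paths.
    """
    path = Path(path)
    csv_path = Path(csv_path) if csv_path else path.with_suffix(".csv")
    colors = colors or MEDIA_COLORS
    cell_types = list(dict.fromkeys(summary["cell_type"]))
    fig, axes = plt.subplots(
        1, max(1, len(cell_types)), figsize=(4.5 * max(1, len(cell_types)), 3.2),
        squeeze=False,
    )
    for ax, ct in zip(axes.ravel(), cell_types or ["(none)"]):
        sub = summary.loc[summary["cell_type"] == ct]
        times = sorted(sub["time_point"].unique())
        treatments = list(dict.fromkeys(sub["treatment"]))
        width = 0.8 / max(1, len(treatments))
        x = np.arange(len(times))
        for ti, tr in enumerate(treatments):
            vals = [
                sub.loc[(sub.time_point == t) & (sub.treatment == tr),
                        "percent_correlated"].mean()
                for t in times
            ]
            ax.bar(
                x + ti * width, vals, width,
                color=colors.get(tr, f"C{ti}"), label=str(tr),
            )
        ax.set_xticks(x + width * (len(treatments) - 1) / 2)
        ax.set_xticklabels([f"{t:g}" for t in times])
        ax.set_xlabel("time point (min)")
        ax.set_ylabel("% spatially correlated")
        ax.set_title(str(ct))
        ax.legend(fontsize=8)
    fig.tight_layout()
    _savefig(fig, path)
    out = summary.copy()
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(csv_path, index=False, float_format="%.17g")
    return path, csv_path
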