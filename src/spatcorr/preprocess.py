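"""Robust per-feature normalization against a time-zero reference population.

Each feature is centered on the reference median and scaled by
``1.4826 * MAD``, where MAD is the median absolute deviation from the
median.  For Gaussian data 1.4826*MAD is a consistent estimator of the SD,
so normalized features are on an approximate z-score scale while remaining
insensitive to the heavy tails and outlier cells typical of segmented
imaging features.

The reference population is all cells of one cell type at time point 0
(treatment cannot yet have acted), and one reference is computed per cell
type because cell types differ in baseline morphology.  Features whose
reference MAD is exactly 0 carry no usable information on this scale and
are removed from the retained feature set; an explicit exclusion list can
remove further features by name.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, SchemaError

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # 1/Phi^-1(3/4): makes MAD consistent for the Gaussian SD


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class NormalizationReference:
    """Per-feature robust location/scale from a reference population."""

    cell_type: str
    medians: pd.Series  # indexed by feature name (all input features)
    mads: pd.Series
    retained_features: list[str]  # MAD > 0 only, input order preserved
    scale_constant: float = MAD_SCALE
    n_reference_cells: int = 0

    @property
    def n_dropped(self) -> int:
        return len(self.medians) - len(self.retained_features)


def compute_reference(
    table: FeatureTable,
    exclude_features: Iterable[str] = (),
    scale_constant: float = MAD_SCALE,
) -> NormalizationReference:
    """Compute the normalization reference from a time-zero table.

    ``table`` must contain a single cell type, all rows at time point 0.
    Median convention: midpoint of the two central order statistics for
    even n.  MAD is the median of absolute deviations from the median,
    without small-sample correction.

    Raises
    ------
    PreprocessError
        On an empty table, mixed cell types, non-zero time points, or if
        every feature has MAD = 0.
    """
    if table.n_cells == 0:
        raise PreprocessError("empty reference table")
    types = table.data["cell_type"].unique()
    if len(types) != 1:
        raise PreprocessError(f"reference must be a single cell type, got {list(types)}")
    if (table.data["time_point"].to_numpy(dtype=float) != 0).any():
        raise PreprocessError("reference population must be at time point 0")

    X = table.features
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    excluded = set(exclude_features)
    retained = [
        f
        for f, m in zip(table.feature_names, mad)
        if m > 0 and f not in excluded
    ]
    if not retained:
        raise PreprocessError("no usable features: all have MAD = 0 (or excluded)")
    n_dropped = len(table.feature_names) - len(retained)
    if n_dropped:
        log.info(
            "dropping %d feature(s) with MAD = 0 or excluded by name", n_dropped
        )
    return NormalizationReference(
        cell_type=str(types[0]),
        medians=pd.Series(med, index=table.feature_names),
        mads=pd.Series(mad, index=table.feature_names),
        retained_features=retained,
        scale_constant=scale_constant,
        n_reference_cells=table.n_cells,
    )


def apply_normalization(
    table: FeatureTable, ref: NormalizationReference
) -> FeatureTable:
    """Normalize a table: x -> (x - median_f) / (scale * MAD_f).

    Output contains exactly the reference's retained features in order;
    metadata and coordinates pass through unchanged.
    """
    missing = [f for f in ref.retained_features if f not in table.feature_names]
    if missing:
        raise SchemaError(f"table lacks retained feature(s): {missing[:5]}")
    out = table.data.drop(columns=table.feature_names).copy()
    X = table.data[ref.retained_features].to_numpy(dtype=float)
    med = ref.medians[ref.retained_features].to_numpy()
    scale = ref.scale_constant * ref.mads[ref.retained_features].to_numpy()
    Z = (X - med) / scale
    out = pd.concat(
        [out, pd.DataFrame(Z, columns=ref.retained_features, index=out.index)],
        axis=1,
    )
    return FeatureTable(out, list(ref.retained_features))
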