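"""Reading and writing per-cell feature tables.

Input tables follow the CellProfiler per-object export convention: one CSV
row per segmented cell, metadata columns prefixed ``Metadata_``, centroid
columns ``Location_Center_X``/``Location_Center_Y``, and one numeric column
per morphology/intensity/texture feature.  Column names are remappable via a
``schema_map`` so exports from other segmentation tools can be ingested.

Coordinates are field-of-view-local pixels with the image convention
(origin top-left, y increasing downward).  Fields of view are imaged as a
non-overlapping grid, so no global slide coordinate system exists and none
is constructed here.

All floats are written with 17 significant digits so that a write/read
round trip reproduces every value bit-exactly; boolean flags are serialized
as 0/1 integers.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: internal metadata field -> default CSV column name (CellProfiler dialect)
DEFAULT_SCHEMA_MAP: dict[str, str] = {
    "cell_id": "Cell_ID",
    "cell_type": "Metadata_CellType",
    "treatment": "Metadata_Treatment",
    "time_point": "Metadata_TimePoint",
    "replicate": "Metadata_Replicate",
    "fov_id": "Metadata_FOV",
    "centroid_x": "Location_Center_X",
    "centroid_y": "Location_Center_Y",
    "cell_area": "AreaShape_Area",
}

#: metadata columns, in canonical output order
METADATA_FIELDS: tuple[str, ...] = tuple(DEFAULT_SCHEMA_MAP)

#: condition key: all cells of one FOV share these values
CONDITION_KEYS: tuple[str, ...] = ("cell_type", "treatment", "time_point", "replicate")

FLOAT_FORMAT = "%.17g"


class SchemaError(ValueError):
    """A mandatory column is missing or feature sets do not match."""


class ValidationError(ValueError):
    """Table contents violate an invariant (duplicate ids, bad values)."""


@dataclasses.dataclass
class FeatureTable:
    """A validated per-cell feature table.

    Parameters
    ----------
    data
        One row per cell.  Contains every column in :data:`METADATA_FIELDS`
        plus one numeric column per feature.
    feature_names
        Ordered list of feature column names.  Order is preserved through
        every pipeline step.
    n_rejected
        Number of input rows dropped at ingest for non-numeric or missing
        feature values.
    """

    data: pd.DataFrame
    feature_names: list[str]
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.feature_names = list(self.feature_names)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in METADATA_FIELDS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
            raise ValidationError(f"duplicate cell_id values, e.g. {list(dupes)}")
        feats = df[self.feature_names]
        if len(df) and not all(np.issubdtype(d, np.number) for d in feats.dtypes):
            raise ValidationError("non-numeric feature column after ingest")
        if len(df) and not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite feature values")
        if len(df):
            if (df["time_point"].to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative time_point")
            if (df["cell_area"].to_numpy(dtype=float) <= 0).any():
                raise ValidationError("non-positive cell_area")
            # every FOV maps to exactly one condition tuple
            per_fov = df.groupby("fov_id", sort=False)[list(CONDITION_KEYS)].nunique()
            if (per_fov > 1).any(axis=None):
                bad = per_fov[(per_fov > 1).any(axis=1)].index.tolist()
                raise ValidationError(f"FOV(s) with mixed condition metadata: {bad}")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def features(self) -> np.ndarray:
        """Feature matrix (cells x features) as float64."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def subset(self, mask) -> "FeatureTable":
        """Row subset (boolean mask or pandas indexer); keeps schema."""
        return FeatureTable(
            self.data.loc[mask].reset_index(drop=True), list(self.feature_names)
        )

    def condition_tuples(self, keys: Iterable[str] = ("cell_type", "treatment", "time_point")):
        """Unique condition tuples present, in first-appearance order."""
        sub = self.data[list(keys)].drop_duplicates()
        return [tuple(row) for row in sub.itertuples(index=False)]

    def groupby_condition(self, keys: Iterable[str] = ("cell_type", "treatment", "time_point")):
        """Yield (condition tuple, FeatureTable) per condition."""
        for cond, idx in self.data.groupby(list(keys), sort=False).groups.items():
            if not isinstance(cond, tuple):
                cond = (cond,)
            yield cond, self.subset(idx)


# ----------------------------------------------------------------------
def read_feature_table(
    path: str | Path, schema_map: Mapping[str, str] | None = None
) -> FeatureTable:
    """Read a CellProfiler-style per-cell CSV into a :class:`FeatureTable`.

    Every column that is neither mapped metadata nor prefixed ``Metadata_``
    is treated as a feature, in file order.  Rows containing any
    non-numeric or missing feature value are rejected; the count is logged
    and stored as ``n_rejected``.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the error names it).
    ValidationError
        On duplicate ``cell_id`` values or inconsistent FOV metadata.
    """
    smap = dict(DEFAULT_SCHEMA_MAP)
    if schema_map:
        smap.update(schema_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [smap[f] for f in METADATA_FIELDS if smap[f] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    mapped = set(smap.values())
    feature_cols = [
        c for c in df.columns if c not in mapped and not c.startswith("Metadata_")
    ]
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = feats.isna().any(axis=1)
    n_rejected = int(bad_rows.sum())
    if n_rejected:
        log.warning("rejected %d row(s) with non-numeric feature values", n_rejected)

    keep = df.loc[~bad_rows].reset_index(drop=True)
    out = pd.DataFrame(index=keep.index)
    for field in METADATA_FIELDS:
        out[field] = keep[smap[field]]
    for field in ("cell_id", "cell_type", "treatment", "replicate", "fov_id"):
        out[field] = out[field].astype(str)
    for field in ("time_point", "centroid_x", "centroid_y", "cell_area"):
        out[field] = pd.to_numeric(out[field])
    for c in feature_cols:
        out[c] = pd.to_numeric(keep[c])
    return FeatureTable(out, feature_cols, n_rejected=n_rejected)


def write_table(
    table: "FeatureTable | pd.DataFrame",
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> Path:
    """Write a feature table or a plain result table to CSV.

    :class:`FeatureTable` objects are written in the input dialect (metadata
    columns renamed via the schema map) so that
    ``read_feature_table(write_table(t))`` reproduces ``t`` exactly.  Plain
    DataFrames (score tables, summaries) are written as-is with boolean
    columns encoded 0/1 and a deterministic column order (input order).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(table, FeatureTable):
        smap = dict(DEFAULT_SCHEMA_MAP)
        if schema_map:
            smap.update(schema_map)
        df = table.data[list(METADATA_FIELDS) + table.feature_names].rename(
            columns={k: v for k, v in smap.items()}
        )
    else:
        df = table.copy()
        for c in df.columns:
            if df[c].dtype == bool:
                df[c] = df[c].astype(int)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path
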