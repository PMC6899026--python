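"""End-to-end pipeline: simulate/ingest -> normalize -> embed -> spatial score.

One structured config (YAML or dict) with a single master seed drives the
whole run; every stochastic step derives its sub-seed deterministically
from that seed, so an entire run is replayable bit-identically.  The run
directory receives all intermediate tables, figures with CSV twins, a
machine-readable manifest (config hash, library versions, seeds, every
filter count and selected dimensionality) and a log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_tables import FeatureTable, read_feature_table, write_table
from .preprocess import MAD_SCALE, apply_normalization, compute_reference
from .embedding import fit_embedding, transform
from .spatial import (
    DEFAULT_K,
    DEFAULT_MIN_NEIGHBORS,
    DEFAULT_N_DRAWS,
    DEFAULT_PERCENTILE,
    build_null,
    classify,
    confusion_against_truth,
    neighbors_by_fov,
    percent_correlated,
    score_cells,
)
from .synthetic import Condition, GeneratorParams, generate_experiment
from .report import spatial_map, summary_report

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The config is structurally invalid; raised before any computation."""


_CONDITION_FIELDS = {"cell_type", "treatment", "time_point", "replicate"}
_GENERATOR_FIELDS = {f.name for f in dataclasses.fields(GeneratorParams)}


@dataclasses.dataclass
class SimulateConfig:
    """Synthetic-experiment section: shared generator defaults plus one
    entry per condition (condition metadata + per-condition overrides)."""

    conditions: list[dict]
    generator: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("simulate.conditions must be non-empty")
        for c in self.conditions:
            unknown = set(c) - _CONDITION_FIELDS - _GENERATOR_FIELDS
            if unknown:
                raise ConfigError(f"unknown condition key(s): {sorted(unknown)}")
        unknown = set(self.generator) - _GENERATOR_FIELDS
        if unknown:
            raise ConfigError(f"unknown generator key(s): {sorted(unknown)}")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Defaults reproduce the published procedure parameters: k = 20 nearest
    neighbors, 2000 null draws, 99% explained-variance threshold, 95%
    classification percentile and the 1.4826 MAD scale constant.
    """

    seed: int = 0
    output_dir: str = "results"
    input_table: str | None = None
    schema_map: dict | None = None
    simulate: SimulateConfig | None = None
    k_neighbors: int = DEFAULT_K
    n_draws: int = DEFAULT_N_DRAWS
    variance_threshold: float = 0.99
    classification_percentile: float = DEFAULT_PERCENTILE
    mad_scale: float = MAD_SCALE
    percentile_method: str = "linear"
    correlation_space: str = "pca"  # "pca" | "features"
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS
    exclude_features: list[str] = dataclasses.field(default_factory=list)
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.correlation_space not in ("pca", "features"):
            raise ConfigError("correlation_space must be 'pca' or 'features'")
        if self.percentile_method not in ("linear", "nearest-rank"):
            raise ConfigError("percentile_method must be 'linear' or 'nearest-rank'")
        if self.input_table is None and self.simulate is None:
            raise ConfigError("either input_table or simulate must be given")
        if isinstance(self.simulate, dict):
            self.simulate = SimulateConfig(**self.simulate)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as e:  # wrong value shapes
        raise ConfigError(str(e)) from e


def derive_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit sub-seed for a keyed stochastic step."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _simulate(config: PipelineConfig):
    sim = config.simulate
    conditions, params = [], []
    for c in sim.conditions:
        meta = {k: v for k, v in c.items() if k in _CONDITION_FIELDS}
        over = {k: v for k, v in c.items() if k in _GENERATOR_FIELDS}
        conditions.append(Condition(**meta))
        params.append(GeneratorParams(**{**sim.generator, **over}))
    return generate_experiment(conditions, params, seed=config.seed)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict[str, Any]:
    """Execute the full pipeline; returns the run manifest.

    The output directory receives: ``features.csv`` (input table),
    ``ground_truth.csv`` (synthetic runs), per-condition null draws,
    ``cell_scores.csv`` (per-cell median neighbor correlation + flag),
    ``summary.csv`` (percent correlated per condition), figures with CSV
    twins, ``manifest.json`` and ``run.log``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = config_from_dict(config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_log = logging.getLogger("spatcorr")
    pkg_log.addHandler(handler)
    old_level = pkg_log.level
    pkg_log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        pkg_log.removeHandler(handler)
        pkg_log.setLevel(old_level)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    manifest: dict[str, Any] = {
        "spatcorr_version": __version__,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "parameters": {
            "k_neighbors": config.k_neighbors,
            "n_draws": config.n_draws,
            "variance_threshold": config.variance_threshold,
            "classification_percentile": config.classification_percentile,
            "mad_scale": config.mad_scale,
            "percentile_method": config.percentile_method,
            "correlation_space": config.correlation_space,
            "min_neighbors": config.min_neighbors,
        },
        "seed": config.seed,
    }

    # ---- ingest or simulate -----------------------------------------
    truth = None
    if config.input_table is not None:
        table = read_feature_table(config.input_table, config.schema_map)
    else:
        table, truth = _simulate(config)
        write_table(table, outdir / "features.csv")
        write_table(truth, outdir / "ground_truth.csv")
    manifest["cells_ingested"] = table.n_cells
    manifest["cells_rejected"] = table.n_rejected
    manifest["n_features_in"] = len(table.feature_names)
    log.info("ingested %d cells, %d features (%d rows rejected)",
             table.n_cells, len(table.feature_names), table.n_rejected)

    # ---- per cell type: reference, normalization, embedding ---------
    cell_types = list(dict.fromkeys(table.data["cell_type"]))
    flagged_parts, null_rows = [], []
    manifest["cell_types"] = {}
    cond_index = 0
    for ct in cell_types:
        sub = table.subset(table.data["cell_type"].to_numpy() == ct)
        at_t0 = sub.subset(sub.data["time_point"].to_numpy(dtype=float) == 0.0)
        ref = compute_reference(
            at_t0, exclude_features=config.exclude_features,
            scale_constant=config.mad_scale,
        )
        normed = apply_normalization(sub, ref)
        ct_info: dict[str, Any] = {
            "n_cells": sub.n_cells,
            "n_reference_cells": ref.n_reference_cells,
            "n_features_dropped_mad0": ref.n_dropped,
            "n_features_retained": len(ref.retained_features),
        }
        if config.correlation_space == "pca":
            model = fit_embedding(
                normed, config.variance_threshold, fit_population=str(ct)
            )
            scores = transform(normed, model)
            ct_info["n_components"] = model.n_components
            log.info("cell type %s: %d components capture %.0f%% variance",
                     ct, model.n_components, 100 * config.variance_threshold)
        else:
            scores = normed
            ct_info["n_components"] = len(normed.feature_names)
        manifest["cell_types"][str(ct)] = ct_info

        # ---- per condition: null, neighbors, scoring, classification
        for cond, cscores in scores.groupby_condition():
            null_seed = derive_seed(config.seed, 1, cond_index)
            null = build_null(
                cscores,
                n_draws=config.n_draws,
                seed=null_seed,
                percentile=config.classification_percentile,
                percentile_method=config.percentile_method,
            )
            nbrs = neighbors_by_fov(cscores, k=config.k_neighbors)
            scored = score_cells(cscores, nbrs, min_neighbors=config.min_neighbors)
            flags = classify(scored, null)
            flagged_parts.append(flags)
            null_rows.append(
                pd.DataFrame(
                    {
                        "cell_type": cond[0], "treatment": cond[1],
                        "time_point": cond[2], "draw": np.arange(null.n_draws),
                        "r": null.draws, "q95": null.q95,
                        "median_r": null.median_r, "seed": null.seed,
                    }
                )
            )
            cond_index += 1

    flagged = pd.concat(flagged_parts, ignore_index=True)
    nulls = pd.concat(null_rows, ignore_index=True)
    summary = percent_correlated(flagged)
    write_table(flagged, outdir / "cell_scores.csv")
    write_table(nulls, outdir / "null_draws.csv")
    write_table(summary, outdir / "summary.csv")

    manifest["cells_unscored"] = int((~flagged["scored"]).sum())
    manifest["conditions"] = [
        {
            "cell_type": r.cell_type, "treatment": r.treatment,
            "time_point": r.time_point, "n_scored": int(r.n_scored),
            "n_flagged": int(r.n_flagged),
            "percent_correlated": float(r.percent_correlated),
        }
        for r in summary.itertuples()
    ]
    q_lookup = nulls.groupby(
        ["cell_type", "treatment", "time_point"], sort=False
    )["q95"].first()
    for c in manifest["conditions"]:
        c["null_q95"] = float(
            q_lookup[(c["cell_type"], c["treatment"], c["time_point"])]
        )
    if truth is not None:
        manifest["confusion"] = confusion_against_truth(flagged, truth)

    if config.make_figures:
        for cond, sub in flagged.groupby(
            ["cell_type", "treatment", "time_point"], sort=False
        ):
            tag = "_".join(f"{v:g}" if isinstance(v, float) else str(v) for v in cond)
            spatial_map(sub, outdir / f"spatial_map_{tag}.png")
        if len(summary):
            summary_report(summary, outdir / "percent_correlated.png",
                           outdir / "percent_correlated_figure.csv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("run complete: %s", outdir)
    return manifest
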