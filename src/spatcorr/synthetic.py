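"""Synthetic multi-FOV single-cell feature tables with planted spatial structure.

The generator emulates the statistical structure the spatial analysis
assumes: a slide imaged as a grid of non-overlapping fields of view, a
baseline cell population whose feature vectors are iid Gaussian noise and
independent of position, and a "responder" sub-population that is both

* spatially clustered — responders are placed by a Thomas-like cluster
  process (cluster centers uniform in the FOV, isotropic Gaussian
  dispersion around them, truncated to the FOV), and
* phenotypically shifted — responders receive a mean shift of
  ``effect_size`` baseline-SD units on the first ``n_shifted_features``
  features.

With ``responder_fraction = 0`` the output satisfies the null hypothesis of
the downstream test exactly: feature vectors are iid and exchangeable
across spatial positions.

Every cell carries a ground-truth responder flag and cluster id so that
sensitivity and specificity of the downstream classification can be scored.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, METADATA_FIELDS

__all__ = [
    "GeneratorParams",
    "Condition",
    "GenerationError",
    "generate_fov",
    "generate_experiment",
    "condition_seed",
]


class GenerationError(RuntimeError):
    """Point placement failed (spacing constraint infeasible) or bad params."""


@dataclasses.dataclass(frozen=True)
class Condition:
    """Experimental condition metadata shared by all cells of one FOV."""

    cell_type: str = "normal"
    treatment: str = "vehicle"
    time_point: float = 0.0
    replicate: str = "r1"

    def tag(self) -> str:
        t = f"{self.time_point:g}".replace(".", "p")
        return f"{self.cell_type}_{self.treatment}_t{t}_{self.replicate}"


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic experiment.

    Defaults describe one slide imaged as a 10x10 grid (100 FOVs) with a
    CellProfiler-scale feature set (390 features) at typical endothelial
    confluence (~500 cells per 1000 px FOV).  The planted responder
    sub-population occupies 20% of cells, gathered in 3 tight clusters per
    FOV (sigma = 5% of the FOV side) and shifted by 2 baseline SDs on the
    first 30 features.

    Attributes
    ----------
    n_fovs : number of fields of view per condition.
    fov_size : FOV side length, pixels; centroids lie in [0, fov_size]^2.
    cells_per_fov : cells placed in each FOV.
    n_features : length of each cell's feature vector.
    responder_fraction : probability a cell is a responder (Bernoulli per cell).
    n_clusters_per_fov : cluster centers drawn uniformly per FOV.
    cluster_sigma : isotropic Gaussian dispersion of responders around their
        cluster center, pixels.
    effect_size : responder mean shift in units of ``baseline_noise_sd``.
    n_shifted_features : the shift applies to the first this-many features
        (deterministic by index, for reproducibility).
    baseline_noise_sd : SD of the iid Gaussian feature noise.
    min_cell_spacing : optional hard-core distance between centroids, pixels;
        0 disables the constraint.
    seed : master seed; every FOV derives a sub-stream deterministically.
    """

    n_fovs: int = 100
    fov_size: float = 1000.0
    cells_per_fov: int = 500
    n_features: int = 390
    responder_fraction: float = 0.2
    n_clusters_per_fov: int = 3
    cluster_sigma: float = 50.0
    effect_size: float = 2.0
    n_shifted_features: int = 30
    baseline_noise_sd: float = 1.0
    min_cell_spacing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise GenerationError("responder_fraction must be in [0, 1]")
        if self.n_shifted_features > self.n_features:
            raise GenerationError("n_shifted_features exceeds n_features")
        if self.baseline_noise_sd <= 0:
            raise GenerationError("baseline_noise_sd must be positive")
        if self.min_cell_spacing < 0 or self.cluster_sigma < 0:
            raise GenerationError("distances must be non-negative")


_MAX_PLACEMENT_ATTEMPTS = 2000

# cell_area is drawn lognormal with these fixed parameters (median ~500 px^2,
# right-skewed like segmented cell footprints); emitted so synthetic tables
# pass the same ingest path as real exports.
_AREA_MU, _AREA_SIGMA = np.log(500.0), 0.35


def _place_point(rng, propose, accepted, min_spacing):
    """Rejection-sample one point satisfying the hard-core constraint."""
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        p = propose()
        if min_spacing <= 0 or not accepted:
            return p
        d2 = np.min(np.sum((np.asarray(accepted) - p) ** 2, axis=1))
        if d2 >= min_spacing**2:
            return p
    raise GenerationError(
        f"could not place cell after {_MAX_PLACEMENT_ATTEMPTS} attempts; "
        "cells_per_fov infeasible under min_cell_spacing"
    )


def generate_fov(
    params: GeneratorParams,
    fov_index: int = 0,
    condition: Condition = Condition(),
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one FOV: feature-table rows plus ground-truth rows.

    Non-responders are uniform in the FOV; responders follow the cluster
    process.  Reproducible: the random stream is derived from
    ``(params.seed, fov_index)`` unless an explicit ``seed_seq`` is given.

    Returns
    -------
    (rows, truth)
        ``rows`` has the full :data:`~spatcorr.io_tables.METADATA_FIELDS` +
        feature columns; ``truth`` has cell_id, responder (bool), cluster_id.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(params.seed, spawn_key=(fov_index,))
    rng = np.random.default_rng(seed_seq)
    n = params.cells_per_fov
    fov_id = f"{condition.tag()}_fov{fov_index:03d}"

    responder = rng.random(n) < params.responder_fraction
    centers = rng.uniform(0, params.fov_size, size=(params.n_clusters_per_fov, 2))
    cluster_of = np.full(n, -1)
    cluster_of[responder] = rng.integers(0, params.n_clusters_per_fov, responder.sum())

    coords: list[np.ndarray] = []
    for i in range(n):
        if responder[i]:
            c = centers[cluster_of[i]]

            def propose(c=c):
                # truncation to the FOV by rejection
                while True:
                    p = rng.normal(c, params.cluster_sigma, size=2)
                    if (0 <= p).all() and (p <= params.fov_size).all():
                        return p

        else:

            def propose():
                return rng.uniform(0, params.fov_size, size=2)

        coords.append(_place_point(rng, propose, coords, params.min_cell_spacing))
    xy = np.asarray(coords).reshape(n, 2)

    feats = rng.normal(0.0, params.baseline_noise_sd, size=(n, params.n_features))
    if params.n_shifted_features and responder.any():
        shift = params.effect_size * params.baseline_noise_sd
        feats[np.ix_(responder, np.arange(params.n_shifted_features))] += shift

    cell_ids = [f"{fov_id}_c{i:04d}" for i in range(n)]
    rows = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": condition.cell_type,
            "treatment": condition.treatment,
            "time_point": float(condition.time_point),
            "replicate": condition.replicate,
            "fov_id": fov_id,
            "centroid_x": xy[:, 0],
            "centroid_y": xy[:, 1],
            "cell_area": rng.lognormal(_AREA_MU, _AREA_SIGMA, size=n),
        }
    )
    feat_cols = pd.DataFrame(
        feats, columns=[f"Feature_{j:04d}" for j in range(params.n_features)]
    )
    rows = pd.concat([rows, feat_cols], axis=1)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "responder": responder,
            "cluster_id": [
                f"{fov_id}_k{k}" if k >= 0 else "" for k in cluster_of
            ],
        }
    )
    return rows, truth


def condition_seed(master_seed: int, condition_index: int) -> int:
    """Deterministic sub-seed for the condition at ``condition_index``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(condition_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def generate_experiment(
    conditions: Sequence[Condition],
    params: GeneratorParams | Sequence[GeneratorParams],
    seed: int = 0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate a multi-condition experiment (snapshot design).

    Each condition receives its own parameter set (a single
    :class:`GeneratorParams` is broadcast to all) and a sub-seed derived
    deterministically from ``seed`` via :func:`condition_seed`, so the whole
    experiment is replayable from one master seed.  cell_ids and fov_ids are
    globally unique.
    """
    if not conditions:
        raise GenerationError("need at least one condition")
    if len(set(conditions)) != len(conditions):
        raise GenerationError("duplicate condition tuples")
    if isinstance(params, GeneratorParams):
        plist = [params] * len(conditions)
    else:
        plist = list(params)
        if len(plist) != len(conditions):
            raise GenerationError("params list length must match conditions")

    all_rows, all_truth = [], []
    for ci, (cond, p) in enumerate(zip(conditions, plist)):
        p_c = dataclasses.replace(p, seed=condition_seed(seed, ci))
        for f in range(p_c.n_fovs):
            rows, truth = generate_fov(p_c, f, cond)
            all_rows.append(rows)
            all_truth.append(truth)
    data = pd.concat(all_rows, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    feature_cols = [c for c in data.columns if c not in METADATA_FIELDS]
    return FeatureTable(data, feature_cols), truth
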