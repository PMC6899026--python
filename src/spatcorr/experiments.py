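"""Self-contained benchmark experiments on synthetic data.

Two canned experiments exercise the full procedure end to end and are used
to characterize it:

* :func:`null_calibration_experiment` — data generated under the null
  (no responders, iid features): the null threshold should sit at the
  theoretical 95th percentile of random-pair correlations and essentially
  no cells should be flagged.
* :func:`recovery_experiment` — a vehicle/time-zero condition provides the
  normalization reference and a treated condition carries a planted,
  spatially clustered responder sub-population; the flagged-cell set is
  scored against ground truth.

Every stochastic step derives its seed from the experiment's master seed,
so results are exactly reproducible.
"""

from __future__ import annotations

from .io_tables import FeatureTable
from .preprocess import apply_normalization, compute_reference
from .embedding import fit_embedding, transform
from .pipeline import derive_seed
from .spatial import (
    build_null,
    classify,
    confusion_against_truth,
    neighbors_by_fov,
    percent_correlated,
    score_cells,
)
from .synthetic import Condition, GeneratorParams, generate_experiment

__all__ = ["null_calibration_experiment", "recovery_experiment"]


def _score_condition(scores: FeatureTable, seed: int, n_draws: int, k: int,
                     min_neighbors: int):
    null = build_null(scores, n_draws=n_draws, seed=seed)
    nbrs = neighbors_by_fov(scores, k=k)
    scored = score_cells(scores, nbrs, min_neighbors=min_neighbors)
    return null, classify(scored, null)


def null_calibration_experiment(
    seed: int,
    n_fovs: int = 20,
    cells_per_fov: int = 300,
    n_features: int = 119,
    n_draws: int = 2000,
    k: int = 20,
    min_neighbors: int = 5,
) -> dict:
    """Run the full scoring procedure on data satisfying the null.

    Feature vectors are iid Gaussian and independent of position, and
    correlations are computed directly on the normalized features, so the
    score vectors are iid in ``n_features`` dimensions.  For d-dimensional
    iid vectors the pairwise correlation is approximately N(0, 1/(d-1)),
    putting the expected null threshold near ``1.645/sqrt(d-1)``.

    Returns q95, the median of the null draws, the end-to-end flagged
    fraction and the cell count.
    """
    params = GeneratorParams(
        n_fovs=n_fovs, cells_per_fov=cells_per_fov, n_features=n_features,
        n_shifted_features=0, responder_fraction=0.0, seed=seed,
    )
    table, _ = generate_experiment([Condition()], params, seed=seed)
    ref = compute_reference(table)
    scores = apply_normalization(table, ref)
    null, flagged = _score_condition(
        scores, derive_seed(seed, 101), n_draws, k, min_neighbors
    )
    n_scored = int(flagged["scored"].sum())
    return {
        "q95": null.q95,
        "null_median_r": null.median_r,
        "flagged_fraction": float(flagged["correlated_flag"].sum()) / n_scored,
        "n_cells": n_scored,
    }


def recovery_experiment(
    seed: int,
    effect_size: float = 2.0,
    cluster_sigma: float = 50.0,
    responder_fraction: float = 0.2,
    n_fovs: int = 20,
    cells_per_fov: int = 500,
    n_features: int = 300,
    n_shifted_features: int = 30,
    n_clusters_per_fov: int = 3,
    fov_size: float = 1000.0,
    variance_threshold: float = 0.99,
    n_draws: int = 2000,
    k: int = 20,
    min_neighbors: int = 5,
) -> dict:
    """Plant a clustered responder population and score its recovery.

    Layout mirrors the snapshot design: a vehicle condition at time zero
    (no responders) supplies the normalization reference; the treated
    condition carries responders.  Correlations are computed on the PCA
    scores capturing ``variance_threshold`` of the pooled variance.

    Returns sensitivity/specificity against ground truth, percent
    correlated in both conditions, the null threshold and sizes.
    """
    gen = dict(
        n_fovs=n_fovs, cells_per_fov=cells_per_fov, n_features=n_features,
        n_shifted_features=n_shifted_features, effect_size=effect_size,
        n_clusters_per_fov=n_clusters_per_fov, cluster_sigma=cluster_sigma,
        fov_size=fov_size,
    )
    conditions = [
        Condition("normal", "vehicle", 0.0),
        Condition("normal", "IGF-1", 1440.0),
    ]
    params = [
        GeneratorParams(**gen, responder_fraction=0.0),
        GeneratorParams(**gen, responder_fraction=responder_fraction),
    ]
    table, truth = generate_experiment(conditions, params, seed=seed)
    ref = compute_reference(
        table.subset(table.data["time_point"].to_numpy() == 0.0)
    )
    normed = apply_normalization(table, ref)
    model = fit_embedding(normed, variance_threshold)
    scores = transform(normed, model)

    out: dict = {"n_components": model.n_components}
    for i, (cond, cscores) in enumerate(scores.groupby_condition()):
        null, flagged = _score_condition(
            cscores, derive_seed(seed, 201, i), n_draws, k, min_neighbors
        )
        pct = percent_correlated(flagged)["percent_correlated"].iloc[0]
        if cond[1] == "IGF-1":
            conf = confusion_against_truth(flagged, truth)
            out.update(
                q95=null.q95,
                sensitivity=conf["sensitivity"],
                specificity=conf["specificity"],
                percent_correlated=float(pct),
                planted_percent=100.0 * responder_fraction,
                n_cells=int(flagged["scored"].sum()),
            )
        else:
            out["vehicle_percent_correlated"] = float(pct)
    return out
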