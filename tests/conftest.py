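import numpy as np
import pandas as pd
import pytest

from spatcorr import Condition, FeatureTable, GeneratorParams, generate_experiment


def make_table(
    n_cells: int = 6,
    feature_values: dict | None = None,
    cell_type: str = "normal",
    time_point: float = 0.0,
    fov_id: str = "fov0",
    coords: np.ndarray | None = None,
) -> FeatureTable:
    """Hand-built single-FOV table for unit tests."""
    if feature_values is None:
        feature_values = {"f1": np.arange(1.0, n_cells + 1)}
    if coords is None:
        coords = np.column_stack(
            [np.arange(n_cells, dtype=float), np.zeros(n_cells)]
        )
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "cell_type": cell_type,
            "treatment": "vehicle",
            "time_point": time_point,
            "replicate": "r1",
            "fov_id": fov_id,
            "centroid_x": coords[:, 0],
            "centroid_y": coords[:, 1],
            "cell_area": 100.0,
            **{k: np.asarray(v, dtype=float) for k, v in feature_values.items()},
        }
    )
    return FeatureTable(df, list(feature_values))


@pytest.fixture
def tiny_table() -> FeatureTable:
    return make_table(5, {"f1": [1, 2, 3, 4, 5], "f2": [2, 2, 2, 2, 2]})


@pytest.fixture(scope="session")
def small_experiment():
    """Two-condition synthetic experiment at unit-test scale."""
    gen = dict(
        n_fovs=3, cells_per_fov=120, n_features=40, n_shifted_features=8,
        effect_size=2.5, n_clusters_per_fov=2, cluster_sigma=40.0, fov_size=500.0,
    )
    conds = [
        Condition("normal", "vehicle", 0.0),
        Condition("normal", "IGF-1", 240.0),
    ]
    params = [
        GeneratorParams(**gen, responder_fraction=0.0),
        GeneratorParams(**gen, responder_fraction=0.2),
    ]
    table, truth = generate_experiment(conds, params, seed=1234)
    return table, truth
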