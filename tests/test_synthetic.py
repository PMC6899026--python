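import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from spatcorr import (
    Condition,
    GenerationError,
    GeneratorParams,
    condition_seed,
    generate_experiment,
    generate_fov,
)


SMALL = GeneratorParams(
    n_fovs=2, cells_per_fov=100, n_features=10, n_shifted_features=3,
    fov_size=300.0, cluster_sigma=20.0, seed=5,
)


class TestGenerateFov:
    def test_zero_responder_fraction_gives_no_responders(self):
        p = dataclasses.replace(SMALL, responder_fraction=0.0)
        rows, truth = generate_fov(p)
        assert not truth["responder"].any()
        assert (truth["cluster_id"] == "").all()

    def test_same_params_and_seed_identical(self):
        a_rows, a_truth = generate_fov(SMALL, 1)
        b_rows, b_truth = generate_fov(SMALL, 1)
        pd.testing.assert_frame_equal(a_rows, b_rows)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_different_fov_index_differs(self):
        a, _ = generate_fov(SMALL, 0)
        b, _ = generate_fov(SMALL, 1)
        assert not np.array_equal(
            a[["centroid_x", "centroid_y"]], b[["centroid_x", "centroid_y"]]
        )

    def test_centroids_inside_fov(self):
        p = dataclasses.replace(SMALL, responder_fraction=0.5, cluster_sigma=200.0)
        rows, _ = generate_fov(p)
        xy = rows[["centroid_x", "centroid_y"]].to_numpy()
        assert (xy >= 0).all() and (xy <= p.fov_size).all()

    def test_min_cell_spacing_respected(self):
        p = dataclasses.replace(SMALL, cells_per_fov=50, min_cell_spacing=10.0)
        rows, _ = generate_fov(p)
        xy = rows[["centroid_x", "centroid_y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_infeasible_spacing_raises(self):
        p = dataclasses.replace(SMALL, cells_per_fov=100, fov_size=10.0,
                                min_cell_spacing=5.0)
        with pytest.raises(GenerationError, match="infeasible"):
            generate_fov(p)

    def test_responder_feature_shift(self):
        p = dataclasses.replace(
            SMALL, cells_per_fov=2000, responder_fraction=0.5, effect_size=3.0
        )
        rows, truth = generate_fov(p)
        feats = rows[[c for c in rows.columns if c.startswith("Feature_")]]
        resp = truth["responder"].to_numpy()
        shifted = feats.iloc[:, : p.n_shifted_features]
        unshifted = feats.iloc[:, p.n_shifted_features:]
        gap = shifted[resp].mean().mean() - shifted[~resp].mean().mean()
        assert gap == pytest.approx(3.0, abs=0.2)
        assert abs(unshifted[resp].mean().mean() - unshifted[~resp].mean().mean()) < 0.2


class TestGenerateExperiment:
    def test_single_condition_equals_generate_fov(self):
        cond = Condition("normal", "vehicle", 0.0)
        p = dataclasses.replace(SMALL, n_fovs=1)
        table, truth = generate_experiment([cond], p, seed=99)
        p_derived = dataclasses.replace(p, seed=condition_seed(99, 0))
        rows, truth_fov = generate_fov(p_derived, 0, cond)
        pd.testing.assert_frame_equal(table.data, rows)
        pd.testing.assert_frame_equal(truth, truth_fov)

    def test_two_conditions_disjoint_ids(self):
        conds = [Condition(treatment="vehicle"), Condition(treatment="IGF-1")]
        table, _ = generate_experiment(conds, SMALL, seed=3)
        ids = table.data["cell_id"]
        assert ids.is_unique
        assert table.data["fov_id"].nunique() == 2 * SMALL.n_fovs

    def test_duplicate_conditions_rejected(self):
        with pytest.raises(GenerationError, match="duplicate"):
            generate_experiment([Condition(), Condition()], SMALL, seed=3)

    def test_responder_count_matches_binomial(self):
        # responder_fraction=0.2, 500 cells/FOV, 100 FOVs: expect 10000 +- 3 SD
        p = GeneratorParams(
            n_fovs=100, cells_per_fov=500, n_features=3, n_shifted_features=0,
            responder_fraction=0.2, seed=17,
        )
        _, truth = generate_experiment([Condition()], p, seed=17)
        n, total = int(truth["responder"].sum()), len(truth)
        assert total == 50000
        sd = np.sqrt(total * 0.2 * 0.8)
        assert abs(n - 10000) <= 3 * sd

    def test_treatment_shift_follows_total_expectation(self):
        # vehicle rf=0 vs treated rf=0.2: mean gap on shifted features is
        # responder_fraction * effect_size * baseline_noise_sd
        gen = dict(
            n_fovs=2, cells_per_fov=2000, n_features=10, n_shifted_features=4,
            effect_size=2.0, baseline_noise_sd=1.5, seed=0,
        )
        conds = [Condition(treatment="vehicle"), Condition(treatment="IGF-1")]
        params = [
            GeneratorParams(**gen, responder_fraction=0.0),
            GeneratorParams(**gen, responder_fraction=0.2),
        ]
        table, _ = generate_experiment(conds, params, seed=8)
        df = table.data
        gap = (
            df.loc[df.treatment == "IGF-1", "Feature_0000"].mean()
            - df.loc[df.treatment == "vehicle", "Feature_0000"].mean()
        )
        assert gap == pytest.approx(0.2 * 2.0 * 1.5, abs=0.15)

    def test_null_data_features_independent_of_position(self):
        # responder_fraction=0: no association between any feature and location
        p = dataclasses.replace(SMALL, responder_fraction=0.0, cells_per_fov=400)
        rows, _ = generate_fov(p)
        r, pval = scipy.stats.pearsonr(rows["centroid_x"], rows["Feature_0000"])
        assert pval > 0.01
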