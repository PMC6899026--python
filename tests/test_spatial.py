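import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatcorr import (
    ZeroVarianceError,
    build_null,
    classify,
    confusion_against_truth,
    empirical_quantile,
    find_neighbors,
    neighbors_by_fov,
    pearson,
    percent_correlated,
    score_cells,
)
from spatcorr.spatial import ConditionMismatchError, NullDistribution

from conftest import make_table


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 2, 2], np.sqrt(3) / 2),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_symmetry_and_bounds_against_numpy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r = pearson(x, y)
            assert r == pytest.approx(pearson(y, x), abs=1e-15)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @given(
        st.integers(0, 2**30),
        st.floats(0.1, 100.0),
        st.floats(-50.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_positive_affine_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 10))
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)


class TestEmpiricalQuantile:
    def test_linear_matches_order_statistic_interpolation(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_quantile(v, 0.5) == 2.5
        assert empirical_quantile(v, 0.95) == pytest.approx(3.85)

    def test_nearest_rank_is_order_statistic(self):
        v = np.arange(1.0, 101.0)
        assert empirical_quantile(v, 0.95, "nearest-rank") == 95.0


def _score_table(vectors, coords=None, **kw):
    vectors = np.asarray(vectors, dtype=float)
    feats = {f"s{j}": vectors[:, j] for j in range(vectors.shape[1])}
    return make_table(len(vectors), feats, coords=coords, **kw)


class TestBuildNull:
    def test_two_point_distribution(self):
        # half the cells at +v, half at -v: every pair correlates at +-1
        v = np.array([1.0, 2.0, 4.0])
        t = _score_table([v, v, -v, -v])
        null = build_null(t, n_draws=500, seed=0)
        assert set(np.round(null.draws, 12)) <= {-1.0, 1.0}
        assert null.q95 == 1.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(1)
        t = _score_table(rng.normal(size=(40, 6)))
        a = build_null(t, seed=42)
        b = build_null(t, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.q95 == b.q95
        c = build_null(t, seed=43)
        assert not np.array_equal(a.draws, c.draws)

    def test_pair_members_always_distinct(self):
        # 2 cells: only one possible pair; all draws equal its correlation
        rng = np.random.default_rng(2)
        t = _score_table(rng.normal(size=(2, 5)))
        null = build_null(t, n_draws=200, seed=0)
        expected = pearson(t.features[0], t.features[1])
        np.testing.assert_allclose(null.draws, expected, atol=1e-12)

    def test_q95_of_iid_high_dim_scores(self):
        # iid N(0,1) score vectors in d dims: r ~ approx N(0, 1/(d-1)),
        # so the 95th percentile is near 1.645/sqrt(d-1)
        rng = np.random.default_rng(3)
        d = 119
        t = _score_table(rng.normal(size=(800, d)))
        null = build_null(t, n_draws=4000, seed=7)
        assert null.q95 == pytest.approx(1.645 / np.sqrt(d - 1), abs=0.02)
        assert abs(null.median_r) < 0.02

    def test_mixed_conditions_rejected(self):
        a = _score_table(np.random.default_rng(0).normal(size=(5, 3)))
        b = a.data.copy()
        b.loc[:, "fov_id"] = "fov1"
        b.loc[:, "treatment"] = "IGF-1"
        b.loc[:, "cell_id"] = [f"x{i}" for i in range(5)]
        df = pd.concat([a.data, b], ignore_index=True)
        from spatcorr import FeatureTable

        with pytest.raises(ConditionMismatchError):
            build_null(FeatureTable(df, a.feature_names))


class TestFindNeighbors:
    def test_three_cell_line(self):
        t = make_table(3, {"f": [1.0, 2.0, 3.0]},
                       coords=np.array([[0.0, 0], [1.0, 0], [3.0, 0]]))
        nb = find_neighbors(t, k=1)
        assert nb == {"c0": ["c1"], "c1": ["c0"], "c2": ["c1"]}

    def test_k_at_least_n_gives_all_others(self):
        rng = np.random.default_rng(4)
        t = make_table(6, {"f": rng.normal(size=6)},
                       coords=rng.uniform(0, 10, (6, 2)))
        nb = find_neighbors(t, k=50)
        for cid, lst in nb.items():
            assert cid not in lst
            assert sorted(lst) == sorted(set(nb) - {cid})

    def test_distance_ties_broken_by_cell_id(self):
        # c1 and c2 equidistant from c0: c1 sorts first
        t = make_table(3, {"f": [0.0, 1.0, 2.0]},
                       coords=np.array([[0.0, 0], [1.0, 0], [-1.0, 0]]))
        nb = find_neighbors(t, k=2)
        assert nb["c0"] == ["c1", "c2"]

    def test_matches_brute_force_on_random_fov(self):
        rng = np.random.default_rng(5)
        n, k = 200, 20
        coords = rng.uniform(0, 500, (n, 2))
        t = make_table(n, {"f": rng.normal(size=n)}, coords=coords)
        nb = find_neighbors(t, k=k)
        ids = t.data["cell_id"].tolist()
        for i, cid in enumerate(ids):
            dists = sorted(
                (np.hypot(*(coords[j] - coords[i])), ids[j])
                for j in range(n) if j != i
            )
            assert nb[cid] == [c for _, c in dists[:k]]

    def test_multiple_fovs_rejected(self):
        t1 = make_table(3, {"f": [1.0, 2.0, 3.0]}, fov_id="fovA")
        t2 = make_table(3, {"f": [1.0, 2.0, 3.0]}, fov_id="fovB")
        t2d = t2.data.assign(cell_id=["d0", "d1", "d2"])
        from spatcorr import FeatureTable

        both = FeatureTable(pd.concat([t1.data, t2d], ignore_index=True), ["f"])
        with pytest.raises(ValueError, match="single FOV"):
            find_neighbors(both)
        nb = neighbors_by_fov(both, k=1)
        assert len(nb) == 6


class TestScoreCells:
    def test_identical_neighbors_give_one(self):
        v = [1.0, 3.0, 2.0]
        t = _score_table([v, v, v, v])
        nb = {c: [o for o in ("c0", "c1", "c2", "c3") if o != c]
              for c in ("c0", "c1", "c2", "c3")}
        scored = score_cells(t, nb, min_neighbors=1)
        np.testing.assert_allclose(scored["median_neighbor_r"], 1.0, atol=1e-12)

    def test_even_count_median_is_midpoint(self):
        # neighbors at r=+1 and r=-1: median 0
        t = _score_table([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        scored = score_cells(t, {"c0": ["c1", "c2"]}, min_neighbors=1)
        assert scored.loc[0, "median_neighbor_r"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_fov(self):
        rng = np.random.default_rng(6)
        n, k, d = 200, 20, 12
        vectors = rng.normal(size=(n, d))
        coords = rng.uniform(0, 400, (n, 2))
        t = _score_table(vectors, coords=coords)
        nb = find_neighbors(t, k=k)
        scored = score_cells(t, nb, min_neighbors=1)
        ids = t.data["cell_id"].tolist()
        for i, cid in enumerate(ids):
            rs = [pearson(vectors[i], vectors[ids.index(o)]) for o in nb[cid]]
            assert scored.loc[i, "median_neighbor_r"] == pytest.approx(
                np.median(rs), abs=1e-10
            )

    def test_below_min_neighbors_left_unscored(self):
        rng = np.random.default_rng(7)
        t = _score_table(rng.normal(size=(4, 5)))
        nb = {"c0": ["c1", "c2"], "c1": ["c0"]}
        scored = score_cells(t, nb, min_neighbors=3)
        assert not scored["scored"].any()

    def test_zero_variance_neighbor_skipped(self):
        t = _score_table([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 5.0]])
        scored = score_cells(t, {"c0": ["c1", "c2"]}, min_neighbors=1)
        # c2 is constant -> only c1 contributes (r = 1)
        assert scored.loc[0, "median_neighbor_r"] == pytest.approx(1.0)
        assert scored.loc[0, "n_neighbors_used"] == 1


def _null_with_q95(t, q95):
    cond = t.condition_tuples()[0]
    return NullDistribution(
        condition=cond, draws=np.array([q95]), n_draws=1, q95=q95,
        median_r=q95, seed=0,
    )


class TestClassify:
    def test_strictly_greater_than_threshold(self):
        v = [1.0, 2.0, 3.0]
        t = _score_table([v, v, v])
        scored = score_cells(t, {"c0": ["c1"], "c1": ["c0"], "c2": ["c0"]},
                             min_neighbors=1)
        # all medians are exactly 1.0
        flags = classify(scored, _null_with_q95(t, 1.0))
        assert not flags["correlated_flag"].any()  # equality -> uncorrelated
        flags = classify(scored, _null_with_q95(t, 0.999))
        assert flags["correlated_flag"].all()

    def test_condition_mismatch_raises(self):
        t = _score_table(np.random.default_rng(8).normal(size=(3, 4)))
        scored = score_cells(t, {"c0": ["c1"]}, min_neighbors=1)
        null = _null_with_q95(t, 0.5)
        null.condition = ("PPHN", "IGF-1", 240.0)
        with pytest.raises(ConditionMismatchError):
            classify(scored, null)


class TestSummaries:
    def test_percent_correlated_simple_fractions(self):
        df = pd.DataFrame(
            {
                "cell_type": "normal", "treatment": "vehicle", "time_point": 0.0,
                "scored": [True] * 50, "correlated_flag": [True] * 5 + [False] * 45,
            }
        )
        out = percent_correlated(df)
        assert out.loc[0, "percent_correlated"] == 10.0
        df["correlated_flag"] = False
        assert percent_correlated(df).loc[0, "percent_correlated"] == 0.0

    def test_unscored_cells_excluded(self):
        df = pd.DataFrame(
            {
                "cell_type": "normal", "treatment": "vehicle", "time_point": 0.0,
                "scored": [True, True, False], "correlated_flag": [True, False, False],
            }
        )
        out = percent_correlated(df)
        assert out.loc[0, "n_scored"] == 2
        assert out.loc[0, "percent_correlated"] == 50.0

    def test_confusion_counts(self):
        flagged = pd.DataFrame(
            {
                "cell_id": list("abcd"), "scored": True,
                "correlated_flag": [True, True, False, False],
            }
        )
        truth = pd.DataFrame(
            {"cell_id": list("abcd"), "responder": [True, False, True, False]}
        )
        conf = confusion_against_truth(flagged, truth)
        assert (conf["tp"], conf["fp"], conf["fn"], conf["tn"]) == (1, 1, 1, 1)
        assert conf["sensitivity"] == 0.5
        assert conf["specificity"] == 0.5
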