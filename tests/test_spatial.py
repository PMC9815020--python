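import numpy as np
import pandas as pd
import pytest

from carescape import (build_knn_weights, classify_lisa, count_categories,
                       global_moran, impute_missing_zero, local_moran,
                       permutation_pseudo_p)
from conftest import weights_from_dense
from oracles import (exhaustive_permutation_morans, local_moran_bruteforce,
                     moran_bruteforce, random_weights)


class TestKnnWeights:
    def test_zero_diagonal_and_unit_rows(self, city_map):
        W = build_knn_weights(city_map, k=5)
        assert not W.matrix.diagonal().any()
        assert np.allclose(np.asarray(W.matrix.sum(axis=1)).ravel(), 1.0)

    def test_binary_when_not_standardized(self, city_map):
        W = build_knn_weights(city_map, k=3, row_standardize=False)
        assert set(W.matrix.data) == {1.0}
        assert W.S0 == 3 * len(city_map)

    def test_line_nearest_neighbours_by_hand(self):
        geoms = pd.DataFrame({"city_id": ["P0", "P1", "P3", "P7"],
                              "longitude": [0.0, 1.0, 3.0, 7.0],
                              "latitude": [0.0, 0.0, 0.0, 0.0]})
        W = build_knn_weights(geoms, k=1, row_standardize=False)
        pairs = {(W.ids[i], W.ids[j]) for i in range(4) for j in W.neighbors(i)}
        assert pairs == {("P0", "P1"), ("P1", "P0"), ("P3", "P1"), ("P7", "P3")}

    def test_k_out_of_range_rejected(self, city_map):
        with pytest.raises(ValueError, match="1 <= k < n"):
            build_knn_weights(city_map, k=len(city_map))


class TestGlobalMoran:
    def test_expected_value_closed_form(self, city_map):
        W = build_knn_weights(city_map)
        x = np.arange(len(city_map), dtype=float)
        res = global_moran(x, W)
        assert res.expected == pytest.approx(-1.0 / (len(city_map) - 1))

    def test_checkerboard_is_minus_one(self):
        # 2x2 rook adjacency, alternating values: perfect dispersion
        W = weights_from_dense([[0, 1, 1, 0], [1, 0, 0, 1],
                                [1, 0, 0, 1], [0, 1, 1, 0]])
        res = global_moran(np.array([1.0, -1.0, -1.0, 1.0]), W)
        assert res.I == pytest.approx(-1.0)

    def test_constant_field_rejected(self, city_map):
        W = build_knn_weights(city_map)
        with pytest.raises(ValueError, match="constant"):
            global_moran(np.ones(len(city_map)), W)

    def test_matches_bruteforce_small(self):
        rng = np.random.default_rng(0)
        dense = random_weights(rng, 12, row_standardize=True)
        x = rng.normal(size=12)
        W = weights_from_dense(dense, row_standardized=True)
        assert global_moran(x, W).I == pytest.approx(
            moran_bruteforce(x.tolist(), dense.tolist()), abs=1e-12)

    def test_permutation_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        dense = random_weights(rng, 15, row_standardize=True)
        x = rng.normal(size=15)
        W = weights_from_dense(dense, row_standardized=True)
        base = global_moran(x, W).I
        # consistent relabelling of units
        perm = rng.permutation(15)
        Wp = weights_from_dense(dense[np.ix_(perm, perm)], row_standardized=True)
        assert global_moran(x[perm], Wp).I == pytest.approx(base, abs=1e-12)
        # affine transform of the values
        assert global_moran(3.5 * x - 2.0, W).I == pytest.approx(base, abs=1e-12)

    def test_randomization_moments_match_exhaustive(self):
        """E and Var of I over all 5! permutations vs the closed forms."""
        rng = np.random.default_rng(7)
        dense = random_weights(rng, 5, row_standardize=True)
        x = rng.normal(size=5)
        sims = exhaustive_permutation_morans(x.tolist(), dense.tolist())
        W = weights_from_dense(dense, row_standardized=True)
        res = global_moran(x, W)
        assert np.mean(sims) == pytest.approx(-1.0 / 4, abs=1e-9)
        assert np.var(sims) == pytest.approx(res.variance, rel=1e-9)


class TestPermutationTest:
    def test_deterministic_given_seed(self, city_map):
        W = build_knn_weights(city_map)
        x = np.random.default_rng(1).normal(size=len(city_map))
        p1 = permutation_pseudo_p(x, W, n_perm=199, seed=42)
        p2 = permutation_pseudo_p(x, W, n_perm=199, seed=42)
        assert p1 == p2

    def test_clustered_field_attains_minimum(self, city_map):
        W = build_knn_weights(city_map)
        # strongly clustered: value = longitude
        x = city_map["longitude"].to_numpy()
        p = permutation_pseudo_p(x, W, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_too_few_permutations_rejected(self, city_map):
        W = build_knn_weights(city_map)
        with pytest.raises(ValueError, match="99"):
            permutation_pseudo_p(np.arange(len(city_map)), W, n_perm=10, seed=0)


class TestLocalMoran:
    def test_decomposition_identity_and_bruteforce(self):
        rng = np.random.default_rng(11)
        dense = random_weights(rng, 20, row_standardize=True)
        x = rng.normal(size=20)
        W = weights_from_dense(dense, row_standardized=True)
        lisa = local_moran(x, W, n_perm=99, seed=0)
        expect = local_moran_bruteforce(x.tolist(), dense.tolist())
        assert np.allclose(lisa.data["I"], expect, atol=1e-12)
        g = global_moran(x, W)
        assert lisa.I_sum == pytest.approx(W.S0 * g.I, abs=1e-9)

    def test_isolated_high_value_is_high_low(self):
        # unit 0 high, all its neighbours low
        dense = [[0, 1, 1, 0, 0], [1, 0, 0, 1, 0], [1, 0, 0, 0, 1],
                 [0, 1, 0, 0, 1], [0, 0, 1, 1, 0]]
        W = weights_from_dense(dense)
        x = np.array([10.0, 1.0, 1.0, 5.0, 5.0])
        lisa = local_moran(x, W, n_perm=99, seed=0)
        row = lisa.data.iloc[0]
        assert row["I"] < 0 and row["z"] > 0 and row["lag"] < 0

    def test_constant_field_rejected(self, city_map):
        from carescape import build_knn_weights
        W = build_knn_weights(city_map)
        with pytest.raises(ValueError, match="constant"):
            local_moran(np.zeros(len(city_map)), W)


class TestLisaClassification:
    @staticmethod
    def _lisa_frame(rows):
        from carescape.spatial import LisaResult
        df = pd.DataFrame(rows, columns=["city_id", "value", "z", "lag", "I",
                                         "p", "category", "imputed_zero"])
        return LisaResult(data=df)

    def test_quadrant_rules(self):
        rows = [("a", 1, 1.0, 1.0, 1.0, 0.001, "insignificant", False),
                ("b", 1, 1.0, -1.0, -1.0, 0.001, "insignificant", False),
                ("c", 1, -1.0, 1.0, -1.0, 0.001, "insignificant", False),
                ("d", 1, -1.0, -1.0, 1.0, 0.001, "insignificant", False),
                ("e", 1, 1.0, 1.0, 1.0, 0.20, "insignificant", False)]
        out = classify_lisa(self._lisa_frame(rows), alpha=0.05)
        assert out.data["category"].tolist() == \
            ["high_high", "high_low", "low_high", "low_low", "insignificant"]

    def test_category_invariants_on_random_field(self, city_map):
        from carescape import build_knn_weights
        W = build_knn_weights(city_map)
        x = np.random.default_rng(3).normal(size=len(city_map))
        lisa = classify_lisa(local_moran(x, W, n_perm=199, seed=5), alpha=0.10)
        df = lisa.data
        sig = df["category"] != "insignificant"
        assert (df.loc[sig, "p"] < 0.10).all()
        assert ((df.loc[df["category"] == "high_high", "z"] > 0)
                & (df.loc[df["category"] == "high_high", "lag"] > 0)).all()
        assert ((df.loc[df["category"] == "low_low", "z"] < 0)
                & (df.loc[df["category"] == "low_low", "lag"] < 0)).all()

    def test_zero_imputed_block_is_low_low_or_insignificant(self, city_map):
        from carescape import build_knn_weights
        W = build_knn_weights(city_map)
        scores = pd.Series(np.random.default_rng(2).uniform(0.3, 0.9,
                                                            size=len(city_map)),
                           index=W.ids)
        # a contiguous missing block: a city and its neighbours
        block = [W.ids[i] for i in [10, *W.neighbors(10)]]
        scores.loc[block] = np.nan
        filled, flags = impute_missing_zero(scores)
        lisa = classify_lisa(local_moran(filled.loc[W.ids], W, n_perm=199, seed=9,
                                         imputed_zero=flags.loc[W.ids].to_numpy()))
        sub = lisa.data[lisa.data["city_id"].isin(block)]
        assert sub["imputed_zero"].all()
        assert sub["category"].isin(["low_low", "insignificant"]).all()


class TestZeroAssignment:
    def test_identity_when_complete(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        filled, flags = impute_missing_zero(s)
        assert filled.equals(s) and not flags.any()

    def test_missing_become_zero_and_flagged(self):
        s = pd.Series([1.0, np.nan], index=["a", "b"])
        filled, flags = impute_missing_zero(s)
        assert filled["b"] == 0.0 and flags["b"] and not flags["a"]

    def test_all_missing_then_moran_errors(self, city_map):
        W = build_knn_weights(city_map)
        s = pd.Series(np.nan, index=W.ids)
        filled, flags = impute_missing_zero(s)
        assert flags.all()
        with pytest.raises(ValueError, match="constant"):
            global_moran(filled, W)


class TestCategoryCounts:
    def test_hand_built_tally(self):
        from carescape.spatial import LisaResult
        df = pd.DataFrame({
            "city_id": list("abcdef"),
            "value": 1.0, "z": 1.0, "lag": 1.0, "I": 1.0, "p": 0.01,
            "category": ["high_high", "high_high", "low_low", "insignificant",
                         "high_low", "low_high"],
            "imputed_zero": False})
        regions = pd.Series(["Eastern", "Eastern", "Western", "Central",
                             "Northeast", "Eastern"], index=list("abcdef"))
        tab = count_categories(LisaResult(data=df), regions)
        assert tab.loc["Eastern", "high_high"] == 2
        assert tab.loc["Western", "low_low"] == 1
        assert tab.loc["Central", "high_low"] == 0
        assert tab.to_numpy().sum() == 6
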