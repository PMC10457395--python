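import numpy as np
import pandas as pd
import pytest

from mixproject import simulate, spatial
from mixproject.datatypes import CellAtlas, ExpressionMatrix


def cells(rows):
    return pd.DataFrame(rows).set_index("cell_id", drop=False)


class TestAssignNeighborhoods:
    def test_default_radius_is_hundred_microns(self):
        import inspect

        sig = inspect.signature(spatial.assign_neighborhoods)
        assert sig.parameters["radius"].default == 100.0

    def test_isolated_cell_has_zero_counts(self):
        table = cells(
            [
                {"cell_id": "a", "x": 0.0, "y": 0.0, "cell_type": "A"},
                {"cell_id": "b", "x": 1000.0, "y": 0.0, "cell_type": "B"},
            ]
        )
        out = spatial.assign_neighborhoods(table, radius=100)
        assert out.loc["a", ["n_A", "n_B"]].sum() == 0

    def test_threshold_geometry_on_collinear_cells(self):
        table = cells(
            [
                {"cell_id": "q", "x": 0.0, "y": 0.0, "cell_type": "A"},
                {"cell_id": "near", "x": 50.0, "y": 0.0, "cell_type": "B"},
                {"cell_id": "far", "x": 150.0, "y": 0.0, "cell_type": "B"},
            ]
        )
        out = spatial.assign_neighborhoods(table, radius=100)
        assert out.loc["q", "n_B"] == 1  # only the 50-um cell
        assert out.loc["near", "n_B"] == 1  # 100-um boundary is inclusive

    def test_query_cell_excluded_from_own_counts(self):
        table = cells(
            [
                {"cell_id": "a", "x": 0.0, "y": 0.0, "cell_type": "A"},
                {"cell_id": "b", "x": 10.0, "y": 0.0, "cell_type": "A"},
            ]
        )
        out = spatial.assign_neighborhoods(table, radius=100)
        assert (out["n_A"] == 1).all()

    def test_invariant_to_rigid_motion(self):
        table, _ = simulate.make_spatial_tissue(
            ["A", "B", "C"], ["L1"], 150, seed=1, extent=(1000.0, 1000.0)
        )
        out1 = spatial.assign_neighborhoods(table, radius=100)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = table.copy()
        xy = moved[["x", "y"]].to_numpy() @ rot.T + np.array([500.0, -200.0])
        moved[["x", "y"]] = xy
        out2 = spatial.assign_neighborhoods(moved, radius=100)
        count_cols = [c for c in out1.columns if c.startswith("n_")]
        pd.testing.assert_frame_equal(out1[count_cols], out2[count_cols])


class TestMotifPermutationTest:
    def test_pvalues_in_unit_interval_with_resolution_floor(self):
        table, _ = simulate.make_spatial_tissue(
            ["A", "B"], ["L1", "L2"], 150, seed=2
        )
        res = spatial.motif_permutation_test(table, n_perm=200, seed=3)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert (res["p_value"] >= 1 / 201).all()

    def test_stratified_mode_requires_layers(self):
        table, _ = simulate.make_spatial_tissue(["A", "B"], ["L1"], 50, seed=4)
        with pytest.raises(ValueError, match="layer"):
            spatial.motif_permutation_test(
                table.drop(columns="layer"), n_perm=10, stratify_by_layer=True
            )

    def test_permutations_never_cross_layers(self):
        # each layer holds exactly one cell type, so any within-layer
        # permutation is the identity and every neighborhood keeps its
        # observed count: all p-values must equal 1
        rng = np.random.default_rng(5)
        rows = []
        for i in range(60):
            rows.append(
                {
                    "cell_id": f"a{i}", "x": rng.uniform(0, 500),
                    "y": rng.uniform(0, 500), "layer": "L1", "cell_type": "A",
                }
            )
            rows.append(
                {
                    "cell_id": f"b{i}", "x": rng.uniform(0, 500),
                    "y": rng.uniform(600, 1100), "layer": "L2", "cell_type": "B",
                }
            )
        res = spatial.motif_permutation_test(cells(rows), n_perm=100, seed=6)
        assert (res["p_value"] == 1.0).all()

    def test_null_pvalues_superuniform(self):
        table, _ = simulate.make_spatial_tissue(
            ["A", "B", "C"], ["L1", "L2"], 300, seed=7
        )
        res = spatial.motif_permutation_test(table, n_perm=500, seed=8)
        for t in (0.01, 0.05, 0.1, 0.25):
            frac = (res["p_value"] < t).mean()
            se = np.sqrt(t * (1 - t) / len(res))
            assert frac <= t + 3 * se

    def test_planted_motif_detected_at_scaled_permutations(self):
        table, _ = simulate.make_spatial_tissue(
            ["A", "B", "C"], ["L1", "L2"], 80,
            motif_spec=[{"types": ["A", "B", "C"], "n_instances": 25, "layer": "L1"}],
            radius=100.0, extent=(15000.0, 2000.0), seed=9,
        )
        res = spatial.motif_permutation_test(
            table, n_perm=2000, min_cells=20, alpha_threshold=1e-3, seed=10
        )
        planted = res[
            (res["query_type"] == "A") & (res["neighbor_bins"] == (0, 1, 1))
        ]
        assert len(planted) == 1
        assert planted["significant"].iloc[0]
        assert planted["p_value"].iloc[0] == pytest.approx(1 / 2001)


class TestKnnLabelTransfer:
    @pytest.fixture
    def atlas(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(3, 30))
        b = rng.normal(4, 0.3, size=(3, 30))
        values = np.concatenate([a, b], axis=1)
        expr = ExpressionMatrix(
            values, ["g0", "g1", "g2"],
            [f"c{i}" for i in range(60)], "scaled",
        )
        return CellAtlas(expr=expr, cell_types=["A"] * 30 + ["B"] * 30)

    def test_exact_atlas_cell_takes_its_label(self, atlas):
        query = atlas.expr.values[:, 5]
        out = spatial.knn_label_transfer(query, atlas, k=1)
        assert out.iloc[0] == "A"

    def test_k_equal_atlas_size_gives_global_majority(self, atlas):
        unbalanced = CellAtlas(
            expr=atlas.expr, cell_types=["A"] * 40 + ["B"] * 20
        )
        out = spatial.knn_label_transfer(np.zeros(3), unbalanced, k=60)
        assert out.iloc[0] == "A"

    def test_two_cluster_queries_accurate(self, atlas):
        rng = np.random.default_rng(1)
        qa = rng.normal(0, 0.3, size=(20, 3))
        qb = rng.normal(4, 0.3, size=(20, 3))
        out = spatial.knn_label_transfer(np.vstack([qa, qb]), atlas, k=5)
        truth = np.array(["A"] * 20 + ["B"] * 20)
        assert (out.to_numpy() == truth).mean() >= 0.95

    def test_tie_resolves_to_closest_neighbor_label(self):
        expr = ExpressionMatrix(
            np.array([[0.0, 3.0]]), ["g0"], ["a", "b"], "scaled"
        )
        atlas = CellAtlas(expr=expr, cell_types=["A", "B"])
        out = spatial.knn_label_transfer(np.array([[1.0]]), atlas, k=2)
        assert out.iloc[0] == "A"

    def test_k_larger_than_atlas_rejected(self, atlas):
        with pytest.raises(ValueError):
            spatial.knn_label_transfer(np.zeros(3), atlas, k=61)


class TestZonationScore:
    def test_one_hot_profile_scores_zero(self):
        table = pd.DataFrame(
            {"g_sharp": [1.0, 0.0, 0.0, 0.0, 0.0], "g_flat": [0.2] * 5},
            index=[f"zone{z}" for z in range(1, 6)],
        )
        out = spatial.zonation_score(table)
        assert out.loc["g_sharp", "score"] == pytest.approx(0.0)
        assert out.loc["g_sharp", "peak_zone"] == "zone1"

    def test_flat_profile_distance_closed_form(self):
        table = pd.DataFrame(
            {"g_flat": [0.2] * 5, "g_sharp": [1.0, 0, 0, 0, 0]},
            index=[f"zone{z}" for z in range(1, 6)],
        )
        out = spatial.zonation_score(table)
        assert out.loc["g_flat", "score"] == pytest.approx(np.sqrt(0.8))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        profiles = rng.gamma(2, 1, size=(5, 8))
        t1 = pd.DataFrame(profiles, columns=[f"g{i}" for i in range(8)])
        t2 = pd.DataFrame(profiles * 37.5, columns=[f"g{i}" for i in range(8)])
        np.testing.assert_allclose(
            spatial.zonation_score(t1)["score"], spatial.zonation_score(t2)["score"]
        )

    def test_default_quantile_flags_top_quarter(self):
        import inspect

        assert inspect.signature(spatial.zonation_score).parameters["quantile"].default == 0.75
        table, truth = simulate.make_zonation_profiles(
            40, zonated_fraction=0.25, noise_sd=0.02, seed=1
        )
        out = spatial.zonation_score(table)
        flagged = set(out[out["zonated"]].index)
        expected = set(truth.zonation[truth.zonation["zonated"]].index)
        assert flagged == expected

    def test_zero_total_gene_flagged_unscorable(self):
        table = pd.DataFrame(
            {"dead": [0.0] * 5, "live": [1.0, 0, 0, 0, 0]},
            index=[f"zone{z}" for z in range(1, 6)],
        )
        out = spatial.zonation_score(table)
        assert bool(out.loc["dead", "unscorable"])
        assert np.isnan(out.loc["dead", "score"])
        assert not out.loc["dead", "zonated"]
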