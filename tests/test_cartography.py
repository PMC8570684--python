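import numpy as np
import pytest

from conftest import build_graph, build_partition
from fosnet import (
    classify_hubs,
    compute_node_metrics,
    participation_coefficient,
    summarize_network,
    threshold_graph,
    within_module_degree_z,
)
from fosnet.cartography import export_graph, load_exported_graph, write_metrics
from fosnet.connectivity import CorrelationMatrix
from fosnet.simulate import synthetic_atlas

from _oracles import node_metrics_oracle, random_weighted_graph


def correlation(values):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix(values=values, atlas=synthetic_atlas(values.shape[0]))


class TestThresholdGraph:
    def test_single_strong_edge_kept_with_weight(self):
        g = threshold_graph(correlation([[1.0, 0.8], [0.8, 1.0]]), rmin=0.75)
        assert g.n_edges == 1
        assert g.graph["R001"]["R002"]["weight"] == pytest.approx(0.8)

    def test_weak_edges_all_removed(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        g = threshold_graph(correlation(v), rmin=0.75)
        assert g.n_edges == 0
        assert g.graph.number_of_nodes() == 4  # isolated nodes preserved

    def test_boundary_is_inclusive(self):
        g = threshold_graph(correlation([[1.0, 0.75], [0.75, 1.0]]), rmin=0.75)
        assert g.n_edges == 1


class TestWithinModuleDegreeZ:
    def test_uniform_degree_module_is_all_zero(self, small_atlas):
        # fully connected triangle with equal weights, plus a singleton
        g = build_graph(small_atlas, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)])
        p = build_partition(small_atlas, [1, 1, 1, 2])
        np.testing.assert_allclose(within_module_degree_z(g, p), 0.0)

    def test_hand_computed_star_module(self, small_atlas):
        # A-B and A-C only: k_within = (2, 1, 1), population sd = sqrt(2)/3
        g = build_graph(small_atlas, [(0, 1, 1.0), (0, 2, 1.0)])
        p = build_partition(small_atlas, [1, 1, 1, 2])
        z = within_module_degree_z(g, p)
        assert z[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert z[1] == pytest.approx(-1 / np.sqrt(2), abs=1e-12)
        assert z[2] == pytest.approx(-1 / np.sqrt(2), abs=1e-12)
        assert z[3] == 0.0  # singleton module convention

    def test_missing_partition_coverage_rejected(self, small_atlas):
        g = build_graph(small_atlas, [(0, 1, 1.0)])
        other = synthetic_atlas(4, prefix="Q")
        p = build_partition(other, [1, 1, 2, 2])
        with pytest.raises(ValueError, match="atlas"):
            within_module_degree_z(g, p)


class TestParticipationCoefficient:
    def test_intra_module_only_node_has_zero_pc(self, small_atlas):
        g = build_graph(small_atlas, [(0, 1, 0.9), (0, 2, 0.3)])
        p = build_partition(small_atlas, [1, 1, 1, 2])
        assert participation_coefficient(g, p)[0] == 0.0

    def test_even_spread_over_four_modules(self):
        atlas = synthetic_atlas(5)
        g = build_graph(atlas, [(0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5), (0, 4, 0.5)])
        p = build_partition(atlas, [1, 1, 2, 3, 4])
        # node 0's own module contributes its edge to node 1
        assert participation_coefficient(g, p)[0] == pytest.approx(0.75, abs=1e-12)

    def test_module_degree_vector_2_1_1(self):
        atlas = synthetic_atlas(5)
        g = build_graph(atlas, [(0, 1, 2.0), (0, 2, 1.0), (0, 3, 1.0)])
        p = build_partition(atlas, [1, 1, 2, 3, 4])
        assert participation_coefficient(g, p)[0] == pytest.approx(0.625, abs=1e-12)

    def test_isolated_node_pc_zero(self, small_atlas):
        g = build_graph(small_atlas, [(0, 1, 1.0)])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        assert participation_coefficient(g, p)[3] == 0.0


class TestOracleEquivalence:
    def test_pc_and_wmdz_match_brute_force_on_random_graphs(self):
        """PC/WMDz equal explicit edge-loop oracles to 1e-12 on 200 random
        weighted graphs of up to 20 nodes with random partitions."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n, edges, labels = random_weighted_graph(rng)
            atlas = synthetic_atlas(n)
            g = build_graph(atlas, edges)
            p = build_partition(atlas, labels)
            pc_o, wz_o = node_metrics_oracle(edges, labels)
            np.testing.assert_allclose(participation_coefficient(g, p), pc_o, atol=1e-12)
            np.testing.assert_allclose(within_module_degree_z(g, p), wz_o, atol=1e-12)

    def test_degree_decomposition_and_pc_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, edges, labels = random_weighted_graph(rng, max_nodes=15)
            atlas = synthetic_atlas(n)
            g = build_graph(atlas, edges)
            p = build_partition(atlas, labels)
            metrics = compute_node_metrics(g, p).frame
            w = g.weight_matrix()
            np.testing.assert_allclose(metrics["degree"], w.sum(axis=1), atol=1e-12)
            for i in range(n):
                touched = {int(labels[j]) for j in range(n) if w[i, j] > 0}
                if touched:
                    assert metrics["pc"][i] <= 1 - 1 / len(touched) + 1e-12

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        n, edges, labels = random_weighted_graph(rng, max_nodes=12)
        atlas = synthetic_atlas(n)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        # same graph with regions listed in permuted order
        edges_p = [(int(inv[u]), int(inv[v]), w) for u, v, w in edges]
        labels_p = labels[perm]
        seen: dict[int, int] = {}
        labels_p = np.array([seen.setdefault(int(l), len(seen) + 1) for l in labels_p])
        g1, p1 = build_graph(atlas, edges), build_partition(atlas, labels)
        g2, p2 = build_graph(atlas, edges_p), build_partition(atlas, labels_p)
        np.testing.assert_allclose(
            participation_coefficient(g1, p1)[perm], participation_coefficient(g2, p2),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            within_module_degree_z(g1, p1)[perm], within_module_degree_z(g2, p2),
            atol=1e-12,
        )


class TestClassifyHubs:
    @pytest.mark.parametrize(
        "pc,wmdz,high_pc,high_wmdz",
        [
            (0.32, -1.86, True, False),  # high intermodular only
            (0.48, 0.87, True, True),  # both
            (0.30, 0.80, True, True),  # inclusive boundary
            (0.29, 0.79, False, False),
        ],
    )
    def test_threshold_flags(self, small_atlas, pc, wmdz, high_pc, high_wmdz):
        g = build_graph(small_atlas, [(0, 1, 1.0)])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        table = compute_node_metrics(g, p)
        frame = table.frame.copy()
        frame.loc[0, ["pc", "wmdz"]] = (pc, wmdz)
        flagged = classify_hubs(type(table)(frame=frame)).frame
        assert bool(flagged["high_pc"][0]) is high_pc
        assert bool(flagged["high_wmdz"][0]) is high_wmdz

    def test_changing_thresholds_changes_only_flags(self, small_atlas):
        g = build_graph(small_atlas, [(0, 1, 1.0), (1, 2, 0.9)])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        a = compute_node_metrics(g, p, pc_min=0.3, wmdz_min=0.8).frame
        b = compute_node_metrics(g, p, pc_min=0.1, wmdz_min=0.1).frame
        np.testing.assert_allclose(a["pc"], b["pc"])
        np.testing.assert_allclose(a["wmdz"], b["wmdz"])


class TestSummaryAndExport:
    def test_path_graph_summary(self, small_atlas):
        g = build_graph(small_atlas, [(0, 1, 0.9), (1, 2, 0.8)])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        metrics = compute_node_metrics(g, p)
        s = summarize_network(g, metrics, p, group_label="toy")
        assert s.n_edges == 2
        assert s.module_sizes == {1: 2, 2: 2}
        assert sum(s.module_sizes.values()) == 4

    def test_empty_graph_summary(self, small_atlas):
        g = build_graph(small_atlas, [])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        s = summarize_network(g, compute_node_metrics(g, p), p)
        assert s.n_edges == 0

    @pytest.mark.parametrize("ext", ["graphml", "gexf"])
    def test_export_round_trip_preserves_isolated_nodes(self, small_atlas, tmp_path, ext):
        g = build_graph(small_atlas, [(0, 1, 0.9), (1, 2, 0.8)])  # node 3 isolated
        p = build_partition(small_atlas, [1, 1, 2, 2])
        metrics = compute_node_metrics(g, p)
        path = tmp_path / f"net.{ext}"
        export_graph(g, metrics, path)
        back = load_exported_graph(path)
        assert set(back.nodes) == set(small_atlas.abbreviations)
        assert back.number_of_edges() == 2
        ab = small_atlas.abbreviations
        assert back.nodes[ab[0]]["module"] == 1
        assert back[ab[0]][ab[1]]["weight"] == pytest.approx(0.9)

    def test_metrics_csv_layout(self, small_atlas, tmp_path):
        g = build_graph(small_atlas, [(0, 1, 0.9)])
        p = build_partition(small_atlas, [1, 1, 2, 2])
        write_metrics(compute_node_metrics(g, p), tmp_path / "m.csv")
        header = (tmp_path / "m.csv").read_text().splitlines()[0]
        for col in ("region", "abbreviation", "module", "pc", "wmdz", "high_pc", "high_wmdz"):
            assert col in header.split(",")
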