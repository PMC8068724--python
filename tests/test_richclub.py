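import networkx as nx
import numpy as np
import pytest

from richconn.core import BinaryGraph
from richconn.richclub import (
    classify_edges,
    degree_preserving_rewire,
    group_average_network,
    identify_hubs,
    integrated_class_strengths,
    phi,
    rich_club_profile,
)
from richconn.core import sparsity_sweep
from richconn.synthetic import SyntheticSpec, generate_base_network

from . import oracles
from .conftest import graph_from_adj, make_matrix


def er_graph(n, m, seed):
    return graph_from_adj(
        nx.to_numpy_array(nx.gnm_random_graph(n, m, seed=seed)).astype(int)
    )


class TestPhi:
    def test_complete_k5(self):
        adj = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert phi(graph_from_adj(adj), 2) == pytest.approx(1.0)

    def test_two_high_degree_nodes_unconnected(self):
        # nodes 0,1 have degree 3 but no edge between them
        adj = np.zeros((5, 5), dtype=int)
        for a, b in [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)]:
            adj[a, b] = adj[b, a] = 1
        assert phi(graph_from_adj(adj), 2) == pytest.approx(0.0)

    def test_star_degenerate(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        assert np.isnan(phi(graph_from_adj(adj), 1))

    def test_matches_enumeration_and_networkx(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            adj = oracles.random_graph(int(rng.integers(5, 10)), 0.5, rng)
            g = graph_from_adj(adj)
            G = nx.from_numpy_array(adj)
            if G.number_of_edges() < 2:
                continue
            nx_rc = nx.rich_club_coefficient(G, normalized=False)
            for k in range(0, int(adj.sum(0).max())):
                mine = phi(g, k)
                assert mine == pytest.approx(oracles.bf_phi(adj, k), nan_ok=True)
                if k in nx_rc and not np.isnan(mine):
                    assert mine == pytest.approx(nx_rc[k])

    def test_monotone_undefined(self):
        rng = np.random.default_rng(1)
        adj = oracles.random_graph(8, 0.4, rng)
        g = graph_from_adj(adj)
        undefined_seen = False
        for k in range(0, 10):
            v = phi(g, k)
            if np.isnan(v):
                undefined_seen = True
            elif undefined_seen:
                pytest.fail("phi became defined again after being undefined")


class TestRewire:
    def test_degree_sequence_preserved(self):
        g = er_graph(30, 120, 0)
        h = degree_preserving_rewire(g, seed=3)
        assert np.array_equal(g.degrees(), h.degrees())
        assert g.n_edges == h.n_edges
        assert not np.array_equal(g.adjacency, h.adjacency)

    def test_triangle_returned_unchanged(self):
        adj = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        g = graph_from_adj(adj)
        with pytest.warns(UserWarning, match="no valid"):
            h = degree_preserving_rewire(g, n_swap_attempts=50, seed=0)
        assert np.array_equal(g.adjacency, h.adjacency)

    def test_no_self_loops_or_diagonal(self):
        g = er_graph(20, 60, 1)
        for seed in range(5):
            h = degree_preserving_rewire(g, seed=seed)
            assert np.all(np.diag(h.adjacency) == 0)
            assert np.array_equal(h.adjacency, h.adjacency.T)

    def test_seed_reproducible(self):
        g = er_graph(25, 80, 2)
        a = degree_preserving_rewire(g, seed=9)
        b = degree_preserving_rewire(g, seed=9)
        assert np.array_equal(a.adjacency, b.adjacency)


class TestProfile:
    def test_p_floor_with_one_null(self):
        g = er_graph(20, 60, 3)
        prof = rich_club_profile(g, n_random=1, seed=0)
        defined = np.isfinite(prof.phi)
        assert (prof.p_perm[defined] >= 0.5).all()
        assert np.isfinite(prof.phi_norm[defined]).any()

    def test_planted_core_detected(self):
        spec = SyntheticSpec(
            n_nodes=60,
            n_per_group={"CN": 1},
            hub_fraction=0.2,
            hub_core_boost=3.0,
            seed=4,
        )
        template, hubs = generate_base_network(spec)
        from richconn.core import sparsity_binarize

        g = sparsity_binarize(template, 0.16)
        prof = rich_club_profile(g, n_random=60, seed=1)
        sig = prof.significant_k_range()
        assert sig is not None
        deg = g.degrees()
        hub_idx = [template.node_ids.index(h) for h in hubs]
        hub_deg_range = (deg[hub_idx].min(), deg[hub_idx].max())
        # significant regime overlaps the planted hub-degree range
        assert sig[0] <= hub_deg_range[1] and sig[1] >= hub_deg_range[0] - 1


class TestGroupAverage:
    def _graphs(self, presence):
        out = []
        for pres in presence:
            adj = np.zeros((3, 3), dtype=int)
            if pres:
                adj[0, 1] = adj[1, 0] = 1
            adj[1, 2] = adj[2, 1] = 1  # anchor edge in all subjects
            out.append(graph_from_adj(adj))
        return out

    def test_boundary_inclusive(self):
        gs = self._graphs([1, 1, 1, 1, 0])  # 4 of 5 = 80%
        avg = group_average_network(gs, 0.8)
        assert avg.adjacency[0, 1] == 1

    def test_below_threshold_dropped(self):
        gs = self._graphs([1, 1, 1, 0, 0])  # 3 of 5
        avg = group_average_network(gs, 0.8)
        assert avg.adjacency[0, 1] == 0
        assert avg.adjacency[1, 2] == 1

    def test_occurrence_one_is_intersection(self):
        gs = self._graphs([1, 1, 1, 1, 0])
        avg = group_average_network(gs, 1.0)
        assert avg.adjacency[0, 1] == 0
        assert avg.adjacency[1, 2] == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average_network([])


class TestIdentifyHubs:
    def _graph_with_degrees(self):
        # core of 3 nodes fully connected to everything: degrees 9,9,9 vs 3s
        n = 10
        adj = np.zeros((n, n), dtype=int)
        for i in range(3):
            for j in range(n):
                if i != j:
                    adj[i, j] = adj[j, i] = 1
        return graph_from_adj(adj)

    def test_fixed_k_star(self):
        g = self._graph_with_degrees()
        hubs = identify_hubs(g, k_star=5)
        assert hubs == {0, 1, 2}

    def test_k_star_above_max_degree(self):
        g = self._graph_with_degrees()
        with pytest.warns(UserWarning, match="empty"):
            assert identify_hubs(g, k_star=50) == set()

    def test_mean_sd_rule(self):
        g = self._graph_with_degrees()
        assert identify_hubs(g, rule="mean_sd") == {0, 1, 2}

    def test_planted_recovery_auto(self):
        from richconn.core import sparsity_binarize
        from richconn.richclub import group_average_network

        spec = SyntheticSpec(n_per_group={"CN": 10}, seed=2)
        from richconn.synthetic import generate_cohort

        cohort, truth = generate_cohort(spec)
        bins = [sparsity_binarize(s, 0.16) for s in cohort.subjects]
        avg = group_average_network(bins, 0.8)
        prof = rich_club_profile(avg, n_random=50, seed=1)
        hubs = identify_hubs(avg, prof, k_star="auto")
        assert hubs == set(truth["hub_set"])


class TestClassifyEdges:
    def test_three_way_example(self):
        ids = ["a", "b", "c", "d"]
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (2, 3)]:  # a-b, a-c, c-d
            w[i, j] = w[j, i] = 1.0
        from richconn.core import ConnectomeMatrix

        m = ConnectomeMatrix(w, ids)
        dec = classify_edges(m, {"a", "b"})
        assert dec.class_counts == {"rich": 1, "feeder": 1, "local": 1}
        assert sum(dec.class_proportions.values()) == pytest.approx(1.0)

    def test_empty_hub_set_all_local(self):
        g = er_graph(10, 20, 5)
        dec = classify_edges(g, set())
        assert dec.class_counts["local"] == 20
        assert dec.class_counts["rich"] == dec.class_counts["feeder"] == 0

    def test_all_hubs_all_rich(self):
        g = er_graph(10, 20, 6)
        dec = classify_edges(g, set(range(10)))
        assert dec.class_counts["rich"] == 20
        assert dec.class_proportions["rich"] == pytest.approx(1.0)

    def test_partition_completeness_random(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 15))
            adj = oracles.random_graph(n, rng.uniform(0.2, 0.9), rng)
            g = graph_from_adj(adj)
            hubs = set(rng.choice(n, size=int(rng.integers(0, n)), replace=False))
            dec = classify_edges(g, hubs)
            assert sum(dec.class_counts.values()) == g.n_edges
            if g.n_edges:
                assert sum(dec.class_proportions.values()) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_unknown_hub_rejected(self):
        g = er_graph(5, 6, 8)
        with pytest.raises(ValueError):
            classify_edges(g, {99})


class TestIntegratedStrengths:
    def test_sums_weights_of_surviving_edges(self):
        rng = np.random.default_rng(9)
        w = np.triu(rng.random((12, 12)) + 0.01, 1)
        m = make_matrix(w + w.T)
        sweep = sparsity_sweep(m, 0.1, 0.2, 0.1)
        hubs = {"n0", "n1", "n2"}
        integ = integrated_class_strengths(m, sweep, hubs)
        assert set(integ) == {"rich", "feeder", "local"}
        assert all(v >= 0 for v in integ.values())
        # hand-check one level: total strength at each level = sum of kept weights
        total_levels = []
        for _, g in sweep:
            total_levels.append((m.weights * g.adjacency)[np.triu_indices(12, 1)].sum())
        from richconn.core import integrate_curve

        assert sum(integ.values()) == pytest.approx(
            integrate_curve(total_levels, 0.1)
        )
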