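import numpy as np
import pytest

from richconn.core import (
    ConnectomeMatrix,
    NodeTable,
    integrate_curve,
    read_connectome,
    sparsity_binarize,
    sparsity_sweep,
    streamline_filter,
)
from richconn.synthetic import aal90_node_table

from .conftest import make_matrix


def _node_table(n):
    import pandas as pd

    return NodeTable(
        pd.DataFrame(
            {
                "node_id": [f"n{i}" for i in range(n)],
                "label": [f"n{i}" for i in range(n)],
                "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n)],
            }
        )
    )


class TestReadConnectome:
    def test_reads_delimited_matrix(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("0,5,0\n5,0,2\n0,2,0\n")
        m = read_connectome(p, _node_table(3))
        assert m.n_nodes == 3
        assert np.count_nonzero(np.triu(m.weights)) == 2
        assert m.weights[0, 1] == 5

    def test_symmetrizes_within_tolerance(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t0\t0\n0\t0\t5\n0\t4.9999999\t0\n")
        m = read_connectome(p, _node_table(3))
        assert m.weights[1, 2] == pytest.approx(4.99999995)
        assert m.weights[1, 2] == m.weights[2, 1]

    def test_large_asymmetry_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("0,1,0\n2,0,0\n0,0,0\n")
        with pytest.raises(ValueError, match="asymmetry"):
            read_connectome(p, _node_table(3))

    def test_dimension_mismatch(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("0,1\n1,0\n")
        with pytest.raises(ValueError, match="does not match"):
            read_connectome(p, _node_table(3))

    @pytest.mark.parametrize(
        "content,err",
        [("0,1,nan\n1,0,0\nnan,0,0\n", "NaN"), ("0,-1,0\n-1,0,0\n0,0,0\n", "negative")],
    )
    def test_bad_values_rejected(self, tmp_path, content, err):
        p = tmp_path / "m.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=err):
            read_connectome(p, _node_table(3))


class TestInvariants:
    def test_matrix_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            make_matrix([[0, 1, 0], [2, 0, 0], [0, 0, 0]])

    def test_homologue_must_be_symmetric(self):
        import pandas as pd

        df = aal90_node_table().table.copy()
        df.loc[0, "homologue_id"] = "THA.R"
        with pytest.raises(ValueError, match="homologue"):
            NodeTable(df)


class TestStreamlineFilter:
    def test_strict_cutoff(self):
        m = make_matrix([[0, 4, 3], [4, 0, 2], [3, 2, 0]])
        out = streamline_filter(m, 3)
        assert out.weights[0, 1] == 4  # > 3 kept
        assert out.weights[0, 2] == 0  # == 3 removed (strict)
        assert out.weights[1, 2] == 0

    def test_empty_graph_identity(self):
        m = make_matrix(np.zeros((4, 4)))
        assert np.array_equal(streamline_filter(m).weights, np.zeros((4, 4)))

    def test_zero_threshold_keeps_positive(self):
        m = make_matrix([[0, 0.5, 0], [0.5, 0, 2], [0, 2, 0]])
        out = streamline_filter(m, 0)
        assert np.array_equal(out.weights, m.weights)

    def test_filter_idempotent(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 10, (8, 8)).astype(float)
        w = np.triu(w, 1)
        m = make_matrix(w + w.T)
        once = streamline_filter(m)
        twice = streamline_filter(once)
        assert np.array_equal(once.weights, twice.weights)


class TestSparsityBinarize:
    def test_edge_count_from_sparsity(self):
        rng = np.random.default_rng(1)
        w = np.triu(rng.random((6, 6)) + 0.1, 1)
        g = sparsity_binarize(make_matrix(w + w.T), 0.2)
        assert g.n_edges == 3  # round(0.2 * 15)

    def test_full_sparsity_complete_graph(self):
        w = np.ones((5, 5)) - np.eye(5)
        g = sparsity_binarize(make_matrix(w), 1.0)
        assert g.n_edges == 10

    def test_tie_break_lexicographic_and_deterministic(self):
        # edges (0,1)=5, (0,2)=3, (1,2)=3, (2,3)=3 ... request 2 edges:
        # tie at weight 3 resolved toward the smallest (i, j) pair
        w = np.zeros((4, 4))
        w[0, 1] = 5
        w[0, 2] = w[1, 2] = w[2, 3] = 3
        m = make_matrix(w + w.T)
        g1 = sparsity_binarize(m, 2 / 6)
        g2 = sparsity_binarize(m, 2 / 6)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        assert g1.adjacency[0, 1] == 1 and g1.adjacency[0, 2] == 1
        assert g1.adjacency[1, 2] == 0 and g1.adjacency[2, 3] == 0

    def test_insufficient_nonzero_weights_warns(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 2] = 1.0
        m = make_matrix(w + w.T)
        with pytest.warns(UserWarning, match="nonzero"):
            g = sparsity_binarize(m, 0.5)
        assert g.n_edges == 2
        assert g.sparsity == pytest.approx(2 / 15)

    def test_binarization_idempotent(self):
        rng = np.random.default_rng(2)
        w = np.triu(rng.random((10, 10)), 1)
        g = sparsity_binarize(make_matrix(w + w.T), 0.2)
        again = sparsity_binarize(
            make_matrix(g.adjacency.astype(float)), g.sparsity
        )
        assert np.array_equal(g.adjacency, again.adjacency)


class TestSparsitySweep:
    def test_default_sixteen_levels(self):
        rng = np.random.default_rng(3)
        w = np.triu(rng.random((20, 20)), 1)
        sweep = sparsity_sweep(make_matrix(w + w.T))
        assert len(sweep) == 16
        np.testing.assert_allclose(sweep.sparsities, 0.05 + 0.01 * np.arange(16))

    def test_edge_nesting_over_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(10, 25))
            w = np.triu(rng.random((n, n)), 1)
            m = make_matrix(w + w.T)
            sweep = sparsity_sweep(m, 0.05, 0.20, 0.05)
            prev = None
            for _, g in sweep:
                if prev is not None:
                    assert np.all(prev.adjacency <= g.adjacency)
                prev = g

    def test_degenerate_single_level(self):
        rng = np.random.default_rng(5)
        w = np.triu(rng.random((12, 12)), 1)
        sweep = sparsity_sweep(make_matrix(w + w.T), 0.1, 0.1)
        assert len(sweep) == 1

    def test_invalid_range(self):
        rng = np.random.default_rng(6)
        w = np.triu(rng.random((12, 12)), 1)
        with pytest.raises(ValueError):
            sparsity_sweep(make_matrix(w + w.T), 0.2, 0.1)

    def test_filter_then_binarize_matches_one_pass(self):
        rng = np.random.default_rng(7)
        w = np.triu(rng.integers(0, 12, (15, 15)).astype(float), 1)
        m = make_matrix(w + w.T)
        staged = sparsity_binarize(streamline_filter(m, 3), 0.1)
        w2 = m.weights.copy()
        w2[w2 <= 3] = 0.0
        direct = sparsity_binarize(make_matrix(w2), 0.1)
        assert np.array_equal(staged.adjacency, direct.adjacency)


class TestIntegrateCurve:
    def test_constant_integrand(self):
        vals = np.full(16, 2.5)
        assert integrate_curve(vals, 0.01) == pytest.approx(0.15 * 2.5)

    def test_two_point_trapezoid(self):
        assert integrate_curve([0, 1], 0.01) == pytest.approx(0.005)

    def test_linear_ramp_closed_form(self):
        vals = np.linspace(0, 1, 16)
        assert integrate_curve(vals, 0.01) == pytest.approx(0.075)

    def test_sum_method(self):
        assert integrate_curve([1, 1, 1], 0.01, method="sum") == pytest.approx(0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            integrate_curve([], 0.01)


class TestCohortIO:
    def test_write_read_roundtrip(self, tmp_path, small_cohort):
        from richconn.core import read_cohort, write_cohort

        cohort, _ = small_cohort
        manifest = write_cohort(cohort, tmp_path)
        loaded = read_cohort(manifest, tmp_path / "nodes.tsv")
        assert loaded.n_subjects == cohort.n_subjects
        assert loaded.group == cohort.group
        assert list(loaded.covariates.columns) == list(cohort.covariates.columns)
        for a, b in zip(loaded.subjects, cohort.subjects):
            assert a.subject_id == b.subject_id
            # weights round-trip through %.6g text formatting
            np.testing.assert_allclose(a.weights, b.weights, rtol=1e-5)
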