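import numpy as np
import pytest
from scipy import stats

from richconn.inference import (
    bonferroni_nodes,
    nbs,
    partial_correlation,
    perm_test,
    residualize,
)

from . import oracles


class TestResidualize:
    def test_perfect_fit_zero_residuals(self):
        age = np.array([20.0, 30, 40, 50, 60])
        np.testing.assert_allclose(residualize(2 * age, age), 0.0, atol=1e-10)

    def test_orthogonal_covariate_centers(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        cov = np.ones(50)  # collinear with intercept -> rank deficient
        with pytest.raises(ValueError):
            residualize(v, cov)
        # genuinely orthogonal covariate: residual = centered values
        cov = np.tile([1.0, -1.0], 25)
        v_sym = np.abs(rng.normal(size=50))  # uncorrelated with cov by symmetry
        res = residualize(v_sym, cov)
        beta = np.polyfit(cov, v_sym, 1)[0]
        np.testing.assert_allclose(res.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(res, v_sym - v_sym.mean() - beta * cov, atol=1e-10)

    def test_matches_normal_equations(self):
        x = np.array([1.0, 2, 3, 4])
        v = np.array([1.0, 3, 2, 5])
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        np.testing.assert_allclose(residualize(v, x), v - X @ beta, atol=1e-12)


class TestPermTest:
    def test_identical_groups_p_one(self):
        v = np.tile([1.0, 2.0, 3.0], 4)
        groups = ["A"] * 6 + ["B"] * 6
        v = np.concatenate([v[:6], v[:6]])
        res = perm_test(v, groups, n_perm=500, seed=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_perm == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        res = perm_test(
            np.concatenate([a, b]), ["A"] * 30 + ["B"] * 30, n_perm=10000, seed=2
        )
        assert res.p_perm <= 0.001

    def test_three_group_f_design(self):
        rng = np.random.default_rng(3)
        v = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(3, 1, 15)]
        )
        res = perm_test(v, ["A"] * 15 + ["B"] * 15 + ["C"] * 15, n_perm=2000, seed=4)
        assert res.design == "k-group"
        assert res.p_perm < 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        groups = ["A"] * 20 + ["B"] * 20
        p1 = perm_test(v, groups, n_perm=1000, seed=6).p_perm
        p2 = perm_test(3.5 * v + 11.0, groups, n_perm=1000, seed=6).p_perm
        assert p1 == p2

    def test_null_p_uniform(self):
        """KS check: permutation p under the null is uniform on (0, 1]."""
        rng = np.random.default_rng(7)
        groups = ["A"] * 20 + ["B"] * 20
        ps = [
            perm_test(rng.normal(size=40), groups, n_perm=500, seed=int(s)).p_perm
            for s in rng.integers(0, 2**31, size=400)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_covariate_adjustment_removes_confound(self):
        rng = np.random.default_rng(8)
        groups = np.array(["A"] * 30 + ["B"] * 30)
        age = np.concatenate([rng.normal(30, 5, 30), rng.normal(50, 5, 30)])
        v = 0.5 * age + rng.normal(0, 1, 60)  # group effect only via age
        raw = perm_test(v, groups, n_perm=2000, seed=9)
        adj = perm_test(v, groups, n_perm=2000, covariates=age, seed=9)
        assert raw.p_perm < 0.01
        assert adj.p_perm > 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            perm_test(np.arange(5.0), ["A"] * 5, n_perm=100)


class TestBonferroni:
    def test_threshold_90_nodes(self):
        p = np.ones(90)
        p[3] = 5.0e-4  # below 0.05/90 ~ 5.56e-4
        p[4] = 6.0e-4  # above
        assert list(bonferroni_nodes(p)) == [3]

    def test_all_ones_empty(self):
        assert len(bonferroni_nodes(np.ones(20))) == 0

    def test_boundary_strict(self):
        p = np.full(10, 1.0)
        p[0] = 0.05 / 10
        assert len(bonferroni_nodes(p)) == 0

    def test_dict_input(self):
        assert bonferroni_nodes({"a": 1e-6, "b": 0.9}) == ["a"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_nodes(np.array([]))


class TestPartialCorrelation:
    def test_identity(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        cov = rng.normal(size=30)
        r, p = partial_correlation(x, x, cov)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_pure_covariate_response_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(300):
            z = rng.normal(size=100)
            x = rng.normal(size=100)
            y = z + 0.1 * rng.normal(size=100)
            r, _ = partial_correlation(x, y, z)
            rs.append(abs(r))
        assert np.mean(rs) < 0.1

    def test_matches_recursive_formula(self):
        x = np.array([1.0, 2, 4, 3, 7])
        y = np.array([2.0, 1, 5, 4, 8])
        z = np.array([1.0, 1, 2, 3, 5])
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(oracles.bf_partial_corr_1cov(x, y, z), abs=1e-10)

    def test_insufficient_df(self):
        with pytest.raises(ValueError):
            partial_correlation(
                np.arange(4.0), np.arange(4.0), np.ones((4, 2)) * np.arange(4)[:, None]
            )


class TestNBS:
    def _null_stack(self, rng, n_subj=20, n_nodes=12):
        return rng.normal(10, 2, size=(n_subj, n_nodes, n_nodes))

    def _symmetrize(self, stack):
        sym = (stack + stack.transpose(0, 2, 1)) / 2
        for s in sym:
            np.fill_diagonal(s, 0)
        return np.abs(sym)

    def test_p_edge_one_single_component(self):
        rng = np.random.default_rng(12)
        stack = self._symmetrize(self._null_stack(rng))
        res = nbs(stack, groups=["A"] * 10 + ["B"] * 10, p_edge=1.0, n_perm=50, seed=0)
        n_edges = 12 * 11 // 2
        assert len(res.components) == 1
        assert res.component_sizes[0] == n_edges

    def test_component_sizes_monotone_in_p_edge(self):
        rng = np.random.default_rng(13)
        stack = self._symmetrize(self._null_stack(rng, n_subj=30))
        stack[15:, 2, 3] += 4.0
        stack[15:, 3, 2] += 4.0
        groups = ["A"] * 15 + ["B"] * 15
        tight = nbs(stack, groups=groups, p_edge=0.01, n_perm=50, seed=1)
        loose = nbs(stack, groups=groups, p_edge=0.10, n_perm=50, seed=1)
        assert sum(tight.component_sizes) <= sum(loose.component_sizes)

    def test_no_suprathreshold_edges_empty_result(self):
        rng = np.random.default_rng(14)
        stack = self._symmetrize(self._null_stack(rng))
        res = nbs(
            stack, groups=["A"] * 10 + ["B"] * 10, p_edge=1e-9, n_perm=20, seed=2
        )
        assert res.components == []
        assert res.p_fwe == []

    def test_planted_component_detected(self):
        rng = np.random.default_rng(15)
        n = 20
        stack = self._symmetrize(self._null_stack(rng, n_subj=40, n_nodes=n))
        # connected chain of 6 edges among nodes 0..6, strong group effect
        chain = [(i, i + 1) for i in range(6)]
        for i, j in chain:
            stack[20:, i, j] += 5.0
            stack[20:, j, i] += 5.0
        res = nbs(
            stack, groups=["A"] * 20 + ["B"] * 20, p_edge=0.01, n_perm=200, seed=3
        )
        assert res.components, "no component found"
        iu, ju = res.edge_index
        found = {
            (int(iu[e]), int(ju[e])) for e in res.components[0]
        }
        assert set(chain) <= found
        assert res.p_fwe[0] < 0.05

    def test_cohort_interface_matches_stack(self, small_cohort):
        cohort, _ = small_cohort
        res = nbs(
            cohort, contrast=("CN", "MDDSI"), p_edge=0.05, n_perm=100, seed=4
        )
        assert res.n_perm == 100
        for comp, p in zip(res.components, res.p_fwe):
            assert 0 < p <= 1
            assert len(comp) >= 1


class TestOptionalSchemes:
    def test_freedman_lane_agrees_with_residualize(self):
        rng = np.random.default_rng(20)
        groups = ["A"] * 25 + ["B"] * 25
        age = rng.normal(40, 10, 50)
        v = 0.2 * age + rng.normal(0, 1, 50)
        v[25:] += 0.8
        p_res = perm_test(v, groups, n_perm=4000, covariates=age, seed=1).p_perm
        p_fl = perm_test(
            v, groups, n_perm=4000, covariates=age, seed=1, scheme="freedman_lane"
        ).p_perm
        assert abs(p_res - p_fl) < 0.03

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            perm_test(np.arange(8.0), ["A"] * 4 + ["B"] * 4, n_perm=100, scheme="x")

    def test_nbs_intensity_statistic(self):
        rng = np.random.default_rng(21)
        stack = rng.normal(10, 2, size=(40, 15, 15))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in stack:
            np.fill_diagonal(s, 0)
        stack = np.abs(stack)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            stack[20:, i, j] += 4.0
            stack[20:, j, i] += 4.0
        groups = ["A"] * 20 + ["B"] * 20
        ext = nbs(stack, groups=groups, p_edge=0.01, n_perm=200, seed=2)
        inten = nbs(
            stack, groups=groups, p_edge=0.01, n_perm=200, seed=2,
            statistic="intensity",
        )
        assert ext.components and inten.components
        assert inten.p_fwe[0] < 0.05
        assert ext.component_sizes == inten.component_sizes
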