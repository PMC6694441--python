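"""Residualization, correlation matrices, binarization and connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taunet.network import (GroupNetwork, binarize_at_sparsity,
                            correlation_matrix, edge_count,
                            min_connected_sparsity, residualize)

import oracles


def _edges(P):
    iu, ju = np.triu_indices(P.shape[0], 1)
    return {(i, j) for i, j, v in zip(iu, ju, P[iu, ju]) if v}


class TestResidualize:
    def test_values_linear_in_age_give_zero_residuals(self, rng):
        age = rng.normal(75, 6, 12)
        sex = rng.integers(0, 2, 12).astype(float)
        g = rng.normal(size=12)
        values = np.outer(age, rng.normal(size=6)) + 3.0
        resid = residualize(values, age, sex, g)
        assert np.max(np.abs(resid)) < 1e-9

    def test_constant_covariates_reduce_to_centering(self, rng):
        values = rng.normal(size=(10, 4))
        const = np.ones(10)
        resid = residualize(values, const * 2, const * 0, const * 5)
        np.testing.assert_allclose(resid, values - values.mean(axis=0), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        values = rng.normal(size=(12, 5))
        age, sex, g = rng.normal(size=12), rng.integers(0, 2, 12).astype(float), \
            rng.normal(size=12)
        X = np.column_stack([np.ones(12), age, sex, g])
        expected = oracles.residuals_by_normal_equations(values, X)
        np.testing.assert_allclose(residualize(values, age, sex, g),
                                   expected, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        values = rng.normal(size=(30, 8))
        age, sex = rng.normal(75, 6, 30), rng.integers(0, 2, 30).astype(float)
        g = values.mean(axis=1)
        resid = residualize(values, age, sex, g)
        for cov in (np.ones(30), age, sex, g):
            assert np.max(np.abs(cov @ resid)) < 1e-8

    def test_collinear_covariate_dropped_with_warning(self, rng, caplog):
        values = rng.normal(size=(10, 3))
        age = rng.normal(75, 6, 10)
        with caplog.at_level("WARNING", logger="taunet.network"):
            resid = residualize(values, age, np.zeros(10), 2 * age + 1)
        assert "collinear" in caplog.text
        assert resid.shape == values.shape

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            residualize(rng.normal(size=(4, 3)), np.arange(4.0),
                        np.zeros(4), np.ones(4))


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.normal(size=10)
        net = correlation_matrix(np.column_stack([x, x, rng.normal(size=10)]))
        assert net.R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_column_anticorrelates(self, rng):
        x = rng.normal(size=10)
        net = correlation_matrix(np.column_stack([x, -x + 7.0]))
        assert net.R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula_on_integer_table(self):
        table = np.array([[3, 1, 4, 1], [5, 9, 2, 6], [5, 3, 5, 8],
                          [9, 7, 9, 3], [2, 3, 8, 4]], dtype=float)
        net = correlation_matrix(table)
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected = oracles.pearson_by_formula(table[:, i], table[:, j])
                    assert net.R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariants_and_subject_order_invariance(self, rng):
        data = rng.normal(size=(15, 6))
        net = correlation_matrix(data)
        assert np.allclose(net.R, net.R.T)
        assert np.allclose(np.diag(net.R), 1.0)
        assert np.all(np.abs(net.R) <= 1.0)
        shuffled = correlation_matrix(data[rng.permutation(15)])
        np.testing.assert_allclose(net.R, shuffled.R, atol=1e-12)

    def test_zero_variance_column_names_region(self, rng):
        data = rng.normal(size=(8, 3))
        data[:, 1] = 4.2
        with pytest.raises(ValueError, match="Region_B"):
            correlation_matrix(data, names=("Region_A", "Region_B", "Region_C"))


def _random_net(rng, n=20):
    resid = rng.normal(size=(n + 5, n))
    return correlation_matrix(resid)


class TestBinarize:
    def test_aal_edge_count_at_8_percent(self, rng):
        net = _random_net(rng, n=90)
        bn = binarize_at_sparsity(net, 0.08)
        assert bn.K == 320 == edge_count(90, 0.08)
        assert bn.P.sum() == 640

    def test_full_sparsity_gives_complete_graph(self, rng):
        net = _random_net(rng, n=8)
        bn = binarize_at_sparsity(net, 1.0)
        assert bn.K == 8 * 7 // 2
        assert np.all(bn.P + np.eye(8) == 1)

    def test_top_k_selection_on_distinct_magnitudes(self, rng):
        net = _random_net(rng, n=5)
        bn = binarize_at_sparsity(net, 0.4)
        assert bn.K == 4
        assert _edges(bn.P) == oracles.top_k_edges(net.R, 4)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.5), st.floats(0.55, 1.0))
    def test_edge_sets_nest_across_sparsity(self, seed, s1, s2):
        net = _random_net(np.random.default_rng(seed), n=12)
        e1 = _edges(binarize_at_sparsity(net, s1).P)
        e2 = _edges(binarize_at_sparsity(net, s2).P)
        assert e1 <= e2

    def test_invariant_to_monotone_transform_of_magnitude(self, rng):
        net = _random_net(rng, n=10)
        warped = GroupNetwork(group="", R=np.sign(net.R) * np.abs(net.R) ** 3,
                              n_subjects=net.n_subjects)
        for s in (0.1, 0.3, 0.6):
            np.testing.assert_array_equal(binarize_at_sparsity(net, s).P,
                                          binarize_at_sparsity(warped, s).P)

    def test_edge_list_prefix_is_binarized_edge_set(self, rng):
        from taunet.network import edge_list
        net = _random_net(rng, n=6)
        net.names = tuple("abcdef")
        el = edge_list(net)
        assert len(el) == 15
        assert np.all(np.diff(np.abs(el["r"])) <= 1e-12)
        bn = binarize_at_sparsity(net, 0.4)
        kept = {(net.names.index(a), net.names.index(b))
                for a, b in zip(el["region_i"][:bn.K], el["region_j"][:bn.K])}
        assert kept == _edges(bn.P)

    def test_invalid_sparsity_rejected(self, rng):
        net = _random_net(rng, n=5)
        for s in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                binarize_at_sparsity(net, s)


class TestMinConnectedSparsity:
    def test_planted_spanning_tree_connects_at_k_equals_n_minus_1(self, rng):
        n = 10
        R = rng.uniform(0.01, 0.3, size=(n, n))
        R = (R + R.T) / 2
        for i in range(n - 1):           # path edges dominate all others
            R[i, i + 1] = R[i + 1, i] = 0.9 - 0.01 * i
        np.fill_diagonal(R, 1.0)
        net = GroupNetwork(group="", R=R, n_subjects=50)
        # smallest grid s with round(s*45) >= 9 edges
        assert min_connected_sparsity(net, grid_step=0.01) == pytest.approx(0.19)

    def test_matches_union_find_linear_scan(self):
        step = 0.02
        for seed in range(20):
            rng = np.random.default_rng(seed)
            net = _random_net(rng, n=12)
            expected = None
            for s in np.arange(step, 1.0 + step / 2, step):
                P = binarize_at_sparsity(net, float(min(s, 1.0))).P
                if oracles.connected_by_union_find(P):
                    expected = float(min(s, 1.0))
                    break
            assert min_connected_sparsity(net, grid_step=step) == pytest.approx(expected)

    def test_equal_magnitudes_connect_once_k_spans(self):
        n = 8
        R = np.full((n, n), 0.5)
        np.fill_diagonal(R, 1.0)
        net = GroupNetwork(group="", R=R, n_subjects=50)
        s = min_connected_sparsity(net, grid_step=0.05)
        # ties resolve lexicographically: first K >= n-1 edges span via node 0
        assert edge_count(n, s) >= n - 1
        assert s == pytest.approx(0.25)
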