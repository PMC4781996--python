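"""Shrunk covariance, partial correlation, and sparsity binarization."""

from __future__ import annotations

import numpy as np
import pytest

from scnet import (
    AssociationMatrix,
    binarize_at_sparsity,
    ledoit_wolf_covariance,
    partial_correlation,
    sparsity_grid,
    sparsity_sweep,
)


class TestLedoitWolf:
    def test_constant_columns_give_zero_matrix_and_warning(self):
        x = np.ones((6, 4)) * 3.0
        with pytest.warns(UserWarning):
            sigma, a = ledoit_wolf_covariance(x)
        assert np.allclose(sigma, 0.0) and a == 0.0

    def test_intensity_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for n, p in [(5, 20), (20, 5), (36, 148), (3, 3)]:
            _, a = ledoit_wolf_covariance(rng.standard_normal((n, p)))
            assert 0.0 <= a <= 1.0

    def test_consistency_on_identity_covariance(self):
        """Monte-Carlo oracle: n=5000 samples from I_10 must give an
        estimate within 0.1 of the identity elementwise."""
        rng = np.random.default_rng(42)
        sigma, a = ledoit_wolf_covariance(rng.standard_normal((5000, 10)))
        assert np.max(np.abs(sigma - np.eye(10))) < 0.1
        # when the truth IS the target, heavy shrinkage is correct;
        # the estimate must still be consistent, which the bound above checks
        assert 0.0 <= a <= 1.0

    def test_matches_reference_implementation(self):
        """Cross-check against the scikit-learn Ledoit-Wolf estimator."""
        sklearn = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 50)) @ np.diag(np.linspace(0.5, 2, 50))
        sigma, a = ledoit_wolf_covariance(x)
        ref_sigma, ref_a = sklearn.ledoit_wolf(x, assume_centered=False)
        assert np.allclose(a, ref_a, atol=1e-10)
        assert np.allclose(sigma, ref_sigma, atol=1e-10)

    def test_positive_definite_in_small_n_large_p(self):
        rng = np.random.default_rng(2)
        sigma, a = ledoit_wolf_covariance(rng.standard_normal((36, 148)))
        assert a > 0
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_shrinkage_beats_sample_covariance_when_n_below_p(self):
        """Paired Monte-Carlo: Frobenius error to the true covariance is
        smaller for the shrunk estimate in >= 90% of replicates."""
        rng = np.random.default_rng(3)
        p, n, wins = 40, 20, 0
        truth = np.eye(p)
        for _ in range(30):
            x = rng.standard_normal((n, p))
            xc = x - x.mean(axis=0)
            s = xc.T @ xc / n
            shrunk, _ = ledoit_wolf_covariance(x)
            wins += np.linalg.norm(shrunk - truth) < np.linalg.norm(s - truth)
        assert wins >= 27

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            ledoit_wolf_covariance(np.ones((1, 5)))


class TestPartialCorrelation:
    def test_diagonal_covariance_gives_zero_off_diagonals(self):
        assoc = partial_correlation(np.diag([1.0, 2.0, 3.0]))
        off = assoc.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0) and np.allclose(np.diag(assoc.values), 1.0)

    def test_two_variables_reduce_to_pearson(self):
        sigma = np.array([[2.0, 0.6], [0.6, 1.0]])
        assoc = partial_correlation(sigma)
        assert np.isclose(assoc.values[0, 1], 0.6 / np.sqrt(2.0))

    def test_chain_precision_round_trip(self):
        """Oracle: invert the 1-2-3 chain precision, feed the covariance,
        and recover the conditional-independence zero exactly."""
        omega = np.array([[1, -0.4, 0], [-0.4, 1, -0.4], [0, -0.4, 1.0]])
        assoc = partial_correlation(np.linalg.inv(omega))
        assert abs(assoc.values[0, 2]) < 1e-8
        assert np.isclose(assoc.values[0, 1], 0.4)
        assert np.isclose(assoc.values[1, 2], 0.4)

    def test_sparse_precision_pattern_recovered(self):
        p = 8
        omega = np.eye(p)
        for i, j in [(0, 3), (2, 5), (4, 7)]:
            omega[i, j] = omega[j, i] = 0.3
        assoc = partial_correlation(np.linalg.inv(omega))
        expected = -omega / 1.0
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(assoc.values, expected, atol=1e-8)

    def test_singular_input_raises_helpfully(self):
        sigma = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            partial_correlation(sigma)

    def test_large_n_matches_unshrunk_pipeline(self):
        """As the estimated intensity vanishes (n >> p), partial correlation
        from the shrunk covariance converges to the plain sample version."""
        rng = np.random.default_rng(5)
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.5
        x = rng.multivariate_normal(np.zeros(4), cov, size=20000)
        shrunk, a = ledoit_wolf_covariance(x)
        xc = x - x.mean(axis=0)
        s = xc.T @ xc / len(x)
        plain = partial_correlation(s).values
        via_lw = partial_correlation(shrunk).values
        assert a < 0.01
        assert np.max(np.abs(plain - via_lw)) < 0.01


def _assoc_from_weights(n, weights):
    m = np.zeros((n, n))
    for (i, j), w in weights.items():
        m[i, j] = m[j, i] = w
    np.fill_diagonal(m, 1.0)
    return AssociationMatrix(m, [f"n{i}" for i in range(n)])


class TestBinarize:
    def test_top_two_of_six(self):
        assoc = _assoc_from_weights(4, {
            (0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
            (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4,
        })
        g = binarize_at_sparsity(assoc, 1 / 3)
        assert g.edge_list() == [("n0", "n1"), ("n0", "n2")]

    def test_edge_budget_at_reference_scale(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(148, 148))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = binarize_at_sparsity(AssociationMatrix(w, [f"r{i}" for i in range(148)]), 0.05)
        assert g.n_edges == 543  # floor(0.05 * 148*147/2)

    def test_absolute_ranking_keeps_strong_negatives(self):
        assoc = _assoc_from_weights(3, {(0, 1): -0.9, (0, 2): 0.5, (1, 2): 0.1})
        g_abs = binarize_at_sparsity(assoc, 1 / 3, rank_by="absolute")
        g_pos = binarize_at_sparsity(assoc, 1 / 3, rank_by="positive")
        assert g_abs.adjacency[0, 1] == 1
        assert g_pos.adjacency[0, 1] == 0 and g_pos.adjacency[0, 2] == 1

    def test_tie_at_cutoff_is_deterministic_lexicographic(self):
        assoc = _assoc_from_weights(4, {
            (0, 1): 0.9, (0, 2): 0.5, (1, 3): 0.5,
            (0, 3): 0.5, (1, 2): 0.2, (2, 3): 0.1,
        })
        g1 = binarize_at_sparsity(assoc, 2 / 6)
        g2 = binarize_at_sparsity(assoc, 2 / 6)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # the tied pair kept is the lexicographically smallest, (0, 2)
        assert g1.adjacency[0, 2] == 1
        assert g1.adjacency[0, 3] == 0 and g1.adjacency[1, 3] == 0

    def test_zero_edge_budget_rejected(self):
        assoc = _assoc_from_weights(4, {(0, 1): 0.9})
        with pytest.raises(ValueError, match="zero edges"):
            binarize_at_sparsity(assoc, 0.01)

    def test_no_self_loops_and_symmetry(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = binarize_at_sparsity(AssociationMatrix(w, [f"r{i}" for i in range(20)]), 0.2)
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 0)


class TestSweep:
    def test_default_grid_has_31_values(self):
        grid = sparsity_grid()
        assert len(grid) == 31
        assert np.isclose(grid[0], 0.05) and np.isclose(grid[-1], 0.35)

    def test_single_point_sweep(self):
        assoc = _assoc_from_weights(6, {(i, j): 0.1 * (i + j) for i in range(6)
                                        for j in range(i + 1, 6)})
        graphs = sparsity_sweep(assoc, 0.2, 0.2, 0.01)
        assert len(graphs) == 1

    def test_edge_sets_nested_across_sparsity(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=(30, 30))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        assoc = AssociationMatrix(w, [f"r{i}" for i in range(30)])
        graphs = sparsity_sweep(assoc, 0.05, 0.35, 0.05)
        for g_small, g_big in zip(graphs, graphs[1:]):
            assert set(g_small.edge_list()) <= set(g_big.edge_list())
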