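"""Graphical LASSO solver oracles, stability score, calibration and
rewiring comparison."""

import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy import optimize, stats

from crossomix import synthdata as sd
from crossomix.containers import InvalidConfigError
from crossomix.network import (
    AlignmentError,
    RegularizationError,
    compare_networks,
    default_lambda_grid,
    graphical_lasso,
    multiblock_stability_network,
    stability_score,
    stability_select_network,
    subgradient_violation,
)


def _random_correlation(p, density=0.4, seed=0):
    theta, _ = sd.generate_precision_matrix(
        sd.PrecisionSpec(p=p, density=density), seed=seed
    )
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


from conftest import brute_force_glasso as _brute_force_glasso


class TestGraphicalLasso:
    def test_large_penalty_gives_diagonal(self):
        S = _random_correlation(6, seed=1)
        lam = np.abs(S - np.eye(6)).max() + 0.01
        theta, edges = graphical_lasso(S, lam)
        assert edges == []
        assert np.allclose(theta, np.diag(np.diag(theta)))

    def test_zero_penalty_equals_inverse(self):
        S = _random_correlation(6, seed=2)
        theta, _ = graphical_lasso(S, 0.0)
        assert np.abs(theta - np.linalg.inv(S)).max() < 1e-6

    def test_zero_penalty_singular_matrix_rejected(self):
        X = np.random.default_rng(3).standard_normal((4, 8))
        S = np.corrcoef(X.T)  # rank-deficient
        with pytest.raises(RegularizationError):
            graphical_lasso(S, 0.0)

    @pytest.mark.parametrize("seed,lam", [(7, 0.1), (8, 0.05), (9, 0.2)])
    def test_matches_brute_force_optimizer(self, seed, lam):
        S = _random_correlation(4, seed=seed)
        theta, _ = graphical_lasso(S, lam, tol=1e-9, max_iter=500)
        brute = _brute_force_glasso(S, lam)
        assert np.abs(theta - brute).max() < 1e-5

    def test_matches_sklearn(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = _random_correlation(8, seed=10)
        theta, _ = graphical_lasso(S, 0.08, tol=1e-9, max_iter=500)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = sk_glasso(S, alpha=0.08, tol=1e-10, max_iter=1000)
        assert np.abs(theta - prec).max() < 5e-4

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_subgradient_conditions(self, seed):
        S = _random_correlation(7, seed=seed)
        for lam in (0.05, 0.15):
            theta, _ = graphical_lasso(S, lam, tol=1e-9, max_iter=500)
            assert subgradient_violation(S, theta, lam) < 1e-5

    def test_edge_count_monotone_in_penalty(self):
        S = _random_correlation(10, seed=14)
        grid = default_lambda_grid(S, n_lambda=12)
        counts = [len(graphical_lasso(S, lam)[1]) for lam in grid]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_matrix_penalty_zeroes_targeted_block(self):
        S = _random_correlation(6, seed=15)
        Lam = np.full((6, 6), 0.01)
        Lam[:3, 3:] = Lam[3:, :3] = 1.0  # forbid cross edges
        theta, edges = graphical_lasso(S, Lam)
        assert all(not (j < 3 <= k) for j, k in edges)


class TestStabilityScore:
    def test_uniform_counts_minimal_bimodal_maximal(self):
        """Over all count configurations with the same total, the middle
        pile scores lowest and the {0, K} split highest."""
        K, N = 10, 3
        total = 15
        scores = {}
        for counts in product(range(K + 1), repeat=N):
            if sum(counts) != total:
                continue
            scores[counts] = stability_score(np.array(counts), K, pi=0.8)
        uniform = scores[(5, 5, 5)]
        bimodal = scores[(10, 5, 0)]
        assert uniform == min(scores.values())
        extremes = {c: s for c, s in scores.items() if set(c) <= {0, 5, 10}}
        assert max(scores.values()) == max(extremes.values())

    def test_fully_bimodal_beats_mixed_at_equal_q(self):
        K = 10
        bimodal = stability_score(np.array([10, 10, 0, 0]), K, pi=0.8)
        mixed = stability_score(np.array([7, 6, 4, 3]), K, pi=0.8)
        assert bimodal > mixed

    def test_degenerate_q_is_minus_infinity(self):
        assert stability_score(np.array([2]), K=2, pi=0.9) == -np.inf
        assert stability_score(np.array([0, 0]), K=5, pi=0.9) == -np.inf

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            stability_score(np.array([1]), K=4, pi=0.4)
        with pytest.raises(InvalidConfigError):
            stability_score(np.array([9]), K=4, pi=0.9)


class TestStabilitySelection:
    def test_recovers_sparse_support(self):
        from crossomix.validation import network_recovery

        r = network_recovery(p=15, density=0.12, n=250, K=60, seed=3)
        assert r["f1"] >= 0.7

    def test_tiny_subsample_count_rejected(self):
        X = np.random.default_rng(4).standard_normal((50, 5))
        with pytest.raises(InvalidConfigError, match="K >= 50"):
            stability_select_network(X, K=1)

    def test_subsample_below_dimension_warns(self):
        X = np.random.default_rng(5).standard_normal((20, 18))
        with pytest.warns(UserWarning, match="singular"):
            stability_select_network(X, K=12, frac=0.5)

    def test_proportions_reproducible_under_seed(self):
        X = np.random.default_rng(6).standard_normal((80, 8))
        a = stability_select_network(X, K=20, seed=9)
        b = stability_select_network(X, K=20, seed=9)
        pd.testing.assert_frame_equal(a.proportions, b.proportions)

    def test_adjacency_consistent_with_threshold(self):
        X = np.random.default_rng(7).standard_normal((100, 8))
        net = stability_select_network(X, K=25, seed=10)
        A = net.adjacency.to_numpy()
        P = net.proportions.to_numpy()
        assert (P[A] >= net.pi_star).all()
        assert 0.5 < net.pi_star < 1.0
        assert (A == A.T).all()


@pytest.fixture(scope="module")
def block_data():
    rng = np.random.default_rng(31)
    theta, edges = sd.generate_precision_matrix(
        sd.PrecisionSpec(p=12, density=0.15), seed=32
    )
    L = np.linalg.cholesky(np.linalg.inv(theta))
    X = rng.standard_normal((200, 12)) @ L.T
    blocks = ["met"] * 7 + ["rna"] * 5
    return X, blocks, edges


class TestMultiblock:
    def test_infinite_cross_penalty_removes_cross_edges(self, block_data):
        X, blocks, _ = block_data
        grids = {
            "within_1": np.array([0.05]),
            "within_2": np.array([0.05]),
            "cross": np.array([10.0]),
        }
        net = multiblock_stability_network(
            X, blocks, lam_grids=grids, K=15, seed=1
        )
        assert net.cross_edges() == []

    def test_equal_penalties_reduce_to_single_block(self, block_data):
        X, blocks, _ = block_data
        lam = 0.12
        grids = {g: np.array([lam]) for g in ("within_1", "within_2", "cross")}
        multi = multiblock_stability_network(
            X, blocks, lam_grids=grids, K=20, seed=5
        )
        single = stability_select_network(
            X, lam_grid=np.array([lam]), K=20, seed=5
        )
        assert np.allclose(
            multi.proportions.to_numpy(), single.proportions.to_numpy()
        )
        assert multi.pi_star == single.pi_star

    def test_recovers_planted_cross_edges(self):
        """Cross-block conditional dependencies planted in the precision
        matrix are found by the block-penalized network."""
        rng = np.random.default_rng(41)
        p1, p2 = 15, 10
        p = p1 + p2
        theta = np.zeros((p, p))
        cross_truth = [(1, p1 + 2), (4, p1 + 5), (7, p1 + 1), (11, p1 + 8)]
        for j, k in cross_truth:
            theta[j, k] = theta[k, j] = 0.35
        within = [(0, 3), (5, 6), (p1, p1 + 4), (p1 + 6, p1 + 9)]
        for j, k in within:
            theta[j, k] = theta[k, j] = 0.3
        # diagonal dominance with a 0.5 margin, as the generator builds it
        np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 0.5)
        L = np.linalg.cholesky(np.linalg.inv(theta))
        X = rng.standard_normal((400, p)) @ L.T
        blocks = ["a"] * p1 + ["b"] * p2
        net = multiblock_stability_network(
            X, blocks, K=40, seed=42, n_lambda=4
        )
        names = net.nodes
        found = {
            tuple(sorted((names.index(u), names.index(v))))
            for u, v in net.cross_edges()
        }
        truth = {tuple(sorted(e)) for e in cross_truth}
        assert len(found & truth) >= 3

    def test_requires_two_blocks(self):
        X = np.random.default_rng(51).standard_normal((50, 6))
        with pytest.raises(InvalidConfigError):
            multiblock_stability_network(X, ["a"] * 6, K=15)


class TestCompareNetworks:
    def _adj(self, nodes, edges):
        A = pd.DataFrame(False, index=nodes, columns=nodes)
        for u, v in edges:
            A.loc[u, v] = A.loc[v, u] = True
        return A

    def test_identical_networks_all_stable(self):
        nodes = list("abcd")
        A = self._adj(nodes, [("a", "b"), ("c", "d")])
        rep = compare_networks(A, A.copy(), A.copy())
        assert rep["counts"]["stable"] == 2
        assert sum(rep["counts"].values()) == 2

    def test_disjoint_edge_sets_have_no_persistent(self):
        nodes = list("abcd")
        pre = self._adj(nodes, [("a", "b")])
        post2 = self._adj(nodes, [("c", "d")])
        post24 = self._adj(nodes, [("a", "c")])
        rep = compare_networks(pre, post2, post24)
        assert rep["counts"]["persistent"] == 0
        assert rep["counts"]["baseline_only"] == 1
        assert rep["counts"]["acute"] == 1
        assert rep["counts"]["lagged"] == 1

    def test_planted_persistent_edges(self):
        nodes = [f"n{i}" for i in range(6)]
        base = [("n0", "n1")]
        added = [("n2", "n3"), ("n4", "n5"), ("n1", "n2")]
        pre = self._adj(nodes, base)
        post2 = self._adj(nodes, base + added)
        post24 = self._adj(nodes, base + added)
        rep = compare_networks(pre, post2, post24)
        assert rep["counts"]["persistent"] == 3
        assert rep["counts"]["stable"] == 1

    def test_reverting_pattern_classified(self):
        nodes = list("abc")
        pre = self._adj(nodes, [("a", "b")])
        post2 = self._adj(nodes, [])
        post24 = self._adj(nodes, [("a", "b")])
        rep = compare_networks(pre, post2, post24)
        assert rep["counts"]["reverting"] == 1

    def test_node_mismatch_raises(self):
        a = self._adj(list("abc"), [])
        b = self._adj(list("abd"), [])
        with pytest.raises(AlignmentError, match="c"):
            compare_networks(a, b, b)
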