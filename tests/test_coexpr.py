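import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markerpipe.coexpr import (ModuleSet, adjacency_matrix,
                               detect_and_merge_modules,
                               intramodular_connectivity, module_eigengene,
                               paired_spearman_screen, pick_soft_threshold,
                               spearman_rho, tom_from_adjacency, wgcna_modules)
from markerpipe.io_meta import ValidationError


def _tom_oracle(A):
    """Naive triple-loop topological overlap."""
    n = A.shape[0]
    k = A.sum(axis=1)
    W = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n))
            W[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return W


def _block_data(seed, n_samples=50, sizes=(40, 40), r=0.9, n_noise=0,
                cross_factor_r=0.0):
    gen = np.random.default_rng(seed)
    f1 = gen.normal(size=n_samples)
    f2 = cross_factor_r * f1 + np.sqrt(1 - cross_factor_r ** 2) * gen.normal(
        size=n_samples)
    rows = []
    for size, f in zip(sizes, (f1, f2)):
        noise = gen.normal(size=(size, n_samples))
        rows.append(np.sqrt(r) * f[None, :] + np.sqrt(1 - r) * noise)
    if n_noise:
        rows.append(gen.normal(size=(n_noise, n_samples)))
    X = np.vstack(rows)
    ids = [f"v{i}" for i in range(X.shape[0])]
    truth = np.concatenate([np.full(s, b + 1) for b, s in enumerate(sizes)]
                           + ([np.zeros(n_noise, int)] if n_noise else []))
    return X, ids, truth


class TestTOM:
    def test_isolated_pair_full_overlap(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        W = tom_from_adjacency(A)
        assert W[0, 1] == pytest.approx(1.0)

    def test_unconnected_pair_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        W = tom_from_adjacency(A)
        assert W[0, 2] == pytest.approx(0.0)

    def test_three_clique_unit_overlap(self):
        A = np.ones((3, 3)) - np.eye(3)
        W = tom_from_adjacency(A)
        off = W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_naive_oracle_and_bounds(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 12))
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            W = tom_from_adjacency(A)
            assert np.allclose(W, _tom_oracle(A), atol=1e-12)
            assert np.all((W >= -1e-12) & (W <= 1 + 1e-12))

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            tom_from_adjacency(A)


class TestSoftThreshold:
    def test_singleton_candidate_returned(self, rng):
        X = rng.normal(size=(30, 20))
        with pytest.warns(UserWarning):
            beta, fit = pick_soft_threshold(X, powers=(6,), target_r2=0.99)
        assert beta == 6

    def test_perfectly_correlated_falls_through(self, rng):
        base = rng.normal(size=30)
        X = np.vstack([base * s for s in rng.uniform(0.5, 2.0, 25)])
        with pytest.warns(UserWarning):
            beta, fit = pick_soft_threshold(X, powers=(2, 4), target_r2=0.8)
        assert beta in (2, 4)

    def test_deterministic(self):
        X, ids, _ = _block_data(1, n_noise=40)
        b1, f1 = pick_soft_threshold(X)
        b2, f2 = pick_soft_threshold(X)
        assert b1 == b2
        pd.testing.assert_frame_equal(f1, f2)

    def test_constant_variable_rejected(self, rng):
        X = rng.normal(size=(25, 30))
        X[3] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            adjacency_matrix(X, 6)


class TestModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        X, ids, truth = _block_data(2)
        A = adjacency_matrix(X, 6)
        ms = detect_and_merge_modules(1 - tom_from_adjacency(A), X, ids,
                                      min_size=20, merge_cut=0.25)
        assigned = ms.labels
        assert len(ms.module_ids) == 2
        assert adjusted_rand_score(truth, assigned) == 1.0

    def test_correlated_eigengenes_merge_under_default_cut(self):
        # force an initial split via the dissimilarity, keep profiles correlated
        X, ids, _ = _block_data(3, cross_factor_r=0.95, r=0.95)
        n = X.shape[0]
        D = np.ones((n, n))
        D[:40, :40] = 0.1
        D[40:, 40:] = 0.1
        np.fill_diagonal(D, 0.0)
        merged = detect_and_merge_modules(D, X, ids, min_size=20, merge_cut=0.25)
        unmerged = detect_and_merge_modules(D, X, ids, min_size=20, merge_cut=0.0)
        assert len(unmerged.module_ids) == 2      # merge_cut=0 never merges
        assert len(merged.module_ids) == 1
        assert merged.merge_history and merged.merge_history[0][2] < 0.25

    def test_no_module_reaches_min_size(self, rng):
        # maximal dissimilarity everywhere: every branch is a singleton
        X = rng.normal(size=(30, 40))
        D = np.ones((30, 30))
        np.fill_diagonal(D, 0.0)
        with pytest.warns(UserWarning, match="unassigned"):
            ms = detect_and_merge_modules(D, X, [f"v{i}" for i in range(30)],
                                          min_size=25, merge_cut=0.25)
        assert ms.module_ids == []
        assert np.all(ms.labels == 0)

    def test_permutation_invariance_of_partition(self):
        from sklearn.metrics import adjusted_rand_score
        X, ids, truth = _block_data(5, n_noise=30)
        perm = np.random.default_rng(0).permutation(X.shape[0])
        A1 = adjacency_matrix(X, 6)
        A2 = adjacency_matrix(X[perm], 6)
        m1 = detect_and_merge_modules(1 - tom_from_adjacency(A1), X, ids,
                                      min_size=20, merge_cut=0.25)
        m2 = detect_and_merge_modules(1 - tom_from_adjacency(A2), X[perm],
                                      [ids[i] for i in perm],
                                      min_size=20, merge_cut=0.25)
        assert adjusted_rand_score(m1.labels[perm], m2.labels) == 1.0

    def test_eigengene_maximizes_explained_variance(self, rng):
        X, _, _ = _block_data(6, sizes=(30,))
        e = module_eigengene(X)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        best = np.sum((Z @ e) ** 2)
        for _ in range(50):
            v = rng.normal(size=e.size)
            v /= np.linalg.norm(v)
            assert np.sum((Z @ v) ** 2) <= best + 1e-9

    def test_wgcna_blockwise_matches_truth(self):
        from sklearn.metrics import adjusted_rand_score
        X, ids, truth = _block_data(7, n_noise=20)
        ms, fit, tops = wgcna_modules(X, ids, min_size=20, merge_cut=0.25,
                                      max_block=60, seed=1)
        mask = truth > 0
        assert adjusted_rand_score(truth[mask], ms.labels[mask]) >= 0.9


class TestConnectivity:
    def test_full_clique_kwithin(self):
        A = np.ones((4, 4)) - np.eye(4)
        ms = ModuleSet(np.ones(4, int), ["a", "b", "c", "d"])
        kw, tops = intramodular_connectivity(A, ms, top_frac=1.0)
        assert np.allclose(kw, 3.0)
        assert list(tops[1]["id"]) == ["a", "b", "c", "d"]

    def test_quarter_of_six_is_two(self, rng):
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        ms = ModuleSet(np.ones(6, int), [f"v{i}" for i in range(6)])
        _, tops = intramodular_connectivity(A, ms, top_frac=0.25)
        assert len(tops[1]) == 2        # ceil(0.25 * 6)

    def test_top_sorted_descending(self, rng):
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        ms = ModuleSet(np.ones(8, int), [f"v{i}" for i in range(8)])
        _, tops = intramodular_connectivity(A, ms, top_frac=1.0)
        assert tops[1]["kWithin"].is_monotonic_decreasing


class TestPairedSpearman:
    def test_perfect_inverse_monotone(self):
        assert spearman_rho(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == -1.0

    def test_midrank_ties_match_scipy(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 25))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            expected = stats.spearmanr(x, y).statistic
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_gate_requires_both_rho_and_fdr(self):
        gen = np.random.default_rng(1)
        n = 30
        base = gen.normal(size=(3, n))
        X1 = np.vstack([base, gen.normal(size=(20, n))])
        X2 = np.vstack([base + 0.2 * gen.normal(size=(3, n)),
                        gen.normal(size=(20, n))])
        ids = [f"v{i}" for i in range(23)]
        table, sig = paired_spearman_screen(X1, X2, ids, rho_cut=0.5,
                                            fdr_cut=0.05)
        assert set(sig) == {"v0", "v1", "v2"}
        weak = table[(table["rho"] > 0.5) & (table["FDR"] >= 0.05)]
        assert not set(weak["id"]) & set(sig)

    def test_too_few_pairs_untestable(self):
        X1 = np.array([[1.0, 2, np.nan, np.nan, 5]])
        X2 = np.array([[2.0, 1, 3, 4, np.nan]])
        table, sig = paired_spearman_screen(X1, X2, ["v0"])
        assert np.isnan(table.loc[0, "rho"])
        assert table.loc[0, "n"] == 2
        assert sig == []
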