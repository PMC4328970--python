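"""Network construction, TOM, UPGMA clustering, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from coexdiv.network import (
    CoexpressionModules,
    adjacency_from_correlation,
    average_linkage_dendrogram,
    correlation_matrix,
    cut_modules,
    kruskal_wallis,
    linkage_to_newick,
    module_eigengene,
    topological_overlap,
)


def naive_tom(A):
    """O(n^3) literal triple loop over the TOM formula."""
    n = len(A)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


def naive_upgma_heights(D):
    """Merge heights of a from-scratch O(n^3) UPGMA."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    nxt = len(D)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return np.sort(np.array(heights))


class TestCorrelation:
    def test_identical_profiles(self):
        x = np.array([[1.0, 2, 3, 5], [1.0, 2, 3, 5]])
        assert correlation_matrix(x)[0, 1] == pytest.approx(1.0)

    def test_negated_profile(self):
        x = np.array([[1.0, 2, 3, 5], [-1.0, -2, -3, -5]])
        assert correlation_matrix(x)[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self, rng):
        X = rng.normal(size=(5, 8))
        cor = correlation_matrix(X)
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_gene_raises(self):
        x = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(x)


class TestAdjacency:
    def test_endpoints(self):
        cor = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = adjacency_from_correlation(cor)
        assert A[0, 1] == 0.0 and A[0, 0] == 1.0

    def test_power_of_point_nine(self):
        cor = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert adjacency_from_correlation(cor, beta=10)[0, 1] == pytest.approx(
            0.9**10
        )

    def test_beta_one_is_absolute_value(self, rng):
        cor = np.clip(rng.uniform(-1, 1, size=(6, 6)), -1, 1)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        A = adjacency_from_correlation(cor, beta=1)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(A[off], np.abs(cor)[off])

    def test_monotone_in_beta(self, rng):
        """Raising the soft-threshold power never increases any edge."""
        cor = rng.uniform(-1, 1, size=(10, 10))
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        off = ~np.eye(10, dtype=bool)
        prev = adjacency_from_correlation(cor, beta=1)[off]
        for beta in (2, 5, 10, 20):
            cur = adjacency_from_correlation(cor, beta=beta)[off]
            assert (cur <= prev + 1e-15).all()
            prev = cur


class TestTopologicalOverlap:
    def test_two_gene_full_edge(self):
        A = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert topological_overlap(A)[0, 1] == pytest.approx(1.0)

    def test_three_gene_half_adjacency(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert topological_overlap(A)[0, 1] == pytest.approx(0.5)

    def test_empty_network(self):
        A = np.eye(4)
        tom = topological_overlap(A)
        off = ~np.eye(4, dtype=bool)
        assert (tom[off] == 0).all()

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 25))
            A = rng.uniform(0, 1, size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(
                topological_overlap(A), naive_tom(A), atol=1e-12
            )

    def test_entries_bounded_by_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            A = rng.uniform(0, 1, size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            assert (topological_overlap(A) <= 1.0 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(A)


class TestUpgma:
    def test_three_point_trace(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        Z = average_linkage_dendrogram(D)
        np.testing.assert_allclose(Z[:, 2], [0.1, 0.9])

    def test_identical_points_merge_at_zero(self):
        D = np.zeros((4, 4))
        Z = average_linkage_dendrogram(D)
        np.testing.assert_allclose(Z[:, 2], 0.0)

    def test_matches_naive_upgma(self, rng):
        D = rng.uniform(0.1, 1.0, size=(10, 10))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = average_linkage_dendrogram(D)
        np.testing.assert_allclose(np.sort(Z[:, 2]), naive_upgma_heights(D), atol=1e-10)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            average_linkage_dendrogram(D)


class TestCutModules:
    def test_cut_above_root_gives_one_cluster(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        Z = average_linkage_dendrogram(D)
        ms = cut_modules(Z, ["a", "b", "c"], cut_height=0.99, min_module_size=1)
        assert ms.n_modules == 1 and set(ms.assignment) == {"turquoise"}

    def test_cut_at_zero_all_unassigned(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        Z = average_linkage_dendrogram(D)
        ms = cut_modules(Z, ["a", "b", "c"], cut_height=0.0, min_module_size=2)
        assert set(ms.assignment) == {"unassigned"}

    def test_planted_two_block_network_recovered(self, rng):
        """Two dense blocks with weak cross edges split into exactly two
        modules matching the planted labels (ARI = 1)."""
        n = 40
        A = np.full((n, n), 0.01)
        A[:20, :20] = 0.6
        A[20:, 20:] = 0.6
        A += rng.uniform(0, 0.01, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = topological_overlap(A)
        Z = average_linkage_dendrogram(1 - tom)
        ms = cut_modules(Z, [f"g{i}" for i in range(n)], cut_height=0.6, min_module_size=5)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, ms.assignment.to_numpy()) == 1.0


class TestEigengene:
    def test_coherent_module_explains_everything(self):
        profile = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        X = pd.DataFrame(
            [profile, profile * 3 + 1, profile * 0.5 - 2],
            index=["g1", "g2", "g3"],
            columns=list("abcde"),
        )
        eig = module_eigengene(X, ["g1", "g2", "g3"], "m")
        assert eig.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(np.abs(eig.v1), np.abs(z / np.linalg.norm(z)), atol=1e-12)

    def test_sign_convention_positive_with_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 9)))
        X.index = [f"g{i}" for i in range(6)]
        eig = module_eigengene(X, X.index, "m")
        Z = ((X.T - X.mean(axis=1)) / X.std(axis=1)).T
        assert float(eig.v1 @ Z.mean(axis=0)) >= 0

    def test_antagonistic_pair(self):
        x = np.array([1.0, 2.0, 4.0, 0.0])
        X = pd.DataFrame([x, -x], index=["g1", "g2"], columns=list("abcd"))
        eig = module_eigengene(X, ["g1", "g2"], "m")
        assert eig.variance_explained == pytest.approx(1.0)

    def test_matches_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 12)))
        X.index = [f"g{i}" for i in range(8)]
        eig = module_eigengene(X, X.index, "m")
        Z = ((X.T - X.mean(axis=1)) / X.std(axis=1)).T.to_numpy()
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        lead = evecs[:, -1]
        np.testing.assert_allclose(np.abs(eig.v1), np.abs(lead), atol=1e-10)
        assert eig.variance_explained == pytest.approx(evals[-1] / evals.sum())

    def test_singleton_module_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 5)), index=["g1", "g2", "g3"])
        with pytest.raises(ValueError):
            module_eigengene(X, ["g1"], "m")


class TestKruskalWallis:
    def test_hand_computed_statistic(self):
        h, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert h == pytest.approx(2.4)

    def test_all_identical_values(self):
        h, p = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert (h, p) == (0.0, 1.0)

    def test_null_p_distribution_roughly_uniform(self, rng):
        """Permuting labels under the null gives ~uniform p-values."""
        values = rng.normal(size=24)
        ps = []
        for _ in range(300):
            groups = rng.permutation(["a"] * 12 + ["b"] * 12)
            ps.append(kruskal_wallis(values, groups)[1])
        ps = np.array(ps)
        # coarse uniformity: KS test should not reject wildly
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2], ["a", "a"])


class TestCoexpressionModulesEstimator:
    def test_sklearn_params_roundtrip(self):
        est = CoexpressionModules(beta=6, cut_height=0.9, min_module_size=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_recovers_planted_blocks(self, small_synthetic):
        cfg, datasets, truth = small_synthetic
        ds = datasets["A"]
        labels = truth.labels["A"]
        module_genes = labels.index[labels != "background"]
        expr = np.log2(ds.tpm + 1.0).loc[module_genes]
        est = CoexpressionModules().fit(expr)
        ari = adjusted_rand_score(labels.loc[module_genes], est.module_labels_)
        assert ari > 0.9

    def test_labels_align_with_module_set(self, small_synthetic):
        cfg, datasets, truth = small_synthetic
        expr = np.log2(datasets["A"].tpm + 1.0).iloc[:120]
        est = CoexpressionModules(min_module_size=10)
        labels = est.fit_predict(expr)
        assert len(labels) == 120
        assert set(est.module_labels_) >= {"unassigned"} or est.module_set_.n_modules > 0

    def test_newick_export_round_trips(self, rng):
        from skbio.tree import TreeNode
        import io

        X = pd.DataFrame(rng.normal(size=(12, 8)), index=[f"g{i}" for i in range(12)])
        est = CoexpressionModules(min_module_size=2).fit(X)
        tree = TreeNode.read(io.StringIO(linkage_to_newick(est.linkage_, est.genes_)))
        assert {t.name for t in tree.tips()} == set(est.genes_)
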