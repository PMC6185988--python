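"""Diversity: Shannon closed forms, weighted UniFrac against closed forms,
reductions and scikit-bio, jackknife rarefaction, PCoA, paired comparisons."""

import numpy as np
import pytest
from io import StringIO

from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as skbio_pcoa
from scipy import stats

import mbperm as M
from mbperm.diversity import DistanceMatrix
from mbperm.tables import TableError


def _tree(nwk):
    return TreeNode.read(StringIO(nwk))


class TestShannon:
    def test_closed_forms(self):
        assert M.shannon(np.ones(16)) == pytest.approx(4.0)
        assert M.shannon([0, 5, 0]) == 0.0
        assert M.shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_base_parameter(self):
        assert M.shannon(np.ones(10), base=np.e) == pytest.approx(np.log(10))

    def test_permutation_invariance_and_uniform_maximum(self):
        rng = np.random.default_rng(0)
        v = rng.random(12)
        assert M.shannon(v) == pytest.approx(M.shannon(v[::-1]))
        assert M.shannon(v) <= M.shannon(np.ones(12)) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            M.shannon([0.0, 0.0])


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = _tree("(A:1,B:2);")
        for normalized in (True, False):
            assert M.weighted_unifrac([0.3, 0.7], [0.3, 0.7], tree, ["A", "B"],
                                      normalized=normalized) == 0.0

    def test_two_leaf_disjoint_closed_form(self):
        tree = _tree("(A:1.0,B:1.0);")
        raw = M.weighted_unifrac([1, 0], [0, 1], tree, ["A", "B"], normalized=False)
        norm = M.weighted_unifrac([1, 0], [0, 1], tree, ["A", "B"], normalized=True)
        assert raw == pytest.approx(2.0)
        assert norm == pytest.approx(1.0)

    def test_star_tree_reduces_to_l1(self):
        """Unit-branch star topology: raw weighted UniFrac equals the
        taxon-wise L1 distance (tree-free oracle)."""
        taxa = ["A", "B", "C", "D", "E"]
        tree = _tree("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(1)
        a, b = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        raw = M.weighted_unifrac(a, b, tree, taxa, normalized=False)
        assert raw == pytest.approx(np.abs(a - b).sum())

    def test_matches_scikit_bio(self, random_tree16):
        taxa, tree = random_tree16
        rng = np.random.default_rng(2)
        counts = rng.multinomial(50_000, rng.dirichlet(np.ones(16)), size=5)
        P = counts / counts.sum(axis=1, keepdims=True)
        ids = [f"s{i}" for i in range(5)]
        tab = M.AbundanceTable(taxa, ids, P.T, mode="proportions")
        for normalized in (False, True):
            mine = M.beta_distance_matrix(tab, tree, normalized=normalized)
            ref = beta_diversity("weighted_unifrac", counts, ids=ids, taxa=taxa,
                                 tree=tree, normalized=normalized)
            np.testing.assert_allclose(mine.values, ref.data, atol=1e-12)

    def test_branch_rescaling(self, random_tree16):
        """Scaling all branch lengths by c scales raw UniFrac by c and
        leaves the normalized variant unchanged."""
        taxa, tree = random_tree16
        rng = np.random.default_rng(3)
        a, b = rng.dirichlet(np.ones(16)), rng.dirichlet(np.ones(16))
        raw = M.weighted_unifrac(a, b, tree, taxa, normalized=False)
        norm = M.weighted_unifrac(a, b, tree, taxa, normalized=True)
        scaled = tree.copy()
        for nd in scaled.postorder(include_self=False):
            nd.length *= 3.5
        assert M.weighted_unifrac(a, b, scaled, taxa, normalized=False) == \
            pytest.approx(3.5 * raw)
        assert M.weighted_unifrac(a, b, scaled, taxa, normalized=True) == \
            pytest.approx(norm)
        assert 0 <= norm <= 1

    def test_missing_leaf_rejected(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(TableError, match="C"):
            M.weighted_unifrac([0.5, 0.5], [0.5, 0.5], tree, ["A", "C"])


class TestBetaMatrix:
    def test_matrix_consistent_with_pairwise(self, random_tree16):
        taxa, tree = random_tree16
        rng = np.random.default_rng(4)
        P = rng.dirichlet(np.ones(16), size=4).T
        ids = ["w", "x", "y", "z"]
        tab = M.AbundanceTable(taxa, ids, P, mode="proportions")
        dm = M.beta_distance_matrix(tab, tree)
        assert dm.values.shape == (4, 4)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
        for i in range(4):
            for j in range(i + 1, 4):
                assert dm.values[i, j] == pytest.approx(
                    M.weighted_unifrac(P[:, i], P[:, j], tree, taxa)
                )

    def test_duplicated_sample_zero_distance(self, random_tree16):
        taxa, tree = random_tree16
        rng = np.random.default_rng(5)
        v = rng.dirichlet(np.ones(16))
        tab = M.AbundanceTable(taxa, ["a", "b"], np.column_stack([v, v]),
                               mode="proportions")
        dm = M.beta_distance_matrix(tab, tree)
        assert dm.values[0, 1] == 0.0


class TestJackknife:
    def _counts(self, seed=6, depth=10_000, n=4, k=16):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(depth, rng.dirichlet(np.ones(k)), size=n).T
        taxa = [f"T{i:03d}" for i in range(k)]
        ids = [f"s{i}" for i in range(n)]
        return M.AbundanceTable(taxa, ids, counts, mode="counts"), taxa

    def test_fraction_one_reproduces_full_matrix(self, random_tree16):
        taxa16, tree = random_tree16
        counts, _ = self._counts()
        full = M.beta_distance_matrix(M.normalize_to_proportions(counts), tree)
        mean, reps = M.jackknife_beta(counts, tree, fraction=1.0, reps=3, seed=0)
        for dm in reps:
            np.testing.assert_array_equal(dm.values, full.values)
        np.testing.assert_array_equal(mean.values, full.values)

    def test_seed_determinism(self, random_tree16):
        _, tree = random_tree16
        counts, _ = self._counts()
        m1, _ = M.jackknife_beta(counts, tree, fraction=0.05, reps=5, seed=3)
        m2, _ = M.jackknife_beta(counts, tree, fraction=0.05, reps=5, seed=3)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_deep_subsampling_consistency(self, random_tree16):
        """At high depth, 1% subsampling perturbs the beta matrix little."""
        _, tree = random_tree16
        counts, _ = self._counts(depth=10**6)
        full = M.beta_distance_matrix(M.normalize_to_proportions(counts), tree)
        mean, _ = M.jackknife_beta(counts, tree, fraction=0.01, reps=10, seed=1)
        assert np.max(np.abs(mean.values - full.values)) < 0.05

    def test_zero_subsample_rejected(self, random_tree16):
        _, tree = random_tree16
        counts, _ = self._counts(depth=50)
        with pytest.raises(TableError, match="fraction"):
            M.jackknife_beta(counts, tree, fraction=0.01, reps=2, seed=0)


class TestPcoa:
    def test_colinear_points(self):
        D = DistanceMatrix(["a", "b", "c"],
                           [[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = M.pcoa(D, k=2)
        axis1 = res.coordinates["PC1"].to_numpy()
        assert np.abs(axis1) == pytest.approx([1, 0, 1], abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_distances(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = M.pcoa(D, k=2)
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0)

    def test_euclidean_embedding_recovered(self):
        """Gower: for a Euclidean-embeddable matrix the pairwise coordinate
        distances reproduce the input within 1e-8."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        res = M.pcoa(dm, k=5)
        C = res.coordinates.to_numpy()
        rec = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
        np.testing.assert_allclose(rec, D, atol=1e-8)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_matches_scikit_bio(self, random_tree16):
        taxa, tree = random_tree16
        rng = np.random.default_rng(8)
        P = rng.dirichlet(np.ones(16), size=5).T
        tab = M.AbundanceTable(taxa, [f"s{i}" for i in range(5)], P,
                               mode="proportions")
        dm = M.beta_distance_matrix(tab, tree)
        mine = M.pcoa(dm, k=3)
        ref = skbio_pcoa(dm.values, method="eigh")
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues)[::-1][:3], ref.eigvals.values[:3], atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.values[:, :3]),
            atol=1e-8,
        )

    def test_k_too_large(self):
        D = DistanceMatrix(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            M.pcoa(D, k=2)


class TestPairedBetaComparison:
    def _design(self, n):
        return M.PairedDesign.from_pairs(
            {f"s{i}": (f"s{i}_pre", f"s{i}_post") for i in range(n)}
        )

    def test_pair_counting_n8(self):
        n = 8
        design = self._design(n)
        ids = design.all_sample_ids()
        rng = np.random.default_rng(9)
        X = rng.random((len(ids), 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(ids, D)
        within, between, p = M.within_vs_between_beta_test(dm, design)
        assert len(within) == 8
        assert len(between) == 28
        assert 0 <= p <= 1

    def test_extreme_separation_minimal_p(self):
        n = 4
        design = self._design(n)
        ids = design.all_sample_ids()
        D = np.ones((2 * n, 2 * n))
        np.fill_diagonal(D, 0)
        for i, s in enumerate(design.subjects):
            a = ids.index(design.pre_sample[s])
            b = ids.index(design.post_sample[s])
            D[a, b] = D[b, a] = 0.0
        # make pre-pre distances 1, within-pair 0; p = exact rank-sum floor
        dm = DistanceMatrix(ids, D)
        within, between, p = M.within_vs_between_beta_test(dm, design)
        assert np.all(within == 0) and np.all(between == 1)
        ref = stats.mannwhitneyu(within, between, alternative="less").pvalue
        assert p == pytest.approx(ref)
        assert p < 0.01

    def test_null_calibration(self):
        """With exchangeable within/between values the one-sided p is
        roughly uniform: its mean over replicates is near 0.5."""
        n = 6
        design = self._design(n)
        ids = design.all_sample_ids()
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(2 * n, 3))
            D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            np.fill_diagonal(D, 0)
            dm = DistanceMatrix(ids, D)
            _, _, p = M.within_vs_between_beta_test(dm, design)
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) < 0.1


class TestAlphaCompare:
    def test_identical_vectors_convention(self):
        assert M.alpha_compare([1, 2, 3], [1, 2, 3]) == 1.0

    def test_strict_increase_minimal_exact_p(self):
        pre = np.arange(8, dtype=float)
        post = pre + 1.0
        # exact two-sided signed-rank floor at n=8 is 2/2^8
        assert M.alpha_compare(pre, post) == pytest.approx(2 / 256)

    def test_matches_exact_enumeration(self):
        """Small mixed sample against a brute-force sign-flip enumeration of
        the signed-rank statistic."""
        rng = np.random.default_rng(11)
        pre = rng.random(7)
        post = pre + rng.normal(0, 0.5, 7)
        d = post - pre
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        ws = []
        for mask in range(1 << n):
            signs = [(mask >> i) & 1 for i in range(n)]
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.asarray(ws, dtype=float)
        mu = n * (n + 1) / 4
        p_exact = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
        assert M.alpha_compare(pre, post) == pytest.approx(p_exact)
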