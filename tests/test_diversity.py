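import io

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from gutmediate.containers import FeatureTable, FormatError, PhyloTree
from gutmediate.diversity import alpha_diversity, canberra, permanova, unifrac


def counts_table(arr, taxa=None, samples=None):
    arr = np.asarray(arr)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=taxa, columns=samples), "counts")


class TestAlpha:
    def test_chao1_bias_corrected_hand_value(self):
        # counts (1,1,2,5): S_obs=4, F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
        res = alpha_diversity(counts_table([[1], [1], [2], [5]]))
        assert res.values.iloc[0]["observed"] == 4
        assert res.values.iloc[0]["chao1"] == pytest.approx(4.5)

    def test_shannon_simpson_symmetric_pair(self):
        res = alpha_diversity(counts_table([[5], [5]]))
        assert res.values.iloc[0]["shannon"] == pytest.approx(np.log(2))
        assert res.values.iloc[0]["simpson"] == pytest.approx(0.5)

    def test_single_taxon_zero_diversity(self):
        res = alpha_diversity(counts_table([[7], [0]]))
        assert res.values.iloc[0]["shannon"] == 0.0
        assert res.values.iloc[0]["simpson"] == 0.0

    def test_chao1_equals_observed_without_singletons(self):
        res = alpha_diversity(counts_table([[2], [3], [5]]))
        assert res.values.iloc[0]["chao1"] == res.values.iloc[0]["observed"]

    def test_non_integer_counts_rejected_for_chao1(self):
        t = counts_table([[1.5], [2.0]])
        with pytest.raises(FormatError, match="integer"):
            alpha_diversity(t)

    def test_anova_group_p(self):
        rng = np.random.default_rng(1)
        # zeros included so richness actually varies between samples
        t = counts_table(rng.integers(0, 6, size=(20, 12)))
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=t.sample_ids)
        res = alpha_diversity(t, groups=groups)
        assert set(res.anova_p) == {"observed", "chao1", "shannon", "simpson"}
        assert all(0 <= p <= 1 for p in res.anova_p.values())


class TestCanberra:
    def ra(self, cols):
        arr = np.asarray(cols, dtype=float).T
        arr = arr / arr.sum(axis=0)
        return FeatureTable(pd.DataFrame(arr, columns=[f"s{j}" for j in range(arr.shape[1])]),
                            "relative_abundance")

    def test_identical_samples_zero(self):
        dm = canberra(self.ra([[0.4, 0.6], [0.4, 0.6]]))
        assert dm["s0", "s1"] == 0.0

    def test_disjoint_support(self):
        dm = canberra(self.ra([[1, 0], [0, 1]]))
        assert dm["s0", "s1"] == pytest.approx(2.0)

    def test_hand_value(self):
        dm = canberra(self.ra([[0.4, 0.6], [0.6, 0.4]]))
        assert dm["s0", "s1"] == pytest.approx(0.4)

    def test_symmetry_zero_diagonal_random(self):
        rng = np.random.default_rng(3)
        arr = rng.random((10, 6)) + 0.01
        arr /= arr.sum(axis=0)
        dm = canberra(FeatureTable(pd.DataFrame(arr, columns=[f"s{j}" for j in range(6)]),
                                   "relative_abundance"))
        d = dm.data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


TREE4 = "((A:1,B:1):1,(C:1,D:1):1);"


def tree4():
    return PhyloTree(skbio.TreeNode.read(io.StringIO(TREE4)))


class TestUnifrac:
    def test_identical_presence_zero(self):
        t = counts_table([[3, 1], [2, 5], [0, 0], [0, 0]], taxa=list("ABCD"))
        dm = unifrac(t, tree4(), weighted=False)
        assert dm["s0", "s1"] == pytest.approx(0.0)

    def test_disjoint_subtrees_one(self):
        t = counts_table([[1, 0], [1, 0], [0, 1], [0, 1]], taxa=list("ABCD"))
        dm = unifrac(t, tree4(), weighted=False)
        assert dm["s0", "s1"] == pytest.approx(1.0)

    def test_weighted_identical_abundance_zero(self):
        t = counts_table([[2, 2], [1, 1], [4, 4], [3, 3]], taxa=list("ABCD"))
        dm = unifrac(t, tree4(), weighted=True)
        assert dm["s0", "s1"] == pytest.approx(0.0)

    def test_unweighted_presence_only(self):
        t1 = counts_table([[1, 0], [1, 0], [0, 2], [0, 3]], taxa=list("ABCD"))
        t2 = counts_table([[9, 0], [4, 0], [0, 1], [0, 7]], taxa=list("ABCD"))
        d1 = unifrac(t1, tree4(), weighted=False)["s0", "s1"]
        d2 = unifrac(t2, tree4(), weighted=False)["s0", "s1"]
        assert d1 == pytest.approx(d2)

    def test_missing_taxon_listed(self):
        t = counts_table([[1], [1]], taxa=["A", "Z"])
        with pytest.raises(FormatError, match="Z"):
            unifrac(t, tree4())


def clustered_distance(seed=0, spread=0.1, sep=5.0, n=4):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, spread, (n, 3)), rng.normal(sep, spread, (n, 3))])
    ids = [f"s{i}" for i in range(2 * n)]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


class TestPermanova:
    def test_separated_clusters_significant(self):
        dm = clustered_distance()
        res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=1)
        assert res.p_value <= 0.05

    def test_statistic_matches_skbio(self):
        dm = clustered_distance(seed=2, spread=1.0, sep=1.0)
        ours = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0).statistic
        theirs = float(skbio_permanova(dm, ["a"] * 4 + ["b"] * 4,
                                       permutations=99)["test statistic"])
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_exhaustive_enumeration_agreement(self):
        # n=6: exact p by enumerating all C(6,3)=20 label arrangements
        from itertools import combinations
        dm = clustered_distance(seed=4, spread=1.5, sep=2.0, n=3)
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, labels, n_perm=4999, seed=7)
        from gutmediate.diversity import _pseudo_f
        d2 = dm.data ** 2
        f_obs = _pseudo_f(d2, np.array([0, 0, 0, 1, 1, 1]), np.array([0, 1]))
        fs = []
        for grp in combinations(range(6), 3):
            lab = np.ones(6, dtype=int)
            lab[list(grp)] = 0
            fs.append(_pseudo_f(d2, lab, np.array([0, 1])))
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(exact_p, abs=0.03)

    def test_null_rejection_rate_nominal(self):
        # random labels w.r.t. distances: rejection at 0.05 stays near 0.05
        rng = np.random.default_rng(10)
        rej = 0
        reps = 200
        for r in range(reps):
            pts = rng.normal(size=(16, 3))
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[f"s{i}" for i in range(16)])
            res = permanova(dm, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=r)
            rej += res.p_value <= 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.035)

    def test_label_name_invariance(self):
        dm = clustered_distance(seed=6, spread=1.0, sep=1.0)
        p1 = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=3).p_value
        p2 = permanova(dm, ["x"] * 4 + ["y"] * 4, n_perm=99, seed=3).p_value
        assert p1 == p2

    def test_single_group_rejected(self):
        dm = clustered_distance()
        with pytest.raises(FormatError):
            permanova(dm, ["a"] * 8, n_perm=9, seed=0)

    def test_p_bounded_below(self):
        dm = clustered_distance()
        res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100
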