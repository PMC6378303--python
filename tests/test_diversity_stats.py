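import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from nichebreadth.community_io import OTUTable
from nichebreadth.diversity_stats import (alpha_diversity, anosim, bray_curtis,
                                          group_compare, pcoa)


def _table(counts):
    counts = np.asarray(counts)
    return OTUTable([f"t{i}" for i in range(counts.shape[0])],
                    [f"s{j}" for j in range(counts.shape[1])], counts)


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        a = alpha_diversity(_table([[5], [5], [5], [5]])).iloc[0]
        assert a["observed"] == 4
        assert a["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert a["simpson"] == pytest.approx(0.75, abs=1e-12)
        assert a["chao1"] == pytest.approx(4.0)

    def test_bias_corrected_chao1(self):
        # S=10 with 4 singletons and 2 doubletons: 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 7, 9, 11]
        a = alpha_diversity(_table([[c] for c in counts])).iloc[0]
        assert a["chao1"] == pytest.approx(12.0)

    def test_single_taxon_degenerate(self):
        a = alpha_diversity(_table([[9], [0]])).iloc[0]
        assert a["observed"] == 1
        assert a["shannon"] == 0.0 and a["simpson"] == 0.0

    def test_estimator_inequalities(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 9, size=(40, 6)) + (rng.random((40, 6)) < .2))
        a = alpha_diversity(t)
        assert np.all(a["chao1"] >= a["observed"] - 1e-9)
        assert np.all(a["shannon"] <= np.log(a["observed"]) + 1e-12)
        assert np.all((a["simpson"] >= 0) & (a["simpson"] < 1))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            alpha_diversity(_table([[3, 0], [1, 0]]))


class TestBrayCurtis:
    def test_identity_maximum_and_hand_value(self):
        t = _table(np.array([[2, 1, 2, 0],
                             [0, 1, 0, 0],
                             [0, 0, 0, 7]]))
        dm = bray_curtis(t)
        assert dm["s0", "s2"] == 0.0                       # identical samples
        assert dm["s0", "s3"] == 1.0                       # disjoint samples
        assert dm["s0", "s1"] == pytest.approx(0.5)        # (2,0,0) vs (1,1,0)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 30, size=(25, 8)) + 1)
        dm = bray_curtis(t)
        d = np.asarray(dm.data)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        assert d.max() <= 1.0 and d.min() >= 0.0


class TestPCoA:
    def test_reconstructs_euclidean_configuration(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [6.0, 5.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = pcoa(dm)
        again = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(again, dm.data, atol=1e-8)

    def test_coincident_samples_share_coordinates(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = pcoa(dm)
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[1], atol=1e-9)

    def test_trace_identity_for_euclidean_input(self):
        pts = np.random.default_rng(3).normal(size=(6, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = pcoa(dm)
        a = -0.5 * d ** 2
        b = (a - a.mean(axis=0, keepdims=True)
             - a.mean(axis=1, keepdims=True) + a.mean())
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), rel=1e-8)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 40, size=(30, 9)) + 1)
        res = pcoa(bray_curtis(t))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.array([[0, 1.0], [0.5, 0]]), ids=["a", "b"])


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # two tight clusters far apart: all between > all within
        pts = np.vstack([np.random.default_rng(0).normal(0, .1, (4, 2)),
                         np.random.default_rng(1).normal(50, .1, (4, 2))])
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(8)])
        r, p = anosim(dm, ["A"] * 4 + ["B"] * 4, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100, abs=0.05)

    def test_minimum_p_with_999_perms(self):
        pts = np.vstack([np.zeros((5, 2)), np.full((5, 2), 9.0)])
        pts += np.random.default_rng(2).normal(0, .01, pts.shape)
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(10)])
        _, p = anosim(dm, ["A"] * 5 + ["B"] * 5, n_perm=999, seed=0)
        assert p >= 1 / 1000

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(12)])
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        r, _ = anosim(dm, groups, n_perm=0 or 9, seed=0)
        sk = sk_anosim(dm, grouping=groups, permutations=9)
        assert r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        groups = ["A"] * 5 + ["B"] * 5
        r1, _ = anosim(DistanceMatrix(d, ids=[str(i) for i in range(10)]),
                       groups, n_perm=9, seed=1)
        r2, _ = anosim(DistanceMatrix(np.sqrt(d), ids=[str(i) for i in range(10)]),
                       groups, n_perm=9, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_pairwise_mode_covers_group_pairs(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(12)])
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        _, _, pw = anosim(dm, groups, n_perm=49, seed=0, pairwise=True)
        assert len(pw) == 3
        assert set(map(tuple, pw[["group1", "group2"]].to_numpy())) == {
            ("A", "B"), ("A", "C"), ("B", "C")}

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.random.default_rng(0)
                                             .normal(size=(5, 2)))),
                            ids=list("abcde"))
        with pytest.raises(ValueError, match="size 1"):
            anosim(dm, ["A", "A", "B", "B", "C"], n_perm=9)


class TestGroupCompare:
    def test_identical_data_gives_f_zero(self):
        f, p, letters = group_compare([3.0] * 6, ["A"] * 3 + ["B"] * 3)
        assert f == 0.0 and len(set(letters.values())) == 1

    def test_two_groups_f_equals_t_squared(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        f, p, _ = group_compare(np.concatenate([a, b]),
                                ["A"] * 8 + ["B"] * 8)
        t = ttest_ind(a, b).statistic
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_indistinguishable_groups_share_a_letter(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, 15)
        _, _, letters = group_compare(vals, ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        shared = set.intersection(*[set(v) for v in letters.values()])
        assert shared  # no significant Tukey pair -> one common letter

    def test_separated_groups_get_distinct_letters(self):
        vals = np.concatenate([np.random.default_rng(1).normal(0, .1, 5),
                               np.random.default_rng(2).normal(10, .1, 5),
                               np.random.default_rng(3).normal(20, .1, 5)])
        _, p, letters = group_compare(vals, ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        assert p < 0.001
        assert len({letters[g] for g in "ABC"}) == 3
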