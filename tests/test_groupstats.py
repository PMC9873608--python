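import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from metacodon.distances import DistanceMatrix, within_between_split
from metacodon.groupstats import (
    anosim,
    ci_permutation_test,
    clustering_index,
    compare_within_between,
    ordination,
)
from metacodon.profiles import FrequencyProfile


def _dm(data, ids=None):
    data = np.asarray(data, float)
    ids = ids or [f"s{i}" for i in range(len(data))]
    return DistanceMatrix(ids, data, "EU")


def _separated_matrix(n_per_group=3, within=1.0, between=10.0):
    n = 2 * n_per_group
    d = np.full((n, n), between)
    for g in (range(n_per_group), range(n_per_group, n)):
        for i in g:
            for j in g:
                d[i, j] = within
    np.fill_diagonal(d, 0)
    return _dm(d)


def _labels(n_per_group=3):
    return {f"s{i}": ("A" if i < n_per_group else "B") for i in range(2 * n_per_group)}


def _anosim_r_oracle(dist, labels_list):
    """Independent evaluation of Clarke's R from first principles."""
    n = len(labels_list)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = rankdata([dist[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs)
              if labels_list[i] == labels_list[j]]
    between = [r for r, (i, j) in zip(ranks, pairs)
               if labels_list[i] != labels_list[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        res = anosim(_separated_matrix(), _labels(), n_permutations=200, seed=0)
        assert res.R == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_all_equal_distances_give_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = anosim(_dm(d), _labels(), n_permutations=100, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_matches_bruteforce_oracle_and_exhaustive_p(self):
        rng = np.random.default_rng(42)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = _labels()
        res = anosim(_dm(d), labels, n_permutations=20_000, seed=1)
        lab_list = [labels[f"s{i}"] for i in range(6)]
        assert res.R == pytest.approx(_anosim_r_oracle(d, lab_list), abs=1e-12)
        # exhaustive P over all distinct balanced relabelings
        r_obs = res.R
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = ["A" if i in combo else "B" for i in range(6)]
            total += 1
            if _anosim_r_oracle(d, perm) >= r_obs - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / total, abs=0.02)

    def test_agrees_with_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        x = rng.random((8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = anosim(_dm(d), labels, n_permutations=999, seed=3)
        sk = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d, [f"s{i}" for i in range(8)]),
            [labels[f"s{i}"] for i in range(8)], permutations=0)
        assert res.R == pytest.approx(float(sk["test statistic"]), abs=1e-12)

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = _labels()
        perm = [3, 1, 4, 0, 5, 2]
        d2 = d[np.ix_(perm, perm)]
        ids2 = [f"s{i}" for i in perm]
        res1 = anosim(_dm(d), labels, 10, seed=0)
        res2 = anosim(DistanceMatrix(ids2, d2, "EU"), labels, 10, seed=0)
        assert res1.R == pytest.approx(res2.R, abs=1e-12)

    @pytest.mark.parametrize("labels", [
        {f"s{i}": "A" for i in range(6)},                      # one group
        {f"s{i}": ("A" if i else "B") for i in range(6)},      # singleton group
    ])
    def test_degenerate_groups_rejected(self, labels):
        with pytest.raises(ValueError):
            anosim(_separated_matrix(), labels, 10, seed=0)


class TestClusteringIndex:
    def test_ratio_arithmetic(self):
        ci = clustering_index(_separated_matrix(within=1.0, between=2.0),
                              _labels(), "A")
        assert ci == pytest.approx(0.5)

    def test_all_equal_distances_give_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        assert clustering_index(_dm(d), _labels(), "A") == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        d = np.array([
            [0, 1, 2, 3, 4],
            [1, 0, 5, 6, 7],
            [2, 5, 0, 8, 9],
            [3, 6, 8, 0, 1],
            [4, 7, 9, 1, 0]], float)
        labels = {"s0": "X", "s1": "X", "s2": "X", "s3": "Y", "s4": "Y"}
        # within X: 1,2,5 -> 8/3; X->Y: 3,4,6,7,8,9 -> 37/6
        assert clustering_index(_dm(d), labels, "X") == pytest.approx(
            (8 / 3) / (37 / 6))

    def test_small_group_is_error(self):
        labels = {"s0": "X", "s1": "Y", "s2": "Y", "s3": "Y", "s4": "Y",
                  "s5": "Y"}
        with pytest.raises(ValueError, match="X"):
            clustering_index(_separated_matrix(), labels, "X")


class TestCiPermutationTest:
    def test_strong_clustering_gives_p_zero(self):
        res = ci_permutation_test(_separated_matrix(within=0.1, between=50.0),
                                  _labels(), "A", n_random=100, seed=0)
        assert res.ci < 1
        assert res.p == 0.0

    def test_p_granularity(self):
        res = ci_permutation_test(_separated_matrix(), _labels(), "A",
                                  n_random=100, seed=1)
        assert res.p * 100 == pytest.approx(round(res.p * 100))


class TestOrdination:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        base = np.array([0.5, 0.3, 0.2])
        direction = np.array([0.1, -0.05, -0.05])
        profs = [FrequencyProfile(f"s{i}", "absCUF",
                                  pd.Series(base + i * direction,
                                            index=list("xyz")))
                 for i in range(4)]
        summary = ordination(profs)
        assert summary.variance_explained[0] == pytest.approx(1.0)

    def test_variance_fractions_match_eigendecomposition(self, rng):
        x = rng.random((4, 3))
        frame = pd.DataFrame(x, index=list("abcd"), columns=list("xyz"))
        summary = ordination(frame)
        cov = np.cov(x, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = eig[eig > eig[0] * 1e-12]
        assert np.allclose(summary.variance_explained, eig / eig.sum(), atol=1e-10)

    def test_duplicated_dataset_has_same_fractions(self, rng):
        x = rng.random((5, 4))
        f1 = pd.DataFrame(x, index=[f"a{i}" for i in range(5)])
        f2 = pd.DataFrame(np.vstack([x, x]),
                          index=[f"b{i}" for i in range(10)])
        assert np.allclose(ordination(f1).variance_explained,
                           ordination(f2).variance_explained, atol=1e-10)

    def test_constant_profiles_rejected(self):
        frame = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        with pytest.raises(ValueError):
            ordination(frame)


class TestCompareWithinBetween:
    def test_null_behaviour(self, rng):
        d = rng.random((20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        split = within_between_split(_dm(d, list(labels)), labels)
        report = compare_within_between(split)
        assert report.p_raw > 0.05

    def test_complete_separation_and_bonferroni(self):
        split = within_between_split(_separated_matrix(4), _labels(4))
        r1 = compare_within_between(split, n_groups_tested=1)
        r7 = compare_within_between(split, n_groups_tested=7)
        assert r1.p_raw < 1e-3
        assert r7.p_adjusted == pytest.approx(min(1.0, r1.p_raw * 7))
        assert r1.mean_within < r1.mean_between
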