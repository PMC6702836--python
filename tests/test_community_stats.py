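import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import squareform

from ticklink.community_stats import (
    DistanceMatrix,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    observed_richness,
    pca_ordination,
    rarefaction_expected,
    shannon_diversity,
    venn_partition,
)


class TestRarefaction:
    def test_two_taxa_depth_one(self):
        assert rarefaction_expected([2, 2], 1) == pytest.approx(1.0)

    def test_enumeration_oracle_small(self):
        # counts [3,1], depth 2: enumerate all C(4,2)=6 subsets
        assert rarefaction_expected([3, 1], 2) == pytest.approx(1.5)

    def test_depth_equals_total_gives_richness(self):
        counts = [5, 0, 3, 1]
        assert rarefaction_expected(counts, 9) == pytest.approx(observed_richness(counts))

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_expected([2, 2], 5)

    def test_monte_carlo_agreement(self, rng):
        counts = np.array([50, 30, 10, 5, 3, 1, 1])
        depth = 40
        expected = rarefaction_expected(counts, depth)
        pool = np.repeat(np.arange(len(counts)), counts)
        n_rep = 10_000
        richness = np.empty(n_rep)
        for i in range(n_rep):
            sub = rng.choice(pool, size=depth, replace=False)
            richness[i] = len(np.unique(sub))
        se = richness.std(ddof=1) / math.sqrt(n_rep)
        assert abs(richness.mean() - expected) <= 3 * se


class TestAlphaDiversity:
    def test_uniform_is_log_richness(self):
        assert shannon_diversity([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon_diversity([5]) == 0.0

    def test_hand_value(self):
        # p = (0.75, 0.25)
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert shannon_diversity([3, 1]) == pytest.approx(h)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0, 0])


class TestBrayCurtis:
    def test_disjoint_supports(self):
        assert bray_curtis([1, 0], [0, 2]) == pytest.approx(1.0)

    def test_identical_vectors(self):
        assert bray_curtis([3, 4], [3, 4]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            u = rng.integers(0, 20, size=8).astype(float)
            v = rng.integers(0, 20, size=8).astype(float)
            if u.sum() + v.sum() == 0:
                continue
            assert bray_curtis(u, v) == pytest.approx(scipy_bc(u, v), abs=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_entries_in_unit_interval(self, rng):
        counts = pd.DataFrame(rng.integers(0, 30, size=(6, 4)).astype(float) + 1,
                              columns=list("abcd"))
        dm = bray_curtis_matrix(counts)
        x = dm.data.to_numpy()
        assert ((x >= 0) & (x <= 1)).all()


def _dm(values, labels):
    return DistanceMatrix(pd.DataFrame(values, index=labels, columns=labels))


class TestAnosim:
    def _separated(self):
        # within distances all < between distances
        labels = list("abcd")
        x = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        return _dm(x, labels), {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}

    def test_perfect_separation_r_one(self):
        dm, groups = self._separated()
        res = anosim(dm, groups, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_all_equal_distances_r_zero(self):
        labels = list("abcd")
        x = np.ones((4, 4)) - np.eye(4)
        res = anosim(_dm(x, labels), {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                     n_perm=99, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_exhaustive_matches_independent_enumeration(self, rng):
        n = 6
        x = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        labels = [f"s{i}" for i in range(n)]
        groups = ["g1"] * 3 + ["g2"] * 3
        res = anosim(_dm(x, labels), groups, n_perm=1000, seed=1)
        assert res.exhaustive

        # independent oracle: naive mid-ranks + itertools over all 20 splits
        def naive_r(assign):
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            d = [x[i, j] for i, j in pairs]
            order = sorted(range(len(d)), key=lambda k: d[k])
            ranks = [0.0] * len(d)
            k = 0
            while k < len(d):
                j = k
                while j + 1 < len(d) and d[order[j + 1]] == d[order[k]]:
                    j += 1
                mid = (k + j) / 2 + 1
                for t in range(k, j + 1):
                    ranks[order[t]] = mid
                k = j + 1
            within = [ranks[t] for t, (i, j) in enumerate(pairs)
                      if assign[i] == assign[j]]
            between = [ranks[t] for t, (i, j) in enumerate(pairs)
                       if assign[i] != assign[j]]
            m = len(pairs)
            return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2)

        r_obs = naive_r(groups)
        assert res.R == pytest.approx(r_obs, abs=1e-12)
        perms = set()
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), 3):
            assign = ["g2"] * n
            for i in combo:
                assign[i] = "g1"
            total += 1
            if naive_r(assign) >= r_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        n = 7
        x = squareform(rng.uniform(0.1, 0.9, size=n * (n - 1) // 2))
        labels = [f"s{i}" for i in range(n)]
        groups = ["g1"] * 3 + ["g2"] * 4
        r1 = anosim(_dm(x, labels), groups, n_perm=50, seed=3).R
        r2 = anosim(_dm(np.sqrt(x), labels), groups, n_perm=50, seed=3).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        n = 8
        x = squareform(rng.uniform(0.05, 1.0, size=n * (n - 1) // 2))
        labels = [f"s{i}" for i in range(n)]
        groups = ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"]
        ours = anosim(_dm(x, labels), groups, n_perm=999, seed=0)
        ref = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(x, ids=labels), groups, permutations=0,
        )
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_all_singletons_rejected(self):
        x = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="no within-group pairs"):
            anosim(_dm(x, list("abc")), {"a": "g1", "b": "g2", "c": "g3"}, n_perm=9)


class TestPCA:
    def test_collinear_samples_single_component(self):
        # samples on a line in feature space
        counts = pd.DataFrame(
            {"S1": [1.0, 2.0], "S2": [2.0, 4.0], "S3": [3.0, 6.0]}
        )
        res = pca_ordination(counts)
        assert res.explained[0] == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self, rng):
        base = rng.uniform(0, 1, size=(5, 3))
        counts = pd.DataFrame(np.hstack([base, base]),
                              columns=["a", "b", "c", "a2", "b2", "c2"])
        res = pca_ordination(counts)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["a2"])

    def test_variances_match_eigendecomposition_oracle(self, rng):
        counts = pd.DataFrame(rng.uniform(0, 1, size=(5, 4)),
                              columns=list("wxyz"))
        res = pca_ordination(counts)
        x = counts.to_numpy().T
        cov = np.cov(x, rowvar=False)  # feature covariance over samples
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, eig[:k], atol=1e-10)
        # scores' covariance diagonal matches eigenvalues
        sc = res.scores.to_numpy()
        assert np.allclose(sc.var(axis=0, ddof=1), res.eigenvalues, atol=1e-10)

    def test_feature_permutation_invariance(self, rng):
        counts = pd.DataFrame(rng.uniform(0, 1, size=(6, 4)), columns=list("abcd"))
        res1 = pca_ordination(counts)
        perm = rng.permutation(len(counts))
        res2 = pca_ordination(counts.iloc[perm])
        assert np.allclose(res1.explained, res2.explained, atol=1e-12)

    def test_sign_convention_largest_loading_positive(self, rng):
        counts = pd.DataFrame(rng.uniform(0, 1, size=(7, 5)))
        res = pca_ordination(counts)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_ordination(pd.DataFrame({"S1": [1.0, 2.0]}))


class TestVenn:
    def test_hand_example_triple_region(self):
        res = venn_partition({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c"}})
        assert res.regions[("A", "B", "C")] == 1
        assert res.percentages[("A", "B", "C")] == 25.0
        assert res.union_size == 4

    def test_identical_sets_single_region(self):
        res = venn_partition({"A": {"x", "y"}, "B": {"x", "y"}})
        assert res.regions[("A", "B")] == 2
        assert res.percentages[("A", "B")] == 100.0
        assert res.regions[("A",)] == 0 and res.regions[("B",)] == 0

    def test_disjoint_sets(self):
        res = venn_partition({"A": {"x"}, "B": {"y"}, "C": {"z", "w"}})
        assert res.regions[("A",)] == 1 and res.regions[("C",)] == 2
        assert sum(res.regions.values()) == res.union_size == 4

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            venn_partition([("A", {1}), ("A", {2})])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
        c=st.sets(st.integers(0, 15)),
    )
    def test_region_counts_sum_to_union(self, a, b, c):
        res = venn_partition({"A": a, "B": b, "C": c})
        assert sum(res.regions.values()) == len(a | b | c)
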