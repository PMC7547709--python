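"""Distance matrices and permutation tests vs naive oracles and scikit-bio."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from menanet.community_tests import (
    DistanceMatrix,
    adonis,
    adonis_statistic,
    anosim,
    anosim_statistic,
    distance_matrix,
    mantel,
    mrpp,
    mrpp_statistic,
)
from menanet.otu_io import OtuTable
from .conftest import random_table


# --- naive reference implementations (independent of the package kernels) ---

def naive_anosim_r(d, labels):
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [k for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [k for k in range(len(pairs)) if k not in within]
    rw = np.mean(ranks[within])
    rb = np.mean(ranks[between])
    return (rb - rw) / (len(pairs) / 2)


def naive_pseudo_f(d, labels):
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    k = len(groups)
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def naive_delta(d, labels):
    n = len(labels)
    out = 0.0
    for g in sorted(set(labels)):
        idx = [i for i in range(n) if labels[i] == g]
        pairs = [(i, j) for i in idx for j in idx if i < j]
        out += (len(idx) / n) * np.mean([d[i, j] for i, j in pairs])
    return out


def exhaustive_p(d, labels, stat_fn, direction):
    obs = stat_fn(d, labels)
    labels = list(labels)
    count = total = 0
    for perm in itertools.permutations(labels):
        s = stat_fn(d, list(perm))
        total += 1
        if (s >= obs - 1e-12) if direction == "greater" else (s <= obs + 1e-12):
            count += 1
    return count / total


@pytest.fixture
def dm6(rng):
    t = random_table(rng, n_samples=6, n_otus=10)
    return distance_matrix(t, "bray_curtis")


LABELS6 = ["a", "a", "a", "b", "b", "b"]


class TestDistanceMatrix:
    def test_identical_samples_zero(self):
        t = OtuTable(["x", "y"], ["o1", "o2"], np.array([[3, 4], [3, 4]]))
        assert distance_matrix(t).values[0, 1] == 0.0

    def test_disjoint_supports_bray_one(self):
        t = OtuTable(["x", "y"], ["o1", "o2"], np.array([[5, 0], [0, 7]]))
        assert distance_matrix(t).values[0, 1] == pytest.approx(1.0)

    def test_bray_formula_oracle(self, rng):
        t = random_table(rng, n_samples=2, n_otus=12)
        x, y = t.counts.astype(float)
        expect = np.abs(x - y).sum() / (x + y).sum()
        assert distance_matrix(t).values[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_unknown_metric(self, small_table):
        with pytest.raises(ValueError):
            distance_matrix(small_table, "manhattan")

    def test_invariants(self, rng):
        t = random_table(rng)
        dm = distance_matrix(t)
        assert np.allclose(dm.values, dm.values.T, atol=1e-12)
        assert np.all(np.diag(dm.values) == 0)
        assert dm.values.max() <= 1.0


class TestAnosim:
    def test_perfect_separation_r_one(self):
        # two tight clusters: all between-distances exceed all within
        v = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j:
                    same = (i < 3) == (j < 3)
                    v[i, j] = 0.1 + 0.01 * abs(i - j) if same else 0.9 + 0.01 * abs(i - j)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], v)
        res = anosim(dm, LABELS6, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_naive(self, dm6):
        assert anosim_statistic(dm6, LABELS6) == pytest.approx(
            naive_anosim_r(dm6.values, LABELS6), abs=1e-12
        )

    def test_matches_scikit_bio(self, dm6):
        import skbio
        from skbio.stats.distance import anosim as sk_anosim

        res = anosim(dm6, LABELS6, n_perm=999, seed=3)
        sk = sk_anosim(skbio.DistanceMatrix(dm6.values, dm6.ids),
                       np.array(LABELS6), permutations=999, seed=3)
        assert res.statistic == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_exhaustive_permutation_agreement(self, dm6):
        p_exact = exhaustive_p(dm6.values, LABELS6, naive_anosim_r, "greater")
        res = anosim(dm6, LABELS6, n_perm=999, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 4 * se + 2 / 999


class TestAdonis:
    def test_duplicate_samples_r2_one(self):
        X = np.array([[10, 0], [10, 0], [0, 10], [0, 10]])
        t = OtuTable(list("wxyz"), ["a", "b"], X)
        dm = distance_matrix(t)
        res = adonis(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.extra["R2"] == pytest.approx(1.0)

    def test_statistic_matches_naive(self, dm6):
        f, _ = adonis_statistic(dm6, LABELS6)
        assert f == pytest.approx(naive_pseudo_f(dm6.values, LABELS6), abs=1e-10)

    def test_matches_scikit_bio(self, dm6):
        import skbio
        from skbio.stats.distance import permanova as sk_permanova

        res = adonis(dm6, LABELS6, n_perm=999, seed=3)
        sk = sk_permanova(skbio.DistanceMatrix(dm6.values, dm6.ids),
                          np.array(LABELS6), permutations=999, seed=3)
        assert res.statistic == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_exhaustive_permutation_agreement(self, dm6):
        p_exact = exhaustive_p(dm6.values, LABELS6, naive_pseudo_f, "greater")
        res = adonis(dm6, LABELS6, n_perm=999, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 4 * se + 2 / 999


class TestMrpp:
    def test_all_distances_equal_a_zero(self):
        v = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], v)
        res = mrpp(dm, LABELS6, n_perm=199, seed=0)
        assert res.extra["A"] == pytest.approx(0.0, abs=1e-12)

    def test_tight_groups_minimum_p_attained(self):
        v = np.zeros((6, 6))
        v[:3, 3:] = 1.0
        v[3:, :3] = 1.0
        dm = DistanceMatrix([f"s{i}" for i in range(6)], v)
        res = mrpp(dm, LABELS6, n_perm=999, seed=0)
        assert res.extra["A"] > 0
        # delta = 0 is attained only by partition-preserving relabellings
        # (2 * 3! * 3! / 6! = 10% of permutations at n = 6)
        p_exact = 72 / 720
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 4 * se + 2 / 999

    def test_statistic_matches_naive(self, dm6):
        assert mrpp_statistic(dm6, LABELS6) == pytest.approx(
            naive_delta(dm6.values, LABELS6), abs=1e-12
        )

    def test_exhaustive_permutation_agreement(self, dm6):
        p_exact = exhaustive_p(dm6.values, LABELS6, naive_delta, "less")
        res = mrpp(dm6, LABELS6, n_perm=999, seed=4)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 4 * se + 2 / 999


class TestMantel:
    def _dm_pair(self, rng, n=7, dependent=True):
        a = np.abs(rng.normal(size=(n, n)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        if dependent:
            b = a + np.abs(rng.normal(0, 0.05, (n, n)))
        else:
            b = np.abs(rng.normal(size=(n, n)))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        ids = [f"s{i}" for i in range(n)]
        return DistanceMatrix(ids, a), DistanceMatrix(ids, b)

    def test_self_correlation_r_one(self, rng):
        a, _ = self._dm_pair(rng)
        res = mantel(a, a, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_scikit_bio(self, rng):
        import skbio
        from skbio.stats.distance import mantel as sk_mantel

        a, b = self._dm_pair(rng)
        res = mantel(a, b, n_perm=999, seed=5)
        r, p, _ = sk_mantel(skbio.DistanceMatrix(a.values, a.ids),
                            skbio.DistanceMatrix(b.values, b.ids),
                            permutations=999, alternative="greater", seed=5)
        assert res.statistic == pytest.approx(r, abs=1e-10)

    def test_exhaustive_4x4(self, rng):
        a, b = self._dm_pair(rng, n=4)
        iu = np.triu_indices(4, 1)
        y = b.values[iu]

        def corr(mat):
            x = mat[iu]
            return np.corrcoef(x, y)[0, 1]

        obs = corr(a.values)
        count = total = 0
        for perm in itertools.permutations(range(4)):
            s = corr(a.values[np.ix_(perm, perm)])
            total += 1
            count += s >= obs - 1e-12
        p_exact = count / total
        res = mantel(a, b, n_perm=999, seed=6)
        assert res.statistic == pytest.approx(obs, abs=1e-12)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 4 * se + 3 / 999

    def test_vector_mode_and_shape_mismatch(self, rng):
        x = rng.normal(size=20)
        res = mantel(x, 2 * x + 1, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mantel(x, x[:-1], n_perm=9, seed=0)

    def test_spearman_method(self, rng):
        x = rng.normal(size=30)
        res = mantel(x, np.exp(x), n_perm=99, seed=0, method="spearman")
        assert res.statistic == pytest.approx(1.0)


class TestSharedConventions:
    def test_addone_estimator_and_seed_reproducibility(self, dm6):
        a = anosim(dm6, LABELS6, n_perm=99, seed=7)
        b = anosim(dm6, LABELS6, n_perm=99, seed=7)
        assert a.p_value == b.p_value
        assert a.p_value * (1 + 99) == pytest.approx(round(a.p_value * 100))

    def test_group_validation(self, dm6):
        with pytest.raises(ValueError):
            anosim(dm6, ["a"] * 6, n_perm=9, seed=0)
        with pytest.raises(ValueError):
            anosim(dm6, ["a", "b", "b", "b", "b", "b"], n_perm=9, seed=0)
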