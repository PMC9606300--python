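"""Rank tests, distances, PERMANOVA and variation partitioning against
independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import kruskal, rankdata

from plumezoo.stats_suite import (
    DistanceMatrix, distance_matrix, dunn_posthoc, kruskal_wallis, permanova,
    rda_varpart,
)

# --------------------------------------------------------------- oracles


def kw_oracle(groups):
    """Tie-robust H via the variance-ratio identity
    H = (N-1) * SS_between(ranks) / SS_total(ranks)."""
    pooled = np.concatenate(groups)
    r = rankdata(pooled)
    n = r.size
    grand = r.mean()
    ss_tot = ((r - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_b, start = 0.0, 0
    for g in groups:
        rg = r[start:start + len(g)]
        ss_b += len(g) * (rg.mean() - grand) ** 2
        start += len(g)
    return (n - 1) * ss_b / ss_tot


def dunn_oracle(groups):
    """Dunn z via explicit rank arithmetic."""
    pooled = np.concatenate(groups)
    r = rankdata(pooled)
    n = r.size
    _, t = np.unique(pooled, return_counts=True)
    ties = float((t.astype(float) ** 3 - t).sum())
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    means, sizes, start = [], [], 0
    for g in groups:
        means.append(r[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
            out[(i, j)] = (means[i] - means[j]) / se
    return out


def exact_kw_permutation_p(groups):
    """Exact permutation p-value of H by enumerating every assignment
    of the pooled observations to the group-size pattern."""
    pooled = list(np.concatenate(groups))
    sizes = [len(g) for g in groups]
    h_obs = kw_oracle(groups)
    count = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        vals = [pooled[i] for i in perm]
        gs, start = [], 0
        for s in sizes:
            gs.append(np.array(vals[start:start + s]))
            start += s
        total += 1
        if kw_oracle(gs) >= h_obs - 1e-12:
            count += 1
    return count / total


#: the n <= 8 test battery (with and without ties)
SMALL_BATTERY = [
    [[1.0, 2.0], [3.0, 4.0]],
    [[1, 1, 2], [2, 3], [4, 5, 6]],
    [[5.0], [1.0, 2.0], [3.0, 3.0, 3.0]],
    [[0.1, 0.2, 0.2], [0.2, 0.4], [0.9, 1.2, 0.05]],
    [[2, 2], [2, 2], [2, 2]],
]


class TestKruskalWallis:
    def test_table1_turbidity_change_rounds_to_21(self, table1):
        groups = {}
        for r in table1:
            groups.setdefault(r.regime, []).append(r.turbidity_change_depth)
        kw = kruskal_wallis([groups["S"], groups["I"], groups["D"]])
        assert round(kw.h_statistic) == 21
        assert kw.p_value < 0.001
        assert kw.group_sizes in ((8, 8, 9), (9, 8, 8), (8, 9, 8))

    def test_all_tied_is_zero(self):
        kw = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert kw.h_statistic == 0.0

    def test_two_pair_example(self):
        kw = kruskal_wallis([[1, 2], [3, 4]])
        assert kw.h_statistic == pytest.approx(2.4)
        assert exact_kw_permutation_p([[1, 2], [3, 4]]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("groups", SMALL_BATTERY)
    def test_matches_variance_ratio_oracle(self, groups):
        assert kruskal_wallis(groups).h_statistic == pytest.approx(
            kw_oracle(groups), abs=1e-10)

    def test_matches_scipy_without_ties(self, rng):
        groups = [rng.normal(size=6), rng.normal(1, size=5),
                  rng.normal(2, size=7)]
        assert kruskal_wallis(groups).h_statistic == pytest.approx(
            kruskal(*groups).statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunn:
    def test_identical_groups_p_near_one(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert all(p > 0.95 for p in res.p_values)

    def test_extreme_pair_smallest_p(self):
        res = dunn_posthoc([[1, 2, 3], [10, 11, 12], [100, 101, 102]])
        p = dict(zip(res.pairs, res.p_values))
        assert p[(0, 2)] == min(res.p_values)

    @pytest.mark.parametrize("groups", SMALL_BATTERY[:4])
    def test_matches_rank_oracle(self, groups):
        res = dunn_posthoc(groups)
        oracle = dunn_oracle(groups)
        for pair, z in zip(res.pairs, res.z_statistics):
            assert z == pytest.approx(oracle[pair], abs=1e-10)

    def test_holm_is_monotone_and_larger(self, rng):
        groups = [rng.normal(size=5), rng.normal(1, size=5),
                  rng.normal(3, size=5)]
        plain = dunn_posthoc(groups).p_values
        holm = dunn_posthoc(groups, adjust="holm").p_values
        assert all(h >= p for h, p in zip(holm, plain))


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        dm = distance_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = distance_matrix(np.array([[3.0, 0.0], [0.0, 5.0]]))
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_toy_table_hand_computation(self):
        x = np.array([[1.0, 2.0, 0.0], [2.0, 0.0, 2.0], [0.0, 1.0, 3.0]])
        dm = distance_matrix(x)
        assert dm.data[0, 1] == pytest.approx((1 + 2 + 2) / 7)
        assert dm.data[0, 2] == pytest.approx((1 + 1 + 3) / 7)
        assert dm.data[1, 2] == pytest.approx((2 + 1 + 1) / 8)

    def test_all_zero_pair_flagged(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        dm = distance_matrix(x)
        assert np.isnan(dm.data[0, 1]) and dm.undefined_pairs == [(0, 1)]

    def test_zscore_euclidean(self, rng):
        x = rng.normal(size=(6, 3)) * np.array([1.0, 10.0, 100.0])
        dm = distance_matrix(x, metric="euclidean-normalized")
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        expect = np.sqrt(((z[0] - z[1]) ** 2).sum())
        assert dm.data[0, 1] == pytest.approx(expect)

    def test_log_preprocess(self):
        x = np.array([[0.0, 9.0], [99.0, 0.0]])
        dm = distance_matrix(x, preprocess="log10")
        assert dm.data[0, 1] == pytest.approx(1.0)  # disjoint after log


class TestPermanova:
    def _dm(self, x):
        return distance_matrix(x, metric="euclidean-normalized",
                               preprocess=None)

    def test_pseudo_f_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.gamma(2.0, size=(12, 4))
        labels = np.repeat(["a", "b", "c"], 4)
        dm = distance_matrix(x, metric="bray-curtis", preprocess="log10")
        mine = permanova(dm, labels, n_perm=99, seed=0)
        sk = sk_permanova(
            skbio.DistanceMatrix(dm.data, ids=[str(i) for i in dm.labels]),
            list(labels), permutations=99)
        assert mine.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_separated_clusters_hit_p_floor(self, rng):
        x = np.vstack([rng.normal(0, 0.1, size=(6, 2)),
                       rng.normal(50, 0.1, size=(6, 2))])
        labels = np.repeat(["a", "b"], 6)
        res = permanova(self._dm(x), labels, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        # n = 6: enumerate all 720 relabelings for the exact p-value
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = self._dm(x)
        obs = permanova(dm, labels, n_perm=4999, seed=2)
        d2 = dm.data ** 2
        n = 6

        def pseudo_f(codes):
            ss_tot = d2.sum() / (2 * n)
            ss_w = 0.0
            for g in ("a", "b"):
                idx = np.nonzero(codes == g)[0]
                ss_w += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
            return ((ss_tot - ss_w) / 1) / (ss_w / (n - 2))

        f_obs = pseudo_f(labels)
        count = total = 0
        for perm in itertools.permutations(labels):
            total += 1
            count += pseudo_f(np.array(perm)) >= f_obs - 1e-12
        exact = count / total
        assert obs.pseudo_f == pytest.approx(f_obs, rel=1e-10)
        mc_se = np.sqrt(exact * (1 - exact) / 5000)
        assert abs(obs.p_value - exact) < 4 * mc_se + 1e-3

    def test_relabeling_invariance(self, rng):
        x = rng.normal(size=(10, 3))
        labels = np.repeat(["a", "b"], 5)
        dm = self._dm(x)
        perm = rng.permutation(10)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm],
                             dm.data[np.ix_(perm, perm)], dm.metric)
        r1 = permanova(dm, labels, n_perm=999, seed=3)
        r2 = permanova(dm2, labels[perm], n_perm=999, seed=3)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)

    def test_singular_grouping_rejected(self, rng):
        dm = self._dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["a", "a", "a", "a", "b"])  # level with 1 member


class TestVarpart:
    def test_constructed_response(self, rng):
        x1 = rng.normal(size=(40, 2))
        y = x1 @ rng.normal(size=(2, 3))  # y built purely from X1
        # X2: noise orthogonalised against the (centred) response
        yc = y - y.mean(0)
        x2 = rng.normal(size=(40, 2))
        x2 = x2 - yc @ np.linalg.lstsq(yc, x2 - x2.mean(0), rcond=None)[0]
        vp = rda_varpart(y, x1, x2, adjusted=False)
        assert vp.fractions["X1"] == pytest.approx(vp.total_r2, abs=1e-6)
        assert abs(vp.fractions["X2"]) < 1e-6
        assert abs(vp.fractions["X1&X2"]) < 1e-6

    def test_raw_fractions_sum_to_full_r2(self, rng):
        y = rng.normal(size=(15, 4))
        xs = [rng.normal(size=(15, 2)) for _ in range(3)]
        vp = rda_varpart(y, *xs, adjusted=False)
        assert sum(vp.fractions.values()) == pytest.approx(vp.total_r2,
                                                           abs=1e-9)

    def test_normal_equations_oracle(self, rng):
        # independent R^2 route: solve X'X b = X'y per response column
        y = rng.normal(size=(10, 2))
        x1 = rng.normal(size=(10, 2))
        x2 = rng.normal(size=(10, 1))
        yc = y - y.mean(0)

        def oracle_r2(x):
            xc = np.column_stack([np.ones(10), x])
            xtx = xc.T @ xc
            fitted = xc @ np.linalg.solve(xtx, xc.T @ yc)
            return (fitted ** 2).sum() / (yc ** 2).sum()

        r1, r2_, r12 = (oracle_r2(x1), oracle_r2(x2),
                        oracle_r2(np.hstack([x1, x2])))
        vp = rda_varpart(y, x1, x2, adjusted=False)
        assert vp.fractions["X1"] == pytest.approx(r12 - r2_, abs=1e-8)
        assert vp.fractions["X2"] == pytest.approx(r12 - r1, abs=1e-8)
        assert vp.fractions["X1&X2"] == pytest.approx(r1 + r2_ - r12,
                                                      abs=1e-8)

    def test_single_set_is_plain_rda_r2(self, rng):
        y = rng.normal(size=(12, 3))
        x = rng.normal(size=(12, 2))
        vp = rda_varpart(y, x, adjusted=False)
        assert vp.fractions == {"X1": pytest.approx(vp.total_r2)}

    def test_adjusted_can_go_negative(self, rng):
        y = rng.normal(size=(10, 2))
        xs = [rng.normal(size=(10, 2)) for _ in range(2)]
        vp = rda_varpart(y, *xs, adjusted=True)
        assert vp.adjusted  # fractions reported as-is, sign unconstrained

    def test_collinear_predictors_warn(self, rng):
        x1 = rng.normal(size=(12, 1))
        x1 = np.hstack([x1, 2 * x1])
        with pytest.warns(UserWarning, match="collinear"):
            rda_varpart(rng.normal(size=(12, 2)), x1, adjusted=False)
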