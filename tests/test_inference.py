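import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel, permanova as skbio_permanova

from enteropipe import (
    ContingencyTable,
    CountTable,
    bh_adjust,
    clr_da,
    concordant_da,
    contingency_test,
    mantel,
    permanova,
    permanova_multi,
    rank_tests,
    spearman_corr,
    t_test_summary,
)
from enteropipe.preprocess import ParameterError
from conftest import euclid_dm


class TestPermanova:
    def test_two_tight_far_clusters_floor_p(self):
        rng = np.random.default_rng(0)
        # clusters large enough that a random permutation essentially never
        # recreates the exact split, so only the identity attains F_obs
        pts = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(100, 0.01, 10)])
        dm = euclid_dm(pts)
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        dm = euclid_dm(pts)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = permanova(dm, labels, n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=9)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]))

    def test_exhaustive_matches_brute_force_oracle(self):
        # independent oracle: compute F from coordinates via the classical
        # ANOVA decomposition (centroids in point space), enumerate all 6!
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclid_dm(pts)

        def f_from_coords(lab):
            grand = pts.mean(axis=0)
            ssw = ssb = 0.0
            for g in np.unique(lab):
                sub = pts[lab == g]
                cen = sub.mean(axis=0)
                ssw += ((sub - cen) ** 2).sum()
                ssb += len(sub) * ((cen - grand) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        f_obs = f_from_coords(labels)
        perms = [np.array(p) for p in itertools.permutations(labels)]
        p_oracle = np.mean([f_from_coords(p) >= f_obs - 1e-12 for p in perms])
        res = permanova(dm, labels, n_perm="exhaustive")
        assert res.statistic == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_oracle)

    def test_level_with_one_sample_errors(self, four_point_dm):
        with pytest.raises(ParameterError):
            permanova(four_point_dm, ["a", "a", "a", "b"], n_perm=9)

    def test_multi_factor_bh_adjusted(self):
        rng = np.random.default_rng(3)
        dm = euclid_dm(rng.normal(size=(12, 2)))
        factors = pd.DataFrame(
            {
                "f1": ["a", "b"] * 6,
                "f2": ["x"] * 6 + ["y"] * 6,
            },
            index=dm.ids,
        )
        res = permanova_multi(dm, factors, n_perm=99, seed=0)
        assert len(res) == 2
        for r in res:
            assert r.p_adjusted >= r.p_value


class TestMantel:
    def test_identical_matrices_r_one(self, four_point_dm):
        res = mantel(four_point_dm, four_point_dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(1)
        da = euclid_dm(rng.normal(size=(8, 2)))
        db = DistanceMatrix(
            euclid_dm(rng.normal(size=(8, 2))).data, ids=da.ids
        )
        ours = mantel(da, db, n_perm=9, seed=0)
        r_ref, _, _ = skbio_mantel(da, db, method="spearman", permutations=9)
        assert ours.statistic == pytest.approx(float(r_ref))

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        da = euclid_dm(rng.normal(size=(5, 2)))
        db = DistanceMatrix(euclid_dm(rng.normal(size=(5, 2))).data, ids=da.ids)
        iu = np.triu_indices(5, k=1)

        def rho(mat):
            return stats.spearmanr(da.data[iu], mat[iu]).statistic

        r_obs = rho(db.data)
        rs = [
            rho(db.data[np.ix_(p, p)])
            for p in itertools.permutations(range(5))
        ]
        p_oracle = np.mean([r >= r_obs - 1e-12 for r in rs])
        res = mantel(da, db, n_perm="exhaustive")
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(p_oracle)

    def test_mismatched_ids_error(self, four_point_dm):
        other = DistanceMatrix(four_point_dm.data, ids=list("wxyz"))
        with pytest.raises(ParameterError):
            mantel(four_point_dm, other, n_perm=9)

    def test_reordered_ids_aligned(self, four_point_dm):
        perm = [2, 0, 3, 1]
        other = DistanceMatrix(
            four_point_dm.data[np.ix_(perm, perm)],
            ids=[four_point_dm.ids[i] for i in perm],
        )
        res = mantel(four_point_dm, other, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(1.0)


class TestRankTests:
    def test_identical_groups_p_one(self):
        res = rank_tests([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])],
                         "wilcoxon_two_sample")
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        # 2 of the 20 arrangements are at least as extreme
        res = rank_tests([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])],
                         "wilcoxon_two_sample")
        assert res.p_value == pytest.approx(0.1)

    def test_kruskal_two_groups_equals_uncorrected_wilcoxon(self):
        x = np.array([1.2, 3.4, 2.2, 5.5, 0.1])
        y = np.array([2.0, 4.1, 6.3])
        k = rank_tests([x, y], "kruskal")
        w = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert k.p_value == pytest.approx(float(w.pvalue))

    def test_wilcoxon_exact_matches_enumeration(self):
        # brute-force oracle over all C(6,3) group assignments
        rng = np.random.default_rng(0)
        pooled = rng.normal(size=6)
        x, y = pooled[:3], pooled[3:]
        obs = abs(stats.rankdata(pooled)[:3].sum() - 3 * 7 / 2)
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        for idx in combos:
            r = stats.rankdata(pooled)
            s = abs(r[list(idx)].sum() - 3 * 7 / 2)
            if s >= obs - 1e-12:
                count += 1
        res = rank_tests([x, y], "wilcoxon_two_sample")
        assert res.p_value == pytest.approx(count / len(combos))

    def test_empty_group_errors(self):
        with pytest.raises(ParameterError):
            rank_tests([np.array([1.0]), np.array([])], "wilcoxon_two_sample")


class TestSpearman:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4])
        assert spearman_corr(x, x).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
        rhos = [
            abs(np.corrcoef(rx, np.array(p))[0, 1])
            for p in itertools.permutations(ry)
        ]
        p_oracle = np.mean([r >= rho_obs - 1e-12 for r in rhos])
        res = spearman_corr(x, y)
        assert res.p_value == pytest.approx(p_oracle)
        assert res.notes == "exact enumeration"

    def test_constant_vector_errors(self):
        with pytest.raises(ParameterError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestContingency:
    # Frozen cross-tabulations with their R-convention p-values
    # (chisq.test: Yates for 2x2, plain Pearson otherwise).
    @pytest.mark.parametrize(
        "cells,expected_p",
        [
            ([[24, 11], [19, 8], [30, 7], [55, 4]], 0.011),  # 4x2 education-style
            ([[81, 20], [47, 11]], 1.000),  # Yates floors the statistic at 0
            ([[6, 3], [85, 23], [32, 5]], 0.354),
        ],
    )
    def test_chisq_compatibility_profile(self, cells, expected_p):
        cells = np.array(cells)
        ct = ContingencyTable(
            [f"r{i}" for i in range(cells.shape[0])], ["b", "p"], cells
        )
        res = contingency_test(ct, "chisq")
        assert round(res.p_value, 3) == expected_p

    def test_yates_statistic_floored_at_zero(self):
        ct = ContingencyTable(["r0", "r1"], ["a", "b"], np.array([[81, 20], [47, 11]]))
        res = contingency_test(ct, "chisq")
        assert res.statistic == 0.0 and res.notes == "yates"

    def test_fisher_2x2_hypergeometric(self):
        ct = ContingencyTable(["r0", "r1"], ["a", "b"], np.array([[2, 0], [0, 2]]))
        assert contingency_test(ct, "fisher").p_value == pytest.approx(1 / 3)

    def test_fisher_rxc_enumeration_matches_hand_oracle(self):
        # 2x3 oracle: enumerate tables with fixed margins directly
        cells = np.array([[3, 1, 2], [1, 3, 2]])
        ct = ContingencyTable(["r0", "r1"], ["a", "b", "c"], cells)
        rs, cs = cells.sum(1), cells.sum(0)
        n = cells.sum()

        def prob(t):
            num = math.prod(math.comb(cs[j], t[0][j]) for j in range(3))
            return num / math.comb(n, rs[0])

        p_obs = prob(cells)
        total = 0.0
        for a in range(min(rs[0], cs[0]) + 1):
            for b in range(min(rs[0] - a, cs[1]) + 1):
                c = rs[0] - a - b
                if 0 <= c <= cs[2]:
                    t = [[a, b, c], [cs[0] - a, cs[1] - b, cs[2] - c]]
                    if min(t[1]) >= 0 and prob(t) <= p_obs * (1 + 1e-9):
                        total += prob(t)
        res = contingency_test(ct, "fisher")
        assert res.p_value == pytest.approx(total)

    def test_fisher_3x3_matches_r(self):
        # frozen from R fisher.test on the same table
        cells = np.array([[3, 1, 2], [1, 3, 2], [2, 2, 1]])
        ct = ContingencyTable(list("abc"), list("xyz"), cells)
        res = contingency_test(ct, "fisher")
        assert res.p_value == pytest.approx(0.8441684, abs=1e-6)

    def test_fisher_monte_carlo_close_to_exact(self):
        cells = np.array([[3, 1, 2], [1, 3, 2], [2, 2, 1]])
        ct = ContingencyTable(list("abc"), list("xyz"), cells)
        from enteropipe.inference import _fisher_rxc

        exact = contingency_test(ct, "fisher").p_value
        res = _fisher_rxc(ct, seed=0, n_mc=20_000, max_enumeration=0)
        assert res.notes == "rxc monte carlo"
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_empty_margin_rejected(self):
        with pytest.raises(ParameterError):
            ContingencyTable(["r0", "r1"], ["a", "b"], np.array([[0, 0], [1, 2]]))


class TestTTest:
    def test_equal_means_p_one(self):
        res = t_test_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        a = t_test_summary(0.0, 1.0, 10, 1.0, 1.0, 10)
        b = t_test_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_hand_value(self):
        res = t_test_summary(0.0, 1.0, 10, 1.0, 1.0, 10, pooled=True)
        assert res.statistic == pytest.approx(-2.2360, abs=1e-4)
        assert res.df == 18

    def test_invalid_sd(self):
        with pytest.raises(ParameterError):
            t_test_summary(0, 0.0, 10, 1, 1.0, 10)


class TestBH:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 0.0])


class TestDifferentialAbundance:
    def _table(self, shift_taxon=None, fold=10.0, n_per=25, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 2.0, size=20)
        rows, groups = [], []
        for g, n in (("a", n_per), ("b", n_per)):
            for _ in range(n):
                alpha = base.copy()
                if g == "b" and shift_taxon is not None:
                    alpha[shift_taxon] *= fold
                comp = rng.dirichlet(alpha * 50)
                rows.append(rng.multinomial(3000, comp))
                groups.append(g)
        t = CountTable(
            [f"s{i}" for i in range(2 * n_per)],
            [f"g{j}" for j in range(20)],
            np.array(rows),
        )
        return t, groups

    def test_shifted_taxon_detected(self):
        t, groups = self._table(shift_taxon=0)
        res = clr_da(t, groups, mc_instances=16, seed=1)
        assert res.loc["g0", "p_adjusted"] < 0.05
        assert res.loc["g0", "statistic"] < 0  # higher in group b

    def test_deterministic_per_seed(self):
        t, groups = self._table(shift_taxon=None)
        a = clr_da(t, groups, mc_instances=8, seed=3)
        b = clr_da(t, groups, mc_instances=8, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_null_has_no_bh_hits(self):
        t, groups = self._table(shift_taxon=None, seed=5)
        res = clr_da(t, groups, mc_instances=8, seed=2)
        assert (res["p_adjusted"] < 0.05).sum() == 0

    def test_small_group_errors(self):
        t, _ = self._table()
        with pytest.raises(ParameterError):
            clr_da(t, ["a"] + ["b"] * (t.n_samples - 1))


class TestConcordance:
    def _frame(self, sig, direction):
        taxa = ["x", "y", "z"]
        return pd.DataFrame(
            {
                "statistic": [direction.get(t, 1.0) for t in taxa],
                "p_value": [0.001 if t in sig else 0.5 for t in taxa],
                "p_adjusted": [0.003 if t in sig else 0.7 for t in taxa],
            },
            index=taxa,
        )

    def test_intersection(self):
        a = self._frame({"x", "y"}, {})
        b = self._frame({"y", "z"}, {})
        assert concordant_da(a, b) == ["y"]

    def test_opposite_direction_excluded(self):
        a = self._frame({"y"}, {"y": 1.0})
        b = self._frame({"y"}, {"y": -1.0})
        assert concordant_da(a, b) == []

    def test_alpha_one_keeps_all_matching_direction(self):
        a = self._frame(set(), {})
        b = self._frame(set(), {})
        assert concordant_da(a, b, alpha=1.01) == ["x", "y", "z"]

    def test_taxon_mismatch_errors(self):
        a = self._frame(set(), {})
        b = self._frame(set(), {}).rename(index={"z": "w"})
        with pytest.raises(ParameterError):
            concordant_da(a, b)
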