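"""Hypothesis tests and multiplicity correction.

Permutation tests (PERMANOVA, Mantel, envfit) report
p = (1 + exceedances) / (1 + n_perm), so the smallest attainable p is
1/(n_perm + 1).  Contingency tests follow the compatibility profile of the
R defaults this kind of analysis is usually run with: Yates continuity
correction (floored at 0) for 2x2 chi-squared, plain Pearson otherwise,
complete-case handling of missing values.  Differential abundance is a
CLR-based Monte-Carlo Wilcoxon procedure with a two-method concordance
intersection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import CountTable
from .preprocess import ParameterError


@dataclass
class TestResult:
    """A single hypothesis-test outcome with its bookkeeping."""

    method: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n_used: int | None = None
    df: float | None = None
    n_permutations: int | None = None
    effect_direction: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            # a p of exactly 0 cannot arise from the add-one convention or
            # from continuous reference distributions; clamp defensively
            self.p_value = max(self.p_value, np.finfo(float).tiny)

    def to_report_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "n_used": self.n_used,
            "df": self.df,
            "n_permutations": self.n_permutations,
            "notes": self.notes,
        }


@dataclass
class ContingencyTable:
    """Cross-tabulation with labelled margins (at least 2x2)."""

    row_labels: list[str]
    col_labels: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        r, c = self.cells.shape
        if r < 2 or c < 2:
            raise ParameterError("contingency table must be at least 2x2")
        if (self.cells < 0).any():
            raise ParameterError("negative cell count")
        if (self.cells.sum(axis=1) == 0).any() or (self.cells.sum(axis=0) == 0).any():
            raise ParameterError("empty margin")

    @classmethod
    def from_labels(cls, rows, cols) -> "ContingencyTable":
        ct = pd.crosstab(pd.Series(rows), pd.Series(cols))
        return cls([str(r) for r in ct.index], [str(c) for c in ct.columns], ct.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels, columns=self.col_labels)


# ---------------------------------------------------------------------------
# PERMANOVA


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squared distances, Anderson decomposition."""
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova(
    dist: DistanceMatrix,
    factor,
    n_perm: int = 999,
    seed: int | None = 0,
) -> TestResult:
    """One-factor PERMANOVA (permutational MANOVA) pseudo-F test.

    SST = sum d^2 / n over all pairs; SSW sums within-group pairwise d^2
    scaled by group size; F = [(SST - SSW)/(a - 1)] / [SSW/(n - a)].
    Significance by free permutation of the factor labels;
    ``n_perm="exhaustive"`` enumerates every label permutation instead
    (feasible for n <= ~8) and reports the exact permutation p.
    """
    labels = np.asarray(pd.Series(factor).values)
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if len(labels) != n:
        raise ParameterError("factor length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ParameterError("each factor level needs >= 2 samples")
    a = len(uniq)
    d2 = d**2
    sst = d2.sum() / (2 * n)

    def pseudo_f(lab):
        ssw = _group_ss(d2, lab)
        return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(labels)
    if n_perm == "exhaustive":
        stats_all = [
            pseudo_f(np.asarray(p)) for p in itertools.permutations(labels)
        ]
        exceed = sum(1 for f in stats_all if f >= f_obs - 1e-12)
        return TestResult(
            method="permanova",
            statistic=f_obs,
            p_value=exceed / len(stats_all),
            n_used=n,
            df=a - 1,
            n_permutations=len(stats_all),
            notes="exhaustive enumeration",
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(labels[rng.permutation(n)]) >= f_obs - 1e-12:
            exceed += 1
    return TestResult(
        method="permanova",
        statistic=f_obs,
        p_value=(1 + exceed) / (1 + n_perm),
        n_used=n,
        df=a - 1,
        n_permutations=n_perm,
    )


def permanova_multi(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
) -> list[TestResult]:
    """Marginal PERMANOVA per factor with BH adjustment across factors.

    Rows with a missing factor value are dropped for that factor
    (complete-case per test)."""
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    results = []
    for i, col in enumerate(factors.columns):
        vals = factors[col].reindex(dist.ids)
        ok = vals.notna().to_numpy()
        sub = dist.filter([s for s, m in zip(dist.ids, ok) if m])
        res = permanova(
            sub, vals[ok], n_perm=n_perm,
            seed=int(np.random.default_rng([ss.entropy, i]).integers(2**31)),
        )
        res.method = f"permanova[{col}]"
        results.append(res)
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = q
    return results


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
) -> TestResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the Spearman (or Pearson) correlation of corresponding
    off-diagonal entries; significance from simultaneous row/column
    permutation of the second matrix, one-sided (greater).
    ``n_perm="exhaustive"`` enumerates all n! permutations.
    """
    if list(d_a.ids) != list(d_b.ids):
        if set(d_a.ids) != set(d_b.ids):
            raise ParameterError("distance matrices cover different samples")
        d_b = d_b.filter(d_a.ids)
    a = np.asarray(d_a.data, dtype=float)
    b = np.asarray(d_b.data, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    if method == "spearman":
        va = stats.rankdata(a[iu])
    elif method == "pearson":
        va = a[iu].astype(float)
    else:
        raise ParameterError(f"unknown method {method!r}")

    def corr_with(bm):
        vb = bm[iu]
        if method == "spearman":
            vb = stats.rankdata(vb)
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr_with(b)
    if n_perm == "exhaustive":
        rs = [
            corr_with(b[np.ix_(p, p)])
            for p in itertools.permutations(range(n))
        ]
        exceed = sum(1 for r in rs if r >= r_obs - 1e-12)
        return TestResult(
            method=f"mantel_{method}",
            statistic=r_obs,
            p_value=exceed / len(rs),
            n_used=n,
            n_permutations=len(rs),
            notes="exhaustive enumeration",
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr_with(b[np.ix_(p, p)]) >= r_obs - 1e-12:
            exceed += 1
    return TestResult(
        method=f"mantel_{method}",
        statistic=r_obs,
        p_value=(1 + exceed) / (1 + n_perm),
        n_used=n,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# rank tests, correlation, t, contingency


def rank_tests(groups: list[np.ndarray], mode: str) -> TestResult:
    """Wilcoxon rank-sum (two groups) or Kruskal-Wallis (>= 2 groups).

    The two-sample test uses the exact null distribution for small
    untied samples and the tie-corrected, continuity-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ParameterError("empty group")
    if mode == "wilcoxon_two_sample":
        if len(groups) != 2:
            raise ParameterError("wilcoxon_two_sample needs exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return TestResult(
            method="wilcoxon_rank_sum",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_used=sum(map(len, groups)),
            effect_direction=float(np.median(groups[0]) - np.median(groups[1])),
        )
    if mode == "kruskal":
        res = stats.kruskal(*groups)
        return TestResult(
            method="kruskal_wallis",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_used=sum(map(len, groups)),
            df=len(groups) - 1,
        )
    raise ParameterError(f"unknown mode {mode!r}")


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with exact small-sample inference.

    For n <= 9 without ties the p-value is computed by full enumeration of
    rank permutations (two-sided); otherwise the t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ParameterError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("constant input vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = len(set(rx)) == n and len(set(ry)) == n
    if n <= 9 and no_ties:
        denom = n * (n**2 - 1)
        rhos = np.array(
            [
                1 - 6 * float(((rx - np.array(p)) ** 2).sum()) / denom
                for p in itertools.permutations(ry)
            ]
        )
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        note = "exact enumeration"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        note = "t approximation"
    return TestResult(
        method="spearman", statistic=rho, p_value=p, n_used=n, notes=note
    )


def contingency_test(table: ContingencyTable, method: str = "chisq", seed: int | None = 0) -> TestResult:
    """Chi-squared or Fisher's exact test on a contingency table.

    chisq: Pearson statistic with df = (r-1)(c-1); a 2x2 table gets the
    Yates continuity correction with the statistic floored at 0.
    fisher: exact two-sided test summing the probabilities of tables at
    most as probable as the observed one; 2x2 uses the hypergeometric
    closed form, r x c full enumeration when the table-count bound is
    <= 1e6, else seeded Monte Carlo with 1e5 sampled tables.
    """
    cells = table.cells
    r, c = cells.shape
    if method == "chisq":
        correction = (r, c) == (2, 2)
        chi2, p, dof, _ = stats.chi2_contingency(cells, correction=correction)
        return TestResult(
            method="chisq",
            statistic=float(chi2),
            p_value=float(p),
            n_used=int(cells.sum()),
            df=dof,
            notes="yates" if correction else "pearson",
        )
    if method != "fisher":
        raise ParameterError(f"unknown method {method!r}")
    if (r, c) == (2, 2):
        _, p = stats.fisher_exact(cells, alternative="two-sided")
        return TestResult(
            method="fisher", statistic=float("nan"), p_value=float(p),
            n_used=int(cells.sum()), notes="2x2 exact",
        )
    return _fisher_rxc(table, seed=seed)


def _log_table_prob(cells: np.ndarray, row_sums, col_sums, log_n_fact) -> float:
    """Log conditional probability of a table given its margins."""
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - log_n_fact
        - gammaln(cells + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, cols_left, rows):
        if i == r - 1:
            yield rows + [list(cols_left)]
            return
        # enumerate row i cell by cell
        def rec_row(j, remaining, row):
            if j == c - 1:
                if remaining <= cols_left[c - 1]:
                    yield row + [remaining]
                return
            hi = min(remaining, cols_left[j])
            for v in range(hi + 1):
                yield from rec_row(j + 1, remaining - v, row + [v])

        for row in rec_row(0, row_sums[i], []):
            new_cols = [cl - v for cl, v in zip(cols_left, row)]
            yield from rec(i + 1, new_cols, rows + [row])

    yield from rec(0, list(col_sums), [])


def _fisher_rxc(
    table: ContingencyTable,
    seed: int | None = 0,
    n_mc: int = 100_000,
    max_enumeration: float = 1e6,
) -> TestResult:
    cells = table.cells
    row_sums = cells.sum(axis=1)
    col_sums = cells.sum(axis=0)
    n = int(cells.sum())
    log_n_fact = float(gammaln(n + 1))
    lp_obs = _log_table_prob(cells, row_sums, col_sums, log_n_fact)
    # crude bound on the number of tables: free cells range over their margin
    bound = 1.0
    for rs in row_sums[:-1]:
        for cs in col_sums[:-1]:
            bound *= min(rs, cs) + 1
            if bound > max_enumeration:
                break
        if bound > max_enumeration:
            break
    if bound <= max_enumeration:
        p = 0.0
        for t in _enumerate_tables(row_sums, col_sums):
            lp = _log_table_prob(np.asarray(t), row_sums, col_sums, log_n_fact)
            if lp <= lp_obs + 1e-9:
                p += math.exp(lp)
        return TestResult(
            method="fisher", statistic=float("nan"), p_value=min(p, 1.0),
            n_used=n, notes="rxc full enumeration",
        )
    rng = np.random.default_rng(seed)
    rt = stats.random_table(row_sums, col_sums)
    samples = rt.rvs(n_mc, random_state=rng)
    lps = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - log_n_fact
        - gammaln(samples + 1).sum(axis=(1, 2))
    )
    exceed = int((lps <= lp_obs + 1e-9).sum())
    return TestResult(
        method="fisher",
        statistic=float("nan"),
        p_value=(1 + exceed) / (1 + n_mc),
        n_used=n,
        n_permutations=n_mc,
        notes="rxc monte carlo",
    )


def t_test_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    pooled: bool = True,
) -> TestResult:
    """Two-sample t-test from summary statistics (pooled Student by
    default, Welch with ``pooled=False``); two-sided."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled
    )
    df = n1 + n2 - 2 if pooled else float(res.df) if hasattr(res, "df") else None
    return TestResult(
        method="t_pooled" if pooled else "t_welch",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=n1 + n2,
        df=df,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential abundance


def clr_da(
    table: CountTable,
    groups,
    mc_instances: int = 128,
    seed: int | None = 0,
) -> pd.DataFrame:
    """CLR-based Monte-Carlo differential abundance between two groups.

    Per Monte-Carlo instance, each sample's composition is drawn from
    Dirichlet(counts + 0.5), centered-log-ratio transformed, and every taxon
    is tested with a two-sided Wilcoxon rank-sum; p-values are averaged over
    instances and BH-adjusted across taxa.  Effect direction is the mean CLR
    difference (group1 - group2).  This emulates the CLR + Wilcoxon skeleton
    of ALDEx2-style testing; it is not a reimplementation of that package.

    Returns a DataFrame indexed by taxon with columns
    ``statistic`` (mean CLR difference), ``p_value``, ``p_adjusted``.
    """
    groups = pd.Series(np.asarray(groups), index=table.sample_ids)
    levels = [g for g in dict.fromkeys(groups)]
    if len(levels) != 2:
        raise ParameterError("clr_da needs exactly two groups")
    m1 = (groups == levels[0]).to_numpy()
    m2 = (groups == levels[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ParameterError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    counts = table.counts + 0.5
    n, t = counts.shape
    p_sum = np.zeros(t)
    eff_sum = np.zeros(t)
    for _ in range(mc_instances):
        # Dirichlet draw per sample via normalized gammas
        comp = rng.standard_gamma(counts)
        comp /= comp.sum(axis=1, keepdims=True)
        clr = np.log(comp) - np.log(comp).mean(axis=1, keepdims=True)
        res = stats.mannwhitneyu(
            clr[m1], clr[m2], alternative="two-sided", axis=0, method="asymptotic"
        )
        p_sum += res.pvalue
        eff_sum += clr[m1].mean(axis=0) - clr[m2].mean(axis=0)
    p_mean = np.minimum(p_sum / mc_instances, 1.0)
    return pd.DataFrame(
        {
            "statistic": eff_sum / mc_instances,
            "p_value": p_mean,
            "p_adjusted": bh_adjust(p_mean),
        },
        index=table.taxon_ids,
    )


def concordant_da(
    res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Taxa BH-significant in both differential-abundance result frames
    with matching effect direction — the two-method concordance rule."""
    if set(res_a.index) != set(res_b.index):
        raise ParameterError("result frames cover different taxa")
    res_b = res_b.loc[res_a.index]
    sig = (res_a["p_adjusted"] < alpha) & (res_b["p_adjusted"] < alpha)
    same_dir = np.sign(res_a["statistic"]) == np.sign(res_b["statistic"])
    return sorted(res_a.index[sig & same_dir])
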