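"""End-to-end workflows: the cross-sectional enterotype analysis of a
single timepoint and the longitudinal comparison of two timepoints.

Cross-timepoint statistics (alpha Spearman, Mantel, enterotype
cross-tabulation) use the intersection of sample identifiers — not every
sample amplifies at both timepoints.  Every result object carries the
parameters and seeds that produced it, and a fixed seed yields a
byte-identical report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .diversity import alpha_diversity, beta_diversity
from .enterotype import LOW_BIOMASS_LABEL, EnterotypeModel, EnterotypeResults
from .inference import ContingencyTable, TestResult
from .io import CountTable, PhyloTree, SampleMetadata
from .ordination import EnvfitResult, OrdinationResult, envfit, pcoa
from .preprocess import filter_rare_taxa, rarefy, to_relative


def _substream(seed: int | None, offset: int) -> int:
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    return int(np.random.default_rng([ss.entropy, offset]).integers(2**31))


@dataclass
class CrossSectionalResult:
    """Results of the single-timepoint enterotype analysis."""

    fit: EnterotypeResults
    ordination: OrdinationResult
    envfit: list[EnvfitResult]
    alpha_overall: dict[str, TestResult]
    alpha_vs_reference: dict[str, dict]
    beta_dispersion_vs_reference: dict
    permanova: list[TestResult]
    association_screen: dict[str, TestResult]
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [self.fit.summary(), ""]
        if self.envfit:
            lines.append("envfit (driver genera on first ordination axes)")
            for e in self.envfit:
                lines.append(
                    f"  {e.variable:<16} r2={e.r_squared:.3f}  p={e.p_value:.4g}"
                )
        for idx, res in self.alpha_overall.items():
            lines.append(
                f"alpha {idx} across enterotypes: {res.method} "
                f"stat={res.statistic:.3f} p={res.p_value:.4g}"
            )
        for r in self.permanova:
            lines.append(
                f"{r.method}: F={r.statistic:.3f} p={r.p_value:.4g} "
                f"q={r.p_adjusted:.4g}"
            )
        if self.association_screen:
            lines.append("association screen (metadata vs enterotype):")
            for var, r in self.association_screen.items():
                lines.append(f"  {var:<28} {r.method:<10} p={r.p_value:.4g}")
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "fit": self.fit.to_report_dict(),
            "ordination": self.ordination.to_report_dict(),
            "envfit": [e.to_report_dict() for e in self.envfit],
            "alpha_overall": {k: v.to_report_dict() for k, v in self.alpha_overall.items()},
            "alpha_vs_reference": {
                k: {str(c): r.to_report_dict() for c, r in v.items()}
                for k, v in self.alpha_vs_reference.items()
            },
            "beta_dispersion_vs_reference": {
                str(c): r.to_report_dict()
                for c, r in self.beta_dispersion_vs_reference.items()
            },
            "permanova": [r.to_report_dict() for r in self.permanova],
            "association_screen": {
                k: v.to_report_dict() for k, v in self.association_screen.items()
            },
            "params": self.params,
        }


@dataclass
class LongitudinalComparison:
    """Results of the two-timepoint comparison."""

    fit_t1: EnterotypeResults
    fit_t2: EnterotypeResults
    alpha_change: dict[str, TestResult]
    alpha_spearman: dict[str, TestResult]
    mantel: dict[str, TestResult]
    crosstab: ContingencyTable
    fisher: TestResult
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Longitudinal comparison",
            "=" * 60,
            f"t1: {self.fit_t1.n_classes} classes "
            f"(k={self.fit_t1.chosen_k}"
            + (
                f" + low-biomass [{len(self.fit_t1.low_biomass_samples)}]"
                if self.fit_t1.low_biomass_samples
                else ""
            )
            + f"); t2: {self.fit_t2.n_classes} classes (k={self.fit_t2.chosen_k})",
            "",
        ]
        for idx, r in self.alpha_change.items():
            lines.append(
                f"alpha change ({idx}): {r.method} stat={r.statistic:.2f} p={r.p_value:.4g}"
            )
        for idx, r in self.alpha_spearman.items():
            lines.append(
                f"alpha cross-timepoint Spearman ({idx}): rho={r.statistic:.3f} p={r.p_value:.4g}"
            )
        for metric, r in self.mantel.items():
            lines.append(
                f"Mantel ({metric}): r={r.statistic:.3f} p={r.p_value:.4g}"
            )
        lines += [
            "",
            "enterotype cross-tabulation (t1 rows x t2 columns):",
            self.crosstab.to_dataframe().to_string(),
            f"Fisher exact p = {self.fisher.p_value:.4g}",
        ]
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "fit_t1": self.fit_t1.to_report_dict(),
            "fit_t2": self.fit_t2.to_report_dict(),
            "alpha_change": {k: v.to_report_dict() for k, v in self.alpha_change.items()},
            "alpha_spearman": {k: v.to_report_dict() for k, v in self.alpha_spearman.items()},
            "mantel": {k: v.to_report_dict() for k, v in self.mantel.items()},
            "crosstab": {
                "rows": self.crosstab.row_labels,
                "cols": self.crosstab.col_labels,
                "cells": self.crosstab.cells,
            },
            "fisher": self.fisher.to_report_dict(),
            "params": self.params,
        }


def _preprocess(
    counts: CountTable,
    min_otu_fraction: float,
    rarefy_depth,
    seed: int | None,
) -> tuple[CountTable, list[str]]:
    table = filter_rare_taxa(counts, min_otu_fraction)
    if rarefy_depth is None:
        return table, []
    return rarefy(table, rarefy_depth, seed=_substream(seed, 10))


def run_cross_sectional(
    counts: CountTable,
    tree: PhyloTree | None = None,
    metadata: SampleMetadata | None = None,
    *,
    k_max: int = 10,
    pseudocount: float = 1e-6,
    low_biomass_threshold: int = 0,
    min_otu_fraction: float = 0.00005,
    rarefy_depth=None,
    reference_class: int = 0,
    permanova_factors: list[str] | None = None,
    n_perm: int = 999,
    n_axes: int = 2,
    seed: int | None = 0,
) -> CrossSectionalResult:
    """Single-timepoint analysis: preprocess, fit enterotypes, ordinate with
    driver-genus vectors, compare diversity between enterotypes against a
    reference class, PERMANOVA on metadata factors, and a Table-1-style
    univariate association screen of metadata against enterotype membership.
    """
    table, _ = _preprocess(counts, min_otu_fraction, rarefy_depth, seed)
    model = EnterotypeModel(
        table,
        k_max=k_max,
        pseudocount=pseudocount,
        low_biomass_threshold=low_biomass_threshold,
    )
    fit = model.fit(seed=_substream(seed, 11))
    analyzable = [s for s in table.sample_ids if fit.labels[s] != LOW_BIOMASS_LABEL]
    sub = table.select_samples(analyzable)
    labels = fit.labels[analyzable].astype(int)

    ordination = pcoa(fit.distance, n_axes=n_axes)
    rel = to_relative(sub)
    driver_names = sorted(set(fit.drivers.values()))
    rel_df = pd.DataFrame(rel.fractions, index=rel.sample_ids, columns=rel.taxon_ids)
    env = envfit(
        ordination, rel_df[driver_names], n_perm=n_perm, seed=_substream(seed, 12)
    )

    alpha_overall: dict[str, TestResult] = {}
    alpha_vs_ref: dict[str, dict] = {}
    classes = sorted(labels.unique())
    for idx in ("chao1", "shannon"):
        alpha = alpha_diversity(sub, idx)
        groups = [alpha[labels == c].to_numpy() for c in classes]
        if len(classes) >= 2 and all(len(g) > 0 for g in groups):
            alpha_overall[idx] = inference.rank_tests(groups, "kruskal")
        per_class = {}
        if reference_class in classes:
            ref_vals = alpha[labels == reference_class].to_numpy()
            for c in classes:
                if c == reference_class:
                    continue
                per_class[c] = inference.rank_tests(
                    [alpha[labels == c].to_numpy(), ref_vals], "wilcoxon_two_sample"
                )
        alpha_vs_ref[idx] = per_class

    # within-cluster beta dispersion: pairwise distances inside each cluster
    dist = fit.distance
    d = np.asarray(dist.data)
    pos = {s: i for i, s in enumerate(dist.ids)}

    def within(c):
        idx_c = [pos[s] for s in analyzable if labels[s] == c]
        ii, jj = np.triu_indices(len(idx_c), k=1)
        return d[np.ix_(idx_c, idx_c)][ii, jj]

    beta_disp = {}
    if reference_class in classes:
        ref_pairs = within(reference_class)
        for c in classes:
            if c == reference_class or len(within(c)) == 0 or len(ref_pairs) == 0:
                continue
            beta_disp[c] = inference.rank_tests(
                [within(c), ref_pairs], "wilcoxon_two_sample"
            )

    perman: list[TestResult] = []
    screen: dict[str, TestResult] = {}
    if metadata is not None:
        factors = permanova_factors or []
        cat_cols = [c for c in factors if metadata.schema.get(c) == "categorical"]
        if cat_cols:
            perman = inference.permanova_multi(
                dist, metadata.data[cat_cols], n_perm=n_perm, seed=_substream(seed, 13)
            )
        # univariate association of every metadata column with enterotype
        ent = fit.labels.astype(str)
        for col, kind in metadata.schema.items():
            vals = metadata.data[col].reindex(ent.index)
            ok = vals.notna()
            if kind == "categorical":
                ct = ContingencyTable.from_labels(ent[ok], vals[ok])
                screen[col] = inference.contingency_test(ct, "chisq")
            else:
                cls = sorted(ent[ok].unique())
                gr = [vals[ok][ent[ok] == c].to_numpy(dtype=float) for c in cls]
                if len(gr) == 2:
                    from scipy import stats as _st

                    r = _st.ttest_ind(gr[0], gr[1], equal_var=True)
                    screen[col] = TestResult(
                        "t_pooled", float(r.statistic), float(r.pvalue),
                        n_used=int(ok.sum()), df=int(ok.sum()) - 2,
                    )
                else:
                    screen[col] = inference.rank_tests(gr, "kruskal")

    return CrossSectionalResult(
        fit=fit,
        ordination=ordination,
        envfit=env,
        alpha_overall=alpha_overall,
        alpha_vs_reference=alpha_vs_ref,
        beta_dispersion_vs_reference=beta_disp,
        permanova=perman,
        association_screen=screen,
        params={
            "k_max": k_max, "pseudocount": pseudocount,
            "low_biomass_threshold": low_biomass_threshold,
            "min_otu_fraction": min_otu_fraction, "rarefy_depth": rarefy_depth,
            "reference_class": reference_class, "n_perm": n_perm,
            "n_axes": n_axes, "seed": seed,
        },
    )


def run_longitudinal(
    counts_t1: CountTable,
    counts_t2: CountTable,
    tree_t1: PhyloTree | None = None,
    tree_t2: PhyloTree | None = None,
    *,
    k_max: int = 10,
    pseudocount: float = 1e-6,
    low_biomass_threshold_t1: int = 0,
    min_otu_fraction: float = 0.00005,
    rarefy_depth=None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> LongitudinalComparison:
    """Two-timepoint comparison over the shared samples.

    Per-timepoint enterotype fits; unpaired Wilcoxon on the alpha change
    between timepoints; Spearman correlation of per-sample alpha values
    across timepoints; Mantel tests per beta metric; Fisher's exact test on
    the enterotype cross-tabulation, with the low-biomass class kept as its
    own category.
    """
    t1, _ = _preprocess(counts_t1, min_otu_fraction, rarefy_depth, seed)
    t2, _ = _preprocess(counts_t2, min_otu_fraction, rarefy_depth, None if seed is None else seed + 1)
    fit1 = EnterotypeModel(
        t1, k_max=k_max, pseudocount=pseudocount,
        low_biomass_threshold=low_biomass_threshold_t1,
    ).fit(seed=_substream(seed, 20))
    fit2 = EnterotypeModel(t2, k_max=k_max, pseudocount=pseudocount).fit(
        seed=_substream(seed, 21)
    )

    # amplifiable intersection for the quantitative cross-timepoint statistics
    ok1 = [s for s in t1.sample_ids if fit1.labels[s] != LOW_BIOMASS_LABEL]
    shared = [s for s in ok1 if s in set(t2.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between timepoints")
    sub1 = t1.select_samples(shared)
    sub2 = t2.select_samples(shared)

    alpha_change: dict[str, TestResult] = {}
    alpha_rho: dict[str, TestResult] = {}
    for idx in ("chao1", "shannon"):
        a1 = alpha_diversity(sub1, idx)
        a2 = alpha_diversity(sub2, idx)
        alpha_change[idx] = inference.rank_tests(
            [a2.to_numpy(), a1.to_numpy()], "wilcoxon_two_sample"
        )
        alpha_rho[idx] = inference.spearman_corr(a1.to_numpy(), a2.to_numpy())

    mantel_res: dict[str, TestResult] = {}
    for metric, trees in (
        ("braycurtis", (None, None)),
        ("unifrac", (tree_t1, tree_t2)),
    ):
        if metric == "unifrac" and (tree_t1 is None or tree_t2 is None):
            continue
        d1 = beta_diversity(sub1, metric, tree=trees[0])
        d2 = beta_diversity(sub2, metric, tree=trees[1])
        mantel_res[metric] = inference.mantel(
            d1, d2, method="spearman", n_perm=n_perm,
            seed=_substream(seed, 22),
        )

    # cross-tabulation over every sample present at both timepoints,
    # including the low-biomass class at t1 as its own row
    both = [s for s in t1.sample_ids if s in set(t2.sample_ids)]
    lab1 = fit1.labels[both].astype(str)
    lab2 = fit2.labels[both].astype(str)
    crosstab = ContingencyTable.from_labels(lab1, lab2)
    fisher = inference.contingency_test(
        crosstab, "fisher", seed=_substream(seed, 23)
    )

    return LongitudinalComparison(
        fit_t1=fit1,
        fit_t2=fit2,
        alpha_change=alpha_change,
        alpha_spearman=alpha_rho,
        mantel=mantel_res,
        crosstab=crosstab,
        fisher=fisher,
        params={
            "k_max": k_max, "pseudocount": pseudocount,
            "low_biomass_threshold_t1": low_biomass_threshold_t1,
            "min_otu_fraction": min_otu_fraction,
            "rarefy_depth": rarefy_depth, "n_perm": n_perm, "seed": seed,
        },
    )
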