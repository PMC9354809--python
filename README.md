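# enteropipe

Enterotyping and longitudinal comparison of gut-microbiota count tables.

Amplicon cohort studies routinely ask two questions of a sample-by-taxon
read-count table: *does the cohort stratify into discrete community types
(enterotypes), and how do those types, and the community's diversity,
relate across timepoints or to clinical covariates?* `enteropipe` packages
that analysis for microbiome researchers as a tested, reusable library and
CLI — from raw genus/OTU count tables through enterotype fits, diversity
statistics, ordination, and permutation inference — together with a
Dirichlet-multinomial cohort simulator so every stage can be validated
without access to cohort data.

## The model

Samples are compared through the square root of the Jensen–Shannon
divergence of their relative-abundance profiles,

    d(i, j) = sqrt( JSD(p_i, p_j) ),   JSD(p, q) = ½ KL(p‖m) + ½ KL(q‖m),

with m = (p+q)/2 and natural logarithms (√JSD is a proper metric; JSD is
not). The distance matrix is clustered with Partitioning Around Medoids
(PAM) for k = 2..k_max, and the number of enterotypes is chosen by
maximizing the Calinski–Harabasz index

    CH(k) = [SSB/(k−1)] / [SSW/(n−k)]

computed in the PCoA embedding of the distances, cross-validated by the
mean silhouette width and the Tibshirani–Walther prediction strength. Each
cluster is named for its *driver genus* — the genus with the highest
within-cluster mean relative abundance. Samples whose library size falls
below an amplification threshold form their own low-biomass class, kept
out of the clustering but carried through cross-tabulations.

Around the fit sit the standard cohort statistics: Chao1 and Shannon alpha
diversity; Bray–Curtis, unweighted UniFrac and √JSD beta diversity;
PCoA with envfit driver-genus vectors; PERMANOVA and Mantel permutation
tests (add-one p-values, `(1+exceedances)/(1+n_perm)`); Wilcoxon /
Kruskal–Wallis / Spearman / chi-squared / Fisher / t tests with BH-FDR
correction; and a CLR-based Monte-Carlo differential-abundance screen with
a two-method concordance rule. See `docs/methods.md` for every convention.

## Worked example

Simulate a childhood-style cohort — 159 samples, two Dirichlet-multinomial
components driven by Bacteroides/Prevotella analogues (`g000`/`g001`) —
and fit enterotypes:

```python
from enteropipe import simulate_cohort, fit_enterotypes
from enteropipe.synthetic import childhood_config

table, truth = simulate_cohort(childhood_config(seed=4))
fit = fit_enterotypes(table, k_max=6, seed=4)
print(fit.summary())
```

```
Enterotype fit
============================================================
samples: 159 (0 low-biomass)
chosen k (argmax CH): 2

   calinski_harabasz  mean_silhouette  prediction_strength
k
2            46.0401           0.3138               0.9665
3            25.2087           0.0509               0.4888
4            18.0446           0.0448               0.3416
5            14.1573           0.0429               0.2793
6            11.8692           0.0175               0.2331

cluster  size  medoid        driver genus
      0   130  S0102         g000
      1    29  S0113         g001
```

The CH index peaks at k = 2 and the prediction strength (0.97) confirms the
split is reproducible across random halves; the two clusters recover the
two simulated components (130 vs 29 samples against the simulated 128/31
mixing weights) and each cluster's driver genus is the component's boosted
taxon. The same objects drive the end-to-end workflows:
`run_cross_sectional` (enterotypes + ordination + diversity comparisons +
covariate screen) and `run_longitudinal` (per-timepoint fits, cross-
timepoint Spearman/Mantel correlations, and Fisher's exact test on the
enterotype cross-tabulation). Equivalent CLI:

```bash
enteropipe simulate --preset childhood --seed 4 simdir
enteropipe enterotype simdir/counts.tsv fitdir --kmax 6 --seed 4
enteropipe run longitudinal counts_t1.tsv counts_t2.tsv outdir --seed 1
```

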