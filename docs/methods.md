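# Methods

## Overview

`enteropipe` implements the analysis pipeline used to stratify gut-microbiota
count tables into *enterotypes* — discrete community-composition classes —
and to compare cohorts across timepoints. The pipeline operates on
sample-by-taxon read-count tables (typically genus-aggregated 16S amplicon
profiles) and consists of:

1. **Preprocessing** — rare-taxon filtering, rarefaction, genus aggregation,
   relative-abundance conversion, low-biomass flagging.
2. **Enterotyping** — PAM clustering on the sqrt-JSD distance matrix with
   cluster-number selection by the Calinski–Harabasz (CH) index,
   cross-validated by mean silhouette width and prediction strength.
3. **Diversity** — Chao1, Shannon; Bray–Curtis, unweighted UniFrac, sqrt-JSD.
4. **Ordination** — PCoA with envfit-style driver-genus vectors.
5. **Inference** — PERMANOVA, Mantel, rank tests, Spearman correlation,
   contingency tests, summary-statistic t-tests, BH-FDR, and a CLR-based
   differential-abundance screen with a two-method concordance rule.
6. **Synthetic cohorts** — a Dirichlet-multinomial mixture generator that
   produces data with the statistical structure the analysis assumes, so the
   whole pipeline is testable without access to cohort data.

## Enterotyping model

Let `p_i` be the relative-abundance profile of sample `i` (zeros replaced by
a pseudocount, default `1e-6`, rows renormalized). The clustering distance is

    d(i, j) = sqrt(JSD(p_i, p_j))

with the Jensen–Shannon divergence in natural log. Plain JSD violates the
triangle inequality; its square root is a proper metric, which the test
suite verifies on random triples.

PAM (partitioning around medoids) minimizes the total distance of samples to
their cluster medoid. The implementation is the classical BUILD + SWAP
scheme made fully deterministic: BUILD seeds greedily from the most central
sample, SWAP accepts the best strictly-improving medoid/non-medoid exchange,
and all ties break toward the lowest sample index. PAM is a local search:
the SWAP phase guarantees no single exchange improves the objective, not a
global optimum, and the tests assert exactly that contract.

For each `k` in 2..k_max (default 10) the fit records:

- **CH index**, computed in the PCoA embedding of the distance matrix
  (axes with positive eigenvalues). CH is classically defined on
  coordinates, not distances; embedding first is the distance-native
  analogue used by enterotyping practice. `SSB/(k-1) / (SSW/(n-k))`, with a
  `+inf` sentinel when the within-cluster dispersion is numerically zero.
- **Mean silhouette width**, with singleton clusters scored 0 and the
  undefined 0/0 case (coincident data) scored 0 by convention.
- **Prediction strength** (Tibshirani–Walther): repeated 50/50 splits, PAM
  on each half, test samples assigned to the nearest training medoid, score
  = worst-cluster proportion of co-clustered test pairs also co-assigned by
  the training medoids. This is the only seeded step of the fit.

The selected `k` is the argmax of CH (ties to the smallest `k`); silhouette
and prediction strength are reported for cross-validation but never
override CH. Each cluster is named after its **driver genus** — the genus
with the highest within-cluster mean relative abundance; exact ties go to
the lexicographically first genus and are flagged.

Samples whose library size falls below the amplification threshold form a
separate **low-biomass class**: they are excluded from the distance matrix
and the PAM fit but retained in enterotype cross-tabulations as their own
category, mirroring how non-amplifiable samples are handled in practice.

## Preprocessing conventions

- Rare-taxon filter: drop taxa whose dataset-wide share of reads is
  *strictly* below the cut (default 0.005%); ties at the threshold are kept.
- Rarefaction subsamples each library without replacement
  (multivariate-hypergeometric draws) to a common depth, by default the
  dataset minimum. Samples below the target depth are excluded and
  reported rather than raising: with the dataset-minimum depth nothing is
  excluded, but synthetic cohorts contain amplification failures.
- The pipeline order is fixed as filter → rarefy. The operations do not
  commute (a taxon rare overall can dominate a rarefied library); the order
  is asserted as part of the contract.
- The differential-abundance prevalence filter keeps taxa reaching an
  abundance cut in at least a prevalence-cut fraction of samples. The
  abundance cut is interpreted on the relative scale with default 0.001
  (0.1%); the unit convention for this filter varies between pipelines, so
  both cuts are exposed as parameters.

## Diversity measures

- **Chao1** is the bias-corrected form `S_obs + F1(F1-1)/(2(F2+1))`
  (defined when F2 = 0); the classic variant is available by flag.
  Computed via scikit-bio.
- **Shannon** uses natural log by default, with the base exposed.
- **Bray–Curtis** on counts or relative abundances (equal at equal depth).
- **UniFrac** is the unweighted (incidence) variant: the fraction of
  observed branch length unique to one of the two samples. It is computed
  by postorder incidence propagation over the tree, which handles
  multifurcations (including star trees) directly; results match
  scikit-bio's implementation on rooted binary trees (tested). The
  weighted variant is out of scope. Choosing the unweighted form where the
  variant is unstated is recorded as an assumption of this package.

## Ordination and envfit

PCoA is classical metric scaling: Gower double-centering of −½ squared
distances and an `eigh` eigendecomposition. Negative eigenvalues (possible
for semi-metric dissimilarities) are dropped and their magnitudes reported;
no Cailliez/Lingoes correction is applied. Axis signs are fixed by forcing
the largest-magnitude loading positive so biplots are reproducible.

envfit regresses a continuous variable (e.g. a driver genus's relative
abundance) on the ordination axes (default: first 2). The reported
direction is the unit coefficient vector, `r²` the squared multiple
correlation, and the p-value comes from row permutations with the add-one
convention `p = (1 + exceedances)/(1 + n_perm)`; the smallest attainable p
is `1/(n_perm + 1)`. Zero-variance variables are flagged and excluded.

## Inference conventions

- **PERMANOVA** is the one-factor Anderson decomposition:
  `SST = Σ d²/n`, `SSW = Σ_groups Σ_within d²/n_g`,
  `F = [(SST−SSW)/(a−1)] / [SSW/(n−a)]`, with free label permutations and
  the add-one p. Multiple factors are tested marginally with BH adjustment
  across factors; missing factor values are dropped per test.
  `n_perm="exhaustive"` enumerates all permutations for small n.
- **Mantel** correlates corresponding off-diagonal entries (Spearman by
  default) under simultaneous row/column permutation of one matrix,
  one-sided (greater).
- **Rank tests** delegate to scipy: the two-sample Wilcoxon rank-sum uses
  the exact null distribution for small untied samples and the
  tie-corrected, continuity-corrected normal approximation otherwise;
  Kruskal–Wallis uses the tie-corrected H with a chi-squared reference.
- **Spearman correlation** uses exact enumeration of rank permutations for
  n ≤ 9 without ties, the t-approximation otherwise.
- **Contingency tests** follow the compatibility profile of R's defaults,
  under which the published Table-1-style cross-tabulations reproduce
  exactly: Yates continuity correction (statistic floored at 0) for 2×2
  chi-squared, plain Pearson otherwise, complete-case rows only. Fisher's
  exact test is the hypergeometric closed form for 2×2; for r×c it
  enumerates all tables when a cheap bound on the table count is ≤ 1e6 and
  otherwise switches to seeded Monte Carlo with 1e5 tables drawn from the
  margin-conditional distribution. The enumeration branch matches R's
  `fisher.test` on fixtures.
- **t-test from summary statistics** defaults to the pooled Student form
  (Welch by flag) so printed per-group means/SDs/ns are directly testable.
  Note that p-values recomputed from *rounded* printed summaries can differ
  from the originals in the last digit.
- **BH-FDR** is the step-up procedure via statsmodels.

### Differential abundance

`clr_da` is a CLR-based Monte-Carlo screen: per instance, each sample's
composition is drawn from Dirichlet(counts + 0.5), CLR-transformed, and
each taxon tested with a two-sided Wilcoxon rank-sum; p-values are averaged
over instances (default 128) and BH-adjusted across taxa. It preserves the
CLR + Wilcoxon skeleton of compositional DA practice but is not a
reimplementation of any published package. Averaging over posterior
instances makes the procedure mildly conservative, increasingly so at
shallow depth where posterior uncertainty decorrelates the instances; at
study-realistic depths (~2×10⁴ reads) the null per-taxon rejection rate
sits near the nominal level (measured in the acceptance suite).
`concordant_da` implements the two-method concordance rule: a taxon counts
only if BH-significant in both result sets with the same effect direction.

## Synthetic cohort generator

Each sample draws a mixture component `z` from the mixing weights, a
composition from Dirichlet(base with the component's driver concentration
multiplied by `driver_boost`), a library size from a rounded lognormal, and
counts from a multinomial. Amplification failure is a library-size
threshold, not a separate class. Two presets encode the regimes the
pipeline targets:

- **neonatal style**: five components with unequal, *fixed* class sizes
  (proportions 69/18/25/18/11, assigned by largest-remainder apportionment
  and shuffled — cohort group sizes are observed constants, not random
  draws), strong dominance (`boost = 60`, base 0.3 over 40 taxa),
  lognormal depths around 22,619 reads (a realistic amplicon median), and a
  failure-injection helper that forces a chosen number of samples (18 of
  159 in the paper-shaped scenario) to very low depth.
- **childhood style**: two components (fixed sizes in proportion 128/31,
  assigned the same way) driven by
  Bacteroides/Prevotella analogues with moderate dominance (`boost = 8`)
  and a shared elevated-baseline taxon, so the Bacteroides-analogue remains
  second-ranked inside the Prevotella-driven component.

Dominance levels are not published quantities; the boosts are simulation
knobs chosen so that the neonatal regime is strongly single-genus dominated
and the childhood regime only moderately so. Paired cohorts couple the two
timepoints through a single `association` parameter: with probability
`association` a sample's second-timepoint component is a fixed mapping of
its first; `association = 0` gives independent memberships.

All randomness flows from one seed; sub-streams are derived by fixed
offsets so each stage is reproducible in isolation, and every seeded entry
point is bit-reproducible (asserted in the tests).

What the generator does **not** emulate: taxonomic misassignment,
sequence-level errors, within-subject autocorrelation beyond the single
association parameter, or realistic phylogenetic signal (trees are random
binary trees with exponential branch lengths). Passing recovery tests
therefore show that the pipeline recovers the structure it assumes, not
that real cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

- sqrt-JSD guards tiny negative values from cancellation on identical rows.
- CH returns a capped `+inf` sentinel when SSW ≤ 1e-12·max(SSB, 1).
- PCoA treats eigenvalues within `1e-10·|λ_max|` of zero as zero.
- Permutation exceedance comparisons use a `1e-12` slack so ties at the
  observed statistic count as exceedances.
- All-zero samples are rejected by `to_relative` and alpha diversity with
  the offending sample named.

## Problem sizes in the validation suite

The acceptance checks run on simulated cohorts of 141–159 samples (the
cohort scale the pipeline targets), 40 taxa, and depths around 10⁴–2.2×10⁴
reads; type-I error is measured over 500 null replicates at 99 permutations
each; enumeration oracles run at n ≤ 6 where the full permutation group is
tractable. These sizes were chosen to exercise every code path at the scale
the analysis is designed for while keeping the suite quick to run.

## Known limitations

- PAM is a greedy local search; on adversarial fixtures it can return a
  swap-local optimum that is not the global k-medoids optimum.
- The CH-in-PCoA-embedding convention differs from computing CH on raw
  coordinates when the dissimilarity is strongly non-Euclidean.
- The r×c Fisher enumeration bound is crude (a product of margin ranges);
  it errs toward Monte Carlo, which is safe but stochastic.
- The multivariate mixed-effects modelling stage of typical cohort analyses
  (random-intercept logistic regression) is intentionally out of scope, as
  is full reimplementation of published DA packages.
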