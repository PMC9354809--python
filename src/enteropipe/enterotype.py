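"""Enterotype classification: PAM on the sqrt-JSD distance matrix with
cluster-number selection by the Calinski-Harabasz index, cross-validated by
mean silhouette width and prediction strength.

An enterotype is a discrete community-composition class obtained by
clustering samples on genus-level dissimilarities; each cluster is named
after its driver genus, the genus with the highest within-cluster mean
relative abundance.  Samples whose library size falls below an
amplification threshold form their own low-biomass class, excluded from the
distance computation but carried through cross-tabulations.

The clustering itself is fully deterministic (BUILD initialization,
index-based tie-breaks); prediction strength is the only seeded step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .diversity import beta_diversity
from .io import CountTable
from .ordination import pcoa
from .preprocess import RelAbundanceTable, flag_low_biomass, to_relative

#: sentinel reported when the within-cluster dispersion is exactly zero
CH_INFINITE = np.inf

LOW_BIOMASS_LABEL = "low_biomass"


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PAM


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: first medoid minimizes total distance, each next
    medoid maximizes the decrease in cost.  Ties broken by lowest index."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, d[:, m])
    return medoids


def pam_cluster(dist: DistanceMatrix, k: int) -> tuple[np.ndarray, list[str]]:
    """Partitioning Around Medoids (BUILD + SWAP) on a distance matrix.

    Minimizes the total distance of samples to their cluster medoid.  Fully
    deterministic: no random initialization, ties broken by lowest sample
    index.  Returns integer labels (clusters numbered by medoid order after
    sorting medoids by index) and the medoid sample ids.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if not 2 <= k <= n:
        raise ParameterError(f"k={k} out of range [2, {n}]")
    medoids = _pam_build(d, k)
    # SWAP phase: accept the best strictly-improving (medoid, non-medoid) swap
    while True:
        med = np.array(medoids)
        dist_to_med = d[:, med]  # (n, k)
        order = np.argsort(dist_to_med, axis=1)
        nearest = dist_to_med[np.arange(n), order[:, 0]]
        second = dist_to_med[np.arange(n), order[:, 1]]
        nearest_idx = order[:, 0]
        best_delta, best_swap = -1e-12, None
        non_med = [h for h in range(n) if h not in medoids]
        for mi in range(k):
            others_mask = nearest_idx == mi
            # cost change of removing medoid mi and adding candidate h
            base = np.where(others_mask, second, nearest)
            for h in non_med:
                delta = float(np.sum(np.minimum(base, d[:, h]) - nearest))
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    # medoids must belong to their own cluster even under distance ties
    for ci, m in enumerate(medoids):
        labels[m] = ci
    return labels, [dist.ids[m] for m in medoids]


def pam_objective(dist: DistanceMatrix, labels: np.ndarray, medoid_ids: list[str]) -> float:
    d = np.asarray(dist.data)
    med_idx = [list(dist.ids).index(m) for m in medoid_ids]
    return float(sum(d[i, med_idx[labels[i]]] for i in range(d.shape[0])))


# ---------------------------------------------------------------------------
# cluster-quality indices


def ch_index(dist: DistanceMatrix, labels: np.ndarray) -> float:
    """Calinski-Harabasz index computed in the PCoA embedding of the
    distance matrix (axes with positive eigenvalues).

    CH = [SSB / (k - 1)] / [SSW / (n - k)] with SSB/SSW the between/within
    sums of squared Euclidean distances to centroids in the embedding.
    Returns +inf when SSW is exactly 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ParameterError("ch_index needs >= 2 clusters")
    for c in uniq:
        if not (labels == c).any():
            raise ParameterError(f"cluster {c} is empty")
    x = pcoa(dist).coordinates
    grand = x.mean(axis=0)
    ssw = 0.0
    ssb = 0.0
    for c in uniq:
        xc = x[labels == c]
        cen = xc.mean(axis=0)
        ssw += float(((xc - cen) ** 2).sum())
        ssb += len(xc) * float(((cen - grand) ** 2).sum())
    if ssw <= 1e-12 * max(ssb, 1.0):
        return CH_INFINITE
    return (ssb / (k - 1)) / (ssw / (n - k))


def silhouette(dist: DistanceMatrix, labels: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b).

    a(i) is the mean intra-cluster distance excluding self, b(i) the
    smallest mean distance to another cluster.  Singleton clusters get
    s = 0; an undefined ratio (coincident data, max(a, b) = 0) is 0 by
    convention.
    """
    labels = np.asarray(labels)
    d = np.asarray(dist.data)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("silhouette needs >= 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            continue  # singleton -> 0
        a = d[i, same].sum() / (n_same - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def prediction_strength(
    dist: DistanceMatrix,
    k: int,
    n_splits: int = 20,
    seed: int | None = 0,
) -> float:
    """Tibshirani-Walther prediction strength for PAM at a given k.

    Each of ``n_splits`` rounds: random 50/50 split; PAM on each half;
    test-half samples are assigned to the nearest training medoid; the round
    score is the minimum over test clusters of the proportion of same-cluster
    test pairs that the training medoids also co-assign.  The mean over
    rounds is returned.  Deterministic per seed.
    """
    d = np.asarray(dist.data)
    n = d.shape[0]
    half = n // 2
    if k > half:
        raise ParameterError(f"k={k} exceeds half size {half}")
    rng = np.random.default_rng(seed)
    ids = list(dist.ids)
    scores = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr, te = np.sort(perm[:half]), np.sort(perm[half:])
        sub_tr = DistanceMatrix(d[np.ix_(tr, tr)], ids=[ids[i] for i in tr])
        sub_te = DistanceMatrix(d[np.ix_(te, te)], ids=[ids[i] for i in te])
        _, med_tr_ids = pam_cluster(sub_tr, k)
        te_labels, _ = pam_cluster(sub_te, k)
        med_tr = [ids.index(m) for m in med_tr_ids]
        assign = np.argmin(d[np.ix_(te, med_tr)], axis=1)
        worst = 1.0
        for c in np.unique(te_labels):
            members = np.flatnonzero(te_labels == c)
            m = len(members)
            if m < 2:
                continue
            # pairs co-assigned by training medoids: sum of C(n_v, 2) over
            # the assignment multiplicities within this test cluster
            _, cnt = np.unique(assign[members], return_counts=True)
            agree = float((cnt * (cnt - 1) // 2).sum())
            worst = min(worst, agree / (m * (m - 1) / 2))
        scores.append(worst)
    return float(np.mean(scores))


def driver_genera(
    relabund: RelAbundanceTable, labels: np.ndarray | pd.Series
) -> tuple[dict, list]:
    """Driver genus per cluster: the genus with the highest within-cluster
    mean relative abundance.  Exact ties go to the lexicographically first
    genus and are reported."""
    labels = pd.Series(np.asarray(labels), index=relabund.sample_ids)
    fr = pd.DataFrame(relabund.fractions, index=relabund.sample_ids, columns=relabund.taxon_ids)
    drivers: dict = {}
    ties: list = []
    for c in sorted(labels.unique()):
        means = fr[labels == c].mean(axis=0)
        top = means.max()
        best = sorted(means.index[means == top])
        drivers[c] = best[0]
        if len(best) > 1:
            ties.append((c, best))
    return drivers, ties


# ---------------------------------------------------------------------------
# model / results


@dataclass
class EnterotypeResults:
    """Fitted enterotype classification.

    Attributes
    ----------
    k_grid, ch, mean_silhouette, pred_strength : per-k selection indices
    chosen_k : argmax of CH over the grid (ties -> smallest k)
    labels : pd.Series mapping every input sample to its class; analyzable
        samples carry integer classes 0..k-1, flagged samples the
        ``low_biomass`` class
    medoids : medoid sample id per cluster
    drivers : driver genus per cluster
    """

    k_grid: list[int]
    ch: dict[int, float]
    mean_silhouette: dict[int, float]
    pred_strength: dict[int, float]
    chosen_k: int
    labels: pd.Series
    medoids: list[str]
    drivers: dict
    driver_ties: list
    low_biomass_samples: list[str]
    distance: DistanceMatrix = field(repr=False)
    params: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.chosen_k + (1 if self.low_biomass_samples else 0)

    def class_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "calinski_harabasz": [self.ch[k] for k in self.k_grid],
                "mean_silhouette": [self.mean_silhouette[k] for k in self.k_grid],
                "prediction_strength": [self.pred_strength[k] for k in self.k_grid],
            }
        ).set_index("k")

    def summary(self) -> str:
        lines = [
            "Enterotype fit",
            "=" * 60,
            f"samples: {len(self.labels)} "
            f"({len(self.low_biomass_samples)} low-biomass)",
            f"chosen k (argmax CH): {self.chosen_k}"
            + (f"  (+1 low-biomass class)" if self.low_biomass_samples else ""),
            "",
            self.selection_table().to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "cluster  size  medoid        driver genus",
        ]
        sizes = self.class_sizes()
        for c in range(self.chosen_k):
            lines.append(
                f"{c:>7}  {sizes.get(c, 0):>4}  {self.medoids[c]:<12}  {self.drivers.get(c, '-')}"
            )
        if self.low_biomass_samples:
            lines.append(
                f"{LOW_BIOMASS_LABEL:>7}  {len(self.low_biomass_samples):>4}  "
                f"{'-':<12}  - (non-amplifiable)"
            )
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "k_grid": self.k_grid,
            "calinski_harabasz": {str(k): self.ch[k] for k in self.k_grid},
            "mean_silhouette": {str(k): self.mean_silhouette[k] for k in self.k_grid},
            "prediction_strength": {str(k): self.pred_strength[k] for k in self.k_grid},
            "labels": {s: str(v) for s, v in self.labels.items()},
            "medoids": self.medoids,
            "drivers": {str(c): g for c, g in self.drivers.items()},
            "low_biomass_samples": self.low_biomass_samples,
            "params": self.params,
        }


class EnterotypeModel:
    """Enterotype classification model over a genus-level count table.

    Pipeline: flag low-biomass samples -> relative abundances -> sqrt-JSD
    distance matrix -> PAM for each k in the grid with CH / silhouette /
    prediction-strength indices -> chosen k = argmax CH -> driver genera.
    Flagged samples are appended as their own class.

    Parameters
    ----------
    table : CountTable
        Genus-level counts (aggregate OTUs first if needed).
    k_max : int
        Largest cluster number tried (grid is 2..k_max).
    pseudocount : float
        Zero replacement applied before the Jensen-Shannon divergence.
    low_biomass_threshold : int
        Samples with fewer total reads are flagged as non-amplifiable.
    """

    def __init__(
        self,
        table: CountTable,
        k_max: int = 10,
        pseudocount: float = 1e-6,
        low_biomass_threshold: int = 0,
    ) -> None:
        self.table = table
        self.k_max = int(k_max)
        self.pseudocount = float(pseudocount)
        self.low_biomass_threshold = int(low_biomass_threshold)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EnterotypeModel":
        table = CountTable(
            [str(s) for s in df.index], [str(t) for t in df.columns], df.to_numpy()
        )
        return cls(table, **kwargs)

    def fit(self, seed: int | None = 0, n_splits: int = 20) -> EnterotypeResults:
        analyzable, flagged = flag_low_biomass(self.table, self.low_biomass_threshold)
        if analyzable.n_samples < 3:
            raise ParameterError("need >= 3 analyzable samples")
        rel = to_relative(analyzable)
        dist = beta_diversity(rel, "sqrt_jsd", pseudocount=self.pseudocount)
        k_hi = min(self.k_max, analyzable.n_samples - 1, analyzable.n_samples // 2)
        k_grid = list(range(2, k_hi + 1))
        if not k_grid:
            raise ParameterError("k grid is empty; too few samples")
        ch: dict[int, float] = {}
        sil: dict[int, float] = {}
        ps: dict[int, float] = {}
        fits: dict[int, tuple[np.ndarray, list[str]]] = {}
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        for k in k_grid:
            labels_k, medoids_k = pam_cluster(dist, k)
            fits[k] = (labels_k, medoids_k)
            ch[k] = ch_index(dist, labels_k)
            sil[k] = silhouette(dist, labels_k)
            ps[k] = prediction_strength(
                dist, k, n_splits=n_splits,
                seed=np.random.default_rng([ss.entropy, k]).integers(2**31),
            )
        chosen_k = min(k for k in k_grid if ch[k] == max(ch.values()))
        labels_arr, medoids = fits[chosen_k]
        drivers, ties = driver_genera(rel, labels_arr)
        labels = pd.Series(
            list(labels_arr), index=analyzable.sample_ids, dtype=object
        )
        labels = labels.reindex(self.table.sample_ids)
        labels[labels.isna()] = LOW_BIOMASS_LABEL
        return EnterotypeResults(
            k_grid=k_grid,
            ch=ch,
            mean_silhouette=sil,
            pred_strength=ps,
            chosen_k=chosen_k,
            labels=labels,
            medoids=medoids,
            drivers=drivers,
            driver_ties=ties,
            low_biomass_samples=flagged,
            distance=dist,
            params={
                "k_max": self.k_max,
                "pseudocount": self.pseudocount,
                "low_biomass_threshold": self.low_biomass_threshold,
                "seed": seed,
                "n_splits": n_splits,
            },
        )


def fit_enterotypes(
    table: CountTable,
    k_max: int = 10,
    pseudocount: float = 1e-6,
    seed: int | None = 0,
    low_biomass_threshold: int = 0,
    n_splits: int = 20,
) -> EnterotypeResults:
    """Functional wrapper around :class:`EnterotypeModel`."""
    return EnterotypeModel(
        table,
        k_max=k_max,
        pseudocount=pseudocount,
        low_biomass_threshold=low_biomass_threshold,
    ).fit(seed=seed, n_splits=n_splits)
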