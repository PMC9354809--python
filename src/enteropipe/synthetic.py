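"""Synthetic cohort generation.

Communities are drawn from a Dirichlet-multinomial mixture: each sample
picks a component, the component's Dirichlet base (with its driver taxon's
concentration boosted) generates a composition, and reads are multinomial
at a lognormal library size.  This reproduces the overdispersed,
single-genus-dominated profiles typical of hospitalized preterm neonates
(strong boost, several components, one low-biomass group) as well as the
childhood regime (two components driven by Bacteroides/Prevotella
analogues, with a shared second-rank taxon).  Amplification failure is
modeled as a library-size threshold: failed samples are emitted with their
low depth and flagged, not dropped.

All generation is a pure function of the seed; sub-streams are derived from
the global seed by fixed offsets so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CountTable, PhyloTree, SampleMetadata, read_tree_string


class ConfigError(ValueError):
    pass


def _rng(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(o) for o in offsets])


@dataclass
class CohortConfig:
    """Parameters of a single-timepoint Dirichlet-multinomial cohort.

    ``dirichlet_base`` is the shared per-taxon concentration vector; each
    component multiplies its driver taxon's concentration by
    ``driver_boost``.  Library sizes are rounded lognormal; samples below
    ``failure_threshold`` reads are non-amplifiable.
    """

    n_samples: int = 159
    n_taxa: int = 40
    k: int = 5
    mixing_weights: np.ndarray | None = None
    dirichlet_base: np.ndarray | None = None
    driver_taxa: list[int] | None = None
    driver_boost: float = 50.0
    depth_log_mean: float = np.log(22_619.0)
    depth_log_sd: float = 0.6
    failure_threshold: int = 0
    exact_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.n_taxa:
            raise ConfigError("K cannot exceed n_taxa")
        if self.mixing_weights is None:
            self.mixing_weights = np.full(self.k, 1.0 / self.k)
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        if len(self.mixing_weights) != self.k:
            raise ConfigError("mixing_weights length != K")
        if abs(self.mixing_weights.sum() - 1.0) > 1e-12:
            raise ConfigError("mixing_weights must sum to 1 within 1e-12")
        if self.dirichlet_base is None:
            self.dirichlet_base = np.full(self.n_taxa, 1.0)
        self.dirichlet_base = np.asarray(self.dirichlet_base, dtype=float)
        if (self.dirichlet_base <= 0).any():
            raise ConfigError("dirichlet_base must be positive")
        if self.driver_taxa is None:
            self.driver_taxa = list(range(self.k))
        if len(self.driver_taxa) != self.k or len(set(self.driver_taxa)) != self.k:
            raise ConfigError("exactly one distinct driver taxon per component")
        if self.driver_boost < 1:
            raise ConfigError("driver_boost must be >= 1")

    def component_base(self, z: int) -> np.ndarray:
        base = self.dirichlet_base.copy()
        base[self.driver_taxa[z]] *= self.driver_boost
        return base


@dataclass
class PairedCohortConfig:
    """Two coupled timepoints.

    ``association`` in [0, 1] is the probability a sample keeps the fixed
    component mapping between timepoints: 1 couples membership fully, 0
    makes the second timepoint independent of the first.
    """

    config_t1: CohortConfig
    config_t2: CohortConfig
    association: float = 0.0
    component_map: dict[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.association <= 1:
            raise ConfigError("association must lie in [0, 1]")
        if self.config_t1.n_samples != self.config_t2.n_samples:
            raise ConfigError("paired cohorts need equal n_samples")
        if self.component_map is None:
            self.component_map = {
                z: z % self.config_t2.k for z in range(self.config_t1.k)
            }


def _taxon_ids(n_taxa: int) -> list[str]:
    return [f"g{j:03d}" for j in range(n_taxa)]


def _draw_cohort(
    config: CohortConfig, labels: np.ndarray, rng: np.random.Generator
) -> CountTable:
    comps = np.empty((config.n_samples, config.n_taxa))
    for i, z in enumerate(labels):
        comps[i] = rng.dirichlet(config.component_base(int(z)))
    depths = np.round(
        rng.lognormal(config.depth_log_mean, config.depth_log_sd, config.n_samples)
    ).astype(np.int64)
    depths = np.maximum(depths, 0)
    counts = np.empty((config.n_samples, config.n_taxa), dtype=np.int64)
    for i in range(config.n_samples):
        counts[i] = rng.multinomial(depths[i], comps[i])
    return CountTable(
        [f"S{i:04d}" for i in range(config.n_samples)],
        _taxon_ids(config.n_taxa),
        counts,
    )


def _draw_labels(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Component labels: iid categorical draws, or — with ``exact_counts`` —
    a random shuffle of the fixed class sizes implied by the mixing weights
    (largest-remainder apportionment), emulating a cohort whose group sizes
    are observed constants rather than random."""
    if not config.exact_counts:
        return rng.choice(config.k, size=config.n_samples, p=config.mixing_weights)
    raw = config.mixing_weights * config.n_samples
    counts = np.floor(raw).astype(int)
    remainder = config.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(config.k), counts)
    return labels[rng.permutation(config.n_samples)]


def simulate_cohort(config: CohortConfig) -> tuple[CountTable, np.ndarray]:
    """Draw a cohort count table and its true component labels."""
    rng = _rng(config.seed, 1)
    labels = _draw_labels(rng, config)
    table = _draw_cohort(config, labels, rng)
    return table, labels


def simulate_failures(
    config: CohortConfig, table: CountTable
) -> list[str]:
    """Sample ids whose library size fell below the failure threshold."""
    totals = table.sample_totals()
    return [s for s, t in zip(table.sample_ids, totals) if t < config.failure_threshold]


def simulate_paired(
    config: PairedCohortConfig,
) -> tuple[CountTable, CountTable, np.ndarray, np.ndarray]:
    """Draw two coupled timepoints over the same samples.

    With probability ``association`` a sample's t2 component is the fixed
    mapping of its t1 component; otherwise it is drawn fresh from the t2
    mixing weights, so association = 0 gives independent memberships.
    """
    rng = _rng(config.seed, 2)
    c1, c2 = config.config_t1, config.config_t2
    labels1 = _draw_labels(rng, c1)
    keep = rng.random(c1.n_samples) < config.association
    fresh = rng.choice(c2.k, size=c1.n_samples, p=c2.mixing_weights)
    mapped = np.array([config.component_map[int(z)] for z in labels1])
    labels2 = np.where(keep, mapped, fresh)
    table1 = _draw_cohort(c1, labels1, _rng(config.seed, 2, 1))
    table2 = _draw_cohort(c2, labels2, _rng(config.seed, 2, 2))
    return table1, table2, labels1, labels2


def simulate_tree(taxon_ids: list[str], seed: int = 0, rate: float = 1.0) -> PhyloTree:
    """Random rooted binary tree over the taxa with exponential branch
    lengths (random sequential joins), deterministic per seed."""
    if len(taxon_ids) < 2:
        raise ConfigError("need >= 2 taxa for a tree")
    rng = _rng(seed, 3)
    nodes = [f"{t}:{rng.exponential(rate):.6f}" for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")  # root: no length
        else:
            nodes.append(f"({a},{b}):{rng.exponential(rate):.6f}")
    return read_tree_string(nodes[0] + ";")


def simulate_metadata(
    labels,
    effects: dict,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> SampleMetadata:
    """Draw covariates conditionally on group labels.

    ``effects`` maps a variable name to either
    ``{"type": "continuous", "means": {label: mean}, "sd": s}`` or
    ``{"type": "categorical", "probs": {label: {level: prob}}}``.
    A variable whose per-group parameters coincide is independent of the
    labels (zero effect).
    """
    import pandas as pd

    labels = np.asarray(labels)
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    rng = _rng(seed, 4)
    cols = {}
    schema = {}
    for var, spec in effects.items():
        if spec["type"] == "continuous":
            means = np.array([spec["means"][z] for z in labels], dtype=float)
            cols[var] = means + rng.normal(0.0, spec["sd"], size=n)
            schema[var] = "continuous"
        elif spec["type"] == "categorical":
            values = []
            for z in labels:
                levels, probs = zip(*spec["probs"][z].items())
                probs = np.asarray(probs, dtype=float)
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigError(
                        f"probabilities for {var!r} group {z!r} do not sum to 1"
                    )
                values.append(levels[rng.choice(len(levels), p=probs)])
            cols[var] = values
            schema[var] = "categorical"
        else:
            raise ConfigError(f"unknown effect type {spec['type']!r}")
    return SampleMetadata(pd.DataFrame(cols, index=sample_ids), schema)


# ---------------------------------------------------------------------------
# study-shaped presets


def neonatal_config(seed: int = 0, n_samples: int = 159) -> CohortConfig:
    """Neonatal-style cohort: five strongly dominated components plus an
    amplification-failure fraction emulating the low-biomass class.

    Five driver components with unequal weights shaped like the observed
    class sizes (Enterobacter-, Clostridium-, Escherichia-, Enterococcus-
    and Staphylococcus-analogue dominance) and 18/159 of samples expected
    to fail amplification via a depressed library-size draw.
    """
    weights = np.array([69, 18, 25, 18, 11], dtype=float)
    weights /= weights.sum()
    return CohortConfig(
        n_samples=n_samples,
        n_taxa=40,
        k=5,
        mixing_weights=weights,
        dirichlet_base=np.full(40, 0.3),
        driver_taxa=[0, 1, 2, 3, 4],
        driver_boost=60.0,
        depth_log_mean=np.log(22_619.0),
        depth_log_sd=0.6,
        failure_threshold=1000,
        exact_counts=True,
        seed=seed,
    )


def childhood_config(seed: int = 0, n_samples: int = 159) -> CohortConfig:
    """Childhood-style cohort: two components driven by Bacteroides- and
    Prevotella-analogues, with the Bacteroides-analogue kept second-rank in
    the Prevotella-driven component."""
    n_taxa = 40
    base = np.full(n_taxa, 0.8)
    base[0] = 4.0  # Bacteroides-analogue stays abundant in both components
    weights = np.array([128, 31], dtype=float)
    weights /= weights.sum()
    return CohortConfig(
        n_samples=n_samples,
        n_taxa=n_taxa,
        k=2,
        mixing_weights=weights,
        dirichlet_base=base,
        driver_taxa=[0, 1],
        driver_boost=8.0,
        depth_log_mean=np.log(22_619.0),
        depth_log_sd=0.5,
        failure_threshold=0,
        exact_counts=True,
        seed=seed,
    )


def neonatal_failure_injection(
    table: CountTable, n_fail: int, seed: int = 0, max_reads: int = 200
) -> CountTable:
    """Replace the libraries of ``n_fail`` randomly chosen samples with very
    low read totals, emulating non-amplifiable low-biomass samples."""
    rng = _rng(seed, 5)
    idx = rng.choice(table.n_samples, size=n_fail, replace=False)
    counts = table.counts.copy()
    for i in idx:
        depth = int(rng.integers(0, max_reads))
        comp = counts[i] + 1.0
        counts[i] = rng.multinomial(depth, comp / comp.sum())
    return CountTable(list(table.sample_ids), list(table.taxon_ids), counts)
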