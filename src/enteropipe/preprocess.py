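"""Count-table preprocessing: rare-taxon filtering, rarefaction, genus
aggregation, relative abundances, low-biomass flagging and the
differential-abundance prevalence filter.

The pipeline order is fixed as filter -> rarefy: the rare-taxon filter is
applied on raw counts during table processing and rarefaction afterwards.
The two operations do not commute and the order is part of the contract.
All operations are pure functions of (input, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountTable, ValidationError


class ParameterError(ValueError):
    pass


@dataclass
class RelAbundanceTable:
    """Sample-by-taxon relative abundances; every row sums to 1."""

    sample_ids: list[str]
    taxon_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("fractions shape mismatch")
        if (fr < 0).any() or (fr > 1).any():
            raise ValidationError("fractions outside [0, 1]")
        sums = fr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(sums - 1)))]
            raise ValidationError(f"row {bad!r} does not sum to 1")
        self.fractions = fr


def filter_rare_taxa(table: CountTable, min_fraction: float = 0.00005) -> CountTable:
    """Drop taxa whose dataset-wide count share is strictly below ``min_fraction``.

    Mirrors the usual amplicon QC step of discarding OTUs representing less
    than 0.005% of all reads (mostly singletons).  The inequality is strict:
    a taxon exactly at the threshold is retained.
    """
    if not 0 <= min_fraction <= 1:
        raise ParameterError(f"min_fraction must be in [0, 1], got {min_fraction}")
    grand = table.total()
    taxon_totals = table.counts.sum(axis=0)
    keep = taxon_totals >= min_fraction * grand
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {
            t: g
            for t, g in table.taxonomy.items()
            if keep[table.taxon_ids.index(t)]
        }
    return CountTable(
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.counts[:, keep],
        taxonomy,
    )


def rarefy(
    table: CountTable,
    depth: int | str = "min",
    seed: int | None = 0,
) -> tuple[CountTable, list[str]]:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the smallest library size in the table.  Samples
    whose total is below ``depth`` are excluded and their ids returned,
    rather than raising: with the dataset-minimum depth nothing is excluded,
    but synthetic cohorts may contain amplification failures.

    Returns
    -------
    (rarefied_table, excluded_sample_ids)
    """
    totals = table.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    keep = totals >= depth
    if not keep.any():
        raise ParameterError(f"no sample reaches depth {depth}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    excluded = [s for s, k in zip(table.sample_ids, keep) if not k]
    out = CountTable(
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.taxon_ids),
        np.asarray(rows, dtype=np.int64),
        table.taxonomy,
    )
    return out, excluded


def aggregate_taxa(
    table: CountTable,
    level_map: dict[str, str] | None = None,
    unclassified: str = "unclassified",
) -> CountTable:
    """Sum counts within taxon groups (e.g. OTU -> genus).

    Taxa absent from the map fall into the ``unclassified`` bucket.  With no
    map given, the table's own taxonomy is used.  Group order follows first
    appearance in taxon_ids; the grand total is conserved.
    """
    if level_map is None:
        level_map = table.taxonomy or {}
    groups = [level_map.get(t, unclassified) for t in table.taxon_ids]
    group_ids = list(dict.fromkeys(groups))
    out = np.zeros((table.n_samples, len(group_ids)), dtype=np.int64)
    col = {g: j for j, g in enumerate(group_ids)}
    for j_src, g in enumerate(groups):
        out[:, col[g]] += table.counts[:, j_src]
    return CountTable(list(table.sample_ids), group_ids, out)


def to_relative(table: CountTable) -> RelAbundanceTable:
    """Convert counts to per-sample relative abundances."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    return RelAbundanceTable(
        list(table.sample_ids),
        list(table.taxon_ids),
        table.counts / totals[:, None],
    )


def flag_low_biomass(
    table: CountTable, threshold: int
) -> tuple[CountTable, list[str]]:
    """Partition samples into analyzable and low-biomass (non-amplifiable).

    Samples with fewer than ``threshold`` total reads are flagged: they are
    excluded from clustering but kept for enterotype-membership
    cross-tabulations, where they form their own class.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    totals = table.sample_totals()
    keep = totals >= threshold
    flagged = [s for s, k in zip(table.sample_ids, keep) if not k]
    analyzable = CountTable(
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.taxon_ids),
        table.counts[keep],
        table.taxonomy,
    )
    return analyzable, flagged


def prevalence_filter_da(
    table: CountTable,
    abundance_cut: float = 0.001,
    prevalence_cut: float = 0.01,
) -> CountTable:
    """Keep taxa reaching ``abundance_cut`` relative abundance in at least a
    ``prevalence_cut`` fraction of samples — the screening filter applied
    before differential-abundance testing.
    """
    for name, v in (("abundance_cut", abundance_cut), ("prevalence_cut", prevalence_cut)):
        if not 0 <= v <= 1:
            raise ParameterError(f"{name} must be in [0, 1], got {v}")
    totals = table.sample_totals().astype(float)
    nonzero = totals > 0
    rel = np.zeros_like(table.counts, dtype=float)
    rel[nonzero] = table.counts[nonzero] / totals[nonzero, None]
    # with abundance_cut == 0 every cell qualifies, so the filter is the identity
    hits = (rel >= abundance_cut).sum(axis=0)
    keep = hits >= prevalence_cut * table.n_samples
    return CountTable(
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.counts[:, keep],
        table.taxonomy
        and {t: g for t, g in table.taxonomy.items() if keep[table.taxon_ids.index(t)]},
    )
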