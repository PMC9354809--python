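"""Alpha- and beta-diversity measures.

Alpha: bias-corrected Chao1 richness and Shannon entropy (natural log by
default).  Beta: Bray-Curtis, unweighted UniFrac, and the square root of the
Jensen-Shannon divergence.  sqrt-JSD is the clustering distance used for
enterotyping: plain JSD violates the triangle inequality, its square root is
a proper metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import chao1 as _chao1

from .io import CountTable, PhyloTree, ValidationError
from .preprocess import RelAbundanceTable, to_relative

ALPHA_INDICES = ("chao1", "shannon")
BETA_METRICS = ("braycurtis", "unifrac", "sqrt_jsd")


def alpha_diversity(
    table: CountTable, index: str, shannon_base: float | None = None,
    chao1_bias_corrected: bool = True,
) -> pd.Series:
    """Per-sample alpha diversity.

    chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)) with F1/F2 the singleton and
    doubleton counts (bias-corrected form, defined even when F2 = 0).
    shannon = -sum p_i log p_i over non-zero p_i, natural log unless
    ``shannon_base`` is given.
    """
    if index not in ALPHA_INDICES:
        raise ValueError(f"unknown alpha index {index!r}")
    values = np.empty(table.n_samples)
    for i, row in enumerate(table.counts):
        if row.sum() == 0:
            raise ValidationError(f"sample {table.sample_ids[i]!r} has zero reads")
        if index == "chao1":
            values[i] = _chao1(row, bias_corrected=chao1_bias_corrected)
        else:
            p = row[row > 0] / row.sum()
            h = float(-(p * np.log(p)).sum())
            if shannon_base is not None:
                h /= np.log(shannon_base)
            values[i] = h
    return pd.Series(values, index=table.sample_ids, name=index)


def _sqrt_jsd_matrix(fractions: np.ndarray, pseudocount: float) -> np.ndarray:
    """Condensed sqrt-JSD distances with zero cells replaced by a pseudocount
    and rows renormalized before the divergence."""
    p = np.where(fractions > 0, fractions, pseudocount)
    p = p / p.sum(axis=1, keepdims=True)
    n = p.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        # scipy's jensenshannon is sqrt(JSD) with natural log
        out[k : k + n - 1 - i] = jensenshannon(p[i][:, None], p[i + 1 :].T, axis=0)
        k += n - 1 - i
    # guard tiny negative/nan from cancellation on identical rows
    return np.nan_to_num(np.clip(out, 0.0, None), nan=0.0)


def beta_diversity(
    table: CountTable | RelAbundanceTable,
    metric: str,
    tree: PhyloTree | None = None,
    pseudocount: float = 1e-6,
) -> DistanceMatrix:
    """Pairwise sample dissimilarity matrix.

    braycurtis : sum |x_i - y_i| / sum (x_i + y_i)
    unifrac    : unweighted (incidence) UniFrac — the fraction of observed
                 branch length unique to either sample; requires ``tree``
                 covering every taxon.
    sqrt_jsd   : square root of the Jensen-Shannon divergence (natural log)
                 on relative abundances, zeros replaced by ``pseudocount``.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown beta metric {metric!r}")
    ids = list(table.sample_ids)
    if metric == "sqrt_jsd":
        rel = table if isinstance(table, RelAbundanceTable) else to_relative(table)
        return DistanceMatrix(
            squareform(_sqrt_jsd_matrix(rel.fractions, pseudocount), checks=False),
            ids=ids,
        )
    if metric == "braycurtis":
        data = (
            table.fractions if isinstance(table, RelAbundanceTable) else table.counts
        )
        return _skbio_beta("braycurtis", data, ids=ids)
    # unweighted UniFrac
    if tree is None:
        raise ValueError("unifrac requires a tree")
    if isinstance(table, RelAbundanceTable):
        raise ValueError("unifrac is incidence-based; pass the count table")
    missing = sorted(set(table.taxon_ids) - set(tree.leaf_names))
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    return DistanceMatrix(_unweighted_unifrac(table, tree), ids=ids)


def _unweighted_unifrac(table: CountTable, tree: PhyloTree) -> np.ndarray:
    """Unweighted UniFrac by postorder incidence propagation.

    For every branch, record which samples contain any taxon below it; the
    distance between two samples is the branch length unique to either,
    divided by the branch length observed in at least one.  Multifurcations
    (including star trees) are handled directly.
    """
    col = {t: j for j, t in enumerate(table.taxon_ids)}
    present = table.counts > 0  # (n_samples, n_taxa)
    n = table.n_samples
    branch_lengths: list[float] = []
    branch_incidence: list[np.ndarray] = []
    node_presence: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            j = col.get(node.name)
            pres = present[:, j].copy() if j is not None else np.zeros(n, bool)
        else:
            pres = np.zeros(n, bool)
            for child in node.children:
                pres |= node_presence.pop(id(child))
        node_presence[id(node)] = pres
        if node.parent is not None and node.length:
            branch_lengths.append(float(node.length))
            branch_incidence.append(pres)
    lengths = np.asarray(branch_lengths)
    inc = (
        np.asarray(branch_incidence)
        if branch_incidence
        else np.zeros((0, n), bool)
    )
    d = np.zeros((n, n))
    for i in range(n - 1):
        a = inc[:, i]
        for j in range(i + 1, n):
            b = inc[:, j]
            observed = lengths[a | b].sum()
            unique = lengths[a ^ b].sum()
            d[i, j] = d[j, i] = unique / observed if observed > 0 else 0.0
    return d
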