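"""Reading, writing and validation of on-disk artifacts.

All tabular artifacts are tab-separated text: count tables with samples in
rows and taxa in columns, metadata tables with a header row, distance
matrices with a leading identifier row/column.  Trees are newick.  Reports
are JSON with stable key order plus a TSV summary.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CountTable:
    """Sample-by-taxon matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``counts``.
    taxon_ids : list of str
        Unique taxon identifiers (OTUs or genera), one per column.
    counts : ndarray of int, shape (n_samples, n_taxa)
        Read counts; non-negative integers.
    taxonomy : dict, optional
        Map from taxon_id to genus label, for genus aggregation.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon identifiers")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.taxon_ids)
            if unknown:
                raise ValidationError(f"taxonomy keys not in taxon_ids: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample read totals (library sizes)."""
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(list(keep), list(self.taxon_ids), self.counts[idx], self.taxonomy)


@dataclass
class SampleMetadata:
    """Per-sample covariates with declared column types.

    ``data`` is indexed by sample_id; continuous columns are float with NaN
    for missing, categorical columns keep string levels in first-appearance
    order with missing as NaN.
    """

    data: pd.DataFrame
    schema: dict[str, str]  # column -> "continuous" | "categorical"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample row {dup!r}")
        for col, kind in self.schema.items():
            if kind not in ("continuous", "categorical"):
                raise ValidationError(f"unknown column type {kind!r} for {col!r}")
            if col not in self.data.columns:
                raise ValidationError(f"declared column {col!r} missing from data")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def levels(self, col: str) -> list[str]:
        """Categorical levels in first-appearance order."""
        if self.schema[col] != "categorical":
            raise ValidationError(f"{col!r} is not categorical")
        seen = self.data[col].dropna()
        return list(dict.fromkeys(seen))


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree with non-negative branch lengths."""

    tree: TreeNode
    leaf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if any(n is None for n in names):
            raise ValidationError("tree has unlabeled leaves")
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf labels: {dups}")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        self.leaf_names = names

    def total_branch_length(self) -> float:
        return sum(
            node.length or 0.0 for node in self.tree.traverse(include_self=False)
        )


# ---------------------------------------------------------------------------
# readers


def read_count_table(path: str | Path, taxonomy_path: str | Path | None = None) -> CountTable:
    """Read a tab-separated count table (samples in rows, taxa in columns).

    The first row holds taxon_ids, the first column sample_ids, and the body
    must be non-negative integers.  An optional two-column taxonomy file maps
    taxon_id to genus.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        taxon_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            if len(parts) - 1 != len(taxon_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(taxon_ids)} cells, got {len(parts) - 1}"
                )
            row = []
            for j, cell in enumerate(parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"(sample {parts[0]!r}, taxon {taxon_ids[j]!r})"
                    ) from None
                if v < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count {v} "
                        f"(sample {parts[0]!r}, taxon {taxon_ids[j]!r})"
                    )
                row.append(v)
            rows.append(row)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = {}
        with open(taxonomy_path) as fh:
            for line in fh:
                if line.strip():
                    taxon, genus = line.rstrip("\n").split("\t")[:2]
                    taxonomy[taxon] = genus
    return CountTable(sample_ids, taxon_ids, np.asarray(rows, dtype=np.int64), taxonomy)


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.taxon_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_metadata(
    path: str | Path,
    schema: dict[str, str],
    missing: str = "NA",
) -> SampleMetadata:
    """Read a tab-separated metadata table with a header row.

    ``schema`` declares each column continuous or categorical; the missing
    marker (default "NA") becomes NaN and is never imputed.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, na_values=[missing], keep_default_na=False
    )
    df.index = df.index.astype(str)
    out = {}
    for col, kind in schema.items():
        if col not in df.columns:
            raise ValidationError(f"declared column {col!r} missing from {path}")
        if kind == "continuous":
            try:
                out[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(
                    f"continuous column {col!r} has a non-numeric entry: {exc}"
                ) from None
        else:
            out[col] = df[col]
    return SampleMetadata(pd.DataFrame(out, index=df.index), dict(schema))


def write_metadata(meta: SampleMetadata, path: str | Path, missing: str = "NA") -> None:
    meta.data.to_csv(path, sep="\t", na_rep=missing, index_label="sample_id")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a single newick tree; absent branch lengths are treated as 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises parser-specific errors
        raise FormatError(f"unparseable newick in {path}: {exc}") from None
    return PhyloTree(tree)


def read_tree_string(newick: str) -> PhyloTree:
    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"unparseable newick: {exc}") from None
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    tree.tree.write(str(path), format="newick")


def read_distance_matrix(path: str | Path):
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])


def write_distance_matrix(dm, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# structured report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_report_dict"):
        return _jsonable(obj.to_report_dict())
    return obj


def write_report(results: dict, path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write a machine-readable JSON report (sorted keys, full precision).

    ``results`` maps entry names to result objects (anything exposing
    ``to_report_dict``) or plain values.  If ``summary_path`` is given, a
    flat human-readable TSV summary is written beside the JSON.
    """
    payload = _jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if summary_path is not None:
        rows = []

        def _flatten(prefix, obj):
            if isinstance(obj, dict):
                for k in sorted(obj):
                    _flatten(f"{prefix}.{k}" if prefix else str(k), obj[k])
            elif isinstance(obj, list):
                rows.append((prefix, ";".join(repr(v) for v in obj)))
            else:
                rows.append((prefix, repr(obj)))

        _flatten("", payload)
        with open(summary_path, "w") as fh:
            fh.write("entry\tvalue\n")
            for name, value in rows:
                fh.write(f"{name}\t{value}\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
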