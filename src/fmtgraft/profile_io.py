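"""Reading, validation, and reconciliation of taxonomic profiles.

The pipeline consumes species-level taxonomic profiles (OGU counts per
sample), per-sample metadata describing the FMT study design, and a rooted
phylogeny over the OGUs.  This module defines the in-memory containers and
the TSV/Newick readers, plus rank collapsing of lineage-annotated tables.

File dialects
-------------
Feature table
    Tab-separated, features as rows by default (the Woltka/QIIME
    convention).  First header cell is ``#OGU_ID``; remaining header cells
    are sample ids; cells are non-negative integers.
Metadata
    Tab-separated with columns ``sample_id``, ``animal_id``, ``role``,
    ``phase``, ``timepoint``.
Lineages
    Tab-separated two-column file ``feature_id<TAB>lineage`` where the
    lineage is a semicolon-delimited ranked string
    (``k__...;p__...;c__...;o__...;f__...;g__...;s__...``).
Tree
    Newick with branch lengths on every non-root edge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "SampleRecord",
    "ReconciledBundle",
    "ValidationError",
    "RANKS",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_lineages",
    "read_newick",
    "write_newick",
    "reconcile",
    "collapse_to_rank",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))

ROLES = frozenset({"donor", "recipient", "control", "slurry"})
PHASES = frozenset({"baseline", "fmt_slurry", "post_fmt"})


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass(frozen=True)
class FeatureTable:
    """A features x samples count matrix with optional ranked lineages.

    ``counts[i, j]`` is the number of reads of feature ``feature_ids[i]``
    in sample ``sample_ids[j]``.  Counts are non-negative integers; ids
    are unique within their axis.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    lineages: Mapping[str, str] | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        for axis_name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if list(ids).count(x) > 1})
                raise ValidationError(f"duplicate {axis_name} ids: {dupes}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector (over ``feature_ids``) for one sample."""
        return self.counts[:, self.sample_index(sample_id)].copy()

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self, sample_id: str) -> dict[str, float]:
        """Proportions for one sample; empty dict for an all-zero sample."""
        col = self.sample_counts(sample_id)
        total = col.sum()
        if total == 0:
            return {}
        return {f: c / total for f, c in zip(self.feature_ids, col) if c > 0}

    def filter_samples(self, keep: Sequence[str]) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(keep)]
        idx = [self.sample_ids.index(s) for s in keep]
        return replace(self, sample_ids=tuple(keep), counts=self.counts[:, idx])

    def filter_features(self, keep: Sequence[str]) -> "FeatureTable":
        keep_set = set(keep)
        kept = [f for f in self.feature_ids if f in keep_set]
        idx = [self.feature_ids.index(f) for f in kept]
        lineages = None
        if self.lineages is not None:
            lineages = {f: l for f, l in self.lineages.items() if f in keep_set}
        return replace(
            self, feature_ids=tuple(kept), counts=self.counts[idx, :], lineages=lineages
        )

    def with_lineages(self, lineages: Mapping[str, str]) -> "FeatureTable":
        return replace(self, lineages=dict(lineages))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequenced sample in the FMT study design."""

    sample_id: str
    animal_id: str
    role: str  # donor | recipient | control | slurry
    phase: str  # baseline | fmt_slurry | post_fmt
    timepoint: int
    collection_index: int = 0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r} for {self.sample_id}")
        if (self.role == "slurry") != (self.phase == "fmt_slurry"):
            raise ValidationError(
                f"sample {self.sample_id}: role=slurry iff phase=fmt_slurry "
                f"(got role={self.role}, phase={self.phase})"
            )
        if self.timepoint < 0:
            raise ValidationError(f"negative timepoint for {self.sample_id}")
        if self.phase == "baseline" and not (0 <= self.timepoint <= 2):
            raise ValidationError(
                f"baseline timepoint must be 0..2, got {self.timepoint} for {self.sample_id}"
            )
        if self.phase in ("fmt_slurry", "post_fmt") and not (1 <= self.timepoint <= 8):
            raise ValidationError(
                f"{self.phase} timepoint must be 1..8, got {self.timepoint} "
                f"for {self.sample_id}"
            )


@dataclass(frozen=True)
class ReconciledBundle:
    """Feature table, metadata, and tree restricted to their common ids."""

    table: FeatureTable
    records: tuple[SampleRecord, ...]
    tree: TreeNode | None
    dropped_samples: tuple[str, ...]
    dropped_features: tuple[str, ...]

    def record_for(self, sample_id: str) -> SampleRecord:
        for rec in self.records:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)


# -- feature table -------------------------------------------------------------


def read_feature_table(
    path: str | Path | io.TextIOBase, orientation: str = "features_as_rows"
) -> FeatureTable:
    """Read a TSV count table.

    ``orientation`` declares what the file's rows are; with
    ``samples_as_rows`` the parsed matrix is transposed so the returned
    table is always features x samples.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    header = text.split("\n", 1)[0].rstrip("\r").split("\t")
    if len(header) < 2:
        raise ValidationError("feature table has no data columns (header line 1)")
    cols = header[1:]
    if len(set(cols)) != len(cols):  # pandas would silently mangle duplicates
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValidationError(f"duplicate column ids: {dupes}")
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed feature table: {exc}") from exc
    if orientation == "samples_as_rows":
        df = df.T
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate row ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValidationError(f"duplicate column ids: {dupes}")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in feature table: {exc}") from exc
    if np.any(np.isnan(counts)):
        raise ValidationError("missing cell in feature table")
    if np.any(counts < 0):
        raise ValidationError("negative count in feature table")
    if np.any(np.mod(counts, 1) != 0):
        raise ValidationError("non-integer count in feature table")
    return FeatureTable(
        feature_ids=tuple(str(i) for i in df.index),
        sample_ids=tuple(str(c) for c in df.columns),
        counts=counts.astype(np.int64),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "#OGU_ID"
    df.to_csv(path, sep="\t")


# -- metadata ------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "animal_id", "role", "phase", "timepoint")


def read_metadata(path: str | Path | io.TextIOBase) -> tuple[SampleRecord, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            tp = int(getattr(row, "timepoint"))
        except ValueError:
            raise ValidationError(
                f"non-integer timepoint {getattr(row, 'timepoint')!r} "
                f"in metadata row {i + 1}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                animal_id=str(row.animal_id),
                role=str(row.role),
                phase=str(row.phase),
                timepoint=tp,
                collection_index=i,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    return tuple(records)


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "animal_id": r.animal_id,
            "role": r.role,
            "phase": r.phase,
            "timepoint": r.timepoint,
        }
        for r in sorted(records, key=lambda r: r.collection_index)
    ]
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_lineages(path: str | Path) -> dict[str, str]:
    """Read a two-column ``feature_id<TAB>lineage`` file (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValidationError("lineage file needs two tab-separated columns")
    first = str(df.iloc[0, 0]).lstrip("#").lower()
    if first in ("feature_id", "ogu_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# -- tree ----------------------------------------------------------------------


def read_newick(source: str | Path | io.TextIOBase) -> TreeNode:
    """Parse a rooted Newick tree, enforcing branch lengths on non-root edges."""
    try:
        tree = TreeNode.read(source, format="newick")
    except Exception as exc:  # skbio raises parser-specific subclasses
        raise ValidationError(f"Newick parse error: {exc}") from exc
    tips = list(tree.tips())
    if not tips:
        # single-tip string like "(A:1);" parses to a root with one child
        raise ValidationError("tree has no tips")
    labels = [t.name for t in tips]
    if None in labels:
        raise ValidationError("tree has an unlabeled tip")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"missing branch length on edge above {node.name or 'internal node'}"
            )
        if node.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# -- reconciliation ------------------------------------------------------------


def reconcile(
    table: FeatureTable,
    records: Sequence[SampleRecord],
    tree: TreeNode | None = None,
) -> ReconciledBundle:
    """Restrict table/metadata/tree to their common samples and features.

    Samples are kept when present in both the table and the metadata;
    features are kept when they are tips of the tree (if a tree is given).
    Every dropped id is reported in the returned bundle.
    """
    meta_ids = {r.sample_id for r in records}
    table_ids = set(table.sample_ids)
    common = [s for s in table.sample_ids if s in meta_ids]
    if not common:
        raise ValidationError("no samples shared between table and metadata")
    dropped_samples = sorted((table_ids | meta_ids) - set(common))

    dropped_features: list[str] = []
    out = table.filter_samples(common)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        dropped_features = [f for f in out.feature_ids if f not in tips]
        if dropped_features:
            out = out.filter_features([f for f in out.feature_ids if f in tips])
    kept_records = tuple(r for r in records if r.sample_id in set(common))
    return ReconciledBundle(
        table=out,
        records=kept_records,
        tree=tree,
        dropped_samples=tuple(dropped_samples),
        dropped_features=tuple(dropped_features),
    )


# -- rank collapsing -----------------------------------------------------------


def _rank_label(lineage: str, rank: str) -> str:
    prefix = _RANK_PREFIX[rank]
    for part in (p.strip() for p in lineage.split(";")):
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            if name:
                return name
    return "Unclassified"


def collapse_to_rank(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum feature counts within each label at ``rank``.

    Features lacking the rank in their lineage are pooled under
    ``"Unclassified"``.  Per-sample totals are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.lineages is None:
        raise ValidationError("collapse_to_rank requires lineages on the table")
    missing = [f for f in table.feature_ids if f not in table.lineages]
    if missing:
        raise ValidationError(f"features lacking lineage: {missing[:5]}")

    labels = [_rank_label(table.lineages[f], rank) for f in table.feature_ids]
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for label, row in zip(labels, table.counts):
        if label not in rows:
            order.append(label)
            rows[label] = row.astype(np.int64).copy()
        else:
            rows[label] += row
    # truncated lineages keep the collapsed table re-collapsible
    rank_i = RANKS.index(rank)
    new_lineages = {}
    for label, lineage in zip(labels, (table.lineages[f] for f in table.feature_ids)):
        if label == "Unclassified":
            new_lineages.setdefault(label, "")
            continue
        parts = [p.strip() for p in lineage.split(";")][: rank_i + 1]
        new_lineages.setdefault(label, ";".join(parts))
    return FeatureTable(
        feature_ids=tuple(order),
        sample_ids=table.sample_ids,
        counts=np.vstack([rows[label] for label in order]),
        lineages=new_lineages,
    )
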