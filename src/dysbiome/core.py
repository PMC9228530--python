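"""Core data structures and on-disk formats.

The pipeline's central object is a taxa-by-samples integer count table
(:class:`FeatureTable`) whose rows carry Greengenes-style 7-rank lineage
strings.  Sample group labels live in :class:`SampleMetadata`; trees are
:class:`skbio.TreeNode` objects and pairwise dissimilarities are
:class:`skbio.DistanceMatrix` objects.  Everything is read and written as
plain TSV / Newick so any stage of the pipeline can be re-run on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("dysbiome")

#: Column headers recognised as carrying taxonomy in a feature-table TSV
#: (QIIME2 exports use either spelling).
TAXONOMY_COLUMNS = ("taxonomy", "Taxon")

#: Empty 7-rank lineage used when a table carries no taxonomy column.
EMPTY_LINEAGE = "k__;p__;c__;o__;f__;g__;s__"


class TableError(ValueError):
    """A feature table violated its contract (shape, dtype, ids)."""


@dataclass
class FeatureTable:
    """Taxa x samples non-negative integer counts plus per-taxon lineages.

    Parameters
    ----------
    counts : pd.DataFrame
        Integer counts, taxa in rows, samples in columns.  Row and column
        labels must be unique.
    lineages : pd.Series, optional
        Lineage string per taxon.  Defaults to the empty 7-rank lineage.
    """

    counts: pd.DataFrame
    lineages: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise TableError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise TableError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise TableError("counts must be numeric")
        if arr.size:
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise TableError(
                    f"negative count at taxon {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise TableError(
                    f"non-integer count at taxon {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}"
                )
        self.counts = self.counts.astype(np.int64)
        if self.lineages is None:
            self.lineages = pd.Series(EMPTY_LINEAGE, index=self.counts.index)
        else:
            self.lineages = self.lineages.reindex(self.counts.index)
            if self.lineages.isna().any():
                missing = self.lineages.index[self.lineages.isna()].tolist()
                raise TableError(f"taxa without lineage: {missing[:5]}")

    # -- identity ---------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lineages.equals(
            other.lineages
        )

    # -- views ------------------------------------------------------------
    def sample_totals(self) -> pd.Series:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised view; never written back to disk as counts."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise TableError(f"samples with zero total reads: {bad}")
        return self.counts / totals

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    # -- subsetting (order-stable) ----------------------------------------
    def select_taxa(self, taxa) -> "FeatureTable":
        taxa = [t for t in self.taxon_ids if t in set(taxa)]
        return FeatureTable(self.counts.loc[taxa], self.lineages.loc[taxa])

    def select_samples(self, samples) -> "FeatureTable":
        samples = [s for s in self.sample_ids if s in set(samples)]
        return FeatureTable(self.counts[samples], self.lineages)

    def with_counts(self, counts: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(counts, self.lineages.reindex(counts.index))


@dataclass
class SampleMetadata:
    """Mapping of sample id to a group label (two-level factor, e.g. CD/HC)."""

    groups: pd.Series

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        self.groups = self.groups.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def members(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])

    def labels_for(self, sample_ids) -> pd.Series:
        labels = self.groups.reindex(sample_ids)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise TableError(f"samples without metadata: {missing[:5]}")
        return labels

    def require_two_levels(self) -> tuple[str, str]:
        lv = self.levels()
        if len(lv) != 2:
            raise TableError(f"expected exactly two group levels, got {lv}")
        return lv[0], lv[1]


@dataclass
class GroupTestResult:
    """One group-comparison test: statistic, raw p and BH q within a family."""

    metric: str
    statistic: float
    p_value: float
    q_value: float | None = None
    permutations: int | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "q_value": None if self.q_value is None else float(self.q_value),
            "permutations": self.permutations,
        }


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path,
    orientation: str = "taxa-in-rows",
    taxonomy_columns=TAXONOMY_COLUMNS,
) -> FeatureTable:
    """Read a TSV count table (first column = ids, optional taxonomy column).

    ``orientation`` is ``taxa-in-rows`` (default) or ``samples-in-rows``;
    either way the result is normalised to taxa x samples.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate row ids in {path}: {dupes[:5]}")
    lineages = None
    for col in taxonomy_columns:
        if col in raw.columns:
            lineages = raw.pop(col)
            break
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            row = converted.index[converted.isna()][0]
            raise TableError(
                f"non-numeric count at row {row!r}, column {col!r} in {path}"
            )
        numeric[col] = converted
    if orientation == "samples-in-rows":
        numeric = numeric.T
        if lineages is not None:
            raise TableError("taxonomy column requires taxa-in-rows orientation")
    elif orientation != "taxa-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return FeatureTable(numeric, lineages)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.counts.copy()
    out["taxonomy"] = table.lineages
    out.index.name = "feature-id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    """Read a two-column TSV: sample id, group label (header row required)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise TableError(f"metadata {path} needs a group column")
    return SampleMetadata(df.iloc[:, 0])


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.groups.to_frame("group")
    df.index.name = "sample-id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths default to 0."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise TableError(f"duplicate leaf names in {path}: {dupes}")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise TableError(f"negative branch length at {node.name!r}")
    if n_missing:
        logger.warning("%d branch lengths missing in %s; set to 0", n_missing, path)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Distance matrix I/O
# ---------------------------------------------------------------------------

SYMMETRY_TOL = 1e-9


def read_distance_matrix(path, tol: float = SYMMETRY_TOL) -> DistanceMatrix:
    """Read a square labelled TSV; symmetrise within ``tol``, error beyond."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise TableError(f"distance matrix {path} is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise TableError(f"row/column labels differ in {path}")
    arr = df.to_numpy(dtype=float)
    asym = np.abs(arr - arr.T).max() if arr.size else 0.0
    if asym > tol:
        raise TableError(f"asymmetry {asym:.3g} exceeds tolerance {tol:g} in {path}")
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return DistanceMatrix(arr, ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample-id"
    df.to_csv(path, sep="\t")
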