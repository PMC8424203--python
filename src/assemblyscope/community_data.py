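"""Data model and I/O for count tables, phylogenies and sample metadata.

The central currency of every analysis stage is the :class:`CountTable`,
a samples x taxa matrix of non-negative integer abundances (an OTU/ASV
table).  Phylogenies are rooted, branch-length-bearing trees whose tips
cover the table's taxa; all phylogenetic distances are patristic
distances on that tree.  This module also provides rarefaction
(random subsampling without replacement to a common depth) and
reconciliation of a table with a tree.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "PairwiseMatrix",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_tree",
    "write_tree",
    "rarefy",
    "match_tree_table",
    "patristic_distances",
]


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class CountTable:
    """Samples x taxa non-negative integer abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa, values are counts.

    Notes
    -----
    Invariants enforced at construction: unique sample and taxon ids,
    no negative entries, integral values, and strictly positive row
    sums (an all-zero sample is an error naming the sample).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise DataValidationError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy()
        if values.size == 0:
            raise DataValidationError("count table is empty")
        if (values < 0).any():
            raise DataValidationError("negative counts are not allowed")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise DataValidationError(
                    "non-integer counts; rarefy/round upstream or pass allow_float"
                )
            self.data = df.round().astype(np.int64)
        empty = self.data.sum(axis=1) == 0
        if empty.any():
            raise DataValidationError(
                f"samples with zero total counts: {list(self.data.index[empty])}"
            )

    # -- accessors -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_taxa) integer array."""
        return self.data.to_numpy()

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts (each row sums to 1)."""
        x = self.data.to_numpy(dtype=float)
        return x / x.sum(axis=1, keepdims=True)

    def presence(self) -> np.ndarray:
        """Boolean occurrence matrix (count > 0)."""
        return self.data.to_numpy() > 0

    def drop_empty_taxa(self) -> "CountTable":
        """Return a table without all-zero taxon columns."""
        keep = self.data.sum(axis=0) > 0
        return CountTable(self.data.loc[:, keep])

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(taxon_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class PairwiseMatrix:
    """Symmetric id-indexed matrix carrying a named metric.

    Dissimilarities (Bray-Curtis, betaMNTD) have zero diagonal; signed
    scores (betaNTI, RC_bray) use NaN on the diagonal.  Undefined
    entries (e.g. a degenerate null distribution) are NaN.
    """

    ids: list[str]
    values: np.ndarray
    metric: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataValidationError("matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise DataValidationError(f"{self.metric} matrix is not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label=self.metric)

    def pair(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major pair order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


# -- I/O ---------------------------------------------------------------

def read_count_table(
    path,
    format: str = "tsv",
    taxa_as_rows: bool = True,
    allow_float: bool = False,
) -> CountTable:
    """Read a count table from TSV or dense BIOM-JSON.

    The TSV dialect expects taxa as rows and samples as columns with the
    taxon id in the first column (set ``taxa_as_rows=False`` for the
    transposed layout).  Non-integer entries are rejected unless
    ``allow_float`` is set, in which case they are floored with a warning.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        dup_rows = df.index[df.index.duplicated()].unique()
        if len(dup_rows):
            raise DataValidationError(f"duplicate ids in first column: {sorted(dup_rows)}")
        if taxa_as_rows:
            df = df.T
    elif format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise DataValidationError("only dense BIOM-JSON is supported")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        df = pd.DataFrame(np.asarray(doc["data"]), index=taxa, columns=samples).T
    else:
        raise ValueError(f"unknown format: {format!r}")

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if np.allclose(values, np.round(values)):
            df = df.round().astype(np.int64)
        elif allow_float:
            logger.warning("non-integer counts floored to integers")
            df = np.floor(df).astype(np.int64)
        else:
            raise DataValidationError(
                "table contains non-integer counts (pass allow_float to floor them)"
            )
    return CountTable(df.astype(np.int64))


def write_count_table(table: CountTable, path, taxa_as_rows: bool = True) -> None:
    """Write a table as TSV (taxa as rows by default, matching the reader)."""
    df = table.data.T if taxa_as_rows else table.data
    df.to_csv(path, sep="\t", index_label="#OTU_ID")


def read_metadata(path, sample_ids=None) -> pd.DataFrame:
    """Read a per-sample metadata TSV (first column = sample id).

    If ``sample_ids`` is given, validates coverage and returns rows in
    that order.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if sample_ids is not None:
        missing = set(sample_ids) - set(meta.index)
        if missing:
            raise DataValidationError(f"metadata missing samples: {sorted(missing)}")
        meta = meta.loc[list(sample_ids)]
    num = meta.select_dtypes(include=[np.number])
    if not np.isfinite(num.to_numpy()).all():
        raise DataValidationError("non-finite values in numeric metadata columns")
    return meta


def read_tree(source, midpoint_root: bool = False) -> TreeNode:
    """Read a rooted Newick tree (path, file object, or Newick string).

    Polytomies and zero-length branches are permitted.  A basal
    trifurcation is treated as an unrooted tree and rejected unless
    ``midpoint_root`` is set, in which case the tree is midpoint-rooted.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    tree = TreeNode.read(source, format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise DataValidationError("negative branch length in tree")
    tips = list(tree.tips())
    labels = [t.name for t in tips]
    if len(set(labels)) != len(labels):
        raise DataValidationError("duplicate tip labels in tree")
    if len(tree.children) > 2:
        if not midpoint_root:
            raise DataValidationError(
                "tree appears unrooted (basal polytomy); root it first or pass "
                "midpoint_root=True"
            )
        tree = tree.root_at_midpoint()
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def patristic_distances(tree: TreeNode, taxon_ids=None) -> PairwiseMatrix:
    """Tip-to-tip patristic distance matrix, optionally ordered by ``taxon_ids``."""
    dm = tree.tip_tip_distances()
    ids = list(taxon_ids) if taxon_ids is not None else list(dm.ids)
    lookup = {t: i for i, t in enumerate(dm.ids)}
    order = [lookup[t] for t in ids]
    d = dm.data[np.ix_(order, order)]
    return PairwiseMatrix(ids, d, "patristic")


# -- operations --------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    Each retained sample is an independent multivariate-hypergeometric
    draw from its observed counts (one draw per sample, in sample-id
    order, from a single seeded generator).  Samples with fewer than
    ``depth`` reads are dropped with a warning; taxa left with all-zero
    columns are removed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.data.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise DataValidationError(
            f"rarefaction depth {depth} exceeds every sample's total "
            f"(max total = {int(totals.max())})"
        )
    dropped = list(table.data.index[~keep])
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = {}
    for sid in table.data.index:
        if sid not in set(dropped):
            rows[sid] = rng.multivariate_hypergeometric(
                table.data.loc[sid].to_numpy(), depth
            )
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.taxon_ids)
    return CountTable(out).drop_empty_taxa()


def match_tree_table(table: CountTable, tree: TreeNode):
    """Prune table and tree to their shared taxon set.

    Returns ``(table, tree, log)`` where ``log`` records the ids dropped
    from each side.
    """
    tips = {t.name for t in tree.tips()}
    taxa = set(table.taxon_ids)
    shared = taxa & tips
    if not shared:
        raise DataValidationError("table taxa and tree tips share no labels")
    dropped_taxa = sorted(taxa - shared)
    dropped_tips = sorted(tips - shared)
    new_table = table if not dropped_taxa else CountTable(
        table.data.loc[:, [t for t in table.taxon_ids if t in shared]]
    )
    new_tree = tree if not dropped_tips else tree.shear(sorted(shared))
    log = {
        "n_shared": len(shared),
        "dropped_taxa": dropped_taxa,
        "dropped_tips": dropped_tips,
    }
    if dropped_taxa or dropped_tips:
        logger.warning(
            "match_tree_table: dropped %d taxa from table, %d tips from tree",
            len(dropped_taxa), len(dropped_tips),
        )
    return new_table, new_tree, log
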