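"""Data containers and table-level preprocessing for ASV count tables.

The central container is :class:`AsvTable`, a thin validated wrapper around a
samples x taxa :class:`pandas.DataFrame`.  Preprocessing follows the canonical
amplicon workflow: drop globally rare ASVs, rarefy every sample to a common
depth, and (for enterotyping) aggregate ASVs to genus level.  Trees are
handled as :class:`dendropy.Tree` objects; sample distance matrices as
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genus label used to pool ASVs whose lineage carries no genus assignment.
UNASSIGNED_GENUS = "g__unassigned"


class AsvTable:
    """A samples x taxa abundance table with validated identifiers.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are taxa (ASVs or genera).  Values must be
        non-negative and finite.  Row/column labels must be unique.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_bad_cell(counts, lambda v: not _is_number(v))
            raise ValueError(f"non-numeric entry at {bad}")
        if np.isnan(values).any():
            bad = _first_bad_cell(counts, lambda v: isinstance(v, float) and np.isnan(v))
            raise ValueError(f"missing/NaN entry at {bad}")
        if (values < 0).any():
            bad = _first_bad_cell(counts, lambda v: v < 0)
            raise ValueError(f"negative entry at {bad}")
        self.counts = counts
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    # -- basic protocol -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, t = self.shape
        return f"<AsvTable {n} samples x {t} taxa>"

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def is_integer(self) -> bool:
        v = self.values()
        return bool(np.all(np.equal(np.mod(v, 1), 0)))

    def subset_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)])

    def drop_empty_taxa(self) -> "AsvTable":
        keep = self.counts.sum(axis=0) > 0
        return AsvTable(self.counts.loc[:, keep])

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path, orientation: str = "samples") -> "AsvTable":
        """Read a tab-separated abundance table.

        ``orientation='samples'`` means rows are samples; ``'taxa'`` means
        rows are taxa (the common QIIME export layout) and the table is
        transposed on load so the in-memory layout is always samples x taxa.
        """
        if orientation not in ("samples", "taxa"):
            raise ValueError("orientation must be 'samples' or 'taxa'")
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if orientation == "taxa":
            df = df.T
        return cls(df)

    def to_tsv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            self.counts.to_csv(fh, sep="\t")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(df: pd.DataFrame, pred) -> str:
    for i, row in enumerate(df.index):
        for j, col in enumerate(df.columns):
            if pred(df.iat[i, j]):
                return f"row={row!r}, column={col!r}"
    return "unknown cell"


# ---------------------------------------------------------------------------
# companion inputs
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxon_id -> ranked-lineage table (TSV, first column taxon id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids in taxonomy: {dup}")
    return df.fillna(UNASSIGNED_GENUS)


def read_metadata(path) -> pd.DataFrame:
    """Per-sample metadata table (TSV, first column sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    df.index = df.index.astype(str)
    return df


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths.

    Missing branch lengths default to 0 with a warning; a negative branch
    length is a hard error.
    """
    try:
        if isinstance(path_or_string, str) and path_or_string.strip().endswith(";"):
            tree = dendropy.Tree.get(data=path_or_string, schema=schema)
        else:
            tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    except Exception as exc:
        raise ValueError(f"could not parse tree: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    if n_missing:
        warnings.warn(f"{n_missing} missing branch lengths set to 0", stacklevel=2)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def patristic_distance_matrix(tree: dendropy.Tree, taxon_ids=None) -> pd.DataFrame:
    """Leaf-to-leaf patristic (branch-length) distance matrix as a DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    if taxon_ids is None:
        taxon_ids = sorted(taxa)
    missing = [t for t in taxon_ids if t not in taxa]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    n = len(taxon_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[taxon_ids[i]], taxa[taxon_ids[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=taxon_ids, columns=taxon_ids)


@dataclass
class Reconciliation:
    """Record of an explicit tree/table reconciliation."""

    table: AsvTable
    tree: dendropy.Tree
    n_taxa_dropped_from_table: int = 0
    n_leaves_pruned_from_tree: int = 0
    dropped_taxa: list = field(default_factory=list)


def reconcile(table: AsvTable, tree: dendropy.Tree) -> Reconciliation:
    """Prune tree to table taxa and drop table taxa absent from the tree."""
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    table_taxa = set(table.taxon_ids)
    shared = table_taxa & leaf_labels
    if not shared:
        raise ValueError("no taxa shared between table and tree")
    dropped = sorted(table_taxa - leaf_labels)
    pruned = len(leaf_labels - table_taxa)
    new_table = AsvTable(table.counts.loc[:, [t for t in table.taxon_ids if t in shared]])
    tree = tree.clone(depth=1)
    if pruned:
        tree.retain_taxa_with_labels(sorted(shared))
    logger.info(
        "reconcile: dropped %d table taxa absent from tree; pruned %d tree leaves",
        len(dropped), pruned,
    )
    return Reconciliation(new_table, tree, len(dropped), pruned, dropped)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_low_abundance_asvs(table: AsvTable, min_total: int = 5) -> AsvTable:
    """Drop taxa whose total count pooled over all samples is below ``min_total``.

    The threshold is strict: a taxon with pooled total exactly ``min_total``
    is retained ("fewer than" semantics).  Defined on raw integer counts only.
    """
    if not table.is_integer():
        raise ValueError("low-abundance filter is defined on raw integer counts")
    totals = table.counts.sum(axis=0)
    keep = totals >= min_total
    logger.info("filter_low_abundance_asvs: removed %d/%d taxa (< %d reads pooled)",
                int((~keep).sum()), table.shape[1], min_total)
    return AsvTable(table.counts.loc[:, keep])


def rarefy(table: AsvTable, depth: int | None = None, seed: int = 0) -> AsvTable:
    """Subsample each sample without replacement to a common depth.

    ``depth`` defaults to the smallest sample total.  A single seeded draw is
    taken (no averaging over repeated rarefactions).
    """
    if not table.is_integer():
        raise ValueError("rarefaction is defined on integer counts")
    counts = table.counts.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    offending = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if offending:
        raise ValueError(f"samples shallower than depth {depth}: {offending}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        row = counts[i]
        if row.sum() == depth:
            out[i] = row
            continue
        # multivariate hypergeometric == subsampling reads without replacement
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return AsvTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def aggregate_by_genus(table: AsvTable, taxonomy, genus_column: str = "genus") -> AsvTable:
    """Sum counts over ASVs sharing a genus label.

    ``taxonomy`` may be the DataFrame from :func:`read_taxonomy` or a plain
    ``taxon_id -> genus`` mapping.  ASVs without a genus assignment pool under
    :data:`UNASSIGNED_GENUS`.  The grand total is conserved exactly.
    """
    if isinstance(taxonomy, pd.DataFrame):
        if genus_column not in taxonomy.columns:
            raise KeyError(f"taxonomy has no {genus_column!r} column")
        mapping = taxonomy[genus_column].to_dict()
    else:
        mapping = dict(taxonomy)
    missing = [t for t in table.taxon_ids if t not in mapping]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    genera = [mapping[t] if mapping[t] not in (None, "", "nan") else UNASSIGNED_GENUS
              for t in table.taxon_ids]
    grouped = table.counts.T.groupby(pd.Index(genera, name="genus"), sort=True).sum().T
    return AsvTable(grouped)


def relative_abundance(table: AsvTable) -> AsvTable:
    """Convert to within-sample relative abundances (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")
    return AsvTable(table.counts.div(totals, axis=0))
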