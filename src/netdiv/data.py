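"""Core data types and TSV/Newick I/O.

The central container is the :class:`CountTable`, a taxa-by-sample matrix of
non-negative integer counts (``n_Ai`` = individuals of taxon *i* in sample
*A*).  Around it live square taxa matrices on two scales — the raw
:class:`InteractionMatrix` on whatever scale the inference method produces,
and the transformed :class:`AssociationMatrix` on [0, 1] with 0.5 as the
neutral midpoint — plus phylogenetic trees and sample-by-sample
:class:`DistanceMatrix` objects.

All tabular I/O is plain TSV (header row = column IDs, first column = row
IDs); trees are Newick.  Floats are written with 10 significant digits so a
read→write→read round trip is the identity at that precision.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class DataValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountTable:
    """Taxa-by-sample table of non-negative integer counts.

    Rows are taxa, columns are samples.  Derived per-sample quantities:
    ``sample_totals`` (n_A), ``richness`` (N_A, number of taxa with
    n_Ai > 0) and ``relative_abundances`` (p_Ai = n_Ai / n_A).
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa_ids = _check_unique(self.taxa_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise DataValidationError(
                    f"non-integer count at taxon {self.taxa_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise DataValidationError(
                f"negative count at taxon {self.taxa_ids[bad[0]]!r} (row {bad[0]}), "
                f"sample {self.sample_ids[bad[1]]!r} (column {bad[1]})"
            )
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise DataValidationError(f"samples with zero total counts: {empty}")
        self.counts = counts.astype(np.int64)

    # -- derived quantities -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        """n_A: total individuals per sample."""
        return self.counts.sum(axis=0)

    @property
    def richness(self) -> np.ndarray:
        """N_A: number of observed (count > 0) taxa per sample."""
        return (self.counts > 0).sum(axis=0)

    @property
    def presence(self) -> np.ndarray:
        """Boolean taxa-by-sample incidence matrix."""
        return self.counts > 0

    @property
    def relative_abundances(self) -> np.ndarray:
        """p_Ai = n_Ai / n_A; columns sum to 1."""
        return self.counts / self.sample_totals[np.newaxis, :]

    # -- subsetting ---------------------------------------------------------
    def select_taxa(self, taxa: Sequence[str]) -> "CountTable":
        idx = [self.taxa_ids.index(t) for t in taxa]
        return CountTable(list(taxa), list(self.sample_ids), self.counts[idx, :])

    def select_samples(self, samples: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return CountTable(list(self.taxa_ids), list(samples), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)


@dataclass
class InteractionMatrix:
    """Square taxa association matrix on the inference method's native scale.

    Holds either a co-occurrence interaction matrix (correlations on [-1, 1],
    taxa-wise similarities on [0, 1], ...) or a cophenetic phylogenetic
    similarity matrix; ``method_tag`` records the inference method.
    """

    taxa_ids: list[str]
    values: np.ndarray
    method_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.taxa_ids = _check_unique(self.taxa_ids, "taxon")
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa_ids)
        if v.shape != (n, n):
            raise DataValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataValidationError("interaction matrix is not symmetric")
        self.values = (v + v.T) / 2.0


@dataclass
class AssociationMatrix:
    """Transformed taxa association matrix C (or Phi) on [0, 1].

    0 = avoidance, 0.5 = neutral, 1 = complete association; diagonal is 1.
    Matrices produced by the canonical transform are positive semi-definite,
    since C = (J + R) / 2 with R a correlation matrix and J all ones.
    """

    taxa_ids: list[str]
    values: np.ndarray
    source: str = "cooccurrence"

    def __post_init__(self) -> None:
        self.taxa_ids = _check_unique(self.taxa_ids, "taxon")
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa_ids)
        if v.shape != (n, n):
            raise DataValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataValidationError("association matrix is not symmetric")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise DataValidationError(
                f"association values outside [0, 1]: min={v.min()}, max={v.max()}"
            )
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise DataValidationError("association matrix diagonal must be 1")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree with labelled leaves and branch lengths >= 0.

    Thin wrapper over a scikit-bio ``TreeNode``; ``phi`` gives the
    root-to-leaf path length per taxon (the per-taxon branch length to root).
    """

    tree: TreeNode

    def __post_init__(self) -> None:
        tips = list(self.tree.tips())
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise DataValidationError("tree has unnamed leaves")
        _check_unique(names, "leaf")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise DataValidationError("negative branch length in tree")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def phi(self) -> dict[str, float]:
        """Root-to-leaf path length per taxon."""
        out: dict[str, float] = {}
        for tip in self.tree.tips():
            out[tip.name] = tip.accumulate_to_ancestor(self.tree)
        return out

    def sheared(self, names: Sequence[str]) -> "PhyloTree":
        sub = self.tree.shear(list(names))
        sub.prune()
        return PhyloTree(sub)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal.

    Entries are on [0, 1] (all indices are similarities S on [0, 1], with
    D = 1 - S clamped at 0).
    """

    sample_ids: list[str]
    values: np.ndarray
    index_code: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DataValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise DataValidationError("distance matrix diagonal must be 0")
        if not np.isfinite(v).all():
            raise DataValidationError("non-finite distances")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle vectorisation (scipy 'condensed' order)."""
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_frame(path, what: str) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        body = fh.read()
    col_ids = header[1:]
    _check_unique(col_ids, f"{what} column")
    df = pd.read_csv(io.StringIO(body), sep="\t", header=None, index_col=0)
    df.index = df.index.astype(str)
    df.columns = col_ids
    _check_unique(list(df.index), f"{what} row")
    return df


def read_count_table(path, orientation: str = "taxa-rows") -> CountTable:
    """Read a TSV count table.

    ``orientation`` says what the file's rows are: ``taxa-rows`` (default;
    header = sample IDs) or ``samples-rows`` (transposed on read).
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_tsv_frame(path, "count table")
    if orientation == "samples-rows":
        df = df.T
    return CountTable(list(df.index), list(df.columns), df.to_numpy())


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def read_tree(path) -> PhyloTree:
    """Read a Newick tree; unrooted input (trifurcating root) is midpoint-rooted."""
    tree = TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return PhyloTree(tree)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: first column sample IDs, remaining columns factors."""
    return _read_tsv_frame(path, "metadata")


def _square_to_frame(ids: Sequence[str], values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(ids), columns=list(ids))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    _square_to_frame(d.sample_ids, d.values).to_csv(
        path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv_frame(path, "distance matrix")
    if list(df.index) != list(df.columns):
        raise DataValidationError("row and column sample IDs differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_square_matrix(ids: Sequence[str], values: np.ndarray, path) -> None:
    _square_to_frame(ids, values).to_csv(
        path, sep="\t", index_label="taxon_id", float_format=_FLOAT_FMT
    )


def read_interaction_matrix(path, method_tag: str = "file") -> InteractionMatrix:
    df = _read_tsv_frame(path, "interaction matrix")
    if list(df.index) != list(df.columns):
        raise DataValidationError("row and column taxon IDs differ")
    return InteractionMatrix(list(df.index), df.to_numpy(dtype=float), method_tag)


def read_association_matrix(path, source: str = "file") -> AssociationMatrix:
    df = _read_tsv_frame(path, "association matrix")
    if list(df.index) != list(df.columns):
        raise DataValidationError("row and column taxon IDs differ")
    return AssociationMatrix(list(df.index), df.to_numpy(dtype=float), source)


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def harmonise(
    table: CountTable,
    tree: PhyloTree | None = None,
    interactions: InteractionMatrix | AssociationMatrix | None = None,
):
    """Restrict table/tree/matrix to the shared taxon set, in table order.

    Taxa absent from any provided object are dropped everywhere (and logged);
    the tree is pruned to the surviving leaves and matrices re-indexed in the
    table's taxon order.  Raises if the intersection is empty.
    """
    shared = set(table.taxa_ids)
    if tree is not None:
        shared &= set(tree.leaf_names)
    if interactions is not None:
        shared &= set(interactions.taxa_ids)
    if not shared:
        raise DataValidationError("no taxa shared between the provided objects")
    keep = [t for t in table.taxa_ids if t in shared]
    dropped = sorted(
        (set(table.taxa_ids) | (set(tree.leaf_names) if tree else set())
         | (set(interactions.taxa_ids) if interactions else set())) - shared
    )
    if dropped:
        logger.info("harmonise: dropped %d taxa: %s", len(dropped), dropped)
        warnings.warn(f"harmonise dropped {len(dropped)} taxa", stacklevel=2)
    out_table = table if keep == table.taxa_ids else table.select_taxa(keep)
    # samples can become empty once taxa are dropped
    totals = out_table.counts.sum(axis=0)
    if (totals == 0).any():
        keep_s = [s for s, t in zip(out_table.sample_ids, totals) if t > 0]
        if not keep_s:
            raise DataValidationError("all samples empty after harmonisation")
        warnings.warn(
            f"harmonise dropped {out_table.n_samples - len(keep_s)} empty samples",
            stacklevel=2,
        )
        out_table = out_table.select_samples(keep_s)

    out_tree = None
    if tree is not None:
        out_tree = tree if set(tree.leaf_names) == shared and keep == tree.leaf_names \
            else tree.sheared(keep)
    out_inter = None
    if interactions is not None:
        if interactions.taxa_ids == keep:
            out_inter = interactions
        else:
            idx = [interactions.taxa_ids.index(t) for t in keep]
            out_inter = replace(
                interactions, taxa_ids=keep, values=interactions.values[np.ix_(idx, idx)]
            )
    return out_table, out_tree, out_inter
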