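"""Core domain types and readers/writers for the standard interchange formats.

The pipeline moves four kinds of objects between stages:

* :class:`CountTable` — a samples × taxa matrix of non-negative integer
  read counts (the OTU table);
* :class:`PhyloTree` — a rooted, branch-length-weighted phylogeny whose
  tips are taxon identifiers (the gamma-diversity tree);
* a sample metadata table (``pandas.DataFrame``) validated by
  :func:`validate_sample_frame`;
* :class:`DistanceMatrix` — symmetric pairwise sample dissimilarities.

All on-disk formats are plain text: TSV for tables and matrices, newick
for trees.  Reading and writing round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "PhyloTree",
    "DistanceMatrix",
    "IdentifierError",
    "AlignmentError",
    "METADATA_COLUMNS",
    "LAND_CLASS_TO_LOCAL_TYPE",
    "read_count_table",
    "write_count_table",
    "read_tree",
    "read_sample_frame",
    "validate_sample_frame",
    "align_inputs",
]


class IdentifierError(ValueError):
    """Duplicate or malformed sample/taxon identifiers."""


class AlignmentError(ValueError):
    """Inputs share no taxa or no samples after intersection."""


#: required metadata columns, in canonical order
METADATA_COLUMNS = (
    "sample_id",
    "site",
    "environment",
    "land_class",
    "local_type",
    "phenotype_alleles",
    "sex",
)

#: fixed mapping from land class to local habitat type
LAND_CLASS_TO_LOCAL_TYPE = {
    "campus": "built",
    "suburban_park": "built",
    "urban_forest": "forest",
    "rural_forest": "forest",
}


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Samples × taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        2-D integer array, one row per sample.
    sample_ids, taxon_ids
        Unique identifiers for rows and columns respectively.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_s, n_t = self.counts.shape
        if n_s != len(self.sample_ids) or n_t != len(self.taxon_ids):
            raise ValueError("counts shape does not match identifier lists")
        if len(set(self.sample_ids)) != n_s:
            raise IdentifierError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != n_t:
            raise IdentifierError("duplicate taxon identifiers")
        if n_s < 1 or n_t < 2:
            raise ValueError("need at least 1 sample and 2 taxa")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.round(as_int.astype(float))
            if not np.allclose(as_int.astype(float), rounded, atol=0):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64, copy=False)

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(self.counts[idx], list(ids), list(self.taxon_ids))

    def select_taxa(self, ids: Sequence[str]) -> "CountTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in ids]
        return CountTable(self.counts[:, idx], list(self.sample_ids), list(ids))


def read_count_table(
    path,
    format: str = "tsv",
    orientation: str = "auto",
    known_sample_ids: Iterable[str] | None = None,
) -> CountTable:
    """Read an OTU count table from TSV or BIOM v1 (JSON).

    TSV orientation (samples-as-rows vs taxa-as-rows) is auto-detected by
    matching ``known_sample_ids`` against the two axes; silent transposition
    is the classic microbiome join bug, so pass the metadata sample ids or
    force ``orientation`` to ``"samples"`` / ``"taxa"`` explicitly.
    """
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise ValueError(f"unknown count-table format: {format!r}")

    with open(path) as fh:  # pandas mangles duplicate header names silently
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise IdentifierError(f"duplicate column identifiers in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise IdentifierError(f"duplicate row identifiers in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in count table {path}: {exc}") from exc
    if not np.allclose(values, np.round(values), atol=0):
        raise ValueError(f"non-integer counts in {path}")
    if (values < 0).any():
        raise ValueError(f"negative counts in {path}")
    values = values.astype(np.int64)

    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]

    if orientation == "auto":
        if known_sample_ids is not None:
            known = set(map(str, known_sample_ids))
            row_hits = len(known.intersection(rows))
            col_hits = len(known.intersection(cols))
            orientation = "samples" if row_hits >= col_hits else "taxa"
        else:
            orientation = "samples"
    if orientation == "taxa":
        values, rows, cols = values.T, cols, rows
    elif orientation != "samples":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return CountTable(values, rows, cols)


def write_count_table(table: CountTable, path) -> None:
    """Write as TSV, samples as rows, first column ``sample_id``."""
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def _read_biom_json(path) -> CountTable:
    """Minimal reader for the BIOM v1.0 JSON schema (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    n_r, n_c = doc["shape"]
    mat = np.zeros((n_r, n_c))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    # BIOM stores observations (taxa) as rows; normalise to samples-as-rows
    return CountTable(mat.T, sample_ids, taxon_ids)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths and unique tip labels.

    Wraps a :class:`skbio.TreeNode`; exposes the patristic (tip-to-tip
    path-length) distance matrix the null models consume.
    """

    def __init__(self, tree: skbio.TreeNode):
        self._tree = tree
        self._validate()
        self._patristic_cache: tuple[tuple[str, ...], np.ndarray] | None = None

    def _validate(self) -> None:
        tips = [t.name for t in self._tree.tips()]
        if any(t is None for t in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise IdentifierError("duplicate tip labels")
        for node in self._tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError(
                    f"branch leading to {node.name or '<internal>'} has no length"
                )
            if node.length < 0:
                raise ValueError("negative branch length")

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        return cls(skbio.TreeNode.read(source, format="newick"))

    def to_newick(self, path=None):
        if path is None:
            import io as _io

            buf = _io.StringIO()
            self._tree.write(buf, format="newick")
            return buf.getvalue()
        self._tree.write(path, format="newick")
        return None

    @property
    def tree(self) -> skbio.TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self._tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.tips())

    def patristic(self, taxon_order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Tip-to-tip path-length distances, optionally in a given tip order."""
        if self._patristic_cache is None:
            dm = self._tree.tip_tip_distances()
            self._patristic_cache = (tuple(dm.ids), np.asarray(dm.data, dtype=float))
        ids, mat = self._patristic_cache
        if taxon_order is None:
            return list(ids), mat.copy()
        pos = {t: i for i, t in enumerate(ids)}
        missing = [t for t in taxon_order if t not in pos]
        if missing:
            raise AlignmentError(f"taxa absent from tree: {missing[:5]}")
        idx = np.array([pos[t] for t in taxon_order])
        return list(taxon_order), mat[np.ix_(idx, idx)]

    def shear(self, tip_names: Iterable[str]) -> "PhyloTree":
        """Prune to the given tips (preserving path lengths)."""
        keep = list(tip_names)
        return PhyloTree(self._tree.shear(keep))

    def root_to_tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for tip in self._tree.tips():
            d = 0.0
            node = tip
            while node.parent is not None:
                d += node.length
                node = node.parent
            depths[tip.name] = d
        return depths

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = np.array(list(self.root_to_tip_depths().values()))
        return bool(np.all(np.abs(depths - depths.mean()) <= rtol * max(depths.mean(), 1e-300)))


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree; missing branch lengths are an error."""
    return PhyloTree.from_newick(path)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarity with zero diagonal.

    Standardised-effect-size matrices (betaMNTD_ses, RC_bray) may carry
    negative entries; metric distances are expected to be non-negative but
    this is not enforced here.
    """

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(s) for s in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if len(set(self.ids)) != n:
            raise IdentifierError("duplicate sample identifiers")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(
            self.values[both], self.values.T[both], atol=1e-10, equal_nan=True
        ):
            raise ValueError("matrix is not symmetric within 1e-10")
        diag = np.diag(self.values)
        if not np.allclose(diag[np.isfinite(diag)], 0.0, atol=1e-10):
            raise ValueError("diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)))

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def select(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def validate_sample_frame(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate per-sample covariates and return a normalised copy.

    Checks the controlled vocabularies (environment, land class, local
    type, sex), the 0/1/2 phenotype allele coding, and that the land class
    → local type mapping is internally consistent.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise IdentifierError("duplicate sample_id in metadata")

    def _check(col: str, allowed: set[str]) -> None:
        bad = set(meta[col].astype(str)) - allowed
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")

    _check("environment", {"city", "rural"})
    _check("land_class", set(LAND_CLASS_TO_LOCAL_TYPE))
    _check("local_type", {"built", "forest"})
    _check("sex", {"F", "M"})
    alleles = pd.to_numeric(meta["phenotype_alleles"], errors="raise")
    if not set(alleles.unique()).issubset({0, 1, 2}):
        raise ValueError("phenotype_alleles must be in {0, 1, 2}")
    meta["phenotype_alleles"] = alleles.astype(int)

    expected = meta["land_class"].map(LAND_CLASS_TO_LOCAL_TYPE)
    bad = meta.loc[expected != meta["local_type"], "sample_id"]
    if len(bad):
        raise ValueError(
            f"land_class/local_type mapping inconsistent for samples {list(bad[:5])}"
        )
    return meta.set_index("sample_id", drop=False)


def read_sample_frame(path) -> pd.DataFrame:
    return validate_sample_frame(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_inputs(
    table: CountTable,
    tree: PhyloTree | None,
    meta: pd.DataFrame,
) -> tuple[CountTable, PhyloTree | None, pd.DataFrame]:
    """Restrict table, tree, and metadata to their shared samples and taxa.

    Taxa are intersected with the tree's tips (tree pruned accordingly);
    samples with the metadata's sample_ids.  Dropped identifiers are
    reported to the module logger.  Idempotent.
    """
    meta = validate_sample_frame(meta.reset_index(drop=True))
    shared_samples = [s for s in table.sample_ids if s in set(meta["sample_id"])]
    if not shared_samples:
        raise AlignmentError("no samples shared between count table and metadata")
    dropped_samples = len(table.sample_ids) - len(shared_samples)
    meta_dropped = len(meta) - len(shared_samples)
    if dropped_samples or meta_dropped:
        logger.info(
            "align_inputs: dropped %d table samples and %d metadata rows",
            dropped_samples,
            meta_dropped,
        )
    table = table.select_samples(shared_samples)
    meta = meta.loc[shared_samples]

    if tree is not None:
        tips = set(tree.tip_names)
        shared_taxa = [t for t in table.taxon_ids if t in tips]
        if len(shared_taxa) < 2:
            raise AlignmentError("fewer than 2 taxa shared between table and tree")
        t_dropped = table.n_taxa - len(shared_taxa)
        tip_dropped = len(tips) - len(shared_taxa)
        if t_dropped or tip_dropped:
            logger.info(
                "align_inputs: dropped %d table taxa and %d tree tips",
                t_dropped,
                tip_dropped,
            )
        table = table.select_taxa(shared_taxa)
        if tip_dropped:
            tree = tree.shear(shared_taxa)

    keep_rows = table.sample_sums > 0
    if not keep_rows.all():
        kept = [s for s, k in zip(table.sample_ids, keep_rows) if k]
        logger.info("align_inputs: dropped %d empty samples", (~keep_rows).sum())
        table = table.select_samples(kept)
        meta = meta.loc[kept]
    return table, tree, meta
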