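"""Filtering, rarefaction, and compositional transforms.

The study design these defaults encode: taxa are kept when they carry at
least one read in 5% of samples; samples are rarefied without replacement
to a common depth of 9,724 reads; compositional analyses use the centred
log-ratio (CLR) transform with a +1 pseudocount on raw counts.
"""

from __future__ import annotations

import logging
import math
import zlib

import numpy as np
import pandas as pd
from scipy import special

from .io import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "prevalence_filter",
    "rarefy",
    "clr_transform",
    "relative_abundance",
    "box_cox",
]

DEFAULT_RAREFACTION_DEPTH = 9724
DEFAULT_MIN_PREVALENCE = 0.05


def prevalence_filter(
    table: CountTable,
    min_fraction: float = DEFAULT_MIN_PREVALENCE,
    min_reads: int = 1,
) -> CountTable:
    """Keep taxa with >= ``min_reads`` in at least ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * table.n_samples)
    prevalence = (table.counts >= min_reads).sum(axis=0)
    keep = prevalence >= threshold
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence_filter: dropped %d of %d taxa", dropped, table.n_taxa)
    kept_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.select_taxa(kept_ids)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample substream keyed by sample_id so that subsetting samples
    # does not perturb other samples' draws
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def rarefy(
    table: CountTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> CountTable:
    """Subsample each sample's reads without replacement to a common depth.

    Samples with fewer than ``depth`` reads are dropped (with a logged
    warning), not scaled.  Deterministic under a fixed seed; each sample
    uses its own RNG substream keyed by its identifier.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sample_sums
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"every sample has fewer than {depth} reads")
    n_dropped = int((~keep).sum())
    if n_dropped:
        shallow = [s for s, k in zip(table.sample_ids, keep) if not k]
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s%s",
            n_dropped,
            depth,
            shallow[:5],
            "..." if n_dropped > 5 else "",
        )
    rows = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = table.counts[i]
        if row.sum() == depth:
            rows.append(row.copy())
        else:
            rng = _sample_rng(seed, sid)
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    return CountTable(np.asarray(rows), kept_ids, list(table.taxon_ids))


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of each sample's counts.

    value_ij = ln(c_ij + pseudocount) - mean_k ln(c_ik + pseudocount);
    rows sum to zero by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(table.counts + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Row-normalise counts to proportions (rows sum to 1)."""
    sums = table.sample_sums.astype(float)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValueError(f"zero-sum samples: {bad[:5]}")
    return pd.DataFrame(
        table.counts / sums[:, None], index=table.sample_ids, columns=table.taxon_ids
    )


def box_cox(values, lam: float) -> np.ndarray:
    """Box-Cox transform with a fixed exponent: (y**lam - 1)/lam, ln(y) at lam=0."""
    y = np.asarray(values, dtype=float)
    if lam <= 0 and (y <= 0).any():
        raise ValueError("Box-Cox with lambda <= 0 requires strictly positive input")
    if (y < 0).any():
        raise ValueError("Box-Cox input must be non-negative")
    return special.boxcox(y, lam)
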