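"""Alpha diversity, beta-diversity distances, ordination, and clustering.

Shannon diversity is reported in nats.  The Aitchison distance is the
Euclidean distance between CLR-transformed samples.  Weighted UniFrac is
computed by an explicit branch walk over the shared phylogeny; the
normalised form (default) divides each pair's branch-weighted abundance
difference by the corresponding branch-weighted abundance sum, bounding
the distance in [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import AlignmentError, CountTable, DistanceMatrix, PhyloTree
from .preprocess import relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "alpha_diversity",
    "aitchison_distance",
    "weighted_unifrac",
    "pcoa",
    "PCoAResult",
    "hierarchical_cluster",
]


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed richness and Shannon diversity (nats) per sample.

    Warns when row sums are unequal: alpha diversity on un-rarefied counts
    confounds depth with diversity.
    """
    sums = table.sample_sums
    if (sums <= 0).any():
        raise ValueError("zero-sum sample in alpha_diversity")
    if len(np.unique(sums)) > 1:
        logger.warning(
            "alpha_diversity: unequal sample depths (min %d, max %d); "
            "rarefy before comparing samples",
            sums.min(),
            sums.max(),
        )
    p = table.counts / sums[:, None]
    richness = (table.counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def aitchison_distance(clr_matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance between CLR-transformed samples."""
    vals = squareform(pdist(clr_matrix.to_numpy(), metric="euclidean"))
    return DistanceMatrix(vals, list(clr_matrix.index))


def _branch_table(tree: PhyloTree, taxon_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch tip-membership indicators and lengths.

    Returns (membership, lengths) where membership[b, t] == 1 when taxon t
    descends from branch b.  The root's (length-less) edge is excluded.
    """
    pos = {t: i for i, t in enumerate(taxon_ids)}
    missing = set(taxon_ids) - {t.name for t in tree.tree.tips()}
    if missing:
        raise AlignmentError(f"taxa absent from tree: {sorted(missing)[:5]}")
    rows, lengths = [], []
    # postorder accumulation of descendant-tip sets
    below: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids))
            if node.name in pos:
                vec[pos[node.name]] = 1.0
        else:
            vec = np.zeros(len(taxon_ids))
            for child in node.children:
                vec += below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:  # root edge carries no length
            rows.append(vec)
            lengths.append(node.length)
    return np.asarray(rows), np.asarray(lengths, dtype=float)


def weighted_unifrac(
    table: CountTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Branch-length-weighted abundance-flow distance between samples.

    raw(A, B)  = sum_b len(b) * |p_A(b) - p_B(b)|
    norm(A, B) = raw / sum_b len(b) * (p_A(b) + p_B(b))

    where p_X(b) is the fraction of sample X's total abundance descending
    from branch b.
    """
    rel = relative_abundance(table).to_numpy()
    membership, lengths = _branch_table(tree, table.taxon_ids)
    # P[s, b]: abundance fraction of sample s below branch b
    P = rel @ membership.T
    n = table.n_samples
    vals = np.zeros((n, n))
    weighted_totals = P @ lengths  # sum_b len(b) p_X(b), per sample
    for i in range(n):
        diff = np.abs(P[i] - P[i + 1 :]) @ lengths
        if normalized:
            denom = weighted_totals[i] + weighted_totals[i + 1 :]
            with np.errstate(invalid="ignore", divide="ignore"):
                diff = np.where(denom > 0, diff / denom, 0.0)
        vals[i, i + 1 :] = diff
        vals[i + 1 :, i] = diff
    return DistanceMatrix(vals, list(table.sample_ids))


class PCoAResult:
    """Principal-coordinate decomposition of a distance matrix.

    Attributes
    ----------
    coordinates
        DataFrame (samples × axes) of real coordinates on the
        positive-eigenvalue axes.
    eigenvalues
        All eigenvalues in decreasing order, negatives retained.
    proportion_explained
        Eigenvalue / sum of positive eigenvalues, for positive axes.
    """

    def __init__(self, dm: DistanceMatrix):
        n = dm.n
        a = -0.5 * dm.values**2
        centering = np.eye(n) - np.ones((n, n)) / n
        gower = centering @ a @ centering
        gower = (gower + gower.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(gower)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        self.ids = list(dm.ids)
        self.eigenvalues = eigvals
        self._eigvecs = eigvecs
        pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
        coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
        self.coordinates = pd.DataFrame(
            coords,
            index=pd.Index(self.ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(int(pos.sum()))],
        )
        pos_sum = eigvals[pos].sum()
        self.proportion_explained = (
            eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
        )

    def axes_with_sign(self) -> tuple[np.ndarray, np.ndarray]:
        """All axes scaled by sqrt(|eigenvalue|), plus the eigenvalue signs.

        Negative-eigenvalue axes ("imaginary" coordinates) are needed for
        centroid distances in non-Euclidean spaces.
        """
        scale = np.sqrt(np.abs(self.eigenvalues))
        return self._eigvecs * scale, np.sign(self.eigenvalues)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical (Gower) principal coordinate analysis; negative eigenvalues kept."""
    return PCoAResult(dm)


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "average"):
    """Agglomerative clustering of samples; UPGMA (average linkage) by default.

    Returns the scipy linkage matrix; leaves are ordered as ``dm.ids``.
    """
    return hierarchy.linkage(dm.condensed(), method=linkage)
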