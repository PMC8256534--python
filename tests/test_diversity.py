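"""Alpha diversity, beta distances, ordination, clustering."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

from assemblage.diversity import (
    aitchison_distance,
    alpha_diversity,
    hierarchical_cluster,
    pcoa,
    weighted_unifrac,
)
from assemblage.io import CountTable, DistanceMatrix
from assemblage.preprocess import clr_transform, relative_abundance
from conftest import random_table, random_tree


def table_from(counts, taxon_ids=None):
    counts = np.asarray(counts)
    return CountTable(
        counts,
        [f"S{i}" for i in range(counts.shape[0])],
        taxon_ids or [f"OTU{j}" for j in range(counts.shape[1])],
    )


def brute_force_unifrac(table, tree, normalized=True):
    """Independent per-branch walk: for each branch, share of each sample's
    abundance among its descendant tips."""
    rel = relative_abundance(table)
    out = np.zeros((table.n_samples, table.n_samples))
    branches = []
    for node in tree.tree.postorder(include_self=True):
        if node.parent is None:
            continue
        tips = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length, tips))
    for i in range(table.n_samples):
        for j in range(i + 1, table.n_samples):
            num = den = 0.0
            for length, tips in branches:
                pi = rel.iloc[i][[t for t in tips if t in rel.columns]].sum()
                pj = rel.iloc[j][[t for t in tips if t in rel.columns]].sum()
                num += length * abs(pi - pj)
                den += length * (pi + pj)
            out[i, j] = out[j, i] = num / den if normalized and den > 0 else num
    return out


class TestAlpha:
    def test_even_pair(self):
        res = alpha_diversity(table_from([[10, 10]]))
        assert res["richness"].iloc[0] == 2
        assert res["shannon"].iloc[0] == pytest.approx(np.log(2))

    def test_degenerate_single_taxon(self):
        res = alpha_diversity(table_from([[10, 0, 0]]))
        assert res["richness"].iloc[0] == 1
        assert res["shannon"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        res = alpha_diversity(table_from([[5, 3, 2]]))
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert res["shannon"].iloc[0] == pytest.approx(expected, abs=1e-4)

    def test_shannon_bounded_by_log_richness(self):
        t = random_table(10, 25, seed=6)
        res = alpha_diversity(t)
        assert (res["shannon"] <= np.log(res["richness"]) + 1e-12).all()

    def test_uniform_maximizes_shannon(self):
        rng = np.random.default_rng(3)
        k = 8
        uneven = rng.multinomial(1000, rng.dirichlet(np.ones(k) * 0.2))
        uneven = np.maximum(uneven, 1)  # keep richness fixed at k
        res = alpha_diversity(table_from(np.array([uneven, [125] * k])))
        assert res["shannon"].iloc[1] >= res["shannon"].iloc[0]


class TestAitchison:
    def test_identical_rows_zero(self):
        t = table_from([[3, 1], [3, 1]])
        dm = aitchison_distance(clr_transform(t))
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_hand_euclidean(self):
        import pandas as pd

        clr = pd.DataFrame([[0.0, 0.0], [3.0, -3.0]], index=["a", "b"])
        dm = aitchison_distance(clr)
        assert dm.values[0, 1] == pytest.approx(np.sqrt(18))

    def test_triangle_inequality(self):
        t = random_table(6, 10, seed=5)
        d = aitchison_distance(clr_transform(t)).values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, three_tip_tree):
        t = table_from([[5, 3, 2], [5, 3, 2]], taxon_ids=["A", "B", "C"])
        dm = weighted_unifrac(t, three_tip_tree)
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_two_tip_maximal_separation(self):
        import io

        from assemblage.io import PhyloTree

        tree = PhyloTree.from_newick(io.StringIO("(A:1,B:1);"))
        t = table_from([[1, 0], [0, 1]], taxon_ids=["A", "B"])
        dm = weighted_unifrac(t, tree, normalized=True)
        assert dm.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_branch_walk_oracle(self, seed, normalized):
        tree = random_tree(6, seed=seed)
        t = random_table(3, 6, seed=seed + 50, depth=100)
        t = CountTable(t.counts, t.sample_ids, sorted(tree.tip_names))
        ours = weighted_unifrac(t, tree, normalized=normalized).values
        oracle = brute_force_unifrac(t, tree, normalized=normalized)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_star_tree_equals_manhattan(self):
        """On a unit star tree each taxon owns one unit branch, so raw
        weighted UniFrac reduces to the Manhattan distance between
        relative abundance vectors (verified against the branch-walk
        oracle as well)."""
        import io

        from assemblage.io import PhyloTree

        tree = PhyloTree.from_newick(io.StringIO("(A:1,B:1,C:1,D:1);"))
        t = random_table(4, 4, seed=9, depth=60)
        t = CountTable(t.counts, t.sample_ids, ["A", "B", "C", "D"])
        raw = weighted_unifrac(t, tree, normalized=False).values
        oracle = brute_force_unifrac(t, tree, normalized=False)
        rel = relative_abundance(t).to_numpy()
        for i in range(4):
            for j in range(4):
                manhattan = np.abs(rel[i] - rel[j]).sum()
                assert raw[i, j] == pytest.approx(manhattan, abs=1e-10)
                assert raw[i, j] == pytest.approx(oracle[i, j], abs=1e-10)

    def test_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.diversity import beta_diversity

        tree = random_tree(8, seed=4)
        taxa = sorted(tree.tip_names)
        t = random_table(4, 8, seed=77, depth=200)
        t = CountTable(t.counts, t.sample_ids, taxa)
        ours = weighted_unifrac(t, tree, normalized=False).values
        theirs = beta_diversity(
            "weighted_unifrac",
            t.counts,
            ids=t.sample_ids,
            tree=tree.tree,
            taxa=taxa,
        ).data
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"])
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-9)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_duplicate_samples_identical_coordinates(self):
        vals = np.array(
            [[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]]
        )
        res = pcoa(DistanceMatrix(vals, ["a", "b", "c"]))
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9
        )

    def test_euclidean_input_nonnegative_eigenvalues(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3))
        dm = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(8)])
        res = pcoa(dm)
        assert (res.eigenvalues >= -1e-9).all()

    def test_reconstruction_error_bounded_by_negative_mass(self):
        rng = np.random.default_rng(2)
        # non-Euclidean dissimilarity: element-wise square root warps the metric
        x = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(np.sqrt(pdist(x)))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(7)])
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        neg_mass = -res.eigenvalues[res.eigenvalues < 0].sum()
        err = np.abs(recon - d).max() ** 2
        assert err <= neg_mass + 1e-9


class TestUpgma:
    def test_hand_merge_order(self):
        vals = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        z = hierarchical_cluster(DistanceMatrix(vals, ["A", "B", "C"]))
        assert z[0, 2] == pytest.approx(1.0)  # first merge {A,B} at height 1
        assert z[1, 2] == pytest.approx(4.0)

    def test_identical_points_merge_at_zero(self):
        vals = np.zeros((3, 3))
        z = hierarchical_cluster(DistanceMatrix(vals, ["a", "b", "c"]))
        assert z[:, 2] == pytest.approx(0.0)

    def test_heights_monotone(self):
        t = random_table(9, 12, seed=11)
        dm = aitchison_distance(clr_transform(t))
        z = hierarchical_cluster(dm)
        assert (np.diff(z[:, 2]) >= -1e-12).all()
        assert hierarchy.is_valid_linkage(z)
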