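"""Nearest-taxon statistics, tip-shuffle nulls, Raup-Crick, and the classifier."""

import numpy as np
import pytest

import assemblage as A
from assemblage.io import CountTable
from assemblage.nullmodels import (
    beta_mntd,
    classify_pairs,
    classify_process,
    mntd,
    raup_crick_bray,
    ses_beta_mntd,
    ses_mntd,
)
from conftest import random_table, random_tree


def brute_mntd(community, dmat, weighted=True):
    """Independent enumeration: explicit loop over present taxa."""
    present = [i for i, v in enumerate(community) if v > 0]
    dists = []
    for i in present:
        dists.append(min(dmat[i][j] for j in present if j != i))
    if weighted:
        total = sum(community[i] for i in present)
        return sum(
            community[i] / total * d for i, d in zip(present, dists)
        )
    return float(np.mean(dists))


def brute_beta_mntd(a, b, dmat, weighted=True):
    pa = [i for i, v in enumerate(a) if v > 0]
    pb = [j for j, v in enumerate(b) if v > 0]
    da = [min(dmat[i][j] for j in pb) for i in pa]
    db = [min(dmat[i][j] for i in pa) for j in pb]
    if weighted:
        ta, tb = sum(a[i] for i in pa), sum(b[j] for j in pb)
        return 0.5 * (
            sum(a[i] / ta * d for i, d in zip(pa, da))
            + sum(b[j] / tb * d for j, d in zip(pb, db))
        )
    return 0.5 * (float(np.mean(da)) + float(np.mean(db)))


class TestMntd:
    def test_two_present_taxa_forced_neighbour(self, three_tip_tree):
        _, d = three_tip_tree.patristic(taxon_order=["A", "B", "C"])
        assert mntd([7, 1, 0], d) == pytest.approx(2.0)
        assert mntd([1, 7, 0], d) == pytest.approx(2.0)

    def test_hand_enumeration(self, three_tip_tree):
        _, d = three_tip_tree.patristic(taxon_order=["A", "B", "C"])
        # A=2,B=1,C=1: 0.5*2 + 0.25*2 + 0.25*4 = 2.5
        assert mntd([2, 1, 1], d) == pytest.approx(2.5)

    def test_single_taxon_undefined(self, three_tip_tree):
        _, d = three_tip_tree.patristic(taxon_order=["A", "B", "C"])
        with pytest.raises(ValueError):
            mntd([5, 0, 0], d)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_instances(self, weighted):
        rng = np.random.default_rng(0)
        for rep in range(50):
            tree = random_tree(10, seed=rep)
            _, d = tree.patristic()
            v = rng.integers(0, 5, size=10)
            while (v > 0).sum() < 2:
                v = rng.integers(0, 5, size=10)
            assert mntd(v, d, weighted) == pytest.approx(
                brute_mntd(v, d, weighted), abs=1e-10
            )


class TestBetaMntd:
    def test_identical_communities_zero(self, four_tip_tree):
        _, d = four_tip_tree.patristic(taxon_order=["A", "B", "C", "D"])
        assert beta_mntd([1, 2, 0, 3], [1, 2, 0, 3], d) == pytest.approx(0.0)

    def test_disjoint_single_taxa(self, four_tip_tree):
        _, d = four_tip_tree.patristic(taxon_order=["A", "B", "C", "D"])
        # A-only vs C-only on ((A:1,B:1):1,(C:1,D:1):1) -> 0.5*(4+4)... d(A,C)=4
        assert beta_mntd([1, 0, 0, 0], [0, 0, 1, 0], d) == pytest.approx(4.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_symmetric_and_matches_brute_force(self, weighted):
        rng = np.random.default_rng(1)
        for rep in range(50):
            tree = random_tree(10, seed=100 + rep)
            _, d = tree.patristic()
            a = rng.integers(0, 4, size=10)
            b = rng.integers(0, 4, size=10)
            if (a > 0).sum() == 0 or (b > 0).sum() == 0:
                continue
            ours = beta_mntd(a, b, d, weighted)
            assert ours == pytest.approx(beta_mntd(b, a, d, weighted), abs=1e-12)
            assert ours == pytest.approx(brute_beta_mntd(a, b, d, weighted), abs=1e-10)


class TestSesMntd:
    def test_star_tree_degenerate_null_is_missing(self):
        import io

        from assemblage.io import PhyloTree

        tree = PhyloTree.from_newick(io.StringIO("(A:1,B:1,C:1,D:1);"))
        t = CountTable(
            np.array([[3, 1, 0, 2], [1, 1, 1, 0]]), ["S0", "S1"], ["A", "B", "C", "D"]
        )
        res = ses_mntd(t, tree, n_null=29, seed=0)
        assert res["ses"].isna().all()

    def test_null_self_calibration(self):
        """Communities drawn by the shuffle null itself give ses ~ N(0,1)."""
        rng = np.random.default_rng(2)
        tree = random_tree(60, seed=9)
        n_samples = 80
        counts = np.zeros((n_samples, 60), dtype=int)
        base = rng.integers(1, 20, size=12)
        for s in range(n_samples):
            tips = rng.choice(60, size=12, replace=False)
            counts[s, tips] = base  # same abundance multiset, random tips
        t = CountTable(counts, [f"S{i}" for i in range(n_samples)], [f"x{j}" for j in range(60)])
        t = CountTable(counts, t.sample_ids, sorted(tree.tip_names))
        res = ses_mntd(t, tree, n_null=299, seed=3)
        assert -0.25 < res["ses"].mean() < 0.25
        assert 0.7 < res["ses"].std() < 1.3

    def test_clustered_community_strongly_negative(self):
        tree = random_tree(80, seed=5)
        tips = sorted(tree.tip_names)
        _, d = tree.patristic(taxon_order=tips)
        # community = the 10 tips closest to the tightest anchor
        radius = np.sort(d, axis=1)[:, 9]
        anchor = int(np.argmin(radius))
        members = np.argsort(d[anchor])[:10]
        counts = np.zeros((2, 80), dtype=int)
        counts[:, members] = 5
        counts[1, members[0]] = 9  # second sample, slightly different weights
        t = CountTable(counts, ["S0", "S1"], tips)
        res = ses_mntd(t, tree, n_null=299, seed=4)
        assert (res["ses"] < -2).all()

    def test_abs_ses_consistency(self):
        tree = random_tree(20, seed=6)
        t = random_table(4, 20, seed=7, depth=200)
        t = CountTable(t.counts, t.sample_ids, sorted(tree.tip_names))
        res = ses_mntd(t, tree, n_null=99, seed=5)
        np.testing.assert_allclose(res["abs_ses"], res["ses"].abs())


class TestSesBetaMntd:
    def test_matrix_symmetric_zero_diagonal(self):
        tree = random_tree(20, seed=8)
        t = random_table(5, 20, seed=9, depth=300)
        t = CountTable(t.counts, t.sample_ids, sorted(tree.tip_names))
        m = ses_beta_mntd(t, tree, n_null=99, seed=6)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(m.values), 0.0)

    def test_null_calibration_few_extreme_pairs(self):
        rng = np.random.default_rng(10)
        tree = random_tree(60, seed=11)
        counts = np.zeros((20, 60), dtype=int)
        for s in range(20):
            tips = rng.choice(60, size=15, replace=False)
            counts[s, tips] = rng.integers(1, 10, size=15)
        t = CountTable(counts, [f"S{i}" for i in range(20)], sorted(tree.tip_names))
        m = ses_beta_mntd(t, tree, n_null=299, seed=7)
        vals = m.condensed()
        assert np.mean(np.abs(vals) > 2) <= 0.10

    def test_clade_confined_pair_strongly_negative(self):
        tree = random_tree(100, seed=12)
        tips = sorted(tree.tip_names)
        _, d = tree.patristic(taxon_order=tips)
        radius = np.sort(d, axis=1)[:, 29]
        anchor = int(np.argmin(radius))
        clade = np.argsort(d[anchor])[:30]
        rng = np.random.default_rng(13)
        counts = np.zeros((2, 100), dtype=int)
        counts[0, rng.choice(clade, 12, replace=False)] = 4
        counts[1, rng.choice(clade, 12, replace=False)] = 4
        t = CountTable(counts, ["S0", "S1"], tips)
        m = ses_beta_mntd(t, tree, n_null=299, seed=8)
        assert m.values[0, 1] < -2

    def test_shuffle_preserves_abundance_multiset(self):
        """The null only moves tip identities: per-sample count multisets
        and richness are exactly preserved by construction (column
        permutation of the abundance matrix)."""
        rel = np.random.default_rng(1).dirichlet(np.ones(8), size=3)
        perm = np.random.default_rng(2).permutation(8)
        rel_null = np.empty_like(rel)
        rel_null[:, perm] = rel
        for s in range(3):
            assert sorted(rel_null[s]) == pytest.approx(sorted(rel[s]))


class TestRaupCrick:
    def test_identical_pair_maximally_similar(self):
        rng = np.random.default_rng(14)
        n_taxa = 60
        base = rng.multinomial(2000, rng.dirichlet(np.ones(n_taxa)))
        counts = np.vstack([base, base])
        # add richer companions so the gamma pool is much richer than the pair
        extra = np.array(
            [rng.multinomial(2000, rng.dirichlet(np.ones(n_taxa))) for _ in range(4)]
        )
        t = CountTable(
            np.vstack([counts, extra]),
            [f"S{i}" for i in range(6)],
            [f"OTU{j}" for j in range(n_taxa)],
        )
        rc = raup_crick_bray(t, n_null=199, seed=9)
        assert rc.values[0, 1] <= -0.95

    def test_disjoint_support_high_turnover(self):
        rng = np.random.default_rng(15)
        n_taxa = 60
        counts = np.zeros((6, n_taxa), dtype=int)
        for s in range(6):
            tips = rng.choice(n_taxa, 20, replace=False)
            counts[s, tips] = rng.integers(5, 50, 20)
        # samples 0 and 1 get strictly disjoint supports
        counts[0] = 0
        counts[1] = 0
        counts[0, :20] = rng.integers(5, 50, 20)
        counts[1, 20:40] = rng.integers(5, 50, 20)
        t = CountTable(counts, [f"S{i}" for i in range(6)], [f"OTU{j}" for j in range(n_taxa)])
        rc = raup_crick_bray(t, n_null=199, seed=10)
        assert rc.values[0, 1] > 0.95

    def test_self_calibration_null_assembled_pairs(self):
        """Pairs generated by the null-assembly recipe itself score near 0."""
        rng = np.random.default_rng(16)
        n_taxa, n_samples, depth = 80, 30, 1000
        occ = rng.uniform(0.5, 1.0, n_taxa)
        gamma = rng.dirichlet(np.ones(n_taxa) * 0.5)
        counts = np.zeros((n_samples, n_taxa), dtype=int)
        for s in range(n_samples):
            keys = rng.exponential(size=n_taxa) / occ
            drawn = np.argpartition(keys, 25)[:25]
            p = gamma[drawn] / gamma[drawn].sum()
            counts[s, drawn] = rng.multinomial(depth - 25, p) + 1
        t = CountTable(counts, [f"S{i}" for i in range(n_samples)], [f"OTU{j}" for j in range(n_taxa)])
        rc = raup_crick_bray(t, n_null=299, seed=11)
        vals = rc.condensed()
        assert -0.2 < vals.mean() < 0.2
        assert np.mean(np.abs(vals) > 0.95) <= 0.12

    def test_symmetric_and_deterministic(self):
        t = random_table(6, 30, seed=17, depth=400)
        a = raup_crick_bray(t, n_null=99, seed=12)
        b = raup_crick_bray(t, n_null=99, seed=12)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_allclose(a.values, a.values.T)
        assert np.abs(a.values).max() <= 1.0


class TestClassifier:
    @pytest.mark.parametrize(
        "ses,rc,expected",
        [
            (1.0, 0.97, "dispersal_limitation"),
            (-2.5, 0.99, "homogeneous_selection"),  # selection takes precedence
            (0.0, 0.0, "drift"),
            (2.5, -0.99, "variable_selection"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (2.0, 0.99, "dispersal_limitation"),  # threshold is strict
        ],
    )
    def test_two_stage_rules(self, ses, rc, expected):
        assert classify_process(ses, rc) == expected

    def test_missing_input_unclassified(self):
        assert classify_process(np.nan, 0.5) == "unclassified"

    def test_pair_table_consistent_with_rules(self):
        tree = random_tree(20, seed=20)
        t = random_table(5, 20, seed=21, depth=300)
        t = CountTable(t.counts, t.sample_ids, sorted(tree.tip_names))
        bm = ses_beta_mntd(t, tree, n_null=49, seed=13)
        rc = raup_crick_bray(t, n_null=49, seed=14)
        pairs = classify_pairs(bm, rc)
        assert len(pairs) == 10
        for _, row in pairs.iterrows():
            assert row["process"] == classify_process(row["bmntd_ses"], row["rc_bray"])
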