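"""Synthetic metacommunities with known assembly regimes.

The generator emulates the structure of a multi-site host-microbiome
survey: ~11 trapping sites split between city and rural environments,
land classes mapping onto built versus forest local habitat, per-sample
sequencing depths in the observed range (9,724-60,891 reads), a
phylogeny over the gamma pool, and phylogenetically conserved niche
traits (Brownian motion on the tree).

Each site block is assembled under one of four regimes:

* ``selection`` — the environment filters colonists to a
  phylogenetically tight guild (the tips nearest one of two maximally
  distant anchor tips), built and forest habitats filtering to opposite
  guilds; each sample then recruits a finite uniform colonisation
  lottery from its guild and fills abundances by base metacommunity
  abundance shaped by a Gaussian kernel around the guild's mean niche
  trait.  Same-guild pairs experience homogeneous selection (taxon
  turnover confined to one clade), cross-guild pairs variable
  selection.  Two features are essential for a nearest-taxon statistic
  to see the regime: the guild must be a genuine clade (a trait-value
  window alone is clade-diffuse under Brownian evolution, because of
  convergence), and per-sample supports must turn over (taxa present in
  both communities of a pair contribute zero distance to both the
  observed and the null statistic, since the tip shuffle preserves
  co-occurrence).
* ``dispersal_limitation`` — each site draws its own source pool (a
  weighted subset of the gamma pool) with low migration from the full
  metacommunity; between-site turnover is high, within-site low.
* ``homogenizing_dispersal`` — every sample in the block shares one
  source pool with high migration, so pairs are more similar than
  chance expects.
* ``drift`` — neutral multinomial resampling: each sample's community
  descends from a common ancestral community by repeated finite-size
  multinomial resampling (a Wright-Fisher chain over relative
  abundances), i.e. stochastic divergence with neither selection nor
  dispersal structure.

Counts are multinomial draws at a depth uniform in ``depth_range``.
GroundTruth records the intended regime for every within-block sample
pair and each taxon's simulated trait.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LAND_CLASS_TO_LOCAL_TYPE,
    CountTable,
    PhyloTree,
    validate_sample_frame,
    write_count_table,
)

__all__ = [
    "SiteSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedBundle",
    "simulate_tree",
    "simulate_niche_traits",
    "assemble_communities",
    "generate",
    "write_fixture",
    "PRESETS",
    "preset_config",
]

REGIMES = ("selection", "dispersal_limitation", "homogenizing_dispersal", "drift")


@dataclass(frozen=True)
class SiteSpec:
    """One trapping site: location covariates, sample count, and regime."""

    site: str
    environment: str  # city | rural
    land_class: str  # campus | suburban_park | urban_forest | rural_forest
    n_samples: int
    regime: str

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.land_class not in LAND_CLASS_TO_LOCAL_TYPE:
            raise ValueError(f"unknown land_class {self.land_class!r}")

    @property
    def local_type(self) -> str:
        return LAND_CLASS_TO_LOCAL_TYPE[self.land_class]


@dataclass
class SimulationConfig:
    """Tunable knobs of the metacommunity generator.

    selection_clade_fraction_range bounds the size (as a share of the
    gamma pool) of the monophyletic clades eligible to serve as an
    environment's guild;
    selection_richness_fraction sets how many guild members one sample
    recruits (keeping recruited richness well below guild size preserves
    the taxon turnover a nearest-taxon null needs — shared taxa carry no
    signal).  selection_strength is the Gaussian fill-weight kernel
    coefficient around the guild's mean niche trait (standardised
    units).  migration_rate is the share of a dispersal-limited sample's
    reads sourced from the full metacommunity rather than its site
    pool.  Drift samples evolve from the ancestral metacommunity by
    ``drift_generations`` rounds of multinomial resampling at community
    size ``drift_community_size``; the generations-to-size ratio sets
    how far the block diverges (kept intermediate — beyond sampling
    noise, short of complete turnover — which is what the drift label
    denotes).  All set-size knobs are fractions of n_taxa, so scaling
    the pool does not change their meaning.
    """

    sites: list[SiteSpec]
    n_taxa: int = 150
    depth_range: tuple[int, int] = (9724, 60891)
    bm_variance: float = 1.0
    selection_clade_fraction_range: tuple[float, float] = (0.12, 0.40)
    selection_richness_fraction: float = 0.08
    selection_strength: float = 2.0
    selection_turnover_sigma: float = 0.5
    selection_evenness_exponent: float = 0.3
    migration_rate: float = 0.01
    high_migration_rate: float = 0.10
    site_pool_fraction: float = 0.25
    shared_pool_fraction: float = 0.30
    drift_community_size: int = 2000
    drift_generations: int = 120
    abundance_sigma: float = 1.5
    sample_jitter_sigma: float = 0.1
    hd_jitter_sigma: float = 0.05
    site_lottery_sigma: float = 3.0
    phenotype_selection_modifier: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.migration_rate <= 1 or not 0 <= self.high_migration_rate <= 1:
            raise ValueError("migration rates must be in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not self.sites:
            raise ValueError("need at least one site")

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.sites)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return d


@dataclass
class GroundTruth:
    """Intended assembly regime per within-block pair and per-taxon traits."""

    pair_regimes: pd.DataFrame  # sample_a, sample_b, true_regime
    taxon_traits: pd.DataFrame  # taxon_id, trait, nearest_optimum


@dataclass
class SimulatedBundle:
    table: CountTable
    tree: PhyloTree
    metadata: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Tree and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree, depth normalised to 1."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    from dendropy.simulate import treesim

    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    import io as _io

    tree = PhyloTree.from_newick(_io.StringIO(newick))
    # deterministic tip labels in tip-traversal order
    width = max(4, len(str(n_taxa)))
    for i, tip in enumerate(tree.tree.tips()):
        tip.name = f"OTU{i + 1:0{width}d}"
    # equalise root-to-tip depths exactly, then scale total depth to 1
    depths = tree.root_to_tip_depths()
    max_depth = max(depths.values())
    for tip in tree.tree.tips():
        tip.length += max_depth - depths[tip.name]
    for node in tree.tree.traverse(include_self=False):
        node.length /= max_depth
    return PhyloTree(tree.tree)


def simulate_niche_traits(tree: PhyloTree, bm_variance: float = 1.0, seed: int = 0) -> pd.Series:
    """Brownian-motion trait on the tree: root value 0, edge steps N(0, v * len)."""
    if bm_variance < 0:
        raise ValueError("bm_variance must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(bm_variance * node.length)) if node.length > 0 else 0.0
        val = values[id(node.parent)] + (step if bm_variance > 0 else 0.0)
        values[id(node)] = val
        if node.is_tip():
            out[node.name] = val
    return pd.Series(out, name="trait").loc[tree.tip_names]


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    keys = rng.exponential(size=len(weights)) / weights
    if k >= len(weights):
        return np.arange(len(weights))
    return np.sort(np.argpartition(keys, k)[:k])


def _selection_guilds(
    tree, taxa_pos: dict, dmat: np.ndarray, size_lo: int, size_hi: int,
    sep_fraction: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint, phylogenetically tight, well-separated guilds.

    Candidate guilds are monophyletic clades with between ``size_lo``
    and ``size_hi`` tips, scored by their mean within-clade
    nearest-neighbour distance.  Among disjoint clade pairs whose
    closest cross-guild members are at least ``sep_fraction`` of the
    tree diameter apart (a floor relaxed geometrically when the tree
    cannot honour it), the tightest combined pair wins.  Tight guilds
    make homogeneous selection visible to a nearest-taxon statistic;
    separated guilds make variable selection visible.
    """
    cands: list[tuple[np.ndarray, float]] = []
    for node in tree.tree.non_tips(include_self=False):
        tips = [taxa_pos[t.name] for t in node.tips()]
        if size_lo <= len(tips) <= size_hi:
            idx = np.sort(np.asarray(tips))
            sub = dmat[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            cands.append((idx, float(sub.min(axis=1).mean())))
    cands.sort(key=lambda c: c[1])
    floor = sep_fraction * dmat.max()
    while floor > 1e-12:
        valid: list[tuple[float, float, np.ndarray, np.ndarray]] = []
        for i in range(len(cands)):
            idx_i, nn_i = cands[i]
            set_i = set(idx_i)
            for j in range(i + 1, len(cands)):
                idx_j, nn_j = cands[j]
                if not set_i.isdisjoint(idx_j):
                    continue
                cross = dmat[np.ix_(idx_i, idx_j)].min()
                if cross < floor:
                    continue
                valid.append((nn_i + nn_j, cross, idx_i, idx_j))
        if valid:
            # tightest combined pair, then widest separation among
            # near-ties (within 30% of the best tightness)
            best_score = min(v[0] for v in valid)
            near = [v for v in valid if v[0] <= 1.3 * best_score]
            _, _, idx_a, idx_b = max(near, key=lambda v: (v[1], -v[0]))
            return idx_a, idx_b
        floor /= 2.0
    # degenerate tree (no two disjoint clades in range): fall back to
    # neighbourhoods of the two most distant tips
    a, b = np.unravel_index(np.argmax(dmat), dmat.shape)
    size = max(3, size_lo)
    guild_a = np.sort(np.argsort(dmat[int(a)], kind="stable")[:size])
    in_a = np.zeros(dmat.shape[0], dtype=bool)
    in_a[guild_a] = True
    order_b = [t for t in np.argsort(dmat[int(b)], kind="stable") if not in_a[t]]
    return guild_a, np.sort(np.asarray(order_b[:size]))


def assemble_communities(
    config: SimulationConfig,
    tree: PhyloTree,
    traits: pd.Series,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Draw the count table, sample metadata, and ground truth for a config."""
    taxa = list(traits.index)
    n_t = len(taxa)
    if n_t != config.n_taxa:
        raise ValueError("traits length does not match config.n_taxa")
    tr = traits.to_numpy(dtype=float)

    root = np.random.SeedSequence(config.seed)
    s_meta, s_base, s_pools, s_samples = [
        np.random.default_rng(c) for c in root.spawn(4)
    ]

    # base metacommunity: log-normal rank-abundance
    w_base = np.exp(s_base.normal(0.0, config.abundance_sigma, size=n_t))
    w_base /= w_base.sum()

    # environment-specific guilds for the selection regime
    _, dmat = tree.patristic(taxon_order=taxa)
    lo = max(3, round(config.selection_clade_fraction_range[0] * n_t))
    hi = max(lo, round(config.selection_clade_fraction_range[1] * n_t))
    taxa_pos = {t: i for i, t in enumerate(taxa)}
    guild_built, guild_forest = _selection_guilds(tree, taxa_pos, dmat, lo, hi)
    guilds = {"built": guild_built, "forest": guild_forest}
    z = (tr - tr.mean()) / (tr.std() if tr.std() > 0 else 1.0)
    guild_opt = {lt: float(z[g].mean()) for lt, g in guilds.items()}

    # site pools for dispersal-limited sites; one shared pool for the
    # homogenizing-dispersal block
    pool_size = max(2, round(config.site_pool_fraction * n_t))
    shared_size = max(2, round(config.shared_pool_fraction * n_t))
    site_pools: dict[str, np.ndarray] = {}
    for spec in config.sites:
        if spec.regime == "dispersal_limitation":
            # pure site lottery: pool membership independent of regional
            # abundance, so different sites favour different dominants.
            # The lottery is stratified over contiguous blocks of the
            # tip ordering (which follows the tree's clade structure),
            # keeping every pool phylogenetically representative — the
            # regime is dispersal-limited, not selective, so pools must
            # not be clumped on the phylogeny by accident.
            lottery = np.exp(s_pools.normal(0.0, config.site_lottery_sigma, size=n_t))
            strata = np.array_split(np.arange(n_t), min(10, max(1, n_t // 10)))
            chosen: list[np.ndarray] = []
            for stratum in strata:
                k_str = max(1, round(pool_size * len(stratum) / n_t))
                k_str = min(k_str, len(stratum))
                keys = s_pools.exponential(size=len(stratum)) / lottery[stratum]
                chosen.append(stratum[np.argpartition(keys, k_str - 1)[:k_str]])
            site_pools[spec.site] = np.sort(np.concatenate(chosen))
    shared_pool = _weighted_subset(s_pools, w_base, shared_size)

    rows, meta_rows = [], []
    sample_block: dict[str, str] = {}
    sample_site: dict[str, str] = {}
    sample_guild: dict[str, str] = {}
    counter = 0
    for spec in config.sites:
        for _ in range(spec.n_samples):
            counter += 1
            sid = f"S{counter:03d}"
            alleles = int(s_meta.choice([0, 1, 2], p=[0.4, 0.4, 0.2]))
            sex = str(s_meta.choice(["F", "M"]))
            depth = int(s_samples.integers(config.depth_range[0], config.depth_range[1] + 1))

            if spec.regime == "selection":
                strength = config.selection_strength * (
                    1.0 + config.phenotype_selection_modifier * alleles
                )
                guild = guilds[spec.local_type]
                opt = guild_opt[spec.local_type]
                k_mean = max(3, round(config.selection_richness_fraction * n_t))
                k = min(len(guild), max(3, int(s_samples.poisson(k_mean))))
                # uniform colonisation lottery within the guild: same
                # niche, different winners
                support = np.sort(s_samples.choice(guild, size=k, replace=False))
                e = np.zeros(n_t)
                # flattened base weights: within-guild selection curbs
                # dominance, spreading abundance over the recruited taxa
                e[support] = (
                    w_base[support] ** config.selection_evenness_exponent
                    * np.exp(-strength * (z[support] - opt) ** 2)
                    * np.exp(s_samples.normal(0.0, config.selection_turnover_sigma, k))
                )
            elif spec.regime == "dispersal_limitation":
                pool = site_pools[spec.site]
                e_pool = np.zeros(n_t)
                e_pool[pool] = w_base[pool] / w_base[pool].sum()
                e_pool *= np.exp(s_samples.normal(0.0, config.sample_jitter_sigma, n_t))
                e_pool /= e_pool.sum()
                e = (1 - config.migration_rate) * e_pool + config.migration_rate * w_base
            elif spec.regime == "homogenizing_dispersal":
                e_pool = np.zeros(n_t)
                e_pool[shared_pool] = w_base[shared_pool] / w_base[shared_pool].sum()
                e_pool *= np.exp(s_samples.normal(0.0, config.hd_jitter_sigma, n_t))
                e_pool /= e_pool.sum()
                e = (
                    1 - config.high_migration_rate
                ) * e_pool + config.high_migration_rate * w_base
            else:  # drift: Wright-Fisher resampling chain from the ancestor
                j_size = config.drift_community_size
                freqs = s_samples.multinomial(j_size, w_base) / j_size
                for _ in range(config.drift_generations):
                    freqs = s_samples.multinomial(j_size, freqs) / j_size
                e = freqs

            e = np.maximum(e, 0.0)
            e /= e.sum()
            rows.append(s_samples.multinomial(depth, e))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "site": spec.site,
                    "environment": spec.environment,
                    "land_class": spec.land_class,
                    "local_type": spec.local_type,
                    "phenotype_alleles": alleles,
                    "sex": sex,
                }
            )
            sample_block[sid] = spec.regime
            sample_site[sid] = spec.site
            sample_guild[sid] = spec.local_type

    table = CountTable(np.asarray(rows), [m["sample_id"] for m in meta_rows], taxa)
    meta = validate_sample_frame(pd.DataFrame(meta_rows))

    pair_rows = []
    ids = table.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            ra, rb = sample_block[a], sample_block[b]
            if ra != rb:
                label = "mixed"
            elif ra == "selection":
                label = (
                    "homogeneous_selection"
                    if sample_guild[a] == sample_guild[b]
                    else "variable_selection"
                )
            elif ra == "dispersal_limitation":
                label = (
                    "homogenizing_dispersal"
                    if sample_site[a] == sample_site[b]
                    else "dispersal_limitation"
                )
            else:
                label = "homogenizing_dispersal" if ra == "homogenizing_dispersal" else "drift"
            pair_rows.append({"sample_a": a, "sample_b": b, "true_regime": label})

    in_built = np.zeros(n_t, dtype=bool)
    in_built[guild_built] = True
    in_forest = np.zeros(n_t, dtype=bool)
    in_forest[guild_forest] = True
    opts = np.array([guild_opt["built"], guild_opt["forest"]])
    nearest = opts[np.argmin(np.abs(z[:, None] - opts[None, :]), axis=1)]
    truth = GroundTruth(
        pair_regimes=pd.DataFrame(pair_rows),
        taxon_traits=pd.DataFrame(
            {
                "taxon_id": taxa,
                "trait": tr,
                "nearest_optimum": nearest,
                "in_built_guild": in_built,
                "in_forest_guild": in_forest,
            }
        ),
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# Presets and fixture writing
# ---------------------------------------------------------------------------

def _small_sites() -> list[SiteSpec]:
    return [
        SiteSpec("G01", "city", "campus", 8, "selection"),
        SiteSpec("G02", "rural", "rural_forest", 7, "selection"),
        SiteSpec("G03", "city", "suburban_park", 3, "dispersal_limitation"),
        SiteSpec("G04", "city", "urban_forest", 3, "dispersal_limitation"),
        SiteSpec("G05", "rural", "rural_forest", 3, "dispersal_limitation"),
        SiteSpec("G06", "city", "campus", 3, "dispersal_limitation"),
        SiteSpec("G07", "rural", "rural_forest", 3, "dispersal_limitation"),
        SiteSpec("G08", "city", "suburban_park", 8, "homogenizing_dispersal"),
        SiteSpec("G09", "rural", "rural_forest", 7, "homogenizing_dispersal"),
        SiteSpec("G10", "city", "urban_forest", 7, "drift"),
        SiteSpec("G11", "rural", "rural_forest", 8, "drift"),
    ]


def _full_sites() -> list[SiteSpec]:
    return [
        SiteSpec("G01", "city", "campus", 26, "selection"),
        SiteSpec("G02", "rural", "rural_forest", 23, "selection"),
        SiteSpec("G03", "city", "suburban_park", 10, "dispersal_limitation"),
        SiteSpec("G04", "city", "urban_forest", 10, "dispersal_limitation"),
        SiteSpec("G05", "rural", "rural_forest", 10, "dispersal_limitation"),
        SiteSpec("G06", "city", "campus", 10, "dispersal_limitation"),
        SiteSpec("G07", "rural", "rural_forest", 10, "dispersal_limitation"),
        SiteSpec("G08", "city", "suburban_park", 24, "homogenizing_dispersal"),
        SiteSpec("G09", "rural", "rural_forest", 24, "homogenizing_dispersal"),
        SiteSpec("G10", "city", "urban_forest", 24, "drift"),
        SiteSpec("G11", "rural", "rural_forest", 24, "drift"),
    ]


PRESETS = {
    "squirrel-small": dict(sites=_small_sites, n_taxa=150),
    "squirrel-full": dict(sites=_full_sites, n_taxa=1256),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study-design presets: ``squirrel-small`` (60 samples × 150 taxa)
    and ``squirrel-full`` (195 samples × 1,256 taxa across 11 sites)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    kwargs = dict(sites=spec["sites"](), n_taxa=spec["n_taxa"], seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def generate(config: SimulationConfig) -> SimulatedBundle:
    """Run the full generator: tree → traits → communities."""
    root = np.random.SeedSequence(config.seed)
    tree_seed = int(root.spawn(5)[4].generate_state(1)[0] % (2**31))
    tree = simulate_tree(config.n_taxa, seed=tree_seed)
    traits = simulate_niche_traits(tree, config.bm_variance, seed=tree_seed + 1)
    table, meta, truth = assemble_communities(config, tree, traits)
    return SimulatedBundle(table, tree, meta, truth, config)


def write_fixture(bundle: SimulatedBundle, outdir) -> dict[str, Path]:
    """Write the bundle as the pipeline's plain-text interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_taxa": outdir / "truth_taxa.tsv",
        "config": outdir / "config.json",
    }
    write_count_table(bundle.table, paths["counts"])
    with open(paths["tree"], "w") as fh:
        fh.write(bundle.tree.to_newick())
    bundle.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    bundle.truth.pair_regimes.to_csv(paths["truth_pairs"], sep="\t", index=False)
    bundle.truth.taxon_traits.to_csv(paths["truth_taxa"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
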