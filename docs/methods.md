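# Methods

This note documents the statistical procedures the package implements,
the conventions chosen where the methods literature leaves latitude, the
design of the synthetic metacommunity generator, and the limits of what
the validation suite demonstrates.

## Preprocessing

**Prevalence filter.** A taxon is retained when it has at least
`min_reads` (default 1) reads in at least `ceil(min_fraction × n_samples)`
samples (default fraction 0.05). The ceiling convention means the
threshold can never be satisfied by zero samples.

**Rarefaction.** Each sample is subsampled *without replacement* to a
common depth (default 9,724 reads) — a multivariate hypergeometric draw,
implemented with numpy's generator. Samples below the depth are dropped
with a warning, never scaled. Each sample draws from its own RNG
substream keyed by (pipeline seed, CRC32 of the sample id), so removing
samples from a table does not perturb the draws of the remaining ones.

**CLR transform.** `clr_ij = ln(c_ij + δ) − mean_k ln(c_ik + δ)` with a
pseudocount δ = 1 on raw counts (configurable). The literature offers no
canonical pseudocount; +1 on integer counts is simple and reproducible.
Rows sum to zero by construction, and Euclidean distance on CLR rows
(the Aitchison distance) is invariant to taxon order.

**Box-Cox.** `(y^λ − 1)/λ`, with the `ln y` limit at λ = 0, via
`scipy.special.boxcox`. The pipeline applies λ = 4 to Shannon diversity
and λ = 0.4 to |MNTD_ses|, the defaults recorded in the run manifest.

## Diversity

Richness is the count of taxa with reads; Shannon diversity uses natural
logarithms (nats) — the unit is a convention and is stated in the output
schema. Weighted UniFrac walks every branch of the shared tree: with
`p_X(b)` the fraction of sample X's abundance descending from branch b,

    raw(A,B)  = Σ_b len(b) · |p_A(b) − p_B(b)|
    norm(A,B) = raw(A,B) / Σ_b len(b) · (p_A(b) + p_B(b))

The normalised form (default) is bounded in [0, 1] and comparable across
depths. On a unit-branch star tree the raw form reduces exactly to the
Manhattan distance between relative-abundance vectors — a useful
hand-check, verified in the tests together with a brute-force per-branch
oracle and a cross-check against scikit-bio.

PCoA is the classical Gower double-centring followed by an
eigendecomposition; negative eigenvalues (non-Euclidean input) are
*retained and reported*, not clipped, because the dispersion test needs
the imaginary axes. Hierarchical clustering defaults to UPGMA (average
linkage, configurable), whose merge heights are non-decreasing.

## Permutation inference

**Sequential PERMANOVA.** The distance matrix is converted to the
Gower-centred inner-product matrix G; design terms are fitted in the
order given, each term's hat-matrix increment obtained by orthonormal
basis accumulation (SVD with a rank tolerance). `SS_term = tr(H_term G)`,
R² = SS/SS_total, and pseudo-F compares each term to the residual.
p-values use free permutation of sample identities,
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, so the attainable minimum
is `1/(n_perm+1)`. Survey designs of this kind are nested
(environment ⊂ land class ⊂ site), so later terms can be rank-deficient
given earlier ones: such terms are *absorbed* — df 0, SS 0, p missing —
with a logged warning, rather than silently re-parameterised. Restricted
permutation (strata) is deliberately not the default; free permutation
matches the reference implementations of this test.

**Dispersion homogeneity.** Samples are embedded by PCoA keeping
negative axes; a sample's squared distance to its group centroid is the
positive-axis sum *minus* the negative-axis sum, floored at zero before
the square root. With `bias_adjust` (default on), squared distances are
scaled by `n_g/(n_g − 1)`, countering the downward bias of distances to
an estimated centroid in small groups. The global test permutes group
labels and recomputes the one-way ANOVA F on the distances; pairwise
contrasts repeat the scheme on each group pair.

**Mixed model.** `fit_lmm` wraps statsmodels MixedLM (REML, LBFGS with a
Powell fallback) for the study's model `response ~ sex +
alleles × environment + (1 | site)`. Inference uses the Wald statistics
statsmodels reports; finer denominator-df approximations are out of
scope. Non-convergence sets a flag column — never a silent NaN. A
constant response short-circuits to exact zero slopes.

**Kruskal-Wallis / Dunn.** Tie-corrected rank statistics; Dunn pairwise
z uses the pooled-variance form with the tie correction
`Σ(t³−t)/(12(N−1))`. p-values are unadjusted by default with an optional
Benjamini-Hochberg flag.

## Null models and the process classifier

**Tip-shuffle null.** One null replicate draws a single random
permutation of the taxon↔tip assignment over the full γ pool and applies
it to *every* sample simultaneously — equivalently, a joint
row/column permutation of the patristic matrix. This preserves each
sample's abundance multiset, richness, and the co-occurrence structure
between samples exactly; only phylogenetic identity moves. MNTD uses
9,999 replicates by default and βMNTD 999 (the shared-replicate scheme
also standardises all pairs against the same null draws, the
computationally efficient choice). `ses = (obs − mean_null)/sd_null`
with the sample (n−1) standard deviation; a zero-variance null —
e.g. every tip equidistant on a star tree, or two samples with identical
supports — yields a *missing* ses with a warning, never ±∞.

An algebraic identity makes the pairwise computation fast: with R the
samples × taxa relative-abundance matrix and `M[s, t]` the distance from
taxon t to its nearest taxon present in sample s, the full weighted
βMNTD matrix is `0.5 (R Mᵀ + M Rᵀ)`. A shared taxon has nearest-partner
distance zero, so identical communities score 0.

**Raup-Crick on Bray-Curtis.** For each pair, the observed Bray-Curtis
dissimilarity (on counts) is ranked within `n_null` (default 9,999)
pairs of null communities. A null community preserves the sample's
observed richness k and read total N: k taxa are drawn without
replacement with probability proportional to occurrence frequency
across samples (exponential-key sampling), each seeded with one read,
and the remaining N − k reads are allocated multinomially with
probability proportional to pooled (metacommunity) relative abundance.
`RC = (#{null < obs} + ½·#{null = obs})/n_null`, rescaled to
`(RC − 0.5)·2 ∈ [−1, 1]`; ties take half weight. Null realisations are
generated per sample and shared across the pairs that sample enters —
each pair's marginal null distribution is unchanged, and memory stays
bounded by generating replicates in chunks. Both weight vectors default
to the empirical estimates from the table; they can be overridden with
known metacommunity parameters, which is essential when scoring data
simulated from a known pool (re-estimating occurrence from a small
sample set aligns the null with the dataset's own draws and shifts RC
upward by ≈ +0.2 at 30 samples).

**Classifier.** Selection is read first: βMNTD_ses > +2 → variable
selection, < −2 → homogeneous selection. Only in the absence of a
phylogenetic deviation is turnover consulted: RC_bray > 0.95 → dispersal
limitation, < −0.95 → homogenizing dispersal, otherwise drift. Missing
inputs give `unclassified` with a warning. Thresholds (±2, ±0.95) are
package constants recorded in the manifest.

## Niche deviation and the correlogram

A taxon's niche score is its mean relative abundance in habitat 1 versus
habitat 2, summarised as the signed perpendicular offset from the 1:1
line, `(m₁ − m₂)/√2`; the vertical difference (a flag) differs only by
the constant √2, which Moran's I is invariant to. The correlogram
evaluates Moran's I at `n_lags` distances spanning (0, max patristic
distance], with Epanechnikov kernel proximity weights of bandwidth
`2·d_max/n_lags` (configurable), zero diagonal, row-normalised. The lag
count collapses to the number of distinct pairwise distances when the
tree is small (a two-tip tree has one lag, where I = −1 identically by
the n = 2 arithmetic). The 95% envelope is the 2.5th/97.5th percentile
of I under random permutation of scores across tips — an exact
exchangeability null — and a lag is flagged significant when the
observed I leaves the envelope.

## The synthetic metacommunity generator

The generator reproduces the *structure* of a multi-city host-microbiome
survey — 11 trapping sites in two environments, 60 (small preset) or 195
(full preset) samples, 150 or 1,256 taxa, per-sample sequencing depths
uniform in [9,724, 60,891], an ultrametric pure-birth tree of unit
depth, Brownian niche traits, host phenotype (0/1/2 melanism alleles)
and sex covariates — not any particular taxonomic composition. A
log-normal (σ = 1.5) base metacommunity supplies rank-abundance realism.
Four assembly regimes are encoded per site block, and a GroundTruth
object records the intended regime of every within-block sample pair:

* **Selection.** Each environment filters colonists to a *guild*: a
  monophyletic clade (12–40% of the pool) chosen from the simulated
  tree. The two guilds are picked jointly — disjoint, each tight (small
  mean within-clade nearest-neighbour distance), and separated by a
  floor of 40% of the tree diameter (relaxed only if the tree cannot
  honour it). A sample recruits a finite uniform lottery (~8% of the
  pool) from its guild and fills abundances with flattened base weights
  (`w^0.3`) shaped by a Gaussian kernel around the guild's mean trait.
  Three features are load-bearing, each verified empirically during
  design: (i) the guild must be a genuine clade — under Brownian
  evolution a trait-value window is clade-diffuse because of
  convergence, and a nearest-taxon statistic cannot see it; (ii) the
  recruitment lottery must be finite and uniform — at depth ~10⁴ a
  purely multinomial community contains every taxon with non-negligible
  expected abundance, two such communities share their entire support,
  and shared taxa contribute zero to both the observed and the null
  βMNTD (the tip shuffle preserves co-occurrence); (iii) dominance must
  be curbed — strong log-normal dominance leaves few effective taxa and
  inflates the null standard deviation. Same-guild pairs are
  homogeneous selection, cross-guild pairs variable selection.
* **Dispersal limitation.** Each site draws its own source pool (25% of
  the pool) by a pure log-normal lottery *stratified* over contiguous
  clade-blocks of the tip ordering, keeping pools phylogenetically
  representative — the regime is dispersal-limited, not selective, and
  unstratified pools occasionally clump on the phylogeny and read as
  spurious selection. Samples mix their site pool with a 1% migration
  share of the full metacommunity; migration also pads richness, which
  lowers the Raup-Crick null's Bray-Curtis and sharpens detection.
  Between-site pairs are the dispersal-limitation ground truth;
  within-site pairs (shared pool) are labelled homogenizing dispersal.
* **Homogenizing dispersal.** One shared pool (30% of the pool) for the
  whole block, small per-sample jitter (σ = 0.05), 10% migration:
  near-replicate communities, more similar than any null assembly.
* **Drift.** Each sample's composition descends from the common
  ancestral metacommunity by a Wright-Fisher chain — `G = 120`
  generations of multinomial resampling at community size `J = 2000` —
  yielding stochastic divergence with neither selection nor dispersal
  structure. The G/J ratio sets how far the block diverges and is chosen
  to sit in the intermediate-turnover zone that the drift label denotes:
  far beyond resampling noise (which would read as homogenizing
  dispersal) and short of complete turnover (which would read as
  dispersal limitation).

What the generator does *not* emulate: real taxonomic composition,
overdispersed (non-multinomial) count noise, contamination, chimeras,
spatial gradients within sites, or correlated phenotype-environment
sampling. Passing the regime-recovery tests therefore demonstrates that
the statistics respond to the ecological signals they claim to measure
under controlled conditions — not that real gut microbiome data meet the
generator's assumptions.

## Validation design and problem sizes

The test suite validates at three levels. (1) *Oracles*: MNTD, βMNTD,
weighted UniFrac, and Moran's I agree to 1e-10 with independent
brute-force enumerations on 50 random 10-taxon instances. (2) *Null
self-calibration*: data generated by the tip-shuffle null (200
communities, 999 replicates) give mean ses ≈ 0 and sd ≈ 1 with ≤10% of
|ses| > 2; data generated by the Raup-Crick assembly recipe (30 samples,
999 replicates, known weights) give mean RC ≈ 0 with ≤10% beyond ±0.95;
PERMANOVA, the dispersion test, and Kruskal-Wallis hold rejection rates
near 5% over 200 null simulations, and the mixed model recovers a known
slope within ±3 SE in ≥95 of 100 replicates. (3) *Regime recovery*: on
the default 60 × 150 fixture, homogeneous-selection blocks give median
βMNTD_ses < −2, cross-guild pairs > +2, ≥80% of dispersal-limitation
pairs classify correctly, and drift blocks classify plurality-drift —
verified across 12 generator seeds during design, with one fixed seed in
the suite. Null-model replicate counts in the tests (299–999) are scaled
down from the 9,999 defaults; the statistics' means and standard
deviations are unbiased in the replicate count, so only the Monte-Carlo
error of the checks changes.

## Numerical conventions

Distance matrices must be symmetric to 1e-10 with zero diagonals;
standardised-effect-size matrices may be negative. Patristic distances
come from scikit-bio's tip-to-tip path lengths and are cached per tree.
Zero-length branches are allowed (polytomy artifacts); negative lengths
and missing lengths are errors — no default length is invented, since
branch lengths carry the statistics. Newick tip labels are join keys and
are never munged. TSV count tables auto-detect orientation by matching
metadata sample ids, with an explicit override; silent transposition is
the classic microbiome join bug. All stochastic steps take explicit
seeds; per-sample substreams make rarefaction stable under subsetting;
permutation p-values are reported with the +1 convention and are
bounded below by 1/(n_perm + 1).
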