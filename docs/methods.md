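# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `abtau-modnet`.

## The moderation model and the ΔMI statistic

The scientific object is a *moderated dependence*: the strength of the
statistical coupling between two anchor proteins (APP, the amyloid
precursor, and MAPT, tau) as a function of a third protein's abundance.
A candidate moderator M is scored by the two-group mutual-information
difference

ΔMI(M) = | MI(X, Y | M ∈ top 35%) − MI(X, Y | M ∈ bottom 35%) |,

with MI in bits:  MI(X,Y) = Σ p(x,y) log₂[ p(x,y) / (p(x)p(y)) ], 0·log 0 = 0.

**Discretization.**  Abundances are continuous; MI is estimated by the
plug-in estimator on equal-frequency (rank) bins.  Bin labels are assigned
as `rank · k // n` with a stable sort, which makes the estimator exactly
invariant under strictly increasing transforms of either variable and
deterministic under ties.  The default bin count is ⌊√(n/5)⌋ clamped to
[2, 8] — at the default stratification (35% of a ~300-sample cohort,
n ≈ 105 per stratum) this gives k = 4, a standard bias/variance compromise
for plug-in MI at this sample size.  `n_bins` is overridable everywhere.

**Stratification.**  The top/bottom strata are the floor(0.35·n) samples
with the highest/lowest moderator abundance.  Samples are ordered by
(abundance, sample id); the bottom stratum is the head and the top stratum
the tail of that ordering, so ties — including a fully constant moderator —
resolve deterministically and the strata are always disjoint.

**Null distribution and p-value.**  The resampling null randomizes the
sample-to-stratum assignment: each draw takes a fresh random permutation
of all samples and uses its first and second blocks of the observed
stratum size as pseudo-top/pseudo-bottom.  This preserves the anchors'
joint distribution exactly and tests precisely the null "stratum
membership carries no information about the anchor dependence"; when the
moderator is independent of the anchors the observed split is itself such
a random split, so the test is exact.  The p-value is add-one:
p = (1 + #{ΔMI_null ≥ ΔMI_obs}) / (B + 1), with B = 1,000 by default.
The null is vectorized across draws (rank-binning and joint-table counts
batched over a B×m array), which keeps a 50-candidate screen at B = 1,000
in seconds.  Note the add-one estimator has a resolution floor of
1/(B+1); a screen of C candidates can therefore never produce a BH-adjusted
p below C/(B+1), and B should be chosen so that this floor sits below the
significance level (e.g. B = 2,000 for 51 candidates at α = 0.05).

**Candidates.**  Candidates are the proteins inside the top-5% Euclidean
neighborhood of *both* anchors in the embedding (per anchor the
⌈q(n−1)⌉ nearest non-anchor nodes; intersection, ordered by summed
distance).  BH correction is applied across candidates; both raw and
adjusted p are reported.

## Network construction

The functional network scores every protein pair by Pearson r with the
two-sided p from t = r√((n−2)/(1−r²)); BH is applied across all tested
pairs and pairs with adjusted p < 0.05 are kept.  Retained **signed** r
values are min–max normalized to [0, 1] — strong negative correlations
therefore map near 0; a `use_absolute_r` switch documents and exposes the
alternative reading.  Zero-variance proteins are dropped with a warning
(their correlation is undefined).  The physical network keeps edges with
confidence strictly above 0.7; scores above 1 are auto-detected as the
0–1000 integer scale and divided by 1000.  When all retained scores are
equal, min–max normalization would be 0/0; the weights are defined as 1,
preserving the edges.  Both networks are restricted to their common node
set before fusion.

## Spectral fusion embedding

The upstream feature generator in the original design is a trained
graph-attention fusion network producing 512-dimensional features; the
pipeline's contract is only "a node × feature matrix", and external
embeddings load from TSV.  The built-in embedder is deterministic spectral
fusion: each network's adjacency is symmetrically degree-normalized
(D^−1/2 A D^−1/2), the normalized matrices are averaged, and the
eigenvectors of the d largest eigenvalues are taken (d = min(512, n−1) by
default), scaled by √|λ|, sign-fixed (largest-magnitude entry positive),
and finally **row-normalized to unit length**.  Row normalization is the
standard last step of spectral embedding pipelines; it matters here
because raw eigenvector coordinates scale with connectivity strength, so
hub nodes would be Euclidean-far from their own neighborhoods.  With unit
rows, proximity reflects similarity of connectivity profiles, which is
the property the candidate screen and the module clustering rely on.

**Z-scoring.**  A per-column z-scoring operation (population sd; constant
columns set to 0 with a warning) is provided for externally computed
embeddings, whose coordinates have arbitrary per-dimension scales.  It is
deliberately **not** applied to the spectral features: their per-dimension
scale *is* the √|λ| information weighting, and equalizing column variances
empirically destroys module recovery (adjusted Rand index drops from ~1.0
to ~0.35 at the default dimension).  Downstream functions therefore use
features as given, with `use_zscored` flags where a different convention
is needed.

## Modules and subnetworks

Clustering follows the standard single-cell recipe on the node features:
Euclidean kNN graph with k = 25, union symmetrization (edge if either
direction is a neighbor; ties broken by node name, so the graph is
deterministic), unweighted edges, Louvain at resolution 1 with a fixed
seed, labels renumbered by descending size.  Cluster centroids are mean
feature vectors; modules are related by centroid Pearson r and Euclidean
distance, and summarized as a complete graph weighted by reciprocal
distance (distances below 1e-9 are capped at weight 1e9 with a warning).

The similarity network keeps the top ⌈q·n(n−1)/2⌉ pairs by feature inner
product (ties at the cutoff broken by lexicographic pair order — the edge
count is exact).  Anchored subnetworks take the union of the per-anchor
top-q neighborhoods plus the anchors (an `intersect` flag gives the
common-neighborhood reading) and induce the similarity subgraph.
Community detection uses Newman's leading-eigenvector method (igraph),
with weights retained.  ARPACK occasionally fails to converge from an
unlucky random start on small graphs; the call seeds the start
deterministically and walks a fixed ladder of fallback seeds, so results
are reproducible and robust.

## Cell-type scoring and composition

The signature score of a gene set is the per-cell mean expression of the
set minus the mean of expression-matched controls: genes are ranked by
dataset-wide mean, cut into 24 equal-size bins, and 100 control genes are
drawn (seeded) from the bin of each set gene.  The per-subtype combined
score is mean score × proportion of score-positive cells ("positive" =
control-subtracted score > 0; an expression-based rule would be the
alternative, and the score table reports both factors so either can be
reconstructed), min–max normalized across subtypes.  Over-representation
uses the hypergeometric upper tail P[X ≥ k] with the observed data as the
background universe, BH-corrected across collections.  Subtype composition
is tested on per-donor frequencies: one-way ANOVA across conditions,
followed by Tukey HSD when ANOVA p < 0.05; identical frequencies
everywhere are reported as F = 0, p = 1 rather than NaN.

## Interaction regression

Within each (region, dementia-status) stratum the model
outcome = β0 + β1·x1 + β2·x2 + β3·x1x2 + ε is fit by closed-form normal
equations with classical standard errors; β3's two-sided t-test on n−4 df
is the moderation test.  Rank-deficient designs (e.g. a constant
predictor) are flagged rather than fit; incomplete rows are dropped
listwise with a logged count; strata under 5 complete rows are skipped.
No demographic covariates are included by default — the model is the
literal three-predictor interaction — and both Tau2 and AT8 work as
outcomes.  Severity cross-tabs split donors into top/bottom
floor(0.35·n) by expression (same tie rule as the moderator strata) and
count the full CERAD (1–4) × Braak (0–6) grid including zeros.

## The synthetic-data generator

`synthio` emulates the five inputs at desk scale with planted,
re-measurable structure.  Defaults: 300 samples × 260 proteins; five
co-expression modules of sizes 20–60 (shared Gaussian factor per module,
within-module correlation 0.7); diagnosis labels (NCI/MCI/AD-dementia/
other) with MMSE ranges such that the cohort rule (MCI ∪ early dementia)
retains roughly half the samples; measurement noise sd 0.1 on an
abundance offset of 10; optional MCAR missingness (off by default).

**Moderation mechanism.**  A latent variable u per sample drives three
things: (i) the planted moderators read u out directly; (ii) a small
"anchor neighborhood" (anchors + moderators + 8 background proteins)
co-expresses with u (loading √0.6) and is enriched for physical
interactions, so moderators sit near the anchors in both networks — the
structural premise of the proximity-based candidate screen; (iii) the
anchor coupling: anchor1 loads 0.5 on u, and anchor2 = λ(u)·anchor1 +
0.4u + noise, where λ(u) interpolates between the loadings that give
within-stratum correlations (1−e)/2 and (1+e)/2 via a steep sigmoid
(scale 0.1), e being the configured `moderator_effect`.  The steepness
confines the transition to the middle of u's distribution, so the outer
terciles see near-constant coupling and the terciled correlation gap
re-measures ≈ e (Monte-Carlo sd ≈ 0.1 at n = 300).

**Cells.**  ~2,000 cells × 260 genes, Poisson counts around lognormal
baselines; each of 4 subtypes overexpresses its 10 planted markers by
e^1; subtype S1 has frequency 0.10/0.20/0.30 across Control/Abeta/
AbetaTau; 4 donors per condition enable per-donor composition tests.

**Histology.**  150 donors per dementia status × 4 regions; Tau2 %area =
5 + 0.5·Aβ + 0.3·GFAP + β3·Aβ·GFAP + ε with β3 = 5 only in the (TCx,
dementia) stratum; the intercept is set high enough that truncation at 0
is negligible, so least squares recovers the coefficients without bias.
Braak tracks donor tau burden, CERAD tracks amyloid (1 = definite AD),
and GPNMB FPKM rises with Braak.

**What the generator does not emulate:** TMT reporter-ion chemistry,
batch effects, isoform- or PTM-level variation (APP/MAPT are single
columns), UMI-count overdispersion and dropout structure, and spatial or
demographic confounding in the histology.  Passing tests demonstrate that
the estimators recover the structures they target at realistic sizes and
noise levels — not that those structures are identifiable in any given
real cohort.

## Problem sizes and reproducibility

The test-suite and acceptance simulations use the generator defaults
(n = 300 samples, 260 proteins, 50-decoy screens, 500 regression
simulations, 20-seed repetitions), sizes at which every Monte-Carlo check
runs in seconds to ~1 minute on one CPU.  All randomness flows from
explicit integer seeds: generators use per-artifact child streams of the
config seed, the permutation null derives one child stream per candidate
(CRC-32 of the candidate name), and the pipeline manifest records seeds
and SHA-256 hashes of every output, so reruns are bit-identical.

## Known limitations

- The ΔMI statistic compares only the outer expression strata; moderation
  confined to mid-range expression is invisible to it.
- Equal-frequency binning discards tail-shape information; very heavy
  tails with many ties fall back to order-of-appearance binning.
- The spectral fusion embedder is a stand-in for learned network-fusion
  features: it preserves the downstream properties the pipeline needs
  (module structure, neighborhood proximity) but no equivalence to any
  particular learned embedding is claimed.
- The permutation null assumes exchangeability of samples; cohort
  structure (batches, relatedness) would require a stratified null.
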