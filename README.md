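# abtau-modnet

Integrative network analysis for discovering **moderators of the
amyloid-beta (APP) / tau (MAPT) protein interaction** in proteomics
cohorts, with single-cell and histopathological validation stages.

Amyloid plaques and tau tangles are the two hallmarks of Alzheimer's
disease, and the strength of their coupling varies across patients.  This
package asks: *which proteins change the strength of the APP–MAPT
dependence?*  It implements the full analysis as a tested, reusable Python
library:

1. **Networks** — a functional co-expression network (all-pairs Pearson r,
   Benjamini–Hochberg filtered at adjusted p < 0.05, min–max normalized)
   and a physical interaction network (confidence > 0.7), intersected on
   common proteins.
2. **Embedding** — per-protein feature vectors from the fused networks: a
   deterministic spectral fusion embedder (degree-normalized adjacencies
   averaged, top-*d* eigenvectors scaled by √|λ|, rows unit-normalized),
   or any externally computed embedding loaded from TSV.
3. **Modules** — Euclidean k-nearest-neighbor graph (k = 25) + Louvain
   clustering (resolution = 1); module centroids, centroid correlations /
   distances, and a reciprocal-distance module network.
4. **Moderator screen** — the core statistic.  Candidates are proteins in
   the top-5% embedding neighborhood of *both* anchors.  Each candidate M
   is scored by

   ΔMI(M) = | MI(APP, MAPT | M ∈ top 35%) − MI(APP, MAPT | M ∈ bottom 35%) |

   where MI is mutual information in bits (base-2, equal-frequency
   binning) between the anchor abundances within each stratum of M's
   expression.  Significance comes from a permutation null (randomized
   stratum membership, 1,000 draws, add-one p-value) with BH correction
   across candidates.
5. **Subnetworks** — inner-product similarity network (top 5% of pairs),
   anchored subnetwork extraction, and Newman leading-eigenvector
   community detection; `query_neighborhood` answers interactive
   "neighborhood of these genes" queries.
6. **Cell-type enrichment** — control-matched signature scores per cell,
   per-subtype combined score (mean score × positive proportion, min–max
   normalized), hypergeometric over-representation tests, and
   subtype-composition ANOVA + Tukey HSD across conditions.
7. **Validation** — per-stratum OLS interaction regressions
   (outcome ~ x1 + x2 + x1·x2, e.g. Tau2 %area ~ Aβ %area × GFAP %area)
   and CERAD × Braak severity cross-tabs for high/low expression strata.

A first-class synthetic-data module (`synthio`) generates every input with
planted, recoverable structure, so the entire pipeline is testable without
access to restricted cohort data.

## Worked example

`examples/03_moderator_screen.py` simulates a 300-sample cohort in which
HSPA5 is planted as a moderator of the APP–MAPT dependence (correlation
0.9 in HSPA5-high samples vs 0.1 in HSPA5-low), builds both networks,
fuses them, and runs the screen:

```
modulator  mi_top  mi_bottom  delta_mi  p_value  p_adjusted  rank
    HSPA5  0.6517     0.0769    0.5748   0.0010      0.0022     1
    P0211  0.5987     0.0511    0.5475   0.0010      0.0022     2
    P0205  0.5698     0.0287    0.5410   0.0010      0.0022     3
    ...
    P0234  0.2155     0.3657    0.1502   0.3457      0.3457     9
```

The planted moderator ranks first: the anchors share 0.65 bits of mutual
information among samples with high HSPA5 but only 0.08 bits among
low-HSPA5 samples, and no permutation draw out of 1,000 reached the
observed ΔMI (p = 1/1001).  The other small-p rows are proteins from the
planted anchor neighborhood that co-express with the moderation signal;
the unrelated decoy (P0234) is correctly non-significant.

The remaining examples cover simulation (`01`), network building + module
recovery (`02`), cell-type scoring and composition (`04`), and the
histology interaction regressions (`05`); each prints the quantities it
computes and what they mean.

## Command line

A thin CLI wraps the library for shell use:

```bash
abtau-modnet simulate --outdir data --seed 0
abtau-modnet run --outdir results/run1          # full pipeline + manifest
abtau-modnet moderators --abundance data/abundance.tsv \
    --embedding results/run1/embedding.tsv --anchors APP MAPT --out mods.tsv
abtau-modnet query --embedding results/run1/embedding.tsv \
    --genes APP,MAPT,HSPA5 --pct 5 --out-prefix q
```

`run` writes a `manifest.json` with per-stage parameters and SHA-256
output hashes; reruns with the same seed are hash-identical, and
`--resume` recomputes only stages downstream of missing files.

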