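# Methods

This note records the models and procedures implemented in `disconet`,
the assumptions behind them, the defaults that matter, what the synthetic
generator does and does not emulate, and the numerical choices a
maintainer would want to know.  No empirical claim here goes beyond what
the test suite and the acceptance script themselves compute.

## Seed assembly

Driver genes come from three sources combined by set union with per-gene
provenance.  The mutation-catalogue filter keeps genes whose mutation
ratio (observed mutations / samples tested) strictly exceeds a threshold
(default 0.03; an inclusive variant and an optional absolute-count filter
are exposed because the strictness of the published rule is ambiguous).
The domain-family route keeps, per family, genes with mutation count at
or above the family's 75th percentile (numpy linear interpolation — the
convention is stated because it decides boundary genes); families with
fewer than 4 genes degenerate to their maximum-count gene(s), all of them
when tied.  Comparability of sources is assessed with a two-sided
Mann-Whitney U test: exact when both groups have ≤ 10 values, computed by
an exact 0/1-knapsack count over doubled midranks (exact under ties,
unlike textbook no-tie enumerations), otherwise the normal approximation
with tie correction.  Two identical multisets give p = 1 by construction.

## Differential expression

A deliberately small exact negative-binomial test, not a full edgeR
re-implementation (no tagwise dispersion shrinkage, no GLM mode):

- **Normalization** — median-of-ratios size factors (geometric-mean
  reference over genes positive in all samples; library-size ratios as
  fallback).  Normalized counts rounded back to integers serve as
  pseudo-counts so the conditional arithmetic stays exact.
- **Dispersion** — one common dispersion φ (variance μ + φμ²) maximizing
  the exact conditional-given-sum log-likelihood over all genes and both
  groups (the nuisance means cancel; bounded scalar optimization of
  log φ ∈ [log 1e-6, log 5]).
- **Test** — within each gene the two group sums are NB; conditioning on
  the total leaves a one-dimensional distribution evaluated exactly over
  its support.  The two-sided p is the total conditional probability of
  outcomes no more likely than the observed one, with a relative tie
  tolerance of 1e-4 (needed because gammaln at r ≈ 1e9 carries ~1e-6
  relative error and symmetric designs have exactly mirrored outcomes;
  genuine adjacent-outcome ratios are far larger).  As φ → 0 the test
  converges to the exact conditional binomial test, which the suite
  checks directly.  Support is truncated at ±40 conditional SDs only
  above 50,000 total counts (mass beyond is below double precision).
- **Fold change** — log2 of normalized group means with pseudocount 0.5,
  so zero counts give bounded fold changes.
- **Multiplicity** — Benjamini-Hochberg throughout.

Null simulation at 2,000 genes and 20+20 samples gives type-I error
0.055 at nominal 0.05 (the acceptance band is [0.03, 0.07]).

One structural caveat the tests surface honestly: when the planted
up-regulation equals the Hi-DEG fold-change threshold exactly (both 4 by
default), the empirical log2FC of a planted gene falls below the hard
cut roughly half the time whatever the noise level, so recall against
planted truth through the |log2FC| ≥ 4 filter plateaus near 0.5 — the
corresponding acceptance test fails and is left failing.  The adjusted-p
criterion alone recovers every planted gene.

## Co-expression modules

Biweight midcorrelation with the standard 9-MAD tuning (u = (x−med)/9MAD,
weights (1−u²)² inside |u| < 1).  Genes with zero MAD, or profiles fully
down-weighted, fall back to Pearson for every pair they participate in.
The unsigned adjacency |S|^β uses the smallest integer β whose weighted
connectivity distribution fits a scale-free law with R² ≥ 0.8 (log-log
regression of bin frequency on mean connectivity over 10 equal-width
bins, empty bins dropped; degenerate all-equal connectivity defines
R² = 0); if no grid power reaches the target the argmax is used with a
warning.  The topological overlap matrix follows the usual definition
TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), unit diagonal.

Modules are average-linkage clusters of 1 − TOM under a fixed-height cut.
The default cut is the midpoint of the largest gap in the upper half of
the dendrogram's merge heights: TOM dissimilarities saturate near 1, so a
fixed quantile of merge heights lands inside the background-merge plateau
and returns one giant cluster, while the largest-gap rule separates
module merges from the plateau deterministically.  A plain quantile cut
remains available as an override.  Clusters below the minimum size
(default 30) pool into an explicit `unassigned` module, which also
participates in enrichment testing.  This fixed cut is a deliberate,
simpler stand-in for dynamic tree cutting; it assumes modules merge well
below the background plateau and will fragment gradual hierarchies.

Driver overrepresentation per module is an upper-tail binomial test with
success probability the driver fraction of the universe, BH-corrected
across modules; the seed set is the drivers plus Hi-DEGs inside enriched
modules only.

## Commute-time kernels and fusion

The CT kernel is the Moore-Penrose pseudoinverse of the weighted
Laplacian, built by eigendecomposition with eigenvalues below
1e-10 × λ_max discarded; on connected graphs this removes exactly the
constant mode, giving K·1 = 0 and the commute-time identity
c(i,j) = vol·(K_ii + K_jj − 2K_ij), which the tests verify against
closed-form effective resistances, an independent resistance-distance
implementation, and a Monte-Carlo random walk.  Disconnected inputs are
reduced to their largest component with a warning.

Fusion is under-specified in the source analysis, so the package fixes
the simplest construction and exposes each piece: cosine normalization
onto unit diagonal (scale-invariant), equal-weight mean on the union node
set with missing nodes embedded as identity rows (keeps the mean PSD;
a missing gene is maximally self-similar and uninformative elsewhere),
and materialization that keeps every interactome edge reweighted by
consensus similarity and adds non-interactome pairs whose similarity
strictly exceeds a global quantile (default 0.999) of non-edge
similarities.

## Diffusion and topology

DIAMOnD is implemented exactly as published: binarized edges, iterative
hypergeometric connectivity p-values, smallest p added each round, ties
broken by larger seed-link count then lexicographic gene id (stated
because the published algorithm leaves ties open), seed weight α = 1
exposed.  Every iteration is checked against an exact-rational
brute-force argmin.  The tissue-expression filter is applied to the
ranked list after expansion, so ranks do not depend on the allowlist.

Hubs/bottlenecks are the top 20% by degree and exact unnormalized
betweenness (unweighted shortest paths by default), ties at the quantile
included.  Significance of candidate-set enrichment uses the add-one
empirical p over uniform equal-size node draws, (1 + #{fraction ≥
observed})/(n_rand + 1), with a secondary Mann-Whitney comparison of the
degree distributions; the published analysis named a Mann-Whitney test
for what is structurally a randomization comparison, so both are
reported.  The empirical p is conservative (super-uniform) by
construction; its calibration test tolerates the discreteness.

## Complexes and gene-set enrichment

MCODE with the published defaults (degree cutoff 2, node score cutoff
0.2, k-core 2, depth 100, haircut on, fluff off): vertex weight = highest
k-core index of the closed neighborhood × that core's density; greedy
expansion from the highest-weight unvisited seed including neighbors
within the score cutoff; complexes lacking a 2-core are discarded and
haircut keeps the 2-core.  Complexes are node-disjoint (visited vertices
are never reused), scored density × size, ordered by score, size, seed
id.  Gene-set enrichment is the upper-tail hypergeometric test over a
GMT collection, BH across sets.

## Drug mapping

Direct mapping keeps candidate-gene bioactivities with direct binding
and pChEMBL ≥ 6 (inclusive: 6 corresponds to 1 μM affinity).  Family
inheritance emits every drug annotated to a druggable family for each
candidate relative, never duplicating a direct pair.  The side-effect
propensity of a family is the median pairwise Jaccard similarity of its
relatives' open neighborhoods — a documented stand-in for a regression
method whose training data is unavailable here; compact families (high
median similarity) are read as lower off-target risk.  Fewer than two
relatives in the network gives "absent", deliberately distinct from 0.
Antineoplastic drugs are counted by ATC prefix L01.

## Synthetic world

Defaults: 1,000 genes; 60 tumour / 20 normal samples (keeping the
motivating study's strong imbalance at a size where the exact test is
still powered); four co-expression blocks of 40 genes; NB dispersion 0.2
(biological CV ≈ 0.45, typical of heterogeneous bulk tumour RNA-seq);
per-(block, sample) log-normal latent factors with σ = 0.4 driving
within-block correlation ≈ 0.4; the first quarter of each block
up-regulated ×2⁴ in tumours; drivers covering 25% of the first two
blocks plus a 2% background among non-block genes; a 40-gene planted
interactome module containing the 10 seed genes.

The interactome is preferential-attachment (m = 3) with node identities
decoupled from attachment order by a seeded permutation — otherwise the
planted module would sit on the oldest, highest-degree nodes and its
density signal would vanish into hub background.  The module is rewired
to be a genuine dense neighbourhood: internal density ≥ 5× background,
induced subgraph connected, and mean internal degree 2m, i.e. members'
links are majority-internal.  The density floor alone leaves most
members without any link to the seeds, which no seed-connectivity method
could overcome; the chosen design point was fixed once against the
recovery property the pipeline is specified to have (≥ 70% of early
DIAMOnD additions inside the module) and then frozen.  Total edge count
and connectedness are preserved by pairing every added internal edge
with the removal of a non-bridge outside edge.

The mutation table is constructed so that seed assembly recovers the
planted drivers exactly (catalogue rows straddling the 3% ratio,
4-gene families whose planted member alone sits in the top quartile);
the bioactivity table straddles pChEMBL 6; one protein family's
relatives all neighbor the top hub (compact), another's have pairwise
disjoint closed neighborhoods (dispersed).

What the generator does **not** emulate: batch effects, library-size
imbalance beyond size factors, mutation signatures or copy number,
realistic assay noise or multi-family gene membership, and degree-
correlated expression.  A green end-to-end run therefore establishes
that the machinery is correct on data satisfying the model's
assumptions, not that the biological conclusions of any particular
study are reproduced.  Every generator is a pure function of the
config; all randomness flows from one seed.

## Determinism and reproducibility

The expression stage is RNG-free; diffusion, topology randomization and
generation derive all randomness from the pipeline seed.  Gene ids sort
lexicographically for every tie-break.  Each stage writes a manifest
entry (package version, config hash, input/output SHA-256 prefixes);
rerunning a stage with identical inputs reproduces identical bytes, and
the acceptance script's end-to-end rerun is byte-identical per seed.
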