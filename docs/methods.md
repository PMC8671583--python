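# Methods

## Overview

`speciesdelim` treats species delimitation as three independent inferences
reconciled at the end: a geometric audit of published trait ranges, a
model-based search for phenotypic groups, and a model-based search for
genotypic groups. Nothing in the pipeline assumes the current taxonomy is
right; taxonomy enters only as one candidate model (scored on the same
likelihood surface as the unsupervised fits) and as the reference partition
for correspondence counts.

## Hypercube audit

A species description's per-trait min/max ranges define a closed
axis-aligned hyperrectangle. For boxes *A*, *B* over the same trait set,

    overlap(A, B) = vol(A ∩ B) / vol(A)
                  = ∏_t  len(A_t ∩ B_t) / len(A_t),

computed exactly; the measure is asymmetric by design (a small box nested
in a large one overlaps it completely, not conversely). Containment uses
closed intervals, since published ranges are reported inclusively.

Numerical/degenerate choices:

* a zero-width interval in the denominator box contributes factor 1 when
  the other box covers the point and 0 otherwise, and is excluded from the
  denominator volume — no arbitrary epsilon;
* a box degenerate in *every* dimension is rejected;
* specimens with any missing trait are excluded from matching-prediction
  and reported separately (they cannot be scored against a box);
* geometry is computed on the raw measurement scale as tabulated in range
  files. Containment verdicts are invariant under any strictly increasing
  per-trait transform (tested with log); overlap *proportions* are
  scale-dependent and documented as such.

## Phenogroup delimitation

**Model.** Within a species, continuous traits are assumed multivariate
log-normal — Gaussian on the log scale — so a clade is a finite mixture of
Gaussians and each component is a candidate phenogroup. Specimens with
missing traits are excluded from the mixture stage (complete-case) and
surface later as "unknown specimens".

**Robust rotation.** Projection-pursuit PCA: directions maximise the
normal-consistent median absolute deviation (MAD) of the projections, each
orthogonal to its predecessors, with candidates restricted to the
median-centred data directions. The restriction is deliberate: a
continuous optimiser chases the sampling noise of the MAD objective
(observed ~10° error against the population eigenvector at n = 500, versus
~3° for data-direction candidates), while gross outliers can nominate
themselves as candidates but cannot inflate the MAD score.

**Variable selection.** Greedy forward selection over score axes. Axis *j*
given selected set *S* is scored by

    evidence(j | S) = BIC_clust(S ∪ {j}) − BIC_clust(S) − BIC_single(j),

with BIC_clust the best K ≥ 2 mixture over the family grid (0 for the
empty set) and BIC_single the best one-component Gaussian on the axis
alone — "does axis *j* add clustering signal beyond *S* plus unstructured
noise?" Selection stops when no axis has positive evidence; if none ever
does, the single best axis is returned with a warning rather than an empty
set.

**Mixture fitting.** EM with six covariance families
(spherical/diagonal/full × shared/varying across components), k-means++
hard starts, up to 5 restarts on empty components, convergence at relative
log-likelihood change < 1e-8 (max 1000 iterations; the per-iteration trace
is retained and is non-decreasing by construction). Degenerate components
are kept positive-definite by clipping covariance eigenvalues at
1e-6 × mean trait variance. Criteria, on the larger-is-better scale:

    BIC = 2·logL − k·log N
    ICL = BIC − 2·Σ_i Σ_k (−z_ik log z_ik)   (so ICL ≤ BIC,
                                              equality at hard assignments)

**Model comparison.** The *Naive* model sweeps K = 1..⌈n + n/2⌉ (n =
taxonomic species hypothesised for the clade; the ceiling resolves the
non-integral bound at odd n) across all families. A-priori models
(taxonomy; groups delimited by eye) are scored by one M-step from the
fixed labels — per-group MLE parameters, mixing proportions equal to group
frequencies — with the log-likelihood evaluated as the observed-data
*mixture* likelihood at those parameters, so labelled and unsupervised
models are compared on one surface; a switch selects the classification
likelihood instead for users who want the stricter reading. Singleton
groups trigger variance-floor regularisation with a warning. Rankings
report ΔBIC to the best model; exact ties share a (dense) rank.

## Genogroup delimitation (genotypic clusters)

**Distance.** For diploid dosages a, b ∈ {0,1,2} at one locus, the
shared-allele proportion under optimal pairing is ps = 1 − |a − b| / 2
(heterozygote–heterozygote sharing is 1: both alleles are matchable).
D = 1 − mean(ps) over pairwise-complete loci (pairwise deletion; per-pair
locus counts are reported so unstable pairs are visible). A pair sharing
no non-missing locus is an error, not a guess.

**Ordination.** Non-metric MDS minimising Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

with disparities d̂ from isotonic regression of the configuration distances
on the input-distance order (primary tie handling: ties sorted by current
configuration distance). Initialisation from classical metric scaling plus
3 random restarts; Guttman-transform updates; convergence at relative
stress change < 1e-6 or 500 iterations. Two dimensions are retained by
default with a warning when stress ≥ 0.15 (the embedding-acceptance rule);
the implementation warns rather than silently increasing dimensions.
Because stress-1 is scale-invariant, disparities are renormalised at every
iteration — without this the configuration can collapse toward the origin
with no visible change in stress (observed in testing as machine-scale
embeddings).

**Clustering.** The same mixture sweep as the phenotype side, on the
embedding coordinates; best-by-BIC components are the genogroups. External
delimitations (tree-based or coalescent-based tools) are imported as
assignment tables only, and their marginal likelihoods ranked as below.

## Bayes-factor ranking

BF = 2·(log ML_best − log ML_other) on the natural-log scale, with the
Kass–Raftery reading (≤ 2 bare mention, 2–6 positive, 6–10 strong, > 10
decisive). Marginal likelihoods are always consumed as numbers from files
(external path-sampling runs) or, when internal mixture fits are ranked,
BIC is used and labelled as a BIC approximation — the package never claims
to compute a marginal likelihood. Printed tables elsewhere round their
columns independently, so BFs recomputed from rounded inputs can differ in
the last digit; the implementation computes from full-precision inputs.

## Integration

Crossing phenogroup and genogroup assignments yields a contingency table;
specimens with only one kind of data land in the margins as unknown
specimens. Occupied cells are typed purely by row/column occupancy: good
(1, 1), phenotypic cryptic (row > 1, column 1), genetic cryptic (row 1,
column > 1). The pattern where both the row and the column are multiply
occupied is not covered by the three-way typology, so it carries an
explicit fourth label, `complex`, rather than a silently forced type.
Perfect matches (taxon vs group with identical specimen sets) are counted
on the specimens present in both partitions — specimens absent from one
system can neither witness nor break a bijection. Percentages are rounded
to integers in report headers; machine outputs keep full precision. An
optional k-nearest-neighbour step proposes provisional assignments for
unknown specimens from great-circle-nearest dually-assigned neighbours;
its output is flagged provisional and never mixed into primary counts.

## Synthetic clades

The generator emulates the structure the analyses assume, with ground
truth retained:

* **Traits** — per-phenogroup multivariate Gaussians on the log scale,
  exponentiated on output (measurement files are raw-scale);
* **Genotypes** — two models. Default `island`: Balding–Nichols, ancestral
  frequency per locus ~ U(0.05, 0.95), deme frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) with Fst-like F (scalar, or one per deme),
  genotypes Binomial(2, p) under within-deme Hardy–Weinberg. Alternative
  `spatial`: isolation-by-distance on a latent plane — demes on the unit
  circle, specimen positions jittered around their deme centre
  (sd 0.09 by default), per-locus 2-D logit-frequency clines (slope
  sd 1.2). The island model with many demes is mutually equidistant in
  expectation and therefore has no faithful 2-D ordination; the spatial
  model produces the low-stress two-dimensional structure that
  geographically structured clades show, and is what the scripted
  integration scenario uses;
* **Taxonomy and noise** — true species labels, with `label_noise`
  relabelling a fraction uniformly among the clade's other species;
* **Range boxes** — per-species quantile ranges from a stratified
  "described" subsample (≥ 2 complete specimens per species), so held-out
  specimens can legitimately fall outside;
* **Geography** — per-species centres with isotropic scatter in decimal
  degrees plus elevation;
* **Missingness** — missing completely at random throughout, with rates
  up to the 25/50/75% regimes used in sensitivity checks.

Defaults mirror mid-sized clades: 2–10 species, tens of specimens per
species (clade totals in the tens to low hundreds), hundreds to a few
thousand SNP loci, divergence 0.2–0.5.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: linkage disequilibrium between loci,
coalescent genealogical noise, selection or admixture, non-Gaussian trait
families (allometry is only captured insofar as log-normality absorbs it),
and informative missingness (real incompleteness is sterile-specimen
biased, not MCAR).

### The scripted cryptic scenario

Seven species (30 specimens each, N = 210) map onto six phenogroups (two
species pooled) and six genogroups (two species pooled), so the true table
holds three good cells, one phenotypic-cryptic complex (two cells) and one
genetic-cryptic complex (two cells). The scenario is *defined* to be
exactly recoverable, which pins several of its numbers:

* group mean differences are **low-rank** — the six phenogroup means sit
  on a hexagon in the plane of the first two log-traits, adjacent groups
  8 within-group standard deviations apart (per-pair Bayes error
  ≈ Φ(−4) ≈ 3×10⁻⁵), the remaining eight traits carrying no group signal.
  Low-rank group structure is the morphologically realistic case, and it
  is also what keeps forward selection honest: when every rotated axis
  carries a sliver of signal, selection correctly retains most axes, and
  at these sample sizes BIC then prefers core/shell splits of true
  Gaussian clusters in the high-dimensional score space;
* N = 210 rather than 140: the log N penalty at the smaller size still
  allowed a one-component oversplit on the selected axes by ~10 BIC units;
* genotypes use the **spatial** model (1200 loci, within-deme latent sd
  0.12), embedding the six demes at stress ≈ 0.06 with ≥ 8σ blob
  separation; a symmetric island model with six demes is mutually
  equidistant and cannot embed in two dimensions (stress ~0.20, above the
  retention threshold), and very tight blobs re-introduce the
  near-equidistance that makes NMDS invent ring-shaped substructure.

## Problem sizes

Tests and the acceptance script run at desk scale: recovery suites use 20
seeded replicates of n = 300 trait mixtures and 80-specimen × 1000-locus
SNP panels; the end-to-end scenario is 210 specimens × 10 traits × 1200
loci; Monte-Carlo oracles use 10⁵ points per box pair. These sizes give
the oracles sampling error comfortably below the tolerances they check.

## Known limitations

* The a-priori likelihood convention (mixture vs classification) changes
  ΔBIC values; the default is documented above and switchable.
* NMDS at six or more near-equidistant groups is intrinsically distorted
  in two dimensions; the stress warning fires, but delimitation quality
  degrades with cluster count — a limitation of the two-dimensional
  genotypic-clusters chain itself, not of this implementation (an
  independent SMACOF implementation plateaus at the same stress).
* BIC-based component selection on ordination coordinates can oversplit
  when embedded clusters are non-Gaussian (e.g. near-equidistant points
  embed as rings); the candidate table is retained on every sweep so users
  can inspect the margin.
* Robust PCA directions are limited to the data-direction candidate set;
  with very few specimens the first loading is correspondingly coarse.
* The forward-selection evidence is greedy; axes informative only jointly
  can be missed.
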