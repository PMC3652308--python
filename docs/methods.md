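# Methods

`leukosplice` re-implements, as a tested and reusable pipeline, an
integrative analysis of blood-leukocyte transcriptomes in Parkinson's
disease (PD) and deep-brain-stimulation (DBS) treatment: miRNA expression
from small-RNA sequencing, alternative splicing (AS) from splice-junction
and exon probe-set arrays, gene-set enrichment, cellular-lineage
composition, and miRNA–spliced-target networks.  Because the original
study's datasets live in public repositories and are not required here,
every stage is exercised end-to-end on synthetic data with planted ground
truth.  This note records the models, the tunable parameters, the
numerical choices, and what the synthetic conditions do and do not show.

## Study design

Four sampling states are fixed throughout: healthy controls (HC),
patients before surgery (PD), and patients after surgery on and off
electrical stimulation (DBS_ON, DBS_OFF).  Three contrasts are tested:
HC-vs-PD (disease), PD-vs-DBS_ON (treatment), and DBS_ON-vs-DBS_OFF
(stimulation cessation).  The sequencing arm defaults to 3 libraries per
state (12 total); the array arm simulates 6 samples per state for
HC/PD/DBS_ON.  All contrasts are signed second-condition-over-first.

## Small-RNA quantification

Reads are 50-base, base-space.  Trimming order: (1) drop the last 15
bases (the synthetic tag end); (2) locate and excise the 5' and 3'
adapter fragments; (3) drop the 5' terminal nucleotide; (4) discard reads
shorter than 16 bases (i.e. keep length > 15).

Adapter location uses *end-anchored overlap alignment*: the 5' adapter
contributes a suffix aligned to the read prefix, the 3' adapter a prefix
aligned to the read suffix, scored with the `TrimParams` match/mismatch
weights (defaults +1/−1, minimum overlap score 6; exact 3' fragments are
accepted from 3 bases because they are anchored to the read end).  Gap
moves are not explored: adapter fragments are terminal by construction, and
an unanchored local scan would mis-clip roughly 1 read in 10⁴ on spurious
interior 6-mers — enough to break exact count accounting at realistic
depths.  The default synthetic adapters are *border-free* (the 3'
adapter's first base and the 5' adapter's last base occur nowhere else in
their sequence), so no adapter prefix/suffix matches a shifted copy of
itself and trimming is deterministic.

Matching against the mature-miRNA reference tolerates isomiRs: up to
`iso_extend` = 2 read bases overhanging either reference end, up to
`iso_trim` = 2 uncovered reference bases at either end, and up to 3
substitutions in the overlap.  One further missing 5' reference base is
exempted from this budget (`five_prime_clip` = 1): the protocol removes
every read's 5' terminal nucleotide deterministically, and that known
clip should not consume the isomiR allowance.  Each read receives one
best assignment — ties broken by (fewest mismatches, smallest end shift,
lexicographic mature id, then precursor id) — because integer counts feed
the downstream exact test.  Candidate references come from a 5-mer index
(pigeonhole over at most 3 substitutions) with an exact-truncation
dictionary fast path.  Unmapped reads can be re-aligned against a filter
reference (snoRNA/tRNA/repeat stand-ins) with the same matcher.

Counts are produced per precursor and merged per mature sequence
(precursor families sharing one mature sum into one row; column totals
are conserved).  Features are kept when CPM ≥ 1 in ≥ 3 libraries.

## Differential expression

Counts are modelled negative-binomial, Var = μ + φμ², with a common
dispersion φ.  TMM normalisation factors (doubly trimmed log-ratio mean
against a reference library, 30 % by M and 5 % by A, rescaled to product
1) multiply the library sizes; all libraries are then linearly scaled to
the geometric-mean effective size ("pseudo-counts") so that group sums
are conditionable: the sum of n iid NB(μ, φ) variables is NB(nμ, φ/n).

* **Common dispersion** maximises the summed conditional NB
  log-likelihood (conditioning each group's split on its total) over
  φ ∈ [0, 10] by golden-section search, tolerance 1e-6.
* **Tagwise dispersion** maximises ℓ_g(φ) + prior_df · ℓ̄(φ), where ℓ̄ is
  the across-feature mean conditional log-likelihood; prior_df (default
  10) controls shrinkage toward the common value, recovering it exactly
  as prior_df → ∞.  The implementation is O(G²) and intended for
  matrices of moderate size; the pipeline itself tests at the common
  dispersion.
* **Exact test**: per feature, the group-1 sum conditional on the
  two-group total follows a negative-hypergeometric law with weights
  ∝ C(k+r₁−1, k)·C(s−k+r₂−1, s−k), r_i = n_i/φ.  The two-sided p doubles
  the smaller tail (capped at 1).  Below φ = 1e-10 the binomial (Poisson)
  limit Bin(s, n₁/(n₁+n₂)) is used directly; the enumeration and the
  limit agree to machine precision.  Fold changes are displayed from
  normalised group means with a 0.5 pseudo-count; testing never uses the
  offset.  No multiple-testing correction is applied to these p-values —
  calling is gated on the posterior odds below.
* **B statistic**: on log-CPM values, each feature's two-group mean
  difference gets a moderated variance (scaled inverse-χ² prior fitted by
  matching the marginal moments of the log residual variances; the
  trigamma inversion uses Newton's method).  The log posterior odds of
  differential expression is
  B = log(π₁/π₀) − ½·log r + log t_d(t̃/√r) − log t_d(t̃), with prior
  non-DE proportion π₀ = 0.9 and variance-inflation r = (v+v₀)/v
  estimated by method of moments from the mean squared moderated t,
  floored at 1.  Under a global null the moment estimate collapses to
  r = 1 and B is the constant logit(0.1) ≈ −2.20 for every feature, so
  the B ≥ 1 gate is exactly silent — no tuning involved.  Features are
  called at B ≥ 1.

Measured behaviour under the synthetic conditions (n = 3+3, φ = 0.1,
mean 200): null rejection at p < 0.05 runs at ≈ 4–5 %, planted
|log2FC| = 2 features are recovered with recall ≈ 0.97 and empirical
FDR ≈ 0.04 at B ≥ 1.

## Splicing detection

Probe sets carry one of four roles.  Gene-level expression is the
arithmetic mean of the gene's constitutive probe-set log2 intensities.

**Reciprocal-junction regression.**  For each inclusion/exclusion pair
(I, E), gene-normalised values nI = x_I − g and nE = x_E − g are formed;
a baseline-group regression of nI on nE defines per-sample deviations
d_s = nI_s − (a + b·nE_s), and the event score is the group-2 minus
group-1 mean deviation.  Numerical choice: under the no-event baseline
the population slope is the variance ratio Var(g-noise)/(Var(g-noise) +
Var(ε_E)) ∈ [0, 1), so the small-sample OLS slope is clamped to [0, 1];
the raw estimate is heavy-tailed at n = 6 (noisy variance denominator)
and without clamping deviation scores occasionally collapse on true
events.  A degenerate baseline (zero variance in nE) falls back to unit
slope, d = nI − nE.  An event is called when |score| ≥ log2(2) = 1, a
two-sided Welch t-test on d gives p < 0.05, **and** the raw group-mean
changes of I and E are opposite in sign — the bi-directional
(reciprocity) gate that rejects co-directional expression artifacts.
PSR-vs-exclusion pairs run through the same scorer with the PSR in the
inclusion role.

**Splicing index.**  Per exon/PSR probe set, SI = x_p − g; an event is
called when |ΔSI| between groups ≥ 1 log2 unit with Welch p < 0.05.
Gene-wide expression shifts cancel exactly in both detectors.

**Classification.**  Samples restricted to called features are clustered
agglomeratively with city-block (L1) distance and average linkage (the
linkage is a package choice; the distance is the study's).  The
two-cluster cut is compared against known labels by the best label
assignment; features are processed in sorted order so results are
invariant to input ordering.  Dendrograms export as Newick.

Note on symmetry: with the baseline-group fit, swapping the contrast
negates every score exactly in the noiseless case and up to slope
re-estimation noise otherwise.

## Enrichment (ORA)

For universe N, set size R, changed count n and overlap r:
z = (r − nR/N) / sqrt(n·(R/N)(1−R/N)(1−(n−1)/(N−1))) — the
hypergeometric-moment standardisation (z = 0 when the variance is 0).
Permutation p-values resample the changed list from the universe (2000
permutations, add-one estimator); one shared null ensemble serves all
sets.  A set is reported when z ≥ 1.96 and it holds ≥ 3 changed genes,
ranked by (z, r, name).  Benjamini–Hochberg q-values on the permutation
p are reported alongside but never gate — the published gates are the z
cutoff and the gene count.  Flat gene sets (GMT) are used; ontology-DAG
pruning is out of scope.

## Lineage scoring

Markers are selected per lineage by Pearson correlation of each gene's
compendium profile with the lineage's binary column indicator (top 50–150
genes, ties by name); centroids are mean profiles over the lineage's
columns restricted to the marker union.  Samples are scored by Pearson
correlation with each centroid over shared markers (≥ 50 % of the union
must be present; lineages with < 3 shared markers are undefined), and
correlations are Z-standardised *within each sample across lineages*
(unbiased sd; degenerate sd gives z = 0), so rows sum to zero and the
dominant lineage stands out per sample.  Pearson correlation makes the
scores invariant to per-sample affine transforms.

## Networks

An edge (miRNA m, gene g) requires all three gates: m called in the
contrast's DE table, g carrying ≥ 1 called splice event in the same
contrast, and (m, g) present in the target-prediction table.
Multi-region predictions collapse to a single edge holding a region set;
region fractions are reported over edge-region incidences, and both the
edge count and the incidence count appear in summaries (a "connection"
tally can be read either way).  The seed is miRNA positions 2–8 (strict
7-mer, configurable); its DNA reverse complement (U→A pairing) is scanned
exactly against the *called* junction probe sequences of the edge's gene
to set `seed_verified`.  Exports: SIF and GraphML with canonical
attribute ordering (export → import → export is byte-identical).

## Synthetic data: what it emulates, and what it does not

* Reads: adapter-flanked inserts sampled from a synthetic miRBase-like
  reference (18–25 nt matures, passenger strands, two-precursor shared
  matures), NB counts with dispersion φ = 0.1 (typical for biological
  replicates) and planted per-contrast fold changes; isomiR end variation
  (±2 bases, probability 0.15) and 1–3 substitutions (probability 0.05).
  Constant Q30 qualities; no ligation bias, no colorspace, no realistic
  error profiles.  The 35-base core is laid out so the 3' adapter
  fragment is never 1–2 bases (the boundary shifts into the 5' fragment),
  keeping trimming exact.
* Probe matrices: per gene two constitutive probe sets, one reciprocal
  junction pair, one exon/PSR probe set; planted events move inclusion
  and exclusion by ±effect (default 1.5 log2) in the contrast's second
  condition; Gaussian noise (default sd 0.2 log2).  Probe-level
  summarisation, cross-hybridisation and batch effects are not modelled.
* Target tables: (5'UTR, CDS, 3'UTR) sampled from the simplex
  (0.19, 0.38, 0.43), matching the observed regional split of predicted
  sites in the disease network.
* Lineage compendia: block-structured marker elevation (shift 3 log2,
  noise 0.5); mixtures with recorded dominant labels.
* An independent two-label matrix (24/23 samples, effect d = 2) stands in
  for external-cohort classification.

Passing tests on these conditions demonstrates correctness of the
algorithms and calibration under the stated noise model; they do not
demonstrate robustness to real-data pathologies (adapter sequencing
errors, probe saturation, cell-composition confounding, batch structure).

## Problem sizes

Default test and verification sizes are chosen to exercise each property
at desk scale: 2000 null features × 20 seeds for type-I error, 1000
features × 10 seeds for DE recovery, ~10⁵ reads for quantification, 500
genes/50 events for splice recovery, 200 mixture samples for lineage
scoring, and a 47-sample matrix for classification.  The demo bundle
(`leukosplice demo`) runs the full pipeline in a few seconds.

## Known limitations

* Only two-group contrasts (no GLM designs, no batch correction).
* The tagwise-dispersion estimator is quadratic in feature count.
* The B statistic's moment estimator assumes a mostly-null feature set;
  with very high DE fractions r would be inflated and calls conservative.
* Junction regression assumes exactly paired reciprocal probe sets; probe
  families with more complex connectivity are scored pairwise.
* Seed verification is exact Watson–Crick 7-mer matching — no wobble
  pairing, no context or free-energy scoring.
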