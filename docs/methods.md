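# Methods

`ontodyn` analyzes bulk RNA-seq expression over a developmental age
series.  The reference design is twelve ages (days −2, 0, 1, 3, 5, 10,
15, 20, 25, 30, 45, 60 relative to birth) with three replicates per
age, and all statistics operate on FPKM tables — no read-level data is
touched.  This note records the models, the tunable parameters, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Analysis-gene selection

Genes enter the analysis set through a two-stage filter:

1. **Absolute expression.** A gene is called expressed at an age when at
   least `min_replicates` (default 2 of 3) replicate FPKM values reach
   `theta_fpkm` (default 1 FPKM).  A gene must be expressed at ≥ 1 age.
2. **Differential expression over age.** One-way ANOVA on
   log2(FPKM + 1) across the age groups, Benjamini–Hochberg adjusted
   over all tested features, selecting q ≤ α (default 0.05).

The pseudocount of 1 at FPKM scale is the conventional variance
stabilizer; it compresses sub-FPKM signal, which is intentional — such
genes fail stage 1 anyway.  Features with zero within-age variance
everywhere get p = 0 when their age means differ and p = 1 when flat,
so constant rows can never appear differential through a degenerate F.

## Gene expression rank (GER)

Per gene, the ages are ranked 1..12 by replicate-mean expression, ties
averaged, so every gene's rank vector sums to 78.  Ranks are computed
on per-age replicate means by default; a per-replicate variant (rank
the 36 samples, average within age, rescale to the 1..12 scale) is
available since the choice between the two is not dictated by anything
in the data model.

## Temporal factor model and the six groups

The gene × age matrix of standardized (zero-mean, unit-SD, ddof = 1)
log2 age-mean series is reduced to its age × age correlation matrix.

* **Number of factors.** Horn's parallel analysis: observed eigenvalues
  are compared rank-by-rank with the 0.95 quantile (configurable) of
  eigenvalues from `n_sim` (default 200) same-shaped standard-normal
  matrices; k is the leading run of exceedances.  The scree
  (eigenvalue) vector is returned for manual inspection.
* **Extraction.** Iterative principal-axis factoring: communalities
  start at squared multiple correlations (via pseudo-inverse, so an
  exactly singular correlation matrix — the zero-noise limit — is
  handled), and are re-estimated from the leading eigenpairs of the
  reduced matrix until the largest change drops below 1e-9 (up to 2000
  iterations; exceeding them raises an error carrying the iteration
  count).  PAF is preferred over maximum likelihood because the
  "sample" here is only twelve observed variables.
* **Rotation.** Varimax.  Communalities are invariant under the
  orthogonal rotation (asserted in tests to 1e-9).
* **Canonical orientation.** Sign and order of rotated columns are
  arbitrary, so they are fixed deterministically.  For k = 3 the
  early/mid/late identity is anchored to the profile extremes: the
  (column, sign) candidate loading highest at the first age is the
  oriented early factor, the candidate highest at the last age (from
  the remaining columns) the late factor, and the leftover column is
  oriented so its interior maximum is positive (mid programme).  A
  single-peak-age rule was tried first and proved fragile when factors
  cross-load, because per-age standardization rescales the lobes of a
  loading profile; the extremes are far more stable anchors.
* **Assignment.** Each gene's standardized age-mean series is
  correlated with each oriented loading profile; the gene joins the
  argmax-|r| factor iff |r| ≥ 0.7, and the sign of r splits expression
  (+) from suppression (−).  For k = 3, (factor, sign) maps onto the
  six temporal groups: early+ → "Prenatal and Neonatal", early− →
  "Adolescent and Adult", mid+ → "Neonatal and Adolescent", mid− →
  "Prenatal and Adult", late+ → "Adult", late− → "Neonatal".
  Zero-variance series are flagged and left unassigned.  Correlation
  uses the 12 age means, not the 36 samples, because loadings are
  defined per age.

## Enrichment and overlap statistics

* **Right-tailed Fisher / hypergeometric.** The right tail of Fisher's
  exact test on a 2×2 membership table equals the hypergeometric upper
  tail P(X ≥ k); the tail is accumulated from log-pmf terms via
  log-sum-exp so that extreme overlaps (p ~ 1e-5 and far below) are
  stable.  Association significance uses p ≤ 0.05.
* **Group overlap tables.** Per-period regulator sets are compared
  pairwise with the same upper tail over the regulator universe
  (defaults to the supplied regulator list).
* **Chi-square independence** (molecule type × age/group tables)
  requires every expected count ≥ 1 and otherwise directs the caller
  to an exact alternative.
* **Activation z-score.** For a regulator with N targets of known
  expected direction, z = Σ s_i / √N with s_i = ±1 for agreement/
  disagreement between the observed per-age direction of change and
  the network's expected direction; |z| ≥ 2 is flagged.  The observed
  direction at an age is the sign of the gene's log2 expression
  relative to its own across-age mean.  The score is unweighted; the
  knowledge bases that ship edge-confidence weights are proprietary,
  so a weighted variant is left to the caller's network directions.

## Upstream regulatory modules

Regulator agreement is measured by an intraclass correlation after
each regulator's series is standardized (the anchor-point adjustment):
with m series over n ages, ICC = (MSB − MSE) / (MSB + (m − 1)·MSE),
where MSB is the between-age mean square of the per-age means
(df n − 1) and MSE the residual mean square (df (n − 1)(m − 1)).
Because the rows are standardized, the denominator equals m exactly,
so the statistic is always defined; it is clipped to [−1, 1].  For
m = 2 it reduces algebraically to the Pearson correlation of the two
standardized series, identical series give +1, and exactly opposite
series give −1 — anti-correlated modules are therefore detected with
negative ICC rather than being scored as disagreement.

Discovery is iterative: singleton entries (regulator, its targets
intersected with the temporal group) seed the list; cycle 1 forms all
pairs; each later cycle attempts merges of all pairs involving an
entry added in the previous cycle; a merge (union of regulators,
intersection of targets) is kept when |ICC| ≥ 0.6 and the shared
target set keeps ≥ 5 genes.  Entries are de-duplicated by regulator
set and the loop stops when a cycle adds nothing.  Intersection is
used for the merged target set because a module's targets should be
co-regulated by every member.  The ≥ 5-target constraint is enforced
at every merge by default; a flag relaxes it to pair-formation only,
since reasonable readings of the procedure differ on whether the
constraint binds after the first cycle.  On fixtures small enough to
enumerate, the emitted module sets equal an exhaustive search over all
regulator subsets satisfying both constraints (tested), and an
independent validator re-checks every emitted module post hoc.

## Isoform-level analyses

* **Variant usage.** For a gene with ≥ 2 known transcripts, the
  transcript × age table of mean FPKM is tested for homogeneity of
  column proportions with a Pearson chi-square; all-zero rows and
  columns are dropped first, and a gene that collapses to one
  expressed variant returns p = 1 (no usage signal).  FPKM values are
  not counts, so the p-value is a screening index, not a calibrated
  test; standardized residuals are returned for a per-age report.
* **Durbin–Watson filter.** For a per-age mean series, residuals are
  deviations from the series mean (no regression model is posited) and
  d = Σ(Δe)² / Σe² ∈ [0, 4], ≈ 2 for white noise, < 2 under positive
  autocorrelation.  Significance is a one-sided permutation test of
  the age order: p = (1 + #{permuted d ≤ observed}) / (n_perm + 1)
  with n_perm ≥ 999, since the classical regression-based DW bounds do
  not apply to a 12-point mean-centered series.  The novel-isoform
  filter keeps candidates expressed in ≥ 1 age, then BH-adjusts the DW
  p-values across those stage-1 survivors only and keeps q ≤ 0.05.
  Power is limited for non-monotone (U-shaped) temporal profiles at
  series length 12 — a fraction of genuinely smooth series lands just
  above the cutoff — while the false-positive proportion on
  exchangeable noise stays at the nominal level (tested on 2,000-series
  null simulations).
* **Splice events.** All coordinates are 0-based half-open; GTF input
  is converted at the boundary.  A novel transcript is compared with
  the reference sharing the most splice junctions.  Rules: a novel
  intron covering a complete internal reference exon → exon skip; a
  novel exon covering a complete reference intron → intron retention;
  an internal novel exon overlapping no reference exon → alternative
  exon; differing transcription start / termination boundaries (read
  in transcription direction, strand-aware) → alternative start /
  termination.  Events may co-occur; a transcript with no usable
  reference is "unclassified".

## Synthetic data

The generator produces every input with known truth so the whole
pipeline is testable without external data.

* **Expression.** FPKM(g, a, r) = 2^(baseline_g + amplitude_g ·
  shape_g(a) + ε), ε ~ N(0, noise_sd).  Defaults: baselines
  N(6, 1.5²) log2 units, amplitudes U(1.5, 3), noise_sd 0.3 (which
  puts replicate-to-replicate correlations in the mid-0.9s, matching
  what well-replicated liver series report), a 10% null fraction with
  amplitude 0.
* **Archetypes.** The six temporal groups are ± of three orthogonal
  base profiles (zero mean, unit SD over the twelve ages), shipped as
  configuration in `data/archetypes.yaml`.  The bases were constructed
  once by sketching qualitative early/mid/late curves (early maximal
  at day −2 and low after day 5; mid peaked around days 3–15; late
  rising after day 20), orthogonalizing them, and rotating the basis
  to its varimax-optimal orientation — so the generating basis is a
  fixed point of the rotation the clustering applies, and recovery
  failures indicate real pipeline defects rather than rotation
  indeterminacy.
* **Networks.** Planted modules give each member regulator the
  module's archetype shape at low noise (amplitude 2.5, noise 0.1);
  anti-correlated modules alternate member signs so the per-age mean
  cancels and the ICC is driven negative.  Decoy regulators get
  white-noise series and random edges that never collide with planted
  ones.
* **Isoforms.** Autocorrelated series follow a random archetype at
  noise 0.15; white-noise series are i.i.d. across all samples, hence
  exchangeable over age order — exactly the permutation null of the DW
  test.
* **Events.** Each requested splice event edits a reference exon chain
  by exactly that event, and the classifier run on the result must
  return it (closed-loop tested for all five types on both strands).

All generators are deterministic given a seed; one seed drives
everything through NumPy's seeded `default_rng`.

What the synthetic benchmark does **not** show: real FPKM tables have
gene-length and library-size artifacts, dispersion that varies with
abundance, correlated genes outside the planted structure, and
annotation errors.  Passing the recovery suite demonstrates that the
algorithms are implemented correctly and are recoverable under their
own assumptions, not that the biological conclusions of any particular
dataset would replicate.

## Problem sizes used in validation

The recovery suite uses 600 genes × 5 seeds for clustering (noise SD
0.3, uniform archetype mix), 2,000 features × 3 seeds for the null
error-control checks, 999 permutations for DW significance, and ≤ 6
regulators for the exhaustive module-enumeration cross-checks.  These
sizes give binomial Monte-Carlo standard errors below 0.5 percentage
points on the reported proportions while the full suite runs in a few
seconds.

## Known limitations

* The per-age significance procedure of the original expression screen
  is reconstructed (threshold + ANOVA + BH), so absolute gene counts
  from any specific study are not reproducible and are not targeted.
* The factor-count selection assumes approximately continuous,
  complete data; missing values are rejected at I/O.
* The activation z-score treats targets as independent; correlated
  targets inflate |z|.
* Variant-usage chi-square on FPKM shares is a screen, not a count
  model.
* The splice-event rules classify against a single best reference;
  events spanning multiple references (e.g. fused genes) are out of
  scope.
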