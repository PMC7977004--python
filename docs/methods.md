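# Methods

This note documents the models, rules and numerical choices the package
implements, the design decisions taken where the published description left
the design open, and what the synthetic-data tests do and do not establish.

## Genomic-scar scoring (HRD = LOH + TAI + LST)

Input is a table of allele-specific copy-number segments (1-based, inclusive
coordinates; `major_cn >= minor_cn >= 0`), plus a chromosome annotation with
lengths and centromere intervals (hg19 bundled).  Sex chromosomes are
excluded by default.  The three components:

* **LOH** — maximal runs of adjacent segments with `minor_cn == 0` and total
  copy number > 0 are merged; a region counts if its span is strictly
  greater than 15 Mb and it does not span the whole chromosome (defined as
  covering the full extent of that chromosome's segments).  Homozygous
  deletions (total 0) are not LOH.
* **TAI** — after merging adjacent equal-state segments, a region counts if
  its parental copy numbers differ, it reaches a chromosome end (first base
  or annotated length), does not overlap the centromere interval, and does
  not span the whole chromosome.  No minimum size by default (configurable).
* **LST** — computed per chromosome arm (the centromere interval belongs to
  neither arm, so breakpoints across it never count).  Adjacent equal-state
  segments are merged first, making the count invariant to how a
  segmentation happens to be split; segments shorter than 3 Mb are then
  removed; remaining equal-state neighbours are merged again (merged lengths
  are spans, so smoothed-out bases still count); every boundary between
  consecutive remaining segments that are each at least 10 Mb long counts
  as one transition.

"Adjacent" throughout means the next segment starts exactly one base after
the previous ends; uncovered gaps break runs.  A score of 42 or more flags
HRD-high.  Only the 42 threshold is printed in the source publication; the
size rules (15 / 10 / 3 Mb) follow the established scar-score lineage and
are all configurable through `ScarConfig`.  `ScarConfig.scaled()` applies
the same rule structure at any length scale; the synthetic mini-genome uses
the 1/1000 (kb) scale.

All three counts are verified against an independently coded
base-resolution region scanner on hundreds of randomized small genomes.

## Mutational catalogs and microhomology indels

SBS-96 catalogs use the canonical COSMIC channel ordering (substitution
class C>A, C>G, C>T, T>A, T>C, T>G; then 5' base A,C,G,T; then 3' base).
Purine-reference substitutions are reverse-complemented into the
pyrimidine-centric channel.  A REF allele disagreeing with the reference
sequence is an error, never silently skipped.

Indel classification (deletions and insertions up to 100 bp, left-anchored
VCF alleles): a deletion embedded in a tandem repeat of its own unit (two
or more copies including the deleted one, counting both directions) is a
*repeat-unit deletion*.  Otherwise the microhomology length is the longest
exact match between the deleted sequence and either immediate flank (prefix
against the 3' flank, suffix against the 5' flank — both directions, taking
the maximum; configurable to one direction), capped at one below the
deletion length.  Deletions of length >= 2 with microhomology >= 1 are
*microhomology deletions*; MHID is their count.  Repeat detection takes
precedence over microhomology (a full-unit flank match is a repeat, not
microhomology).  The classifier is verified against brute-force string
matching on a thousand randomized deletions.

Catalog correction rescales each channel by (genome share of its triplet) /
(capture-region share of its triplet), both tables normalized to sum to
one; triplet tables are computed from any FASTA (optionally BED-restricted,
0-based half-open, extended 1 bp for edge contexts), so no hg19 download is
needed for testing.  Correction is exactly inverted by swapping the tables.

## Signature exposures

Exposures solve `min ||m − S e||` subject to `e >= 0` (Lawson–Hanson NNLS
via `scipy.optimize.nnls`), reported in mutation counts because the risk
score multiplies raw per-signature magnitudes.  A channel-ordering mismatch
between catalog and matrix is an error; nothing is reordered silently.

The bundled matrix `ac30_signatures_synthetic.tsv` is a **synthetic
stand-in** for the 30-signature "Alexandrov COSMIC" v2 set, which is
distributed under access conditions that preclude bundling: 30 sparse
column-stochastic signatures over the 96 channels, the first biased toward
C>T at NpCpG like a deamination clock signature, generated deterministically
by `scripts/make_signatures.py`.  Exposures fitted against it exercise
identical code paths but are not biologically interpretable; any matrix in
the same TSV layout can be substituted.

## Burden features

* **TMB** = qualifying variants / target size in Mb (default 33 Mb, the
  exome capture size).  With effect annotations present, coding variants
  count, synonymous included; without annotations all variants count; the
  choice is logged.
* **SNV load** = number of SNVs; **CN load** = merged autosomal regions
  with total copy number ≠ 2 (adjacent aberrant segments merge; raw
  segment counting available); **dup load** = duplications with length in
  [1 kb, 100 kb], bounds inclusive (the published prose once says "1 to 100
  bp", read as a typo for the kb used everywhere else).  Without an SV
  table, duplications can be derived from copy-number gains (total >= 3).
* **Neoantigen count** is an external input (no prediction); missing values
  default to 0 with a warning.

## The risk score and its refit

`drdscore()` applies the published 14-coefficient formula verbatim on raw
feature scales at full floating precision, with a configurable intercept
defaulting to 0; `classify()` predicts resistance strictly above the 0.7584
threshold (ties resolve to sensitive).  Note the published scale tension:
coefficients of order 1e-3 times feature scales of order 10–10^3 give
scores of order ±0.1, which cannot reach the published threshold without an
unprinted intercept or transformation.  The package implements the printed
formula and documents the inconsistency rather than guessing; refitting
yields an internally consistent score/threshold pair.

Refitting (`DRDModel.fit()` / `fit_lasso_loocv`): L1-penalized logistic
regression of resistance on the 14 features, features standardized
internally and coefficients returned on the raw scale.  The penalty grid
(default `logspace(-2, 3, 11)` in the inverse-strength C) is scored by
leave-one-out cross-validation on mean held-out log-likelihood; ties go to
the stronger penalty.  "Leave-one-study-out" in the source is read as
leave-one-out over patients (there is one study), and the solver is saga
(deterministic given seed) because it leaves the intercept unpenalized.
When a fit returns all-zero slopes its intercept is set analytically to the
class log-odds — the exact profile optimum, which the solver itself cannot
reach once the loss term is scaled by a tiny C.  Constant features warn and
are retained.

## Evaluation

Sensitivity, specificity and accuracy (resistant = positive class) carry
two-sided exact 95% Clopper–Pearson intervals (beta quantiles; lower bound
pinned at 0 for zero successes, upper at 1 for all successes).  The exact
method was identified by verification: it reproduces all three published
interval pairs to two decimals.  Percentages are rounded half-up to two
decimals only at the reporting layer.  AUC is the Mann–Whitney U statistic
over n_pos·n_neg with ties counted 1/2.  Fisher's exact test sums
hypergeometric probabilities no larger than the observed table's.  The
Mann–Whitney test enumerates the exact rank-sum distribution (dynamic
programming) when the smaller group has at most 8 observations and there
are no ties, otherwise uses the tie-corrected normal approximation without
continuity correction; zero rank variance gives p = 1.  An empty class
makes a metric undefined, never 0.

## The synthetic cohort generator

The generator emulates the study conditions at desk scale so the whole
pipeline can be verified against planted truth:

* **Genome**: by default 8 chromosomes of 1.5 Mb with mid-chromosome
  centromeres, uniform random sequence (GC ≈ 0.5), an exome BED covering
  ~30%, and scar rules at the 1/1000 (kb) scale.  Eight chromosomes rather
  than 2–3 because TAI is capped at two per chromosome and realistic TAI
  targets need more telomeres.
* **Scar planting**: segment layouts realise exact (LOH, TAI, LST) targets.
  Small (5 kb) imbalanced spacers shield LOH regions so they add no LST
  breakpoints; LST chains alternate large balanced/unbalanced states with
  small stoppers where needed; TAI segments are small telomeric imbalances.
  Each construct is orientation-symmetric so q-arm layouts are mirrored.
  Additional scar-neutral balanced gains (small (2,2) blocks, Poisson mean
  30, identical across groups) supply copy-number change load that is *not*
  a function of the scar score — without them CN load would be collinear
  with HRD, which contradicts the study's finding that CN load alone is
  uninformative.
* **Microhomology sites** are engineered into the reference (the bases
  after each designated deletion repeat a proper prefix of the deleted
  unit; tandem repeats excluded by construction), so planted MHID counts
  are recovered exactly.
* **SNVs** are placed at genome positions whose trinucleotide context
  matches channels sampled from a per-patient signature mixture, drawn from
  a Dirichlet centred on the group mixture (concentration 10).  Both groups
  share the same signature support with different mean weights; sensitive
  tumors carry more of the HRD-associated signature.
* **Group-conditional distributions** (the study conditions): HRD scores
  follow a scaled beta on the published range whose two shape parameters
  jointly match the published median and HRD-high prevalence.  For the
  sensitive group (median 56, range 23–122, prevalence 78.95%) this is
  exactly solvable.  For the resistant group the published median (47) and
  prevalence (47.37% at threshold 42) are mutually inconsistent — a median
  above the threshold forces prevalence >= 50% — so the fitted shape is the
  least-squares compromise (median ≈ 44, prevalence ≈ 0.53).  MHID (medians
  16 vs 13), exome variant counts (medians 497 vs 443) and duplication
  loads (means 8 vs 5 in-window) are negative-binomial with realistic
  overdispersion; neoantigen counts are Poisson with equal means (the study
  publishes no summary for them, and reports them individually
  uninformative).  All outputs are pure functions of (config, seed).

**What passing tests show — and do not.**  Exact recovery of the integer
features demonstrates that parsing, scar rules, indel classification and
counting are correct end to end.  It does not show robustness to real-data
messiness the generator omits: subclonal copy number, caller-specific
segment artifacts, FFPE damage artifacts, alignment errors, germline
contamination.  The refit sign check shows the estimation machinery
recovers a planted direction under study-scale signal; at n = 57 the LASSO
retains or drops the weak HRD effect stochastically across generator
seeds, exactly as one should expect at that sample size.  The published
cohort AUC values and p-values require the restricted patient data and are
not reproduced.

## Problem sizes and tolerances

Default verification sizes: 500 random genomes for the scar oracle, 1,000
random deletions for the microhomology oracle, multinomial catalogs of
5,000 mutations for NNLS recovery (cosine >= 0.90), 2,000 binomial draws
for interval coverage, and the 57-patient discovery preset for the
end-to-end pipeline.  Exact-representation NNLS checks use 1e-6; algebraic
inverses (catalog correction) 1e-9; the linear score is checked at machine
precision.
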