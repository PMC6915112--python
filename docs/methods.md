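# Methods

## The phenomenon and the model

In organisms with a haploid multicellular phase (red-algal gametophytes
being the motivating case), each individual carries one allele per
single-copy locus, so a genotype matrix of a haploid mapping population —
two parents and their meiotic offspring — should be entirely homozygous,
with the parental alleles segregating 1:1 among offspring wherever the
parents differ. Abundant heterozygous calls in such data indicate that
reads from two distinct genomic copies are being mapped to a single
assembly position. When a segmental duplication is collapsed in a
fragmented assembly, a fixed difference between the paralogous copies (a
paralogous sequence variant) is genotyped as a heterozygous SNP in every
individual; a difference that still segregates among haplotypes produces
heterozygous calls in a subset of individuals.

`pseudohet` treats this as a classification problem over a
loci × individuals call grid with four per-locus states (homozygous
reference, homozygous alternative, heterozygous, missing — sufficient
because only biallelic SNPs are analysed), followed by a battery of
screens that exclude the mundane alternative explanations (repeats,
organellar sequence, exogenous DNA) before collapsed duplication is
accepted as the remaining mechanism.

## Pipeline stages and their parameters

Stages run in a fixed order; every removed locus is attributed to exactly
one stage.

1. **Site/genotype quality filter.** Sites are removed when
   QD < 2.0, FS > 60.0, MQ < 40.0, SOR > 10.0 or QUAL < 20 (the standard
   hard-filter recipe for short-variant calls); genotypes with depth
   DP < 4 are set to missing. Absent annotations pass with a warning
   tally so that minimal (e.g. simulated) VCFs are untouched; the filter
   is idempotent.
2. **Missing-rate filter.** A locus is kept when its missing-call
   fraction is strictly below `max_missing_rate` (default 0.15).
3. **Repeat masking.** A locus is removed when its single SNP base
   (position − 1 in 0-based coordinates) falls inside any annotated
   repeat interval. Intervals are 0-based half-open internally; GFF3
   input is converted by start − 1. Flanks are deliberately not
   considered — masking is a property of the variant site itself.
4. **Classification.** A locus is HETEROZYGOUS_ANY when ≥ 1 call is
   heterozygous, else UNIFORM_HOMOZYGOUS. The *identical heterozygous in
   all individuals* flag has two readings: **strict** (default) — every
   individual heterozygous with the same pair, no missing call tolerated
   — and **relaxed** — every non-missing call heterozygous with the same
   pair. Both counts are always reported, because with a ~6% missing
   rate the strict count underestimates the fixed-duplication fraction
   drastically (a locus survives complete strictness with probability
   (1 − m)^N ≈ 0.024 at m = 0.058, N = 62), while the relaxed count is
   the generative-model-faithful estimate. The configuration flag
   `identical_requires_complete` selects the headline number.
5. **Parent patterns.** Each locus is assigned exactly one of:
   BOTH_HET_IDENTICAL (for biallelic loci two heterozygous parents are
   automatically identical), ONE_PARENT_HET (the other parent homozygous
   or missing), PARENTS_HOM_DIFFERENT, PARENTS_HOM_SAME, OTHER (both
   missing, or one homozygous and one missing). The patterns route loci
   to screens: BOTH_HET_IDENTICAL flanks are exported as BLAST queries
   (exogenous-DNA check), ONE_PARENT_HET flanks are aligned to the
   organelle genomes (cytoplasmic-inheritance check).
6. **Segregation test.** At PARENTS_HOM_DIFFERENT loci, offspring
   homozygous for the female vs male allele form a two-cell Pearson
   goodness-of-fit test against 1:1: χ² = Σ(O − E)²/E, E = (n_♀+n_♂)/2,
   df = 1, no continuity correction. Heterozygous and missing offspring
   are excluded from the test but reported. If both cells are zero the
   locus is flagged untestable rather than assigned a p-value. Yates
   correction is not applied; at the n ≈ 60 scale of these populations
   the uncorrected test's exact type-I error is 0.052 (computed by exact
   binomial enumeration), and the correction would make the test
   needlessly conservative.
7. **Screens.**
   * *Flank extraction*: windows of `total_length` (default 400) centred
     on the SNP; for even lengths the convention is 200 bases left /
     199 right, truncated at scaffold ends with the SNP offset adjusted.
     The reference base at the SNP is checked against the locus ref
     allele and mismatches are flagged.
   * *Organelle screen*: exact k-mer seeds (k = 21) between a window
     (both strands) and each organelle sequence are extended without
     gaps while the running identity stays ≥ 0.9; extensions ≥ 100 bp
     are hits. The method is deterministic and self-contained; the
     thresholds are declared conventions, configurable in
     `PipelineConfig`. At k = 21 the expected number of chance seed
     matches between a 400-bp window and a 150-kb target is
     ≈ 380 · 2 · 150 000 / 4²¹ ≈ 3 · 10⁻⁵, so random windows are
     reliably clean while any planted or moderately diverged (≲ 5%)
     copy is recovered.
   * *GC–depth screen*: operates on a user-supplied per-window table
     (window_id, gc, depth); a window is contamination-suspect when its
     GC lies outside [0.40, 0.60] or its depth outside the empirical
     1st–99th percentile band. Computing depth from alignments is out
     of scope. With identical depths the percentile band collapses to a
     point and nothing is depth-flagged.

## The generative model

`simulate()` draws a complete dataset: random uniform-DNA reference
scaffolds, SNP positions uniform without replacement and ≥ 200 bp from
scaffold ends (so default flank windows never truncate), and per-locus
calls under a four-component mixture:

| type | rule |
|---|---|
| FIXED_COLLAPSED_DUP | every individual heterozygous (copies fixed for different alleles) |
| SEG_COLLAPSED_DUP | each parent's copy-2 allele is alternative with probability q; offspring inherit one parent's two-copy haplotype uniformly; call heterozygous iff copies differ |
| SINGLE_COPY_SEG | parents homozygous ref/alt (order random); offspring inherit either allele with probability 1/2 |
| MONOMORPHIC | all homozygous reference |

Calls are then independently set missing with probability m. One named
random stream per component (reference, positions, types, haplotypes,
missingness, repeats, organelles, depths) hangs off the single seed, so
output is bit-identical per seed and changing one component's draws
never perturbs another's.

**Defaults.** n_offspring = 60, n_loci = 9,989, mixture weights
(0.77, 0.06, 0.01, 0.16), m = 0.058, q = 0.8. These reproduce the
composition of the motivating 62-gametophyte dataset: the expected
per-individual heterozygous proportion is
(w_fixed + w_seg·q)(1 − m) = (0.77 + 0.048)·0.942 ≈ 0.770 (observed
range in the real data: 66–84%, mean 77%), the homozygous proportion
(w_mono + w_single + w_seg(1 − q))(1 − m) ≈ 0.171 (real mean 17%), and
the missing proportion m ≈ 0.058. q = 0.8 is the single free parameter
chosen to close this accounting; it encodes that most segregating
collapsed duplications in such data are near fixation.
`repeat_overlap_fraction` defaults to 0 because the emulated matrix is
the *post*-repeat-masking marker set; set it > 0 to exercise the masking
stage. Optional allele depths use total ~ Poisson(mean_depth = 16) and
copy-1 reads ~ Binomial(total, β) with balance β = 0.5; skewed paralog
representation (β ≠ 0.5) is a supported scenario, not a fitted value.

**What the simulator does not model.** Linkage and recombination (loci
are unlinked), read-level errors and mapping artefacts, copy-number > 2
duplications, divergence between paralogs beyond a single variant site,
and real repeat landscapes. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated model,
not the biological composition of any real dataset.

## Estimation

`estimate_duplication_fraction` reports the fraction of loci with ≥ 1
heterozygous call together with a Clopper–Pearson (exact binomial) 95%
interval. Under the generative model its estimand is
w_fixed + w_seg(1 − (1 − q)²) — the probability that a locus carries at
least one heterozygous haplotype — so it is an upper-bound-style proxy
for the collapsed-duplication fraction; the exact interval is
deliberately conservative (coverage ≥ nominal).

## Numerical and formatting choices

* Positions are 1-based in all user-facing I/O (VCF convention),
  0-based half-open internally (BED convention).
* Haploid-style ("0", "1") and diploid-style ("0/0", "0/1") GT fields
  are both accepted; phase separators are ignored. Multiallelic, indel
  and symbolic records are skipped with a logged count, not split.
* Missing genotypes render as an en dash in tabular output; hyphen and
  period are accepted on input.
* Report percentages are rounded half-up to two decimals.
* Loci are processed strictly in matrix order; no stage re-sorts.
* An all-missing locus is a classification error by contract — the
  missing-rate filter removes such loci at any threshold < 1.

## Problem sizes in tests and the reproduction script

The statistical checks use 10,000 loci for segregation-test calibration
(the empirical type-I error is compared with the binomial 99% band
around 0.05), 10 × 2,000 loci for exact truth recovery, 100 × 2,000 loci
for CI coverage (≥ 93/100 expected for an exact interval), and
20 planted + 100 random 400-bp windows against a 150-kb target for the
organelle screen. These sizes give binomial standard errors a factor of
3–10 below the tolerances being checked while keeping the whole suite
fast.

## Known limitations

* The identical-heterozygous headline depends on the strict/relaxed
  reading (both are always reported); with realistic missingness the
  strict count is mostly a data-completeness statistic.
* The organelle screen is ungapped; a duplication junction or indel-rich
  organellar insertion would fragment into shorter extensions and could
  fall below the 100-bp threshold.
* The duplication-fraction estimator does not correct for missingness
  (a fixed-duplication locus with every call missing at the observed
  individuals would be counted against duplication); at m ≤ 0.1 and
  N ≥ 30 individuals the bias is < 10⁻³⁰ and ignored.
* `summarize_annotation` reproduces the class labels of its input table
  as given; it does not re-curate taxonomy.
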