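# Methods

`enzfam` implements a pan-cancer, enzyme-family-centric driver analysis as a
tested pipeline: mutation enrichment per enzyme family against a
coverage-matched permuted background, degree-preserving randomization of the
patient×gene mutation matrix, genome-instability and SV/indel feature
metrics, a hemizygous-essential driver classifier, arrayed-screen scoring,
and an expression-vs-mutation-rate model.  A seeded synthetic-cohort module
generates every input with planted effects, so each stage can be validated
against a known truth.

## Family enrichment (the core statistic)

For one cancer type and one gene set (an enzyme family or class), the
statistic is the number of *recurrently mutated* genes: genes carrying a
deleterious variant — missense, nonsense, splice site, or frameshift
deletion — in at least two distinct patients.  Silent and other classes
never count, and multiple hits in one patient count once.

The null distribution is built by rejection sampling: gene sets drawn
uniformly from the universe, matched to the family in gene count and within
±5% of its total genomic coverage (sum of gene lengths), re-counted with the
same ≥2-patient rule (applied inside every draw, for exchangeability).
Default 10,000 permutations.  Summary statistics:

- **SMD** = (observed − null mean) / null SD, with the sample SD (n−1
  denominator).  A degenerate null (zero SD, observed off the mean) is
  flagged `smd_undefined`, never given a value.
- **Empirical p** = (r+1)/(n+1) with r the number of null counts at or above
  the observed.  The add-one form keeps p strictly positive (a requirement
  for Fisher combination) and bounds it below by 1/(n+1).
- **Across cancer types**: mean SMD, 5th/95th percentiles of the per-type
  SMDs (linear interpolation between order statistics) as the effect range,
  and the Fisher combination X = −2 Σ ln p ~ χ²(2k) of the per-type
  empirical p-values.

Driver-catalog enrichment per family is a two-sided Fisher exact test on the
2×2 table of family × catalog membership over the universe; an odds ratio
with a zero denominator cell is reported as +∞ with the exact p still
computed.

**Calibration note.**  The recurrence count is an integer with a small range
(for a ~60-gene family, a few dozen attainable values), so the tied ≥
counting rule makes the empirical p *super-uniform*: P(p ≤ t) ≤ t with
visible discreteness.  The p-values therefore control type I error
(conservatively) but are not exactly uniform under the null; a randomized
tie-broken variant of the same machinery is exactly uniform, confirming the
sampler itself is calibrated.  Consumers combining these p-values downstream
inherit the conservatism.

Matched sampling is plain rejection sampling (default 10,000 attempts per
draw); an exhausted budget raises an error reporting the closest achieved
coverage ratio rather than silently widening the tolerance.  The class-level
analysis (7 UniProt classes) is the same code path with the class label
column selecting the partition.

## Curveball matrix randomization

The binary patient×gene matrix is randomized by curveball trades: two rows
are chosen uniformly; the columns where they differ are redistributed
uniformly at random, preserving each row's count.  Row and column sums are
invariant under every trade, and the chain's stationary distribution is
uniform over all matrices with the given margins.  Defaults: 5 × n_rows
trades per randomization (the published mixing heuristic), and each ensemble
member restarts from the observed matrix with an independent burn-in so
members are exchangeable.  The ensemble is streamed with O(1 matrix) memory.

## Mutant status and genotype groups

A gene is mutant in a sample when any of three rules fires:

1. **snv** — any nonsynonymous event (missense, nonsense, splice site,
   frameshift deletion, in-frame) in the gene;
2. **cn_loss** — somatic copy-number loss covering ≥50% of the gene body.
   "Loss" means total copy number below the rounded ploidy (round half-up,
   so a 2.9-ploidy sample compares against 3); the covered fraction uses the
   *union* of qualifying segments, so abutting partial losses combine.  The
   boundary is inclusive: exactly 50% fires;
3. **sv_orf** — any SV breakend strictly inside the open interval
   (start, end).  No transcript model is consumed; breakend-in-gene is the
   operational reading of ORF disruption.

Zygosity from allele-specific copy number: `hom_loss` when ≥50% of the gene
sits at total copy 0, `het_loss` when ≥50% sits in [1, ploidy), else `wt`.
A missing or logR-only profile yields `na` — recorded, never silently wild
type.  Genotype groups are assigned from a user-declared rule table (label →
gene → required zygosity); the most specific fully-satisfied label wins, and
unassignable samples are excluded with a reason.  Co-occurrence between two
genes is a two-sided Fisher exact test on the mutant/non-mutant 2×2 table,
with degenerate margins reported as p = 1 and an undefined odds ratio.

## Genome instability

**WGII** is the unweighted mean over chromosomes of the per-chromosome
aberrant fraction — averaging per chromosome keeps large chromosomes from
dominating.  Two dialects:

- *allele_specific*: a segment is aberrant when its integer total copy
  number differs from the rounded sample ploidy.
- *logr*: segments are centered on the length-weighted genome mean logR and
  called aberrant when the centered value falls strictly outside
  [−0.2, 0.2] ("outside the range" read as exclusive, so a segment exactly
  at the window edge is not aberrant).

Unsegmented gaps count as non-aberrant (the denominator is the chromosome
length); chromosomes with zero segmented bases are excluded from the mean
and logged.  Sex chromosomes are treated like any other (nothing in the
machinery distinguishes them).  Both dialects are verified against an
independent per-base brute-force oracle to 1e-12.

**CNA burden** counts maximal runs of contiguous (abutting) aberrant
segments per chromosome — abutting aberrant segments with different values
merge into one alteration; a non-aberrant segment or gap breaks the run —
and bins the count into the nested categories 0 / ≥1 / ≥2 / ≥3.

## SV, indel and exposure features

Per sample, all proportions normalize within their feature class and sum to
1; an empty denominator leaves the class missing, never 0.

- Deletion and duplication sizes: half-open bins [0,1 kb), [1,10 kb),
  [10,100 kb), [100 kb,1 Mb), [1 Mb,∞), normalized separately per SV type
  (half-open because the contiguous printed labels require each boundary to
  belong to exactly one bin; 10,000 bp is a 10–100 kb event).  TRA/INV carry
  no size and are excluded.
- Breakpoint homology: inclusive integer bins 0–3, 4–11, 12–1000 nt over all
  SVs; lengths above 1000 clamp into the top bin with a logged warning.
- Indels: 1 / 2–4 / 5+ nt, separately for deletions and insertions.
- Signature exposures: per-signature counts over the sample's total.

Group associations are OLS of a feature on disjoint genotype-group
indicators against a reference group (coefficients are then group-mean
shifts; an additive gene-wise coding is the caller's choice by building the
design differently), with two-sided t-tests and Benjamini-Hochberg
adjustment per feature class.  A two-sided Mann-Whitney U (exact when the
smaller side has ≤8 tie-free observations, tie-corrected normal
approximation otherwise) is provided for direct two-group comparisons; the
choice between regression and rank test is left to the analysis, so both are
exposed.

## Hemizygous-driver classifier

Per gene, three booleans from the evidence table:

- **essential** — CRISPR dependency score < −1 (strict);
- **recurrent** — focal alteration count ≥ 3 AND pan-cancer focal rate
  > 0.1% (the combinator and both cutoffs are configurable; an OR reading
  with a 0.5% biallelic cutoff is also in circulation and available via
  `Thresholds`, and every run records the thresholds used);
- **biallelic_depleted** — biallelic inactivation rate < 0.1%.

Recurrent genes land in one of four quadrants (essential × biallelic);
non-recurrent genes are set aside.  A hemizygous driver candidate is
essential ∧ recurrent ∧ biallelic-depleted.  The essential∧biallelic
quadrant is expected empty on real-like data — two-hit loss of an essential
gene is cell-lethal.  Genes missing a dependency score are excluded with a
reason code, never defaulted to non-essential.  Focality is consumed as a
precomputed count; no segment-size cutoff is re-derived.  Relaxing any
threshold can only grow the driver list (verified by sweep tests).

## Screen scoring

Per plate, the positivity threshold is the 95th percentile (configurable) of
pooled negative-control cell intensities — strictly per plate, no cross-plate
pooling, which also makes downstream scores invariant under per-plate affine
intensity rescaling.  Each well is summarized as its fraction of cells above
threshold.  Per gene and replicate, a one-sided (greater) rank-sum test
compares the gene's three construct wells against the plate's control wells;
per-replicate p-values are Fisher-combined (k adjusts when a gene is missing
from a replicate) and genes with combined p < α are hits.  SSMD =
(mean difference)/√(summed sample variances) is the effect size; either side
with fewer than two observations yields an undefined flag, never 0.  The
exact rank-sum p-values are discrete, so null hit rates run conservative —
below nominal α.

## Expression-vs-mutation-rate model

Per gene: rate = deleterious events / gene length in kb; genes with fewer
than three events are excluded from fitting.  Zero inflation is handled by a
two-part hurdle — logistic regression of (rate > 0) on expression and
length, then OLS of log rate on expression and length over positive-rate
genes.  The reported effect is the positive-part expression slope (positive
= higher expression, higher rate); a plain linear fit is available as a
sensitivity path.  One model is fit per (cancer type, gene class) over
gene-level records — the class-level reading: expression and rate enter as
single per-gene values, so a per-gene regression has nothing to fit across.
Within each class the per-fit p-values are BH-adjusted and the summary
reports the mean effect and the percentage of tested fits significant at
q < 0.05.

## Synthetic cohorts: what they emulate, and what they do not

Every generator is a pure function of its spec; streams are seeded as
(master seed, generator name), so adding a generator never perturbs the
others.

- **Gene universe**: log-normal gene lengths (median 20 kb, σ = 0.6 on the
  log scale), family labels assigned independently of length at 6% per
  family (the remainder non-enzyme), genes tiled round-robin over 23
  chromosomes.
- **Mutations**: per patient×gene deleterious counts ~ Poisson(length ×
  rate × multiplier), multiplier only on the planted family.  Baseline rate
  1e-7/bp/patient: at 200 patients a median gene expects ~0.4 deleterious
  events cohort-wide, putting ~5–10% of background genes over the
  ≥2-patient bar — recurrence present but unsaturated, the regime the
  statistic needs.  Deleterious classes are drawn with fixed weights
  (missense 0.7, nonsense/splice/frameshift 0.1 each); the counting rule
  uses the class set, not the mix.
- **Segments**: per chromosome, an aberrant fraction near the target WGII
  (clipped normal jitter, SD 0.02) placed as 1–2 disjoint runs; aberrant
  copy number is ploidy±1, or logR ±0.5 with random sign so the
  length-weighted genome mean stays near zero and the logR window recovers
  the planted fraction even for heavily aberrant genomes.
- **Driver tables**: planted hemizygous genes get dependency < −1 (clipped
  noise), ≥3 focal events above the 0.1% rate, biallelic 0; planted TSGs get
  dependency > −1 and biallelic ≥1%; background genes satisfy neither
  pattern, with biallelic rates between the two cutoffs.
- **Screens**: log-normal per-cell intensities (log SD 0.5), one plate per
  replicate, three construct wells per gene, eight control wells per plate;
  hit genes shifted on the log scale (a shift of 1.0 = two control SDs).

These emulate the *statistical structure* the pipeline consumes — not
sequence content, mutational signatures' biochemistry, segmentation noise,
purity artifacts, or inter-gene correlation.  Passing tests therefore show
the machinery is correct and calibrated under its stated model; they do not
show that real cohorts satisfy that model.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; SEG (1-based
  inclusive) and VCF-style positions convert at the I/O boundary.  Intervals
  are strand-agnostic.
- Percentiles: linear interpolation.  SDs and variances: sample (n−1).
- Rounding of ploidy: half-up (floor(x + 0.5)).
- Fisher combination requires p ∈ (0,1]; the add-one empirical p guarantees
  this by construction, and p ≤ 0 raises.
- Ties in rank tests switch to the tie-corrected normal approximation; a
  fully tied comparison returns p = 1 rather than NaN arithmetic.
- Degenerate 2×2 margins (a gene mutant in zero or all samples) return p = 1
  with an undefined odds ratio and are the caller's signal, not an error.

## Problem sizes used in the test and acceptance runs

Statistical checks run at desk scale, chosen to keep each stage's check
minutes-scale while leaving Monte-Carlo margins well away from the asserted
bounds: 200 null cohorts of 1000 genes × 200 patients with 200 permutations
per family for calibration; 20 planted-effect cohorts at 500 permutations
for power; 100,000 (tests) / 50,000 (acceptance script) randomizations for
curveball uniformity; 10,000 draws against exhaustive enumeration on a
12-gene universe; 200 random profiles per dialect for the WGII oracle; 20
seeds for driver recovery; 100 null screens; 100–200 expression-model fits.

## Known limitations

- The ±5% coverage matching conditions on total set coverage only; two sets
  with equal totals but different length spectra are exchangeable under the
  null model here (labels independent of length) but need not be on real
  data where family membership correlates with gene length.
- The empirical p's tie-induced conservatism (above) biases the Fisher
  combination conservative as well.
- Breakend-in-gene is a deliberately transcript-blind reading of ORF
  disruption; exon-aware calling would fire less often.
- Screen per-replicate inference is an exact rank-sum on three construct
  wells versus plate controls — a declared stand-in for protocol-specific
  scoring, with very limited per-replicate resolution (minimum attainable
  one-sided p of 1/C(n_ctrl+3,3)); power comes from replicate combination.
- The hurdle model's two parts are fit independently; no shared dispersion
  or correlated random effects across classes.
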