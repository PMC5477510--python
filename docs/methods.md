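# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study does and does not emulate.

## Clinical model and response rule

Subjects in a two-arm (drug / placebo), double-blind design contribute one
blood sample at baseline (T0) and one after eight weeks (T8). Depression
severity is the MADRS score (points; trial entry requires ≥ 22 at
baseline). Response is a strictly greater than 50% decrease from baseline:
r = (MADRS_T0 − MADRS_T8)/MADRS_T0 > 0.5. A decrease of exactly 50% is
classified nonresponder (the rule is stated as ">50%", so the boundary
goes to the nonresponders); a zero baseline raises an error rather than
silently producing an undefined percent change. The rule is
scale-invariant, which the test suite checks by property.

## Read-level QC

Filters are applied in a fixed order, and the first failure claims the
rejection (so tallies partition the input):

1. **adapter** — leftmost exact occurrence of the adapter's first 10
   bases ("perfect 10-nucleotide seed"); reads without it are dropped;
2. **length** — the insert (bases 5' of the adapter) must be 15–40 nt;
3. **quality** — mean Phred of the *trimmed insert* must exceed 30
   strictly (the insert is the quantity carried downstream, so its
   quality, not the raw read's, is what matters; Q exactly 30.0 fails).

Phred encoding is fixed at +33; +64 input is the caller's responsibility
via the config flag. Counting is exact matching against the mature
reference, extended to exact prefixes of ≥ 16 bases to absorb 3'-end
trimming variability; inserts compatible with ≥ 2 references are discarded
as ambiguous and tallied. This replaces genome alignment (Bowtie +
miRBase-style annotation), which is out of scope here: the stand-in
preserves the pipeline contract and is exactly testable against planted
multiplicities.

## Detection filter and normalization

A miRNA is retained when it has ≥ 10 counts in ≥ ceil(0.8 × n) libraries
(the comparison is float-robust so that exactly 80% passes). The filter is
idempotent.

Normalization is median-of-ratios: size factor of sample s = median over
zero-free miRNAs of count/geometric-mean-across-samples, followed by
log2(count/sf + 1). This is a variance-stabilizing transform in the
practical sense that every downstream statistic is rank- or
correlation-based; it is *not* the DESeq2 VST, which is deliberately not
reproduced bit-exactly. Note that median-of-ratios size factors are
scale-free: multiplying every count by c shifts all normalized values by
log2 c uniformly, leaving ranks, Pearson correlations, and fold changes
unchanged (the test suite pins this down). An all-zero sample has an
undefined size factor and raises an error naming the sample.

## Paired differential expression

The test is a rank-based resampling scheme with the two-class *paired*
character of SAM adapted to counts:

- per resample (default 20), counts are Poisson-downsampled to the minimum
  library depth (λ = count × d_min/d_s); libraries already at the minimum
  depth are left untouched — the identity is the correct λ-scale-1 limit
  and makes the no-signal case exactly null;
- per miRNA, the Wilcoxon signed-rank score of the within-subject
  (T8 − T0) differences is computed (zero differences dropped, ties
  mid-ranked) and averaged over resamples;
- significance comes from the sign-flip permutation null: flipping each
  subject's difference sign is the exact null for exchangeable paired
  data. Because flips act on subjects, the flipped statistic is a linear
  form in the per-pair mean signed ranks, so the whole null is one matrix
  product. For 2^pairs ≤ 4096 (≤ 12 pairs) the full enumeration replaces
  sampling and p-values are exact; otherwise p = (b + 1)/(B + 1) with
  add-one smoothing (default B = 1000);
- BH step-up adjustment across miRNAs, implemented directly
  (q(i) = min_{j≥i} p(j)·m/j, capped at 1) and cross-checked against
  statsmodels in the tests.

**Permutation resolution.** The smallest attainable adjusted p with k true
discoveries among m features is m/(k·(B + 1)). With m ≈ 281 features and
~5 markers, B = 1000 cannot clear a 5% FDR (floor ≈ 0.056), so pipeline
runs use B = 10 000 (floor ≈ 0.0056). This is a resolution requirement,
not a tuning knob.

Fold change is T8/T0 on de-logged normalized values:
FC = (mean(2^v − 1) at T8 + ε)/(same at T0 + ε), ε = 0.5 by default; FC < 1
means downregulation after treatment, and the pseudocount vanishes in the
ε → 0 limit. DE tables are sorted by adjusted p, then |log2 FC|
(descending), then miRNA ID — a documented deterministic tie-break.

## Cross-arm candidate algebra

Inputs are per-(arm, stratum) significant sets. Candidates =
(drug-responder ∩ placebo-responder) minus miRNAs significant in the
nonresponders of *both* arms; the drug-specific set is the responder
difference. miRNA IDs are matched case-insensitively after stripping the
species prefix (published tables mix "miR-636" and "hsa-miR-636"). Two
open cases are resolved conservatively: a miRNA significant in only one
arm's nonresponders is kept with a warning (the exclusion rationale —
outcome-independent change — requires both arms), and shared miRNAs with
discordant fold-change directions are warned about, never dropped.

## Consensus targets and enrichment

Stage 1: gene g is a target of query miRNA µ iff ≥ k of n sources contain
(µ, g) (default 5 of 7). Stage 2: g enters the combined panel iff it
passed stage 1 for ≥ m query miRNAs (default 3). The stages are
sequential (per-miRNA source vote first, then the miRNA vote), support
counts are retained for audit, and the output is monotone in k and m and
invariant to input order. Gene symbols are upper-cased before matching.
Enrichment is a per-pathway one-sided hypergeometric test over a gene
universe (default: all genes any source mentions), BH-adjusted — a plain,
reproducible stand-in for web-service annotation clustering.

## Integration and the random-gene null

Within each stratum (responders; nonresponders; ≥ 4 samples each), Pearson
r and two-sided p are computed for every (panel gene, query miRNA) pair;
a gene is *correlated* when any of its pairs has p < α = 0.05, unadjusted.
The α is per-pair deliberately: the multiplicity burden is carried by the
empirical null, which replaces the panel with random draws of 50 genes
from the measured universe (panel excluded, keeping null and alternative
disjoint) and applies the identical criterion, 100 times. The expected
null fraction under independence is 1 − (1 − α)^M (M query miRNAs), ≈
18.5% for M = 4 — realized means vary roughly between 10% and 27% across
datasets because the M tests share the same miRNA vectors and samples.
The enrichment p is (#{null ≥ observed} + 1)/(B + 1). Zero-variance genes
are flagged and counted as non-significant, never dropped. A pair-level
counting mode (fraction of significant pairs rather than genes with ≥ 1
hit) is available behind the `level="pair"` flag.

## Synthetic study

The generator emulates the trial's *structure*: paired columns per
subject, two arms, Bernoulli responder labels, marker miRNAs downregulated
at T8 in responders only, target genes anticorrelated with their marker in
responders only, and prediction sources with per-pair sensitivity and
false-positive rate. Defaults are the study conditions: 129 subjects/arm
(258 patients), responder fraction 0.5 (balanced strata; the trial's rate
is not published), 281 detected miRNAs with 5 markers at log2 FC −1
(observed candidate fold changes 0.45–0.76), ~15 000 gene probes with a
36-gene shared target panel, target correlation −0.8, 7 sources at
sensitivity 0.9 / false-positive rate 0.05, mean library 10^6 counted
reads, NB dispersion 0.1.

Model choices:

- **Counts**: negative binomial, mean = baseline_i × sizefactor_s ×
  2^(log2FC·1[marker ∧ responder ∧ T8]), variance µ + φµ²; per-miRNA
  baselines log-normal (σ = 1.5) scaled to the library mean, per-sample
  size factors log-normal (σ = 0.25). φ = 0 degenerates to deterministic
  rounded means (a useful exact limit for tests). Baseline abundance
  shapes are chosen for test power, not to match an unpublished empirical
  distribution.
- **MADRS**: T8 = T0·(1 − d) with T0 ~ U[22, 40] and d a scaled Beta(2, 2)
  strictly above 0.5 for planted responders and at or below 0.5 otherwise
  (a mixture of scaled Betas rather than one global Beta: it guarantees
  the planted label round-trips exactly through the clinical rule, with no
  boundary ambiguity).
- **Expression**: gene residuals are ρ·z + √(1 − ρ²)·ε against the
  anchor marker's standardized normalized expression, in responder samples
  only; every marker targets the whole panel (emulating co-regulation) and
  anchors are assigned round-robin.
- **RNG**: each stage draws from its own stream seeded from
  (seed, stage-name), so stages are decoupled and identical configs are
  bit-identical.

What the generator does **not** emulate: sequencing error profiles and
isomiRs (the FASTQ writer is a fixture writer, not a read simulator),
batch/cell-composition effects, covariate structure (age, sex, RIN),
inter-miRNA baseline correlation beyond the planted markers, and real
prediction-database biases (sources err independently here). Passing
tests therefore demonstrate correctness of the *statistical machinery*
under its stated assumptions, not performance on real cohorts.

## Problem sizes in tests and the acceptance script

Type-I calibration uses 280 miRNAs × 40 pairs × 50 seeds (null generator);
marker recovery uses 60 subjects/arm × 20 seeds on the drug-responder
stratum with B = 10 000; the end-to-end run uses the full 129/arm cohort
(candidacy requires detection in the responders of both arms, so per-arm
power must be near one) with 4 000 genes; the random-gene null calibration
uses 4 miRNAs × 600 genes × 80 samples of independent Gaussian data.
These sizes are the package's own choices for tight, reproducible checks.

## Known limitations

- The paired test approximates the named SAM-for-sequencing procedure's
  resampling character rather than reproducing its internals; published
  per-miRNA fold changes and adjusted P values from the original cohorts
  are not locally reproducible without the deposited accession data
  (GSE97154) and are shipped only as input tables for the set algebra.
- The consensus gene counts depend on prediction-database versions; only
  the filtering logic, not the published 5 806/895 totals, is reproduced.
- Median-of-ratios + log2(x + 1) is a documented stand-in for the DESeq2
  VST; absolute normalized values differ, rank-based conclusions do not.
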