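# Methods

This note documents the models and procedures implemented in `trdar`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Region annotation

Coordinates are 0-based half-open everywhere internally (BED native); GFF3
is converted on read and write (1-based inclusive). Each region receives
exactly one genomic category by first match in the precedence order
Promoter > 5′UTR > 3′UTR > Exon > Intron > Distal Intergenic. The promoter
window is `[tss − 1500, tss + 500)` on the plus strand and its mirror image
on the minus strand, half-open on the downstream side; both window sizes
are configurable (`AnnotationConfig`). A region overlapping a gene body but
none of the higher-precedence layers is an Intron. The distal non-coding
(distNC) class — the package's enhancer proxy — is exactly the set of
regions labelled Intron or Distal Intergenic; it carries no independent
state.

The closest gene is the gene whose TSS lies nearest the region midpoint,
with ties broken to the lexicographically smallest gene id for determinism.
This is a deliberately simple, fully specified rule; annotation tools that
assign peaks by gene-body overlap with fall-backs can differ for peaks
spanning multiple genes, and those differences are documented behaviour
here, not bugs. The signed TSS distance is negative upstream of the TSS
(strand-aware). Region strand is ignored for classification, since ATAC
peaks are unstranded; gene strand orients the promoter window. Regions on
chromosomes absent from the annotation are flagged Distal Intergenic with
no closest gene and a warning — never silently dropped.

## Normalization and differential testing

**TMM effective size factors.** The reference sample is the one whose
upper quartile of count proportions is closest to the mean upper quartile.
Per sample, M-values (log₂ proportion ratios against the reference) are
double-trimmed — 30% from each tail of M and 5% from each tail of A, over
features non-zero in both samples — and combined with precision weights
(the delta-method inverse variance). The returned factor is library size ×
composition factor, rescaled so all factors multiply to 1; normalized
counts are `counts / factor`. Returning the depth-inclusive factor (rather
than the pure composition factor) makes the factors directly usable as
divisors and makes a 4×-scaled sample report a 4× relative factor.

**NB Wald test with common dispersion.** The caller is intentionally a
common-dispersion model (no tagwise or trended dispersion, no GLM design
matrices): per feature, normalized group means μ̂_A, μ̂_B; log₂ fold change
`log2((μ̂_B + ½)/(μ̂_A + ½))` (the ½ pseudocount stabilises low counts and
keeps equal means at exactly 0); delta-method standard error
`sqrt((1/μ̂_A + φ)/n_A + (1/μ̂_B + φ)/n_B)/ln 2`; two-sided normal p-value;
BH FDR over all tested features; direction labels at FDR ≤ 0.05 (default,
configurable). Features with zero counts in every sample are excluded
before normalization and reported.

The common dispersion φ is a method-of-moments estimate: per feature, the
pooled within-group variance s² and pooled mean μ̄ give
`φ_f = max(0, (s² − μ̄)/μ̄²)`, and φ is the median of φ_f over features.
One numerical refinement matters at typical replicate numbers: with n = 3
per group the pooled variance has 4 degrees of freedom and its *median* is
only ~0.84 of σ², so the median-over-features systematically underestimates
φ by ~20%. s² is therefore scaled by `d / median(χ²_d)` before the moment
step, which makes the median-based φ estimate median-unbiased. On null NB
data (μ = 100, φ = 0.1, 3 vs 3, 2000 features) the test's type-I error at
p ≤ 0.05 is ~0.05 (the acceptance suite asserts [0.03, 0.07]), and φ is
recovered to within a few percent.

**Wilcoxon rank-sum** (for the per-cell-type single-cell comparison)
returns the rank-sum statistic with midrank ties and a two-sided p: exact
enumeration when n₁+n₂ ≤ 25 without ties, otherwise the normal
approximation with tie correction; complete ties give p = 1. Gene-wise
application with BH adjustment is provided (`wilcoxon_de_table`).

## trDAR integration and directional overlaps

A trDAR is emitted iff the region is a significant DAR, its closest gene is
a significant DEG, and the directions are concordant — (open, up) or
(closed, down); concordance is definitional, not statistical. Excluded
regions are tallied by reason (gene outside the DEG universe, gene not
significant, discordant), so the diagnostics partition the significant
DARs.

Directional overlaps follow the "x > y" notation: regions open in
condition x and closed in condition y. The 2×2 table over the shared
consensus-peak universe (both sets, x only, y only, remainder) gets a
two-sided Fisher exact test; BH runs across all pairs of a run. Region
identity across contrasts is by shared consensus id; trDARs from a foreign
peak set fall back to ≥ 1 bp interval matching against the universe.
Category restriction (distNC, Promoter, 3′UTR, …) filters the trDAR tables
before set construction, so category-restricted counts partition the
total.

## Enrichment machinery

All enrichment is the same primitive: a two-sided Fisher exact test of
subset (`ov_da` of `n_da`) versus background (`ov_nda` of `n_nda`) overlap
with a target, BH-adjusted within the run. The exact p sums hypergeometric
probabilities no larger than the observed table's; the odds ratio is the
sample odds ratio (ad)/(bc), with ∞ when only bc is zero and NaN with p = 1
for degenerate (zero-margin) tables.

Chromatin-state enrichment counts ≥ 1 bp overlaps of subset and background
regions with each state's intervals; a state absent from a region's
chromosome contributes no overlap. States can be aggregated by summing
`ov_da`, `ov_nda` and `tot_tgt` within merged labels and recomputing Fisher
and FDR from the summed tables; summed overlap counts are capped at the set
size (a region overlapping several merged parts is still one region).

Gene-set enrichment intersects every target set with the universe and
tests against `universe \ query`. Cell-type signature sets take genes with
expression strictly above 100 counts; age-regulated sets take genes with
p < 0.05 and fold change above 1 (up) or below 1 (down), excluding exact
ties at the boundary. Fold changes are read on the linear scale by default;
`GeneSetConfig(fc_log_scale=True)` moves the boundary to 0 for log-scale
tables. GO-style enrichment is the same operation on a user-supplied
term → genes collection; no ontology-graph logic is included.

## Motif scanning

Homer-format motifs are renormalized with a 10⁻³ pseudocount and converted
to log-odds in bits against background base frequencies (estimated from
the pooled background sequences with a pseudocount guard, or supplied
explicitly). Per-motif hit thresholds come from the *exact* distribution of
the window score of a random background sequence, computed by positionwise
convolution on a score lattice discretized at 10⁻³ bits; the threshold is
the smallest lattice score with tail probability ≤ α (default 10⁻⁴). If α
is below the minimum attainable tail, the maximum score is returned with a
warning. Scanning uses the same discretized scores, so the threshold
comparison is exact; both strands are scanned, windows containing N are
skipped, and sequences shorter than the motif yield no hits. For
enrichment a region's hit status is binary, and the Fisher/BH machinery
above applies. ChIP mode replaces motif hits with ≥ 1 bp overlap against a
TF's peak set.

Because exact-threshold scanning differs from heuristic scanners in both
threshold and statistic, motif *rankings* from other toolchains are not
expected to reproduce; the planted-truth tests assert recovery under this
scanner's own definitions.

## Survival analysis

Kaplan–Meier product-limit estimation with Greenwood variance; censored
individuals at an event time remain at risk for the events at that time.
The median is interpolated linearly between the last step above 50%
survival (t₁, S₁) and the first at or below it (t₂, S₂):
`t₁ + (S₁ − 0.5)/(S₁ − S₂)(t₂ − t₁)`. A step landing exactly on 0.5
returns that step's time, and when the *first* step already crosses 0.5
there is no earlier step to interpolate from, so that step's time is
returned (this also makes the degenerate all-deaths-at-one-time case
return that time with SE 0). If survival never reaches 0.5 the median is
flagged undefined.

The bootstrap resamples individuals — (time, event) pairs, not event
times — 100 times by default, refits the KM curve, and records the
interpolated median of each replicate. The point estimate is the median of
the replicate medians (the full-data interpolated median is also
reported), the SE their standard deviation; undefined replicates are
dropped with a count, and more than half undefined is an error. The
log-rank test is the standard observed-minus-expected statistic over
pooled event times with hypergeometric variance, χ² with 1 df, two-sided;
it matches an independent reference implementation to 10⁻⁸ on random
censored data.

Summary arithmetic: percent median change is 100 (treated − control)/
control to one decimal; suppression is 100 (reduction_ref − reduction_mut)/
reduction_ref rounded to the nearest integer, with a warning flag for
sign-discordant inputs. Confidence bands in any downstream plotting should
use Greenwood log–log intervals; the estimator exposes the Greenwood
variance for that purpose.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline is designed
to detect; its defaults are the package's study conditions:

- **Genome**: 3 chromosomes × 1.5 Mb; 300 non-overlapping genes with
  5′UTR/exon/intron/3′UTR structure on random strands; 1000 peaks of
  200 bp placed to hit a category mix of 25% promoter, 28% intron, 37%
  distal intergenic, 5% exon, 5% 3′UTR (no 5′UTR share: short 5′UTRs sit
  inside the promoter window, which wins by precedence). Realized
  categories are verified post hoc with the package's own annotator and
  are the ground truth used downstream.
- **Effects**: two contrasts, "aging" (old vs young) and "iis"
  (reduced-IIS mutant vs wild type). 30% of distNC peaks close with age
  (log₂FC −2, i.e. 4-fold); 60% of those re-open under reduced IIS — the
  planted anti-concordant set. Promoter peaks receive *independent* 15%
  effect draws per contrast, so their cross-condition overlap is null by
  construction. Each planted DAR's closest gene responds concordantly with
  probability 0.8, discordantly 0.1, else not at all (log₂FC ±2).
- **Counts**: negative binomial via gamma–Poisson with common dispersion
  φ = 0.1 around a baseline mean of 100 (log-normal feature spread 0.4),
  3 replicates per condition, per-sample depth factors with log-SD 0.15.
- **States**: a background tiling of ~2 kb segments over non-enhancer
  labels with a 6% sprinkle of enhancer segments, plus enhancer segments
  covering each planted anti-concordant peak with probability 0.8.
- **Sequences**: i.i.d. bases at worm-like AT-rich frequencies
  (0.32/0.18/0.18/0.32); a length-10 PWM with 0.85 consensus-base
  probability is planted (as PWM draws, so a realistic fraction of
  degenerate instances) in 50% of the IIS-opening regions.
- **Lifespans**: Weibull times with shape 4 (steep, worm-like mortality),
  scaled so the true median equals each group's target — control 17 d,
  long-lived 34 d, long-lived + knockdown 17 d (a 50% reduction); 150
  animals per group. A 10% fraction of animals carries an independent
  uniform censoring clock on (0, 1.5 × median). Times are continuous; the
  every-2–3-days scoring discretization of real assays is not emulated.

NB counts and Weibull lifespans are modelling choices of the test harness,
not claims about real data. The generator does not emulate read-level
artefacts (GC bias, duplicates, mappability), peak-calling uncertainty,
correlated replicates, batch structure, isoform complexity, or real genome
sequence composition — so passing tests demonstrate the *statistical
machinery* is correct and calibrated under the stated models, not that any
particular biological dataset will behave identically. All randomness
derives from the single config seed through named sub-streams, so every
artefact is bit-reproducible.

## Calibration and verification choices

- Exact tests have discrete, conservative (super-uniform) p-value
  distributions, so "calibration under label permutation" is asserted as
  *validity*: a one-sided Kolmogorov–Smirnov test that the permutation
  p-value distribution is not anti-conservative, plus the empirical
  fraction of p ≤ 0.05 staying at or below nominal. A two-sided
  KS-against-uniform check would reject for any exact test regardless of
  correctness.
- Oracles used by the test suite: full hypergeometric enumeration with
  exact integer arithmetic (Fisher), 4^L sequence enumeration (PWM tails,
  L ≤ 8), rank-assignment enumeration (Wilcoxon, n₁+n₂ ≤ 10), an
  independent step-up reimplementation (BH), a per-base brute-force
  annotator (region categories), quadratic all-pairs scans (interval
  overlap), and an independent survival library (KM / log-rank).
- Problem sizes in the default test and acceptance runs (1000 peaks, 300
  genes, 2000 null features, 5–40 simulation seeds, 100 bootstrap
  replicates) were chosen to keep every Monte-Carlo assertion several
  standard errors away from its threshold while completing in minutes on
  one CPU.

## Known limitations

- The closest-gene rule is TSS-to-midpoint; peaks between two dense genes
  can be assigned differently than by annotators with overlap-priority
  rules.
- Common dispersion only: genuinely tagwise variability inflates the null
  spread for high-variance features and the caller does not model it.
- The motif scanner's binary per-region hit status discards multiplicity;
  regions with many weak instances are not scored higher.
- Right-censoring at the recorded day; interval censoring from discrete
  scoring schedules is not modelled.
- Gene-level GO enrichment is plain set overlap; no ontology-graph
  propagation or term de-redundancy.
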