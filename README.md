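# trdar

Integrative analysis of chromatin accessibility and gene expression for
aging genomics: from ATAC-seq and RNA-seq count matrices to
**transcriptionally relevant differentially accessible regions (trDARs)**,
their genomic context, cross-condition directional overlaps, TF-motif /
ChIP-peak / chromatin-state / gene-set enrichment, and bootstrap
Kaplan–Meier lifespan statistics.

The package is aimed at researchers who study how the chromatin landscape
differs between conditions — e.g. aging wild-type *C. elegans* versus
long-lived insulin/IGF-like signaling (IIS) mutants — and who want to ask
whether regions that close with age are the same regions that re-open under
a longevity intervention, which regulatory elements and transcription
factors they implicate, and whether perturbing those factors changes
lifespan.

## What it computes

**Differential accessibility / expression.** Counts are normalized with TMM
effective size factors (trimmed mean of M-values; the factor for sample *s*
is its library size times the composition factor, rescaled so factors
multiply to 1). Each feature gets a Wald test on its log₂ fold change under
a negative binomial model Var(X) = μ + φμ² with a single common dispersion
φ estimated by the method of moments across features, followed by
Benjamini–Hochberg FDR.

**trDARs.** A significant DAR becomes a trDAR when its closest gene (by
TSS-to-region-midpoint distance) is a significant DEG changing in the
concordant direction: regions that open with an upregulated gene, or
regions that close with a repressed gene.

**Genomic context.** Each region receives exactly one category by
precedence Promoter > 5′UTR > 3′UTR > Exon > Intron > Distal Intergenic,
with the promoter window spanning −1500/+500 bp around the TSS
(strand-aware). Regions labelled Intron or Distal Intergenic form the
distal non-coding (distNC) class used as an enhancer proxy.

**Overlap and enrichment.** Directional cross-condition overlaps ("open in
x and closed in y"), chromatin-state enrichment with `ov_da` / `ov_nda` /
`tot_tgt` bookkeeping and state aggregation, PWM motif enrichment with an
*exact* score-distribution threshold (dynamic programming over a
discretized score lattice; default tail probability 10⁻⁴), ChIP-peak
overlap enrichment, and gene-set overlap against cell-type signatures
(> 100 counts) and age-regulated gene lists (p < 0.05, fold change ≷ 1) —
all as two-sided Fisher exact tests against an explicit background with BH
FDR per run.

**Lifespans.** Kaplan–Meier product-limit estimates with Greenwood
variance; the median interpolated between the two step times nearest 50%
survival; 100-replicate bootstrap of individuals giving the median-of-medians
point estimate and its SE; two-sided log-rank tests; percent median change
and suppression arithmetic.

**Synthetic data.** `trdar.synthetic` generates every input (GFF3, BED,
FASTA, Homer motifs, count TSVs, survival CSV) with planted effect
structure and truth tables, so every stage is testable without downloads.

## Worked example

```python
from trdar import (NBDifferentialTest, call_trdars, DirectionalContrastPair,
                   directional_overlap_matrix)
from trdar.synthetic import SimulationConfig, simulate_genome, simulate_counts

cfg = SimulationConfig(seed=1)
sim = simulate_genome(cfg)                 # genes, peaks, states, sequences
counts = simulate_counts(cfg, sim)         # NB counts for both contrasts

trdars = {}
for contrast, (a, b) in {"aging": ("young", "old"),
                         "iis": ("wt", "iis_mutant")}.items():
    dars = NBDifferentialTest().fit(counts["peaks"][contrast], a, b).results_
    degs = NBDifferentialTest(direction_labels=("up", "down")).fit(
        counts["genes"][contrast], a, b).results_
    trdars[contrast], diag = call_trdars(dars, degs, sim.annotations,
                                         contrast_id=contrast)
    print(f"{contrast}: {diag['dars_significant']} DARs -> {diag['trdars']} trDARs")

pairs = [DirectionalContrastPair("iis", "aging", "x_gt_y")]
for cat in ("distnc", "Promoter"):
    tab = directional_overlap_matrix(trdars, pairs, sim.peaks, category=cat)
    r = tab.iloc[0]
    print(f"{cat:8s} iis>aging overlap: {r.ov_xy}/{r.n_x} "
          f"odds={r.odds_ratio:.1f} p={r.p:.2e}")
```

prints

```
aging: 278 DARs -> 176 trDARs
iis: 192 DARs -> 143 trDARs
distnc   iis>aging overlap: 66/97 odds=25.7 p=2.80e-41
Promoter iis>aging overlap: 1/15 odds=4.3 p=2.28e-01
```

The generator plants anti-concordant accessibility changes (closing with
age, re-opening under reduced IIS) only in distal non-coding regions, and
the analysis recovers exactly that: the distNC-restricted directional
overlap is massively significant while the promoter-restricted overlap is
null.

The same analyses are available from the shell:

```bash
trdar simulate --seed 1 --outdir run/
trdar annotate --genes run/genes.gff3 --peaks run/peaks.bed --out run/ann.tsv
trdar diff --counts run/counts_peaks_iis.tsv --groups run/groups_peaks_iis.json \
      --group-a wt --group-b iis_mutant --out run/dars.tsv
trdar survive --data run/lifespans.csv --control control --out run/surv.tsv
trdar run --config config.yaml --outdir results/   # full pipeline
```

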