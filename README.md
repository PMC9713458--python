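# xqtl

Extreme-QTL ("X-QTL") mapping from pooled sequencing of multiparent
populations: estimate founder-haplotype frequencies of selected vs. control
pools in sliding genetic-map windows, scan the genome for consistent
treatment-driven differentiation, and call QTL with drop-based confidence
intervals. A synthetic-experiment generator makes the whole pipeline
exercisable and testable without any external data.

## What it does

1. **`synthetic_data`** — simulates a complete experiment: F inbred founder
   haplotypes, recombinant mosaic diploid cohorts (Poisson breakpoints on the
   cM axis), truncation survival whose log-odds depend on founder alleles at
   planted causal sites, and Poisson-depth / binomial-count pooled
   sequencing. Emits a truth record (per-window founder frequencies, realized
   survival) for validation.
2. **`io_formats`** — strict TSV readers/writers for the founder allele
   table, per-pool REF/ALT counts + sample sheet, genetic map (piecewise
   linear bp↔cM), scan/QTL exports (TSV + BED), and gene counting in a GFF3
   interval.
3. **`haplotype_inference`** — 1.5 cM windows stepped at 0.05 cM; per
   (window, sample) the founder mixing proportions solve a weighted least
   squares problem constrained to the probability simplex (non-negative,
   sum-to-one), weighted by read depth.
4. **`genome_scan`** — arcsine-square-root transform of the proportions, then
   a balanced replicate × haplotype × treatment ANOVA per window; the
   statistic is MS(H×T)/MS(R×H×T) on ((F−1)(T−1), (R−1)(F−1)(T−1)) df,
   reported as −log10(P).
5. **`peak_calling`** — per-chromosome LOESS (local quadratic, tricube
   weights), QTL calls above a genomewide threshold (default 4), 3-drop
   confidence intervals, interval widths in Mb/cM, and per-founder
   selected-minus-control shift tables.
6. **`phenotype_summaries`** — survival percentages (half-up rounding),
   midpoint death-time imputation with censoring, Welch's t-test.

## CLI

```bash
xqtl simulate --config sim.yaml --out simdir [--seed N]
xqtl haplofreq --panel founders.tsv --samples sample_sheet.tsv --map map.tsv \
     --out freqs.tsv [--window-cm 1.5 --step-cm 0.05 --min-snps 10 --weights depth|equal]
xqtl scan --freqs freqs.tsv --samples sample_sheet.tsv --out scan.tsv \
     [--error-stratum three-way|pooled]
xqtl call-peaks --scan scan.tsv --map map.tsv --out outdir \
     [--freqs freqs.tsv --samples sample_sheet.tsv --threshold 4 --drop 3 --span 0.04]
xqtl pheno-summary --counts survival.tsv --out summary.tsv
```

A minimal `sim.yaml`:

```yaml
n_founders: 8
chromosomes:
  - {name: chr1, length_bp: 25000000, cm_per_mb: 2.0}
snp_density: 60          # SNPs per Mb
breakpoint_rate: 0.5     # per cM per transmitted genome
cohort_size: 700
pool_size_selected: 300
pool_size_control: 300
coverage: 40
n_replicates: 4
seed: 1
survival_model:          # omit for a null experiment
  chrom: chr1
  position_bp: 12500000
  founder_effects: [4.5, 0, 0, 0, 0, 0, 0, 0]
  baseline_logit: -1.7
```

## Notes

- Coordinates are 1-based inclusive bp everywhere except BED output.
- The scan treats each (replicate, sex) sample pair as an independent
  replicate; sex is not a model term.
- The LOESS span is expressed as a fraction of a chromosome's windows;
  span × chromosome length (cM) is the effective smoothing width. The
  default 0.04 corresponds to ~2 cM on a 50 cM arm and was chosen so that
  null simulations at paper-like scale exceed the threshold-4 genomewide
  rate ~5% of the time.
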