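# xenomark

Epigenomic biomarker discovery pipeline for enrichment-based DNA methylation
data (MeDIP-seq style), built around a paired tumor-xenograft / normal-tissue
study design with chemotherapy-response phenotypes.

The package implements, end to end:

- **Absolute methylation estimation** from window-level fragment counts:
  library scaling (CPM), copy-number factors from CpG-free coverage in 1 Mb
  bins, CpG-density enrichment-profile calibration against reference
  high-methylation regions (mean > 0.9, variance < 0.05), direct inversion of
  the enrichment mean model into clamped beta values, promoter-window PCA QC
  and bisulfite-concordance summaries (`xenomark.quantify`).
- **Negative-binomial GLM likelihood-ratio tests** per 250-base window:
  group differences (tumor vs normal DMRs) and quantitative association with
  log relative tumor volume (response DMRs), with Benjamini-Hochberg FDR,
  threshold filtering (FDR < 1e-4, |delta| > 0.20) and
  **large hypomethylated block** calling (>= 1 Mb, >= 20% mean drop)
  (`xenomark.dmr`).
- **ROI annotation and enrichment odds ratios** (promoters = TSS +/- 2 kb,
  CpG islands, arbitrary BED sets), genome-wide-background odds ratios with
  exact Fisher p-values, and prioritized genomic-distribution summaries
  (`xenomark.annotation`).
- **Expression integration and biomarker triage**: probe quality filtering
  and collapsing, expression ratios to the normal median, and the
  three-stage cascade — promoter response-DMR (p < 0.01) -> methylation/volume
  Spearman (p < 0.05) -> opposite-sign expression/volume Spearman (p < 0.05)
  (`xenomark.expression`).
- **Clinical validation statistics**: qMSP control normalization,
  exact/asymptotic Mann-Whitney comparison, maximum-accuracy threshold
  classification (positives = non-responders), Kaplan-Meier curves and the
  log-rank test (`xenomark.validation`).
- **Synthetic data generation** for every input above — CpG-density-dependent
  counts with background, CNV and NB noise; planted hypomethylated blocks,
  focal promoter hypermethylation and response-coupled promoters;
  anti-correlated expression; tumor-volume phenotypes
  (V = 1/2 · length · width²; response categories at T/C 9 / 30 / 78%); and a
  matched validation cohort with censored survival (`xenomark.synthetic`).

## CLI

All stages run from one YAML config and share a working directory:

```bash
xenomark run-all --config configs/demo.yaml --seed 17 --outdir out/
# or stage by stage:
xenomark simulate --config configs/demo.yaml --outdir out/
xenomark quantify --outdir out/
xenomark dmr --outdir out/
xenomark rdmr --outdir out/
xenomark lhb --outdir out/
xenomark enrich --outdir out/
xenomark triage --outdir out/
xenomark validate --outdir out/
```

Outputs are plain TSV/BED/JSON: the window grid (BED4 + island flag),
count and beta matrices, DMR/rDMR tables with LRT statistics and FDR, LHB
intervals, enrichment odds ratios, the candidate-gene table and the
validation report. Reruns with the same config and seed are byte-identical.

Config sections (see `configs/demo.yaml` for a complete example): `genome`
(chromosome lengths, window size, CpG mixture model), `methylome` (sample
count, planted blocks and couplings), `counts` (depth, enrichment profile,
dispersion), `expression`, `cohort`, `thresholds`, and the master `seed`.

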