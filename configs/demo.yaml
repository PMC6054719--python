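# Demo pipeline configuration: a small two-chromosome genome with one planted
# hypomethylated block, focal promoter hypermethylation and response-coupled
# promoter genes. Run with:
#   xenomark run-all --config configs/demo.yaml --seed 17 --outdir out/
seed: 17

genome:
  chrom_lengths:
    chr1: 2000000
    chr2: 1600000
  window_size: 500
  cpg_model:
    background_mean: 2.0
    island_mean: 15.0
    island_rate: 0.8
    island_halfwidth: 1
    promoter_spacing: 20000

methylome:
  n_models: 12
  baseline_beta: 0.8
  island_beta: 0.1
  # keep planted blocks a modest fraction of the genome: enrichment
  # calibration assumes reference high-methylation regions stay high, so
  # genome-scale hypomethylation attenuates the estimated deltas
  lhb:
    - {chrom: chr1, start: 800000, end: 1900000, delta: -0.45}
  n_focal_hyper: 3
  focal_delta: 0.6
  n_rdmr_genes: 2
  coupling_slope: 0.1
  rdmr_b0: 0.35
  noise_sd: 0.02

counts:
  depth: 30.0
  f_max: 60.0
  k: 2.0
  background_rate: 1.0
  dispersion: 50.0
  library_jitter: 0.1

expression:
  coupling: -4.0
  noise_sd: 0.15

cohort:
  n_pairs: 20
  group_means: [7.4, 13.9]
  group_sd: 3.0
  hazard_ratio: 3.0
  censor_rate: 0.2

thresholds:
  dmr_fdr: 1.0e-4
  dmr_delta: 0.20
  rdmr_p: 0.01
  corr_p: 0.05
  lhb_min_size: 1000000
  lhb_min_drop: 0.20
  lhb_tile_size: 100000
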