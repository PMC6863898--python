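# Small end-to-end configuration: two chromosomes of 400 SNPs, 400
# subjects, 200 permutations per region.  Completes in a few minutes on a
# single CPU and exercises every pipeline stage.
master_seed: 20240601
out_dir: smoke_out
window: 200
step: 100
synthetic:
  n_subjects: 400
  validation_n_subjects: 400
  bp_start: 1000000
  bp_step: 5000
  layout:
    - chrom: "1"
      blocks: &twenty_blocks
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
        - {n_snps: 20, rho: 0.7, maf_range: [0.1, 0.5]}
    - chrom: "2"
      blocks: *twenty_blocks
  n_causal: 4
  per_variant_h: 0.01
  prevalence: 0.5
  balanced: true
  missing_rate: 0.02
  platform_keep_fraction: 0.7
priors:
  h_min: 1.0e-4
  h_max: 0.05
  target_size_min: 1
  target_size_max: 5
  max_model_size: 5
mcmc:
  n_iter: 2000
  burn_in: 0.2
  thin: 10
  trait_mode: binary
discovery:
  alpha: 0.1
  b_target: 200
  batch: 50
validation:
  alpha: 0.05
  b: 200
  n_candidates: 3
consensus:
  top_region_frac: 0.2
  top_snp_frac: 0.05
  window_bp: 100000
  r2_threshold: 0.2
plots: true
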