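# Full-protocol parameter set for real mean-genotype data: 1000-SNP
# windows overlapping by 500, one million MCMC iterations per region,
# 100,000 discovery permutations at alpha = 0.1 (Bonferroni over regions),
# 1000 validation permutations at alpha = 0.05.  Point the 'data' block at
# your own files; expect a long run.
master_seed: 1
out_dir: full_out
window: 1000
step: 500
data:
  discovery:
    genotype: discovery_genotypes.txt
    position: discovery_positions.txt
    phenotype: discovery_phenotypes.txt
  validation:
    genotype: validation_genotypes.txt
    position: validation_positions.txt
    phenotype: validation_phenotypes.txt
priors:
  h_min: 1.0e-4      # uniform prior on variance explained: 0.01% ...
  h_max: 0.01        # ... to 1%
  target_size_min: 1 # expected 1-5 relevant SNPs per 1000-SNP region
  target_size_max: 5
  max_model_size: 5
mcmc:
  n_iter: 1000000
  burn_in: 0.2
  thin: 10
  trait_mode: binary
discovery:
  alpha: 0.1
  b_target: 100000
  batch: 100
validation:
  alpha: 0.05
  b: 1000
  n_candidates: 12
consensus:
  top_region_frac: 0.05
  top_snp_frac: 0.01
  window_bp: 100000
  r2_threshold: 0.2
plots: true
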