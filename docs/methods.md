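# Methods

`regionbvs` implements a region-based Bayesian variable-selection (BVS)
scan for case–control GWAS.  This note records the model, its priors and
numerical choices, what the synthetic-data generator does and does not
emulate, and the scaled-down problem sizes used by the test suite.

## Model

Each chromosome's ordered SNPs are cut into sliding windows of `window`
SNPs (default 1000) advancing by `step` (default 500, i.e. 50% overlap).
Windows at a chromosome end are anchored to the last `window` SNPs so
that all full-chromosome windows have equal size; chromosomes shorter
than one window form a single all-SNP region.  Equal-sized windows keep
the sparsity prior comparable across regions.  The exact trailing-window
rule is a design choice of this package — distance-based or LD-adaptive
windows are out of scope.

Within a region of p SNPs with dosage columns x_j (0/1/2 minor-allele
copies, mean-imputed), the trait is modelled through a latent liability
(probit link for binary traits; for continuous traits the response is
used directly and the residual variance is fixed at 1):

    z_i = mu + sum_{j in gamma} beta_j x_ij + eps_i,   eps_i ~ N(0, 1)
    y_i = 1  iff  z_i > 0

gamma is the unknown set of "relevant" SNPs.  Priors:

* beta_j | gamma, h ~ N(0, sigma_a^2) with
  sigma_a^2 = h / ((1 − h) · sum_{j in gamma} s_j^2), where s_j^2 is the
  sample variance of x_j.  This ties the hyper-parameter h to the
  proportion of phenotypic variance explained by the included SNPs under
  unit residual variance.  h is uniform on [h_min, h_max], default
  [10^-4, 10^-2] (0.01%–1%): the per-region signal plausible for a highly
  polygenic trait in which a hundred-odd loci share ~18% of variance, so
  a single variant accounts for ~0.17%.
* P(j in gamma) = pi i.i.d., with log10(pi) uniform on
  [log10(L/p), log10(min(U/p, 0.9))], defaults (L, U) = (1, 5): between 1
  and 5 relevant SNPs expected per region, scaled by the region size.
* |gamma| is hard-capped at `max_model_size` (default 5); proposals
  beyond the cap are rejected.  The joint prior on (gamma, pi) is the
  truncated product pi^|gamma| (1−pi)^(p−|gamma|); the pi-dependent
  truncation constant is omitted from acceptance ratios and the log-joint
  trace, i.e. the effective prior is the untruncated form restricted to
  the cap — a deliberate simplification, stated here for exactness.
* mu ~ N(0, 100): an effectively vague intercept.

## Posterior computation

With (mu, beta) integrated out analytically, the marginal likelihood of a
response vector w given (gamma, h) is a multivariate-normal density whose
log is evaluated with a small Cholesky factorization (Woodbury form; cost
O(n·|gamma|^2) per evaluation).  One MCMC sweep comprises:

1. a Metropolis–Hastings move on gamma, choosing uniformly among add
   (uniform over excluded SNPs), remove (uniform over included) and
   switch (one of each), accepted by the marginal-likelihood ratio times
   the prior ratio times the add/remove proposal-asymmetry correction
   (p−k)/(k+1);
2. a reflected Gaussian random walk on h inside its prior box (step
   default (h_max−h_min)/8), or an independent redraw on a user-supplied
   h grid;
3. a reflected random walk on log10(pi) (step default 0.25), accepted by
   the prior-on-gamma ratio alone;
4. binary traits only: conjugate Gibbs draw of (mu, beta) given the
   latent liabilities, then a truncated-normal Gibbs draw of each z_i
   (positive iff y_i = 1) — naive rejection near the bulk, exponential
   rejection in deep tails, both exact.

PIPs are post-burn-in inclusion frequencies (no Rao-Blackwellization, a
non-goal).  Defaults: 20% burn-in, thinning 10 for traces, 10^5
iterations per run (the full protocol uses 10^6); chains are reproducible
from a single seed, and multi-chain runs derive independent chain seeds
from it.  Monomorphic columns cannot enter the model (sigma_a^2 would be
undefined) and are reported with PIP 0.  Convergence is monitored by the
Gelman–Rubin potential scale reduction factor sqrt((n−1)/n + B/(nW)) on
the h and log-joint traces, with the conventional < 1.04 bound; a
zero-variance chain triggers a warning (inf when chains disagree with no
within-chain spread).

No covariate or population-structure adjustment is performed: regions are
modelled jointly, which multi-SNP Bayesian regressions tolerate better
than single-SNP tests, and the intended inputs are homogeneous-ancestry
panels.

## Significance

The region statistic is the sum of PIPs (discovery; regions have equal
SNP counts) or the mean of PIPs (validation; mapped regions vary in
size).  Significance is assessed by phenotype permutation: each
permutation reruns a full, fresh chain with a seed derived
deterministically from (master seed, region, permutation index), so
results do not depend on batching or early stopping.  The empirical p is
r/B with r the count of permuted statistics >= the observed one (ties
count against significance; r = 0 is reported textually as "< 1/B"; an
add-one estimator (r+1)/(B+1) is available).  Discovery uses a target of
B = 100,000 permutations against a Bonferroni threshold alpha/n_regions
with alpha = 0.1; with 1266 regions this is 0.1/1266 ≈ 7.9×10^-5.
Permutations for a region stop early once r/B_target already exceeds the
threshold — the most-favorable-completion bound, which provably cannot
flip the significance decision relative to exhausting the budget
(a looser "running p exceeds threshold" rule would not have this
property).  Batch size between stop checks defaults to 100.

Validation re-tests candidate regions on an independent cohort: the
candidate's base-pair interval (ends inclusive) is mapped onto the
validation panel, and a mean-of-PIPs permutation test with B = 1000 runs
against alpha = 0.05 / n_candidates.  The consensus analysis compares two
permutation-free scans: top 5% of regions by sum of PIPs, top 1% of SNPs
by PIP within each, all cross-dataset pairs on the same chromosome within
100 kb, LD (squared dosage correlation) computed in a designated
reference panel; a pair with r^2 >= 0.2 (configurable — no canonical
cutoff exists, and reported "in LD" pairs span r^2 0.11–0.93) joins the
consensus set.  Pairing is all-within-window rather than nearest-only and
is symmetric, so the consensus percentage does not depend on dataset
order.  Pairs absent from the reference are excluded from the percentage
denominator and logged.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
nothing more:

* **LD blocks** via a Gaussian copula: within a block, haplotype latents
  share an exchangeable correlation rho (an AR(1) option exists behind a
  flag); an allele is minor when its latent falls below the normal
  quantile of the SNP's MAF (drawn uniformly from the block's MAF range);
  a dosage is the sum of two independent haplotypes.  The implied dosage
  correlation has the closed form
  r = (Phi2(t,t;rho) − maf^2)/(maf(1−maf)), t = Phi^{-1}(maf), which the
  tests use as an oracle.  Blocks are independent; positions are
  synthetic and equally spaced (only ordering and distances matter
  downstream).
* **Phenotype** from a liability-threshold model: each causal SNP
  contributes beta · standardized dosage with beta chosen so the SNP
  explains exactly `per_variant_h` of liability variance (default 0.0017,
  the per-locus share when ~18% of variance spreads over ~108 loci).
  Cases exceed the empirical liability quantile at 1 − prevalence.
  `balanced=True` records a case/control-balanced subject subset (whole
  minority class plus an equal random draw of the majority), which the
  pipeline applies to genotypes and labels.
* **Missingness** masks entries i.i.d. (columns that end up fully masked
  are redrawn a few times, then rejected), creating the condition for
  mean imputation.  **Platform subsets** keep a uniform fraction of SNP
  columns with positions unchanged, emulating a second genotyping chip.

Not emulated: recombination maps, population structure/admixture,
genotyping error, imputation panels.  Passing tests therefore demonstrate
correctness of the machinery under idealized LD and ancestry homogeneity,
not robustness to stratification or platform artefacts.

## Test-suite problem sizes

The acceptance-style checks run the full protocol at desk scale, chosen
once as the smallest sizes at which each property is cleanly expressed:

* convergence: one 200-SNP region (ten rho = 0.7 blocks), 500 balanced
  subjects, one causal SNP at per-variant h = 0.0017, two chains of 10^5
  iterations;
* enumeration oracle: 10 SNPs, model size <= 2, 3-point h grid, fixed
  sparsity, 5×10^5 iterations, tolerance 0.03 on every PIP;
* calibration: 200 independent null regions (48 subjects, 10 SNPs),
  B = 200 full-budget permutations of 1000-iteration chains;
  early-stop/full-budget decision equivalence on 20 further regions;
* recovery/replication: 20 replicates of a 200-SNP single-chromosome
  genome (40-SNP windows, 50% overlap), 300 balanced subjects, four
  causal SNPs each explaining 3% of liability variance (12% aggregate —
  a deliberately well-powered planted signal; the discovery permutation
  budget is 40 per region), with replication on an independent cohort of
  the same size at alpha = 0.05;
* end-to-end determinism: byte-identical TSV outputs of repeated pipeline
  runs from one master seed.

`scripts/acceptance.py` reruns the convergence setting for three master
seeds derived from `--seed` and reports the largest Gelman–Rubin value of
the h trace.

## Known limitations

* The probit latent update makes binary-trait iterations O(n_subjects);
  a 10^6-iteration run on ~5000 subjects takes hours per region — the
  full protocol is a cluster-scale computation (regions are independent
  and trivially parallel).
* PIP estimation by inclusion frequency is noisier than
  Rao-Blackwellized estimates at equal chain length.
* The trailing-window rule, the permutation tie rule (>=), the LD r^2
  cutoff and the all-within-window pairing are declared conventions;
  alternatives exist and are configurable where sensible.
* The sparsity prior's expected model size (1–5) applies per region of
  any size, so very small regions carry a proportionally dense prior.
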