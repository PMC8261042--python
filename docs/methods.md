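# Methods

`tickblup` implements a multi-country, multi-breed genomic evaluation of
cattle tick resistance as a fully testable desk-scale analysis: a
forward simulator generates populations with the statistical structure
such studies assume, and the evaluation stack — genotype QC,
population-genomic diagnostics, single-step GBLUP, Gibbs
variance-component estimation and LR-method validation — runs end to end
on the simulated data. This note records the models, their assumptions,
the defaults, and what the desk-scale experiments do and do not show.

## The evaluation model

Tick infestation recorded in different breeds (or countries) is treated
as a set of distinct, genetically correlated traits: breed-as-trait.
For breed *b* the records follow

    y_b = X_b β_b + Z_b u_b + W_b p_b + e_b,

with fixed effects β_b (contemporary group; covariates zebu fraction,
expected heterozygosity, age linear and quadratic), additive genetic
effects u_b, permanent-environment effects p_b for breeds with repeated
counts, and residuals e_b. Across breeds,

    u ~ N(0, Σ_u ⊗ H),   p_b ~ N(0, I σ²_p(b)),   e_b ~ N(0, I σ²_e(b)),

where Σ_u is the t×t genetic covariance matrix. Because every animal
belongs to exactly one breed, PE and residual effects are necessarily
uncorrelated between traits. H combines pedigree and genomic
relationships; its inverse has the single-step form

    H⁻¹ = A⁻¹ + [0 0; 0 (0.95 G + 0.05 A22)⁻¹ − A22⁻¹],

with A the numerator relationship matrix (tabular method, inbreeding
included), A22 its genotyped block, and G the VanRaden method-1 genomic
matrix, G = ZZ′ / 2Σp_k(1−p_k), using current allele frequencies
averaged across breeds. The 0.95/0.05 blend guarantees invertibility
and leaves a small polygenic share to the pedigree; no further tuning of
G toward A22 is applied. With no genotyped animals H⁻¹ reduces to A⁻¹
exactly; with G = A22 the whole evaluation reduces to pedigree BLUP —
both identities are enforced by tests.

The frequency policy for G defaults to the unweighted mean of per-breed
allele frequencies; a pooled-sample policy is available, and the choice
is recorded in the matrix metadata. Missing dosages are mean-imputed per
marker (within breed) before G.

### Solving

The mixed-model equations are assembled sparsely (additive block
H⁻¹ ⊗ Σ_u⁻¹ in animal-major order, per-record residual weights
1/σ²_e(b)) and solved by Jacobi-preconditioned conjugate gradients,
relative tolerance 1e-10, maximum 10,000 iterations; non-convergence
raises with the residual trace. Identifiability: with an intercept in
the model the first level of each fixed factor is constrained to zero;
a factor-only parameterisation (no intercept) is used otherwise. Age
enters centred and scaled so the quadratic term stays well conditioned.
Animals in the pedigree without records enter through the additive
block only. Univariate (within-breed) evaluations use the breed's
marginal variances from the same Σ_u, so multi- and single-trait
predictions share the same dispersion scale.

### Variance components

Σ_u, σ²_p(b) and σ²_e(b) are estimated by single-chain Gibbs sampling:

* locations (β, u, p) by Gauss–Seidel sweeps over the MME, with each
  animal's t breeding values drawn jointly from their t-dimensional
  conditional (this block update removes the within-animal cross-trait
  autocorrelation that otherwise dominates the mixing time of the
  genetic covariances);
* Σ_u from its inverse-Wishart full conditional,
  IW(ν₀ + q, S₀ + U′H⁻¹U) with q the number of animals;
* each σ²_p, σ²_e from scaled inverse chi-square full conditionals.

Priors are proper and weakly informative by default: ν₀ = t + 2 with
S₀ = 0.1·diag(phenotypic variance) for Σ_u; ν = 3 and scale 0.5 (resp.
0.1) times the phenotypic variance for residual (resp. PE) variances.
Starting values put h² at 0.25 with zero correlations. All of these are
configurable.

The default desk-scale protocol is 20,000 cycles, 4,000 burn-in,
thinning 10; a production-scale 1,000,000 / 100,000 / 50 protocol is a
parameter change. Summaries report posterior means with time-series
standard errors from the initial-positive-sequence autocorrelation
estimator, effective sample sizes, and Geweke's z comparing the first
10% to the last 50% of the chain. Heritability, repeatability and
genetic correlations are derived per draw and then summarised.

Correctness of the sampler is tested directly: with variances frozen,
the location draws must match the dense Gaussian posterior N(C⁻¹r, C⁻¹)
(including a case with PE on a trait that is not first in the layout);
with locations frozen, the Σ_u and σ² draws must match their closed-form
conditional means. The whole chain is bit-reproducible given the seed:
every random number comes from pools pre-generated from one
`SeedSequence`, and records are canonically ordered before sampling.

### LR-method validation

Whole (w) and partial (p) evaluations are compared on validation
animals: ρ_w,p = corr(û_w, û_p), which estimates acc_p/acc_w; the
predictive ability r(y*, û_p) with y* = y − Xβ̂ − Wp̂ from the whole fit
(repeated records averaged after adjustment); and the dispersion slope
β_w,p of û_w on û_p (1 = unbiased, <1 = inflated). Partial data are
formed by old-young (youngest third of the target breed's phenotyped
animals masked, oldest two thirds retained; ties broken by id) or
other-pops (every target-breed phenotype masked). All statistics are
computed over validation animals only; with simulation truth available
the population accuracies corr(û, u) are reported alongside.

## The simulator

The generator reproduces the statistical structure of a multi-breed
tick-resistance study, not tick biology.

* **Ancestral pool and LD.** One pool of ancestral haplotypes (default
  60) with AR(1) Gaussian-copula autocorrelation along each chromosome
  (default φ = 0.8) provides baseline LD; the map is uniform at 1 cM
  spacing unless supplied. Founder haplotypes are recombinant mosaics of
  the pool (segment-switch probability 0.05 per interval), which puts
  mean adjacent-marker r² in the 0.2–0.35 range observed on dense
  bovine panels.
* **Breed divergence.** Each breed passes through a bottleneck of
  ~1/F pool haplotypes, a Balding–Nichols-style drift with a single
  interpretable knob: the expected fixation index between two breeds at
  divergence F is ≈ F (verified against Hudson's estimator). Breeds at
  F = 0 share the pool itself, so their signed LD vectors agree almost
  perfectly (persistence of phase → 1), while panels simulated from
  independent pools show none — the two calibration extremes.
* **Pedigree and composites.** Discrete random-mating generations per
  breed; meioses recombine with Haldane probabilities. Composites are
  crossed from previously defined breeds through dyadic admixture
  fractions (e.g. 3/8 zebu); realistic breeding schemes (F1, backcross,
  composite) are expressed as chained composite specs. Every animal
  carries its pedigree-expected zebu fraction and heterosis coefficient
  (1 − Σ s_i d_i over parental breed fractions).
* **Breeding values.** A random QTL subset of the markers gets
  multivariate-normal per-trait effects with the target genetic
  correlation matrix; dosage-weighted sums are rescaled per trait to hit
  the target genetic variance either in the trait's recorded cohort
  (default) or in the pedigree founders (`scale_to_founders`), i.e. on
  the evaluation model's own base-population scale — the choice used in
  the recovery experiments.
* **Phenotypes.** Latent records are CG effect + covariates + u + pe +
  e with variances implied by heritability/repeatability and a
  phenotypic variance of 1 on the latent (log-count) scale. Modes:
  the latent value directly (log counts), a 0–5 score via
  count = round(10^y − 1) and the field binning (0; ≤10; 11–30; 31–80;
  81–150; >150), or per-animal averages of repeated records. Covariate
  effect sizes and age distributions are free parameters of the
  generator (defaults: zebu −0.3, heterosis −0.1, age +0.1/−0.05 on the
  centred scale), not estimates of any real population.

All randomness descends from one seed through a fixed
`SeedSequence.spawn` order (founders, pedigree, breeding values,
phenotypes), so stages rerun reproducibly.

What the simulator does **not** emulate: real SNP-array ascertainment,
tick-species mixtures, selection, overlapping generations,
genotype-by-environment structure, or sequence-level mutation. Passing
tests therefore demonstrate the correctness and calibration of the
estimation machinery under the assumed model class, not the field
performance of tick-resistance selection.

## Desk-scale experiments and their problem sizes

* **Variance-component recovery** (`experiments.recovery_experiment`):
  a taurine founder breed and its 5/8-taurine : 3/8-zebu composite
  (built through explicit F1 and backcross cohorts), 1,500 phenotyped
  animals each, 200 genotyped per breed, 2,000 markers / 200 QTL,
  simulated truth h² = 0.30/0.40 and r_g = 0.80, chain 20,000 cycles.
  The founder×composite pair mirrors the configuration in which
  cross-breed genetic correlations are identifiable in practice (shared
  ancestry contributes both pedigree and genomic links); with unrelated
  breeds and genomic-only ties the r_g likelihood is nearly flat, and
  its posterior mean sits visibly above a truth of 0.8 because the
  parameter is bounded at 1 — an intrinsic small-information effect, not
  an estimator defect (it persists when data are drawn exactly from the
  fitted model). Tests require posterior means across 20 replicates
  within ±0.1 of truth and ≥80% coverage of the 90% credible intervals.
* **LR calibration** (`experiments.lr_experiment`): single-breed
  old-young validation at n = 2,000, h² = 0.3, true variances supplied;
  across 20 replicates the mean dispersion slope must lie in [0.9, 1.1]
  and mean ρ_w,p must track mean(acc_p/acc_w) within 0.05.
* **Phase-persistence calibration**: 1,000 founders, 5,000 markers;
  same-pool pairs must exceed R = 0.95, independent pools stay below
  |R| = 0.1.

## Numerical and implementation choices

* PLINK bed/bim/fam I/O is implemented directly (2-bit SNP-major codec,
  breed stored in the family id); a hand-coded byte fixture anchors the
  layout.
* Unphased LD uses a vectorised two-locus EM (50 iterations or
  Δ < 1e-8); phased panels use haplotype counts, which equal the
  brute-force indicator correlation exactly.
* The Gibbs kernel is numba-compiled, walks H⁻¹ in split form (sparse
  pedigree part + dense genotyped-block correction) and reuses scratch
  buffers; chains are deterministic given the seed.
* HWE uses the 1-df chi-square goodness-of-fit test (monomorphic
  markers return p = 1); the exact test adds nothing at the panel sizes
  and 1e-7 threshold used here.
* CG trimming is a single pass with the SD computed before trimming;
  group-size filtering happens first.
* Repeated-record pre-adjustment (the "averaged count" treatment) uses
  OLS fixed effects, not a mixed-model solution: its role is one
  fixed-effect-free value per animal, and the original variance ratios
  are unstated.
* Degenerate inputs are reported, not silently zeroed: undefined LD
  pairs are flagged, zero-variance correlations return NaN with NA cells
  and warnings in rendered tables, and empty QC results raise.

## Known limitations

* The desk-scale chains have effective sample sizes of tens, not
  hundreds; credible-interval endpoints carry Monte-Carlo noise. The
  production protocol (1M cycles) is available but not exercised in
  tests.
* Score-mode traits are analysed on the observed 0–5 scale, so their
  heritabilities are attenuated relative to the latent scale — visible
  in the demonstration study and consistent with scores being less
  informative than counts.
* Genetic correlations between weakly linked breeds are estimable only
  through cross-breed genomic relationships and remain wide; this is a
  property of the design, faithfully reproduced.
* The multi-breed base-population incompatibility between G (current
  pooled frequencies) and A (within-line founders) is inherited from
  the method itself; no metafounder or G-tuning correction is applied.
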