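# Methods

## Model

### Likelihood

For two traits with standardized genotypes and unit-variance phenotypes,
`Y_t = X_t β_t + ε_t` with residual variance `1 − h_t²`. When the two
GWAS cohorts share `N_s` individuals, their residuals covary by the
environmental covariance `ρ_e` (per overlapping individual), so the
marginal effect estimates of the two GWAS have correlated sampling
noise. Writing `s = N_s ρ_e / √(N₁N₂)` and deriving
`cov(X₁'ε₁/N₁, X₂'ε₂/N₂) = N_s ρ_e D / (N₁N₂)` gives, per LD block,

```
(β̂₁; β̂₂) | (β₁; β₂) ~ N( (I₂ ⊗ D)(β₁; β₂),  Ω ⊗ A ),
Ω = [[1/N₁, s/√(N₁N₂)], [s/√(N₁N₂), 1/N₂]],  A = D + a·I.
```

`D` is the Pearson LD correlation estimated from a reference panel
(mean-imputed, standardized dosages); the diagonal inflation `a = 0.1`
guards against panel/GWAS mismatch in high LD and keeps `A` positive
definite. The regularization enters every covariance term while the
mean retains `D`. `Ω` is positive definite whenever `|s| < 1`, which
holds for any `0 ≤ N_s ≤ min(N₁, N₂)` and `|ρ_e| ≤ 1`; an `Ω` built
with the cross term `s` itself rather than `s/√(N₁N₂)` would already be
indefinite under complete overlap, which is why the scaled form is used.

`N₁, N₂` are scalars per trait (median of per-variant sample sizes).
When the overlap count is unknown, `approximate_ns` applies the
min-per-shared-cohort rule, and `estimate_overlap_term` estimates `s`
from the cross-trait LD-score regression: the intercept of `z₁ⱼz₂ⱼ` on
LD scores estimates `N_s ρ_pheno/√(N₁N₂)`; subtracting the genetic part
implied by the slope (`slope · M · N_s/(N₁N₂)`) leaves the environmental
coupling. Plain (optionally weighted) least squares is used; `1/ℓ`
weights reduce the variance from correlated SNPs. Direct (N_s, ρ_e)
input takes precedence over the regression estimate.

### Prior

Each SNP's bivariate effect belongs to one of four classes — null for
both traits, trait-1-only, trait-2-only, or shared with correlation —
with class probabilities `(p₀..p₃) ~ Dirichlet(1)`. Each non-null class
is a truncated stick-breaking (Dirichlet-process) mixture of K
components: `V_k ~ Beta(1, α_c)`, `π_k = V_k ∏_{m<k}(1−V_m)`, with the
final component absorbing the residual mass, and an independent
concentration `α_c ~ Gamma(0.1, 0.1)` per class. Components carry their
own variances — `σ₁ₖ² ~ IG(0.5, γ_k)`, `γ_k ~ G(0.5, 0.5)` (trait 2
analogous), and for the shared class a full 2×2 covariance with the
half-t construction `Σ_k ~ IW(2v+1, B_k)`, `B_k = 4v·diag(δ_k, λ_k)`,
`δ_k, λ_k ~ G(0.5, 0.5)` — so heritability per component and the local
effect correlation `r_k` both vary across the genome. The half-t
degrees-of-freedom parameter `v` is not pinned down by the model
description; the conventional `v = 2` is the default and it is exposed
in `PriorConfig`.

K defaults to 1,000; only a handful of components ever receive
appreciable posterior mass, so tests and the bundled acceptance study
run at K = 20 (raising K at these problem sizes changes nothing but the
runtime).

### Sampler

A blocked Gibbs sampler sweeps SNPs sequentially within each LD block.
All cross-SNP coupling flows through running residuals
`r_t = D A⁻¹ β̂_t − H β_t` with `H = D A⁻¹ D`, so each SNP's conditional
likelihood is a 2×2 Gaussian with precision `P = H_jj · Ω⁻¹` and natural
parameter `b = Ω⁻¹ v_j`. The assignment `z_j` is sampled with `β_j`
integrated out analytically (collapsed, which improves mixing); `β_j`
is then redrawn from its conjugate bivariate-normal conditional, and
residuals are updated incrementally. Global updates are all conjugate:
Dirichlet for `p`, Beta for sticks, Gamma for concentrations and
hyper-scales, inverse-gamma for trait variances, inverse-Wishart for
shared covariances (a vectorized 2×2 Bartlett sampler, cross-checked
against `scipy.stats.invwishart`). Empty components are refreshed from
their priors, which the truncated stick-breaking updates require;
components are never relabeled.

Protocol: 1,000 iterations, 200 burn-in, posterior summarized by the
mean of kept draws. Runs are deterministic given the seed; every
(iteration, block) pair gets its own RNG substream derived from the
master seed, so blocks could be processed concurrently without changing
the draw sequence. The hot sweep is a numba kernel; its conditional
distributions are validated against quadrature and closed-form oracles
and the whole chain against a prior-invariance (joint-distribution)
test.

Two numerical points deserve note:

* **Stick fractions in log space.** With `α ~ Gamma(0.1, 0.1)`, draws
  of `V ~ Beta(1, α)` routinely have `1 − V` below double precision;
  clipping V would truncate `−log(1−V)` and systematically inflate the
  α updates (this is detectable by the prior-invariance test). Sticks
  are therefore sampled jointly with their exact `−log(1−V)` via the
  Gamma representation and the small-shape log-gamma identity, and both
  the weights and the α updates consume the exact logs.
* **Variance floors.** Component variances are floored at 1e-12 to keep
  densities finite; gamma draws are floored at 1e-300 before division.

### Ablation and decoupling

`mode="single1"`/`"single2"` fits one trait alone (classes {null, that
trait}), and `run_decoupled` runs both single-trait fits with
independent RNG substreams. This is the "shared class disabled"
ablation: note the joint four-class model with `p₃ = 0` does *not*
factorize across traits (the categorical over {null, t1, t2} couples
them through the shared Dirichlet), so the ablation is defined as the
factorized single-trait special case. With `s = 0` this makes trait-1
results bit-identical under any change to trait-2 inputs, which is
asserted in the tests.

### Scoring and evaluation

Scores are raw allele-count sums `Σ_j dosage_ij · effect_j` with
per-variant mean imputation of missing dosages; since evaluation is
correlation-based, per-SNP scaling conventions cancel. Accuracy is the
squared Pearson correlation between score and phenotype, identical to
the R² of `phenotype ~ score`. With a validation cohort, an OLS linear
combination of the two traits' scores can be fitted and applied to the
test cohort; covariate adjustment is out of scope.

## Simulator

The generator reproduces the statistical structure the model assumes,
with defaults set to the study conditions: M = 30,000 SNPs, 20,000
training individuals per trait (overlap 0, 10,000, or complete),
heritabilities 0.15/0.30, environmental covariance 0.2 under overlap,
mixture proportions (0.88, 0.02, 0.02, 0.01, 0.07), shared-class
correlations 0.9 and one of {0.5, 0.7, 0.9}, 10,000-individual
validation and test sets, a ~500-individual reference panel, and 10
replicates recorded in the manifest. The class-proportion reading "2%
per trait-specific class, remainder to the variable-correlation shared
class" is one of two arithmetically consistent readings of the design;
all five proportions are freely configurable.

* **Genotypes.** Per block, a latent Gaussian AR(1) process per
  haplotype is thresholded at Φ⁻¹(MAF) and two haplotypes are summed,
  giving Hardy–Weinberg dosages with within-block LD and independent
  blocks. The AR coefficient is drawn per block from (0.3, 0.95) by
  default: real genomes have strongly heterogeneous LD, and the
  cross-trait LD-score regression is identified through the spread of
  LD scores — with homogeneous blocks the scores span too narrow a
  range and panel noise in them attenuates the slope (errors in
  variables), biasing the intercept. A scalar coefficient is still
  accepted for controlled experiments. The implied dosage-scale
  correlation of the thresholded model is available in closed form
  (`latent_to_dosage_correlation`) and is what the LD tests check
  against.
* **Effects.** Classes are drawn iid from the mixture; per-class
  variances follow `h_t²/(M·(causal fraction for trait t))` with the
  shared-class cross-covariance `r·√(v₁v₂)`. Drawn effects are rescaled
  so the realized genetic variance on the training cohort equals the
  target heritability exactly.
* **Phenotypes.** Residuals are drawn jointly with covariance ρ_e for
  the first N_s (overlapping) individuals, projected orthogonal to the
  genetic values, and rescaled, so each trait's realized heritability
  is exact on the generating cohort and phenotypic variance is exactly 1.
* **Summary statistics.** Per-SNP regression of the standardized
  phenotype on the standardized dosage (`β̂` = Pearson correlation,
  `se = √((1−β̂²)/(n−2))`); an allele-count-scale emitter exists for
  I/O round-trips.

What the simulator does **not** emulate: real haplotype structure and
long-range LD, MAF-dependent architectures, population stratification,
binary traits, covariates, and imputation error. Passing tests
therefore establish internal correctness of the method under its own
generative assumptions and the direction of its comparative advantages,
not real-data effect sizes.

## Validation strategy

* **Conditional exactness.** On 1- and 2-SNP blocks, the collapsed
  class/component marginals match brute-force quadrature to 1e-6
  relative error, conditional moments match the closed-form conjugate
  posterior, and the compiled kernel's category frequencies match the
  analytic categorical within Monte-Carlo error at 10⁵ draws.
* **Joint-distribution (prior-invariance) test.** Independent replicate
  chains are initialized exactly from the prior and alternately
  re-simulate data given effects and resample all parameters given
  data; after a fixed number of transitions the recorded parameters are
  iid from the chain's invariant distribution, which must equal the
  prior if every conditional is correct. Kolmogorov–Smirnov tests
  against the known prior marginals of the class probabilities, stick
  concentrations, and variance hyper-parameters are Holm-adjusted over
  10 statistics. The replicate design is used because single-long-chain
  rank tests conflate the successive-conditional chain's extreme
  autocorrelation with error.
* **Study replication at desk scale.** M = 2,000, N = 5,000, 5
  replicates: the joint model beats the single-trait ablation on
  trait-1 test R² at shared correlation 0.9, the gain exceeds the gain
  at 0.5, posterior means correlate with true effects better than the
  marginal estimates, the overlap coupling is recovered within its
  replicate-mean standard error under complete overlap, and enabling
  the overlap term does not reduce accuracy. Problem sizes here and in
  `scripts/acceptance.py` are the package's desk-scale choices; the
  model itself has no dependence on them.

## Known limitations

* Two traits only; one LD panel (single population).
* The LDSC-based `s` estimate is noisy at small M (thousands of SNPs);
  it is reliable genome-wide, and the direct (N_s, ρ_e) route is
  preferred when overlap is known.
* Convergence is not adaptively monitored; the fixed 1,000/200 protocol
  is used, with class-count and heritability-proxy traces logged for
  inspection.
* Posterior class probabilities are weakly identified when signal is
  absent (a near-zero-variance causal component mimics the null class);
  posterior-mean effects, the quantity used for scoring, are unaffected.
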