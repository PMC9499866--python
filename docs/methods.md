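# Methods

`genedaly` implements a comparative risk-assessment pipeline for genetic
exposures: it estimates exposure–disease hazard ratios from cohort data,
classifies them as null or non-null with a spike-and-slab Bayesian
procedure, converts retained effects into attributable disability-adjusted
life years (DALYs) against a GBD-style rate table, and quantifies
uncertainty by the delta method and correlated multivariate-normal
resampling. All stages are exercised on synthetic cohorts with known
ground truth; no biobank or GBD accession is required.

## Hazard-ratio estimation

For each exposure–disease pair we fit a Cox proportional-hazards model
with calendar age as the timescale: the event time is the age at first
record of the disease, and individuals are censored at death or the
administrative end of follow-up. The model is additive in exposure level
(allele dosage 0/1/2, a binary top-decile score indicator, or a carrier
flag), with sex and any configured covariates adjusted for. Fitting is
delegated to `lifelines.CoxPHFitter` (Efron tie handling, Newton solver
capped at 100 steps with 1e-9 precision). Pairs that cannot be estimated —
no events, a monomorphic exposure, or failed convergence — are flagged
with a status code and excluded downstream, never silently dropped; the
minimum-event filter is a configurable parameter (`min_events`).

Left truncation and relatedness are deliberately not modelled in the
default configuration; delayed entry is available through the cohort
generator and `fit_cox` handles it via a risk-set entry column when
present. Per-cohort estimates of the same pair are combined by
fixed-effects inverse-variance-weighted meta-analysis
(w_k = 1/se_k², combined SE (Σw_k)^-1/2).

A composite mortality score follows the linear-predictor construction:
one Cox model of all-cause death on all score exposures plus sex and
covariates, with each individual's linear predictor evaluated at sex = 0.5
and covariates = 0 so the result reflects the scores alone. The predictor
is itself usable as a score-type exposure.

## Spike-and-slab shrinkage

A single genetic exposure is expected to affect only a handful of the
disease panel, so per-exposure log HRs b_{e,d} get the prior

    p_e ~ Beta(α, β),   π_{e,d} ~ Bernoulli(0.5),
    b_{e,d} ~ Bernoulli(p_e) [(1−π) N(μ, σ²) + π N(−μ, σ²)]

with defaults α = 1, β = 19, μ = 0.3, σ = 0.1: prior inclusion 0.05
(four expected non-null effects across 80 diseases), slab components
centred at hazard ratios e^±0.3 ≈ 1.35 and 0.74.

The link between the observed estimate and the latent effect is the
standard normal approximation to the Cox estimator, β̂ ~ N(b, se²). This
is a documented assumption, not given by the construction above; it lets
the slab be integrated analytically (marginal component likelihoods
N(0, se²) and N(±μ, σ² + se²)) and makes a collapsed Gibbs sampler exact:
given p_e the three-way component labels are conditionally independent,
and given the labels p_e has a conjugate Beta(α + k, β + d − k) update.
Chains run 10,000 post burn-in sweeps after 1,000 burn-in by default, one
independent chain per exposure seeded `seed + exposure index`, initial
p_e at its prior mean and initial labels drawn from the prior. Because
each sweep is two vectorized draws, independent exposures are run in
lockstep as rows of a batch (`gibbs_null_probabilities`); the
single-exposure API is a one-row wrapper over the same code.

The posterior null probability is the post burn-in fraction of sweeps
with the null label. Pairs are discarded when it is strictly over the
threshold (default 10%; a value exactly at the threshold is retained),
and retained pairs carry their **original unshrunk** Cox estimates
downstream — shrinkage selects, it does not re-estimate.

An exact oracle (`exact_posterior_null`) enumerates all 3^d label
configurations for d ≤ 12, weighting each by
B(α+k, β+d−k)/B(α,β) · (1/2)^k · Π_j L_j; the Gibbs sampler is tested
against it on random low-dimensional problems at Monte-Carlo tolerance.

## Attributable DALYs

The multilevel population-attributable fraction compares the observed
exposure-level frequencies P with a counterfactual P′:

    AFp_d = (Σ_i P_i HR_{d,i} − Σ_i P′_i HR_{d,i}) / Σ_i P_i HR_{d,i}

Per-level HRs come from the additive log HR, HR_{d,i} = exp(i·b_d). The
stock counterfactuals are: move all one-copy carriers to zero copies (the
one-vs-zero contrast; its reverse, zero-to-one, flips only the sign of the
individual estimate), remove the allele entirely, or shift the population
to a reference population's Hardy–Weinberg frequencies (the
frequency-enrichment counterfactual).

Population-attributable DALYs are AFp_d × DALY_d, with DALY_d the GBD
yearly DALYs per 100,000 for the disease (and the matching sex stratum in
sex-stratified runs). Individual-attributable DALYs divide by the exposed
individuals per 100,000 and multiply by life expectancy at birth L to
convert a yearly rate into lifetime healthy life years:

    ind_d = AFp_d × DALY_d / (100,000 × P_exposed) × L

L has no principled universal default and must be configured; the
synthetic analyses fix L = 80 years. Totals are plain sums across
diseases within one exposure, with discarded pairs contributing exactly
zero; totals of different exposures are never added (the joint
counterfactual is not the sum of marginal ones). The conversion assumes
cases accumulate the same DALYs with and without the exposure.

## Uncertainty

Exposure frequencies and DALY rates are treated as fixed; all uncertainty
comes from the log-HR estimates.

*Single disease.* The map b ↦ AFp ↦ DALYs is differentiable, with
dAFp/db = (S′·dS − S·dS′)/S² for S(b) = Σ_i P_i e^{ib}; the delta method
gives a symmetric normal CI on the DALY scale. The analytic gradient is
verified against central finite differences to 1e-6 relative error.

*Totals.* Log HRs of comorbid diseases are correlated, so the total's CI
uses correlated resampling. The disease–disease correlation matrix Ĉ is
the Pearson correlation of raw log HRs across exposures classified null
for **both** diseases of a pair — only then do the coefficients reflect
sampling variability rather than true effects. Entries supported by fewer
than 10 exposures (configurable) are set to zero. Ĉ is repaired to
positive semi-definite by eigenvalue clipping and rescaling to unit
diagonal (a no-op for already-PSD input). The retained log-HR vector is
resampled B = 10,000 times from N(β̂, D Ĉ D) with D = diag(se); totals are
recomputed per draw, the 2.5/97.5 percentiles give the 95% CI, and the
p-value uses the normal approximation z = point estimate / SD(draws).
Sex differences are tested by an independent-strata z-test on the two
totals' resampling SDs; the overlap of strata through shared model
components is ignored, which is a documented simplification.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not any particular registry. Per cohort: Hardy–Weinberg genotype dosages
at configured MAFs (scores standard normal, burdens Bernoulli), sex
Bernoulli(0.5), true effects drawn from the spike-and-slab prior, and
per-disease event ages drawn from exponential (constant-in-age) hazards
λ_d·exp(Σ_e b_{e,d} x_e + γ·covariates). Constant hazards are the
simplest family satisfying proportional hazards and give the closed form
λ = −log(1−F)/t for calibrating a target cumulative incidence F by
horizon t. Death is an independent exponential censoring process
(default 0.005/year); administrative follow-up ends at age 80. Entry is
at birth by default — with a delayed-entry range configured, events
before entry are treated as unobserved. Covariate effects default to
γ = 0 since confounding is not needed to test the pipeline's arithmetic.

The fast path `generate_summary_stats` skips the cohort and draws
β̂ ~ N(b, se²) directly, which is the regime the shrinkage stage assumes.
GBD-style DALY tables draw disease magnitudes log-uniform (default
50–4,000 per 100,000 per year, matching the orders of magnitude in real
exports) with a uniform male:female ratio and a population-weighted
"both" row.

What the generator does **not** emulate: linkage disequilibrium between
loci, registry coding and misclassification, age-varying hazards,
relatedness, and confounding by population structure. Passing tests
therefore demonstrate the pipeline's arithmetic and statistical
calibration under its own assumptions, not robustness to those real-data
complications.

## Shrinkage-performance study

The evaluation module asks how well the shrinkage separates truly null
from truly non-null effects after the same significance screening used on
real data. Per causal proportion π ∈ {0.001, 0.002, 0.005, 0.01}: 80
binary phenotypes are simulated under a liability-threshold model over
independent Hardy–Weinberg genotypes (MAF uniform 0.01–0.5), causal
effects spike-and-slab with per-phenotype heritability uniform on
0.10–0.60, liabilities binarized at per-phenotype prevalences drawn
uniform on 0.01–0.15 (chosen to span the cumulative-incidence range of
registry diseases). The association scan is a vectorized
simple-linear-regression Wald test of the binary phenotype on
standardized dosage — with unrelated individuals and no structure this is
asymptotically equivalent to a mixed-model logistic scan and runs as one
matrix product. Variants with any P < 5e-8 enter the shrinkage (2,000
Gibbs sweeps, 500 burn-in — ample resolution for ranking), and the ROC
AUC of 1 − posterior null probability against the causal mask is computed
over all selected variant–phenotype pairs.

The default scale, 50,000 individuals × 5,000 variants × 80 phenotypes,
was chosen so the full four-scenario study completes in a few minutes on
one core while leaving hundreds to thousands of selected variants per
scenario; `EvalConfig` scales it up.

## Numerical choices and degenerate inputs

- Frequency vectors must sum to 1 within 1e-10; hazard ratios must be
  strictly positive; exposure frequencies in (0, 0.5] for alleles.
- Label sampling uses max-subtracted log-weights (no underflow for
  extreme z-scores); enumeration uses log-sum-exp throughout.
- Top-decile encoding flags exactly floor(q·n) individuals, ties broken
  by stable rank, so the encoding is deterministic.
- Slab draws landing exactly on 0 (probability zero, but possible in
  floating point) are nudged to the smallest positive float so the null
  mask stays exact.
- All generators and samplers are pure functions of their seed; batch and
  single-exposure shrinkage share one code path.

## Known limitations

- The constant-attributable-DALY assumption (equal per-case burden with
  and without the exposure) is inherited by construction; violations
  (e.g. earlier onset in carriers) are out of scope.
- Firth-penalized Cox for rare burdens is not implemented; the standard
  fit with a minimum-events guard substitutes.
- No bootstrap over individuals; the resampling design holds frequencies
  and DALY rates fixed and captures only log-HR sampling variability.
- The sex-difference test assumes independent strata.
- Hyperparameters (α, β, μ, σ) are fixed configuration, not learned.
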