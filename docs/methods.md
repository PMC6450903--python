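# Methods

## Structural model and the constant-slope argument

For one SNP with coded genotype G, incidence X and prognosis Y are assumed
linear in G, a composite confounder U (all common causes of X and Y,
polygenic background included), and unique residuals:

    X = β_GX G + β_UX U + E_X
    Y = β_GY G + β_UY U + β_XY X + E_Y

with G, U, E_X, E_Y pairwise uncorrelated, mean zero, and no
interactions. The estimand reported by a GWAS of prognosis conditional on
incidence (case-only, or X as covariate) is, asymptotically,

    β'_GY = β_GY + b β_GX,
    b = − var(U) β_UX β_UY / (var(U) β_UX² + var(E_X)).

`analytic_b` evaluates this expression. Its sign is negative when the
confounder pushes incidence and prognosis in the same direction. For a
polygenic trait the focal SNP contributes a negligible share of var(X), so
the denominator is effectively var(X) minus that share and b is
approximately constant across SNPs: in a multi-SNP genome the composite U
for SNP j comprises the non-genetic confounder *plus every other SNP
affecting both traits*, giving

    b ≈ − cov(X, Y) / var(X)

with cov(X, Y) the sum of the non-genetic confounder covariance and the
shared-SNP genetic covariance. With unit-variance traits, 40% shared
non-genetic variance and zero genetic correlation this is −0.4; the
textbook single-confounder evaluation that ignores the polygenic
background in the denominator (−0.4/0.5 = −0.8) describes a genome with
no other causal SNPs, not the polygenic regime, and the simulation engine
therefore uses the cov/var form with the realized genetic covariance.

Because b is constant, it is estimable as the slope of the regression of
β̂'_GY on β̂_GX across SNPs, and the residual-based correction
β̂_GY = β̂'_GY − b̂ β̂_GX removes the bias for *every* SNP, pruned or not.
The critical assumption is independence of direct effects on incidence
and prognosis among the SNPs entering the regression; genetic correlation
biases b̂ by (cov of direct effects)/(var of incidence effects) and the
correction then under- or over-shoots — the simulation study quantifies
this.

## Slope estimation

- **Raw slope** (`fit_raw_slope`): OLS with intercept. Marginal GWAS
  effects have allele-frequency- and LD-dependent sampling variances, so
  the slope SE is the HC1 sandwich estimator (statsmodels). The intercept
  absorbs any directional mean of prognosis effects; the correction
  subtracts the slope term only. At least 10 SNPs are required; the
  regression should be run on an LD-pruned set so residuals are
  approximately independent.
- **Hedges–Olkin** (`hedges_olkin_correct`): regression dilution
  multiplies the slope by var(β_GX)/(var(β_GX)+E σ²_GX); the
  method-of-moments estimate of the true-effect variance is
  var(β̂_GX) − mean(σ²_GX), giving the reciprocal correction factor (≥ 1
  in magnitude). When sampling noise exceeds the observed variance the
  factor would flip the slope's sign, which is impossible for a ratio of
  variances; this raises `DilutionInfeasibleError` instead of returning a
  sign-flipped slope (SIMEX is the fallback in that regime). The corrected
  slope's variance is propagated as factor² × robust SE² — a plug-in
  proxy, slightly conservative because the factor itself is noisy.
- **SIMEX** (`simex_correct`): for each λ in {0, 0.25, …, 2} (default),
  `n_sim` = 100 datasets add N(0, λσ²_GX) noise to β̂_GX; the mean slope
  per λ is fit by a quadratic in λ and evaluated at λ = −1. λ = 0 uses the
  observed data exactly, so that grid point equals the raw slope by
  construction. Quadratic extrapolation removes most but not all of the
  dilution (the exact extrapolant for classical error, var/(var+λσ²), is
  not polynomial); the bootstrap over SNPs (default 200 resamples, full
  SIMEX rerun each) supplies the percentile 95% CI and var(b̂) as the
  bootstrap variance. Replicates with degenerate designs are discarded;
  more than 10% discarded (or >10% failed bootstrap replicates) is an
  error. The percentile interval is widened, if necessary, to contain the
  full-sample point estimate.

## Per-SNP adjustment and inference

`adjust_effects` applies β̂_GY = β̂'_GY − b̂ β̂_GX with

    se² = σ²_GY + b̂² σ²_GX + β̂²_GX var(b̂) + σ²_GX var(b̂)

and two-sided normal p-values, floored at the smallest positive double so
p ∈ (0, 1]. The formula treats β̂_GX as random in the var(b̂) cross-terms
(β̂²_GX already contains σ²_GX on average), which leans conservative; it
is used as written. The normal approximation serves by default; for
variants with extreme incidence effects or an asymmetric slope CI,
`bootstrap_snp_inference` simulates β̂'_GY, β̂_GX and b̂ from their
estimated distributions (b̂ from the SIMEX bootstrap draws when
available, else N(b̂, var b̂)), and reports a percentile CI and an
empirical two-sided p floored at 1/n_draws — an order bound, not an exact
level. `genomic_inflation` gives λ_GC = median χ²/0.4549 as a genome-wide
diagnostic.

## Synthetic-data generator

The generator emulates a polygenic two-trait architecture: the default
scenario is 100,000 independent Hardy–Weinberg SNPs with MAF ~ U(0.01,
0.49), of which 5,000 affect incidence only, 5,000 prognosis only and
5,000 both; both traits have heritability 0.5 and share a non-genetic
confounder explaining 40% of the variance of each; 20,000 individuals;
no direct incidence→prognosis effect. Conventions:

- **Effect scale.** Effects are drawn with equal variance per
  *standardized* genotype — every causal SNP explains the same variance in
  expectation (h²/m_causal, i.e. 0.005% each by default) regardless of
  MAF — then converted to the dosage scale. This convention, not
  constant dosage-scale variance, reproduces the published per-SNP power
  and worst-case type-1 profiles of this architecture.
- **Exact rescaling.** Each trait's effect vector is rescaled so
  Σ β²·2p(1−p) equals h² exactly (per realized genotypes in the
  individual engine), stabilising small-scale runs; residual variances
  top traits up to unit variance.
- **Shared SNPs.** Standardized effect pairs are bivariate normal with
  correlation ρ; genome-wide genetic correlation ≈ ρ·m_both/√(m_x m_y)
  (0.5 → 0.25, 0.9 → 0.45 under the defaults).
- **Fixed truth.** One truth draw (MAFs, effects, categories) per
  scenario seed, with individuals/noise redrawn each replicate, so
  per-SNP rejection rates across replicates (worst-SNP type-1, largest
  power gain/loss) are meaningful. Mean rates are then conditional on the
  truth draw; comparisons across independent truth draws must budget for
  that (see tests).
- **Binary designs.** Disease is liability X above its (1−case_fraction)
  sample quantile (20% affected by default); exactly n_cases/n_controls
  are sampled from a pool sized 1.25× the larger requirement; binary
  prognosis splits sampled cases at their median Y. Incidence scans are
  per-SNP logistic case/control fits; prognosis is case-only logistic by
  default, with case-only linear and the impute-zero-for-controls
  case/control-with-covariate variants available.
- **Survival.** T ~ Exponential(rate = exp(Y)) with per-SNP Cox
  partial-likelihood fits (lifelines); no censoring by default, since the
  emulated design reports none — administrative censoring can be layered
  on by truncating times before the scan.

### Two engines

The **individual-level engine** simulates people and runs vectorised
per-SNP scans (linear via Frisch–Waugh residualisation, exact to full OLS;
logistic via batched Newton–Raphson, matching statsmodels to ~1e-7;
Cox via lifelines). The **summary-level engine** draws the per-SNP
estimates directly from their asymptotic sampling distributions:
β̂_GX ~ N(β_GX, var(X|G_j)/(n·v_j)) and β̂'_GY ~ N(β_GY + b·β_GX,
var(Y|G_j,X)/(n·v_j(1−r²_jX))) with v_j = 2p_j(1−p_j) and b the realized
collider slope. One refinement matters: both scans use the same subjects,
so the realized sample correlation between the two models' residual
vectors — a single N(0, var(Y|X)/n) draw per replicate — couples every
SNP's pair of sampling errors. Per SNP this is invisible, but the slope
regression aggregates it and the dilution correction amplifies it by the
noise-to-signal variance ratio (≈10 under the defaults), so it contributes
materially to the replicate spread of b̂; omitting it understates the
adjusted type-1 error under genetic correlation. With the coupling
included the two engines agree within Monte Carlo error at matched
parameters (validated at a 1/5-scale replica preserving m/n and the
dilution ratio).

What the generator does *not* emulate: LD between SNPs (the slope
regression's pruning requirement is therefore untested against real LD),
gene–environment interaction, imputation error (which is bounded and
phenotype-blind, hence non-classical — a documented failure mode for
dilution corrections on real data), population structure, and censoring.
Passing tests show the estimator works under its own assumptions, not
that those assumptions hold in any particular dataset.

### Replicated studies and the slope-variance convention

`run_scenario` runs the full analysis per replicate (slope re-estimated
from that replicate's own estimates, Hedges–Olkin by default, then all
SNPs adjusted) and tabulates metrics with MC standard errors. In these
replicated studies the per-SNP variance treats the fitted slope as known
(`account_slope_uncertainty=False` by default): the method-of-moments
correction provides no variance estimate of its own, and the operating
characteristics under this convention match the published study this
engine replicates; the scaled-robust-variance proxy can be switched on
and is slightly conservative (≈0.1–0.2 points lower rejection rates).
The data-analysis path (`adjust_effects`, CLI) always propagates var(b̂).

### Problem sizes

The replication protocol (`scripts/acceptance.py`) uses the summary-level
engine at the full architecture (100,000 SNPs, n = 20,000) with 500
replicates for the confounded ρ_g = 0 scenario (family-wise error needs
the precision) and 200 for the ρ_g = 0.45 and unconfounded scenarios. The
binary design runs the individual-level logistic pipeline at a reduced
scale — 2,000 SNPs (100/100/100 causal), 2,500 cases/2,500 controls, 80
replicates — which preserves the architecture's proportions while keeping
a full logistic re-analysis affordable; the adjusted type-1 error it
checks is calibration-driven and insensitive to the scale reduction.

## Numerical choices and degenerate inputs

- Palindromic (A/T, C/G) variants are dropped in harmonization by default:
  strand cannot be resolved without frequencies, and the slope needs
  unbiased sign alignment. Allele-set mismatches are dropped and counted.
- Missing eaf/info pass filters only when the corresponding threshold is
  0 (conservative).
- Greedy LD pruning scans left to right; a variant is kept iff r² with
  every kept variant in the trailing window is below threshold;
  zero-variance columns are excluded with a warning. Deterministic given
  input order.
- Slope regressions refuse fewer than 10 SNPs or a constant predictor.
- Logistic Newton steps are clipped to ±5 per iteration (damps overshoot
  on the way to the optimum without changing it); non-converged or
  (quasi-)separated SNPs (|β| > 15 or SE > 100) are returned as NaN and
  excluded from that replicate's analysis.
- Adjusted tables are written with 17 significant digits and read back
  with round-trip float parsing, so values (including p ~ 1e-300) survive
  a write/read cycle bit-exactly.
- Seeds are mandatory for simulation studies; all randomness flows from
  `numpy.random.default_rng` children of the master seed.

## Known limitations

- The constant-slope assumption fails in the presence of major genes
  accounting for substantial covariation of incidence and prognosis; the
  supported mitigation is supplying summary statistics conditioned on the
  major gene and/or excluding its region from the slope regression
  (`--exclude-region`), not recomputing conditional effects from
  genotypes.
- Correlated direct effects on incidence and prognosis bias the slope;
  under strong negative genetic correlation the adjusted analysis can be
  slightly worse than the unadjusted one, as the replication tables show.
- Adjusted effects are by construction decorrelated from incidence
  effects, so genetic-correlation analyses on adjusted statistics are
  meaningless and deliberately unsupported.
- Quantities whose selection biases act through the *precursor* of the
  index trait (risk-factor GWAS in case/control samples) are a different
  problem and out of scope.
- SIMEX quadratic extrapolation under-corrects slightly for strong
  dilution; the bootstrap CI reflects this through its spread, not its
  location.
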