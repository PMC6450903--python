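# indexbias

Adjustment for index event (collider) bias in GWAS of disease prognosis,
severity, survival and other subsequent events.

## The problem

Genome-wide association studies of what happens *after* disease onset —
survival with idiopathic pulmonary fibrosis, prognosis of Crohn's disease,
recurrent coronary events — necessarily select their subjects on disease
status, or adjust for it. Disease incidence is a *collider*: conditioning
on it makes otherwise independent causes of disease negatively correlated
among cases. A variant that raises disease risk therefore becomes
associated, among cases, with lower levels of every other risk factor; if
those factors also drive prognosis, the variant acquires a spurious
association with prognosis. This *index event bias* can be large enough to
reverse the sign of a true effect when the susceptibility effect is strong.

`indexbias` implements a regression-based correction that works entirely
on GWAS summary statistics, for analysts running or re-analysing GWAS of
subsequent events.

## The method

Write β<sub>GX</sub> for a SNP's effect on incidence X and β′<sub>GY</sub>
for its effect on prognosis Y estimated conditional on X (e.g. among cases
only). Under linear structural models with a composite confounder U,

&nbsp;&nbsp;β′<sub>GY</sub> = β<sub>GY</sub> + b·β<sub>GX</sub>,&nbsp;&nbsp;
b = −var(U)β<sub>UX</sub>β<sub>UY</sub> / (var(U)β<sub>UX</sub>² + var(E<sub>X</sub>)),

i.e. the bias is *linear in the incidence effect with a slope b that is
approximately constant across polygenic SNPs*. The procedure:

1. obtain β̂<sub>GX</sub> (σ<sub>GX</sub>) and β̂′<sub>GY</sub>
   (σ<sub>GY</sub>) for every SNP, harmonized to one effect allele;
2. regress β̂′<sub>GY</sub> on β̂<sub>GX</sub> over an LD-pruned SNP set,
   giving the raw slope b̂\* with a heteroscedasticity-robust SE;
3. correct b̂\* for regression dilution (sampling error in
   β̂<sub>GX</sub> attenuates the slope): Hedges–Olkin method-of-moments
   factor var(β̂<sub>GX</sub>)/(var(β̂<sub>GX</sub>) − E σ²<sub>GX</sub>),
   or SIMEX — re-estimate the slope under inflated noise λσ²<sub>GX</sub>
   and extrapolate to λ = −1 — with a bootstrap CI over SNPs;
4. adjust every SNP: β̂<sub>GY</sub> = β̂′<sub>GY</sub> − b̂·β̂<sub>GX</sub>,
   with SE √(σ²<sub>GY</sub> + b̂²σ²<sub>GX</sub> +
   β̂²<sub>GX</sub>var(b̂) + σ²<sub>GX</sub>var(b̂));
5. refer β̂<sub>GY</sub>/SE to the standard normal.

A simulation engine reproduces the operating characteristics of the
adjusted and unadjusted analyses (type-1 error, power, family-wise error,
absolute bias, MSE, by SNP category) under quantitative,
liability-threshold case/control and exponential-survival designs.

## Worked example: command line

Given two whitespace/tab-delimited summary-statistic files with columns
`SNP EA OA BETA SE` (names remappable via `--snp-col` etc.) and a file of
LD-pruned variant IDs:

```bash
indexbias adjust \
    --incidence incidence.tsv --prognosis prognosis.tsv \
    --prune-list pruned.txt --method simex --n-boot 200 \
    --seed 1 --out adjusted.tsv
```

On a synthetic dataset of 5,000 independent SNPs generated by the
package's own engine with a true confounding slope of −0.389 this prints:

```
confounding slope (method=simex, n_snps=5000)
  raw slope      : -0.264347 (robust SE 0.0283737)
  intercept      : +0.000466403
  corrected slope: -0.3647 (SD 0.0370172)
  95% CI         : [-0.434661, -0.284878]
genomic inflation lambda_GC = 1.4181 over 5000 variants
wrote 5000 adjusted records to adjusted.tsv
```

The raw regression slope (−0.264) is attenuated towards zero by sampling
error in the incidence effects; SIMEX extrapolation recovers −0.365 with a
bootstrap CI that covers the true −0.389. `adjusted.tsv` holds one row per
variant: both input effects, the bias-corrected prognosis effect, its SE,
Wald z and p-value. (λ<sub>GC</sub> is well above 1 here simply because
30% of the synthetic SNPs are truly causal.)

## Worked example: simulation study

```python
from indexbias import SimulationScenario, run_scenario

scenario = SimulationScenario(m_total=20_000, m_inc_only=1_000,
                              m_prog_only=1_000, m_both=1_000)
table = run_scenario(scenario, n_reps=50, engine="summary", seed=7)
print(table.round(2))
```

```
                         unadjusted  adjusted  mc_se_unadjusted  mc_se_adjusted
metric
type1_all_null                 5.61      4.99              0.02            0.02
type1_inc_only                15.91      4.85              0.15            0.11
type1_worst_snp               88.00      4.00              4.60            2.77
familywise_error              96.00      6.00              2.77            3.36
power_prognosis               47.39     42.03              0.11            0.14
power_both                    48.43     41.35              0.15            0.16
power_best_gain_snp            4.00     72.00              2.77            6.35
power_worst_loss_snp          96.00     10.00              2.77            4.24
mean_abs_bias_inc_only         0.01      0.01              0.00            0.00
mean_abs_bias_prognosis        0.01      0.01              0.00            0.00
mse_inc_only                   0.00      0.00              0.00            0.00
mse_prognosis                  0.00      0.00              0.00            0.00
```

Rows are percentages (bias/MSE rows on the effect scale). In this
20,000-SNP scenario each causal SNP carries a larger effect than in a
100,000-SNP genome, so the uncorrected inflation is dramatic — 15.9% type-1
error over SNPs affecting incidence only, 88% for the worst single SNP,
96% family-wise — while the adjusted analysis is restored to the nominal
5% (4.85 ± 0.11; worst SNP 4%; family-wise 6%) at a modest power cost
(47.4% → 42.0%). The true collider slope here is −0.403 and the mean
Hedges–Olkin-corrected estimate across replicates is −0.409 (SD 0.036).

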