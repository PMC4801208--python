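# Methods

## Scope and design

`lipidmr` implements a score-based Mendelian-randomization survival analysis:
weighted lipid gene scores as instruments, per-cohort Cox models of incident
atrial fibrillation per 1-SD score, fixed-effects pooling, analytic
instrument power, and the Wald-ratio causal estimator. The package is a
library first (`lipidmr.*` modules, `examples/` scripts); the `lipidmr` CLI
is a thin wrapper because the simulate/score/fit/meta/power stages are also
natural shell commands.

## Score construction

The raw score is Σᵢ dᵢⱼ·|βᵢ| over panel SNPs, where dᵢⱼ counts "unfavorable"
alleles (lipid-raising for LDLc/TC/TG, lipid-lowering for HDLc) and |βᵢ| is
the absolute additive effect in mg/dL. The raw sum is divided by the mean
|β| of the SNPs actually used, then by the cohort-specific sample SD.
Decisions fixed here:

- **No mean-centering.** Cohort score means are positive allele-count-scale
  quantities (≈8–13 in typical panels) with SD exactly 1; centering would
  destroy that interpretation and is not needed by the Cox model, which is
  location-invariant.
- **Sample SD uses the n−1 denominator**, computed within each cohort's
  post-exclusion analysis sample. The choice is immaterial at cohort sizes
  but must be pinned for exact tests.
- **Reduced panels.** SNPs absent from a cohort's genotyping are dropped
  from both the sum and the rescaling denominator, and `n_snps_used` is
  reported, so cohorts with reduced platforms produce slightly lower score
  means rather than silently biased ones.
- **Unit invariance.** Multiplying every |β| by a constant cancels in the
  rescaling, so mixed effect-size units across fractions would not change
  scores; units are metadata.

## Allele harmonization

Genotype dosages (VCF DS/GT or a dosage-TSV dialect with `snpid_allele`
columns) are re-coded so every column counts the panel's scored allele:
columns coded to the other allele are flipped d → 2−d; a coded allele
matching neither panel allele is a hard error, and **no strand flipping is
attempted** — A/T and C/G panel pairs only trigger a logged warning. Silent
strand inference can corrupt a score in ways no downstream check detects;
failing loudly is the safer default for an instrument. Missing dosages are
mean-imputed as 2×(sample scored-allele frequency) by default (the standard
dosage-scale convention for imputed GWAS data); `drop_individual` is
available. Harmonization is idempotent and involutive under allele swaps,
and both properties are tested.

## Cox association

`fit_cox` maximizes the Cox partial likelihood via statsmodels `PHReg`
(Efron ties by default; Breslow by flag; the two agree exactly without
ties). Tiers: (1) age, sex, center/cohort indicators; (2) + education,
height, smoking, BMI, SBP, DBP, antihypertensive use, diabetes, LVH, prior
stroke/CHD/heart failure; (3) + the continuous lipid level of the score's
own fraction and lipid-medication use. "Matching fraction" is the minimal
reading of "adjusted for continuous lipid levels"; adjusting for all four
fractions would be a defensible alternative but conditions the exposure on
its correlates. Center/cohort enter as indicator covariates, not strata.
No left truncation: entry is the baseline exam at time 0.

Covariate resolution per cohort (`covariates_for`) intersects the tier list
with the cohort's available columns and drops inestimable covariates with a
report: constants (sex in an all-female cohort) and binary covariates with
zero events in one level, whose log-HR has a monotone partial likelihood and
diverges. The second rule matters in small simulated cohorts (a 170-person
cohort can easily have all its handful of AF events in one sex) and mirrors
what an analyst would do on seeing a non-converging fit. If BFGS reports
non-convergence the fit is polished by Newton from the current point;
remaining non-convergence or a singular information matrix is an error, as
is exact collinearity (checked by matrix rank including an implicit
intercept, since Cox is invariant to covariate shifts).

## Meta-analysis, power, Wald ratio

Pooling is classical inverse-variance fixed-effects on the log-HR scale;
exponentiation only for reporting. I² = max(0, (Q−df)/Q); no random-effects
model is offered (the design assumes a common effect and tests report Q and
I² to check it). The implementation is authored here and cross-checked in
tests against statsmodels `combine_effects` and a generic weighted
least-squares solve.

Instrument power for a binary outcome uses the non-centrality
z\* = √(N·R²·K(1−K))·|ln OR| with a two-sided normal test, power
Φ(z\*−z₁₋α/₂) + Φ(−z\*−z₁₋α/₂). At the consortium design (N = 65,000,
K = 0.08, R² = 0.05, OR = 0.80, α = 0.05) this formula gives 93.2%
(`scripts/acceptance.py` computes it); published power statements for this
design are a few points lower, consistent with a different calculator
variant, and the tests therefore validate the formula directly against
Monte-Carlo rejection rates rather than against a single printed number.
α defaults to 0.05 two-sided.

The Wald ratio β̂ᶻʸ/β̂ᶻˣ with delta-method SE
√(se²ᶻʸ/β²ᶻˣ + β²ᶻʸ·se²ᶻˣ/β⁴ᶻˣ) is provided as the causal estimator the
pipeline would apply to a non-null score-outcome association; β̂ᶻˣ = 0 is an
error (undefined ratio, weak instrument).

## Synthetic consortium

The generator emulates the statistical structure the analysis assumes, not
any real cohort's data:

- **Panel.** A synthetic 95-SNP stand-in for the published lipid panel
  (`synthetic_teslovich_panel`), with the published membership structure —
  47 HDL, 37 LDL, 52 TC, 32 TG SNPs; 14/13 single-fraction HDL/LDL SNPs —
  and effect sizes/frequencies drawn once from plausible GWAS ranges
  (log-normal |β| centered near 1.5 mg/dL; EAF uniform on 0.05–0.95) with a
  fixed internal constant, so the panel is a deterministic package constant.
- **Genotypes.** dᵢⱼ ~ Binomial(2, eafᵢ): Hardy–Weinberg and linkage
  equilibrium. Panel SNPs are index SNPs of distinct loci, so LD is out of
  scope.
- **Lipids.** lipid = base + (g − E g) + sd·(confounder shifts + noise),
  where g is the signed genetic value (unfavorable alleles lower HDL, raise
  the others), var(g) = Σβᵢ²·2pᵢ(1−pᵢ), and the noise variance is chosen
  analytically so var(g)/var(lipid) equals the configured instrument R²
  (default 0.05). Confounders act in lipid-SD units per covariate SD and
  their variance is debited from the noise.
- **Survival.** AF times are exponential (Weibull shape accepted, default 1)
  with hazard λ₀·exp(θ_lipid·z_lipid + θ_direct·z_score + confounder
  log-HRs); death and dropout are independent exponential censorings and
  follow-up is administratively truncated at the cohort horizon. λ₀ is
  solved per cohort (Brent root find on the closed-form event probability)
  so the expected case fraction equals the cohort's target — the seven
  defaults give an expected 5,434 cases among 64,901 (8.4%). θ_direct ≠ 0
  injects an exclusion-restriction violation for sensitivity studies.
- **Cohorts.** `afgen7.yaml` fixes seven cohorts' n, age, sex mix,
  follow-up horizon, case targets, covariate baselines and the
  availability pattern (no LVH in three cohorts, no education in one, no
  lipid measurements and no TC panel in the reduced-genotyping cohort, one
  all-female cohort, 11 SNPs missing on the reduced platform). Death and
  dropout rates are free parameters set once to plausible age-graded
  values; only n, sex, follow-up, availability and case fraction are
  calibrated. Covariates are independent Gaussians/Bernoullis except for
  explicitly configured confounder paths — the generator does **not**
  emulate realistic covariate correlation, LD, relatedness, imputation
  error or secular trends, so passing tests certify the statistical
  machinery, not robustness to those features of real data.
- **Determinism.** All randomness flows from one scenario seed through
  `numpy.random.SeedSequence` spawning (per cohort, then per component), so
  identical configs are bit-identical and cohorts are independent streams.

Under this architecture the per-SD-score log-HR approximates
θ_lipid·√R² (the rare-event linear bridge), which is what the
parameter-recovery tests check.

## Test problem sizes

The simulation suites use sizes chosen to keep the whole test run in a few
minutes while leaving Monte-Carlo error well below the tested margins:
null calibration uses 200 replicates of the consortium at 1/10 cohort size
(tier-1 adjustment) plus 500 single-cohort replicates at n = 2,000 for
type-I error (±3·binomial-SE band); causal recovery uses one full-size
consortium replicate (n = 64,901, ±3.5 pooled SE) and one n = 50,000 cohort
for the Wald ratio; the power cross-check uses 1,000 logistic replicates at
n = 4,000. R² calibration checks use n = 100,000 single draws.

## Known limitations

- Exposure lipids are simulated, not measured; tier-3 adjustment in the
  simulator conditions on the generated lipid, which is the exposure itself
  — as in the real design, tier 3 is a mediation-flavored sensitivity
  analysis, not an MR estimate.
- No competing-risks estimator: death censors, matching the follow-up
  definition; cumulative-incidence interpretation under high mortality is
  the user's responsibility.
- No per-SNP MR estimators (MR-Egger, weighted median): the instrument is
  the score, and pleiotropy handling is limited to the non-pleiotropic
  sub-scores and the θ_direct stress knob.
- Proportional-hazards diagnostics, time-varying covariates and stratified
  baselines (beyond indicator adjustment) are out of scope.
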