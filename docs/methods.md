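# Methods

## Scope

`taclss` implements a complete limited-sampling-strategy (LSS) workflow for
once-daily extended-release tacrolimus in pediatric kidney recipients: a
generative steady-state pharmacokinetic cohort simulator, observed-exposure
metrics, CYP3A5 pharmacogenetic analyses, all-subsets regression model
building, and clinical validation statistics. It performs no population-PK
estimation (the simulator is generative only), no genotype calling, no
bioequivalence testing between brands, and no clinical-outcome modelling.

## The pharmacokinetic model

Each simulated patient follows a two-compartment disposition model with
first-order oral absorption at steady state under repeated dosing every
τ = 24 h. With apparent clearance CL/F, central and peripheral volumes Vc/F and
Vp/F, inter-compartmental clearance Q/F and absorption constant ka, the
micro-constants are k = CL/Vc, k12 = Q/Vc, k21 = Q/Vp, and the hybrid
disposition rates α, β solve α+β = k+k12+k21, α·β = k·k21 (β computed as
k·k21/α for stability). The steady-state concentration is the superposition

    C(t) = (1000·D·ka/Vc) · Σᵢ Aᵢ·e^(−λᵢt)/(1−e^(−λᵢτ)),  λ = (α, β, ka)

with the standard coefficients A₁ = (k21−α)/((ka−α)(β−α)),
A₂ = (k21−β)/((ka−β)(α−β)), A₃ = (k21−ka)/((α−ka)(β−ka)); the factor 1000
converts mg and L to ng/mL. Two consequences are used as invariants and as
ground truth: C(0) = C(τ) (periodicity) and ∫₀^τ C dt = 1000·D/(CL/F), the
analytic AUC recorded per patient. If a sampled ka collides with α or β the
model is singular; ka is nudged by repeated ×1.000001 steps until the relative
gap exceeds 10⁻⁶ (logged, practically never triggered by the defaults).

## The synthetic cohort generator

The generator emulates a maintenance-phase pediatric cohort under therapeutic
drug monitoring (TDM):

1. **Genotype** at Hardy–Weinberg proportions for a *3 allele frequency
   q₃ = 0.8125 (the admixed-population value of the emulated cohort).
2. **Parameters** per patient: log-normal around population medians
   (σ = √ln(1+CV²)); expressors get CL/F multiplied by 1.6.
3. **Dose titration**: on a 0.5-mg grid between 0.5 and 30 mg, starting from a
   weight-based initial dose (0.1 mg/kg), the dose whose noise-free predicted
   trough C(τ) falls in the 5–7 ng/mL maintenance window with the smallest
   adjustment is chosen (ties to the lower dose); if the window is unreachable
   on the grid, the closest-to-midpoint dose is used and flagged.
4. **Inter-occasion variability**: doses were titrated on earlier clinic
   visits, so on the profiling day every PK parameter receives an independent
   log-normal occasion multiplier. This is what scatters real troughs around
   the TDM target despite conscientious titration.
5. **Sampling** at the nominal times 0, 1, 2, 4, 12, 24 h (no actual-time
   jitter: the emulated protocol reports nominal times), then **assay noise**
   measured = C·(1+εₚ) + εₐ with εₚ ~ N(0, 0.10), εₐ ~ N(0, 0.3 ng/mL);
   values below the 0.5 ng/mL quantification limit are imputed as LLOQ/2 and
   flagged rather than dropped, keeping profiles trapezoid-complete while
   marking censoring.

Randomness: one integer seed per cohort; patient *i* draws from a
counter-derived substream (`SeedSequence(seed, spawn_key=(i,))`), so patient
*i* is bit-reproducible regardless of cohort size, and full runs are
deterministic.

### Parameter defaults and calibration

| parameter | default | unit | rationale |
|---|---|---|---|
| CL/F median | 16 | L/h | gives TAC-D ≈ 0.11 mg/kg at the titrated trough, cohort CL/F ≈ 0.5 L/kg/h |
| Q/F median | 60 | L/h | fast distribution consistent with an early (1–2 h) Tmax |
| Vc/F median | 60 | L | sets peak height: Cmax ≈ 17 ng/mL at ~4.5 mg |
| Vp/F median | 800 | L | deep peripheral pool; flat extended-release-like terminal phase |
| ka median | 0.3 | 1/h | slow absorption of an extended-release formulation |
| weight median | 40 | kg | school-age/adolescent kidney recipients |
| between-subject CV | 0.20 (weight 0.25) | – | cohort TAC-D CV ≈ 0.45 after titration |
| occasion CV | CL 0.16, ka/Vc 0.25, Q/Vp 0.15 | – | absorption varies most between occasions for oral ER dosing; calibrated to trough scatter and trough–AUC correlation (below) |
| expressor CL multiplier | 1.6 | – | the 1.5–2× dose requirement of CYP3A5 expressors |
| trough target | 5–7 | ng/mL | maintenance-phase TDM window |
| AUC target window | 170–250 | ng·h/mL | exposure range used for the range flags |
| assay error | CV 0.10 + 0.3 ng/mL, LLOQ 0.5 | – | immunoassay-like combined error model |

The medians were calibrated once against the emulated cohort's published
summary statistics — TAC-D 0.108 ± 0.049 mg/kg with expressors near 0.145 and
non-expressors near 0.092, mean AUC₀₋₂₄ ≈ 225 ng·h/mL, C₀ ≈ 6 ng/mL,
Cmax ≈ 16.7 ng/mL with Tmax mostly at 1–2 h — and then frozen. The default
cohort reproduces TAC-D 0.110 ± 0.048 (0.151/0.088 by expressor status),
AUC ≈ 220, C₀ ≈ 5.9, Cmax ≈ 17.
The occasion CVs were selected by proximity to that cohort's trough behaviour
(C₀ sd ≈ 2 ng/mL with most troughs outside the window) and its per-subset
adjusted-r² profile for the regressions below; the default generator yields
mean adjusted r² ≈ (0.49, 0.31, 0.44, 0.69) for C₀, C₁, C₂, C₄ alone and
(0.86, 0.88) for C₀+C₄ and C₀+C₁+C₄ — close to the emulated study's
(0.50, 0.35, 0.44, 0.74, 0.85, 0.88).

### What the generator does *not* emulate

Non-adherence, within-day (intra-occasion) kinetics changes, actual-vs-nominal
sampling-time deviations, covariate effects other than CYP3A5 (age, ancestry,
hematocrit, co-medication), and brand differences (brand is an uninformative
grouping label drawn independently of PK). Passing tests therefore demonstrate
correctness of the statistical machinery and plausibility under a faithful but
idealized data-generating process — not clinical performance on real patients.
In particular, real trough scatter partly reflects adherence, so the simulated
trough carries slightly less noise (C₀ sd ≈ 1.6) than a real clinic sees.

## Exposure metrics

AUC₀₋₂₄ is the linear trapezoid over the six observed points — the method
treated as the gold standard in this field; a log-linear variant was
considered and rejected as the default because the reference workflow is
explicitly linear-trapezoid-equivalent. Cmax is the profile maximum and Tmax
the earliest time attaining it (deterministic tie-break). Dose-normalized
AUC = AUC/TAC-D; apparent weight-normalized clearance = 1000·TAC-D/AUC
(L/kg/h), linked by the identity CL·AUC = 1000·TAC-D. Therapeutic-range flags
classify C₀ against 5–7 ng/mL and AUC against 170–250 ng·h/mL with inclusive
boundaries (the conservative TDM reading, since the protocol does not specify
boundary handling).

## CYP3A5 analyses

Genotypes are input labels; missing entries are excluded from counts (the
emulated study genotyped 48 of 51). Allele frequency by allele counting;
Hardy–Weinberg goodness of fit by the chi-square on expected counts
n·(p², 2pq, q²) with df = 1 (one estimated allele frequency); percentages are
reported rounded half away from zero to one decimal, matching the customary
printed style. Group contrasts for TAC-D and AUC/TAC-D between expressors and
non-expressors are reported with *both* one-way ANOVA and the Mann–Whitney U
test, since both appear in practice for this contrast; Fligner–Killeen is
available for the variance-homogeneity check. ANOVA and the HWE statistic are
computed directly from their sum-of-squares definitions (the degenerate cases
F = 0 for identical data and F = ∞ for zero within-group variance are defined
explicitly); Fligner–Killeen and Mann–Whitney come from scipy, the latter with
exact enumeration for tie-free samples with n₁·n₂ ≤ 400 and the tie-corrected
normal approximation otherwise.

## LSS model building

All 2⁴−1 = 15 non-empty subsets of the candidate time-points {C₀, C₁, C₂, C₄}
(late samples excluded by design so sampling fits an outpatient morning; the
candidate set is configurable) are enumerated by size then label order, which
fixes the conventional model numbering 1–15. Each subset is fitted by OLS with
intercept (numpy least squares; rank-deficient designs raise an error naming
the collinear columns). Reported per model: r², adjusted
r² = 1−(1−r²)(n−1)/(n−p−1), in-sample median APE, and Gaussian
profile-likelihood information criteria AIC = n·ln(RSS/n)+2k,
BIC = n·ln(RSS/n)+k·ln(n) with k = p+2 (intercept + residual variance) — only
differences across models on the same response are meaningful; RSS = 0 maps to
−∞ with perfect-fit handling in the weights. Retention uses the strict rule
adjusted r² > 0.799 ("higher than"), and Akaike/BIC weights
wᵢ = exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2) are computed over the retained set (falling back
to all models, with a warning and a flag, if nothing is retained).

## Validation

APE(%) = 100·|predicted − observed|/observed per patient. The summary reports
the median (the field's "MAPE") *and* mean ± sample SD under explicit labels,
because both conventions circulate; the clinical-acceptability fraction counts
APE strictly above 15%. Bland–Altman agreement uses differences
d = predicted − observed with limits mean(d) ± 1.96·SD(d) (sample SD, n−1
denominator). Fixed published equations are built in: the two external
pediatric three-point equations (intercepts 39.179 and 46.062) and the four
retained equations of the emulated cohort, usable by name
(`model7/12/13/15`, `almeida_c0c1c4`, `almeida_c0c2c4`).

Subgroup consistency (brand, genotype, expression, age band) is an
ANCOVA-style F-test: observed ~ predicted + group versus observed ~ predicted,
F = ((RSS_r−RSS_f)/Δdf)/(RSS_f/df_resid). Its type-I error is verified by
simulation to sit at the nominal 5%.

Cross-validation (an addition over the in-sample reference workflow): K-fold
with seeded shuffling, stratified round-robin within expressor status so
genotype balance survives small cohorts; per-fold fits on training patients,
APE pooled over held-out patients.

## Numerical and design choices

- CSV storage at full double precision; reading uses the round-trip float
  parser (the default parser is 1 ulp off). Display rounding only in the
  rendered report.
- One config seed drives every stage; stage-local randomness (fold shuffles)
  derives from it.
- Exclusions are auditable: profiles missing any of the six nominal labels are
  excluded from AUC work with a logged count; duplicate (patient, label) rows
  and orphan patients are hard errors.
- Analysis problem sizes were chosen to keep a desk run fast: default cohorts
  of n = 51 (the emulated study size), 100-seed replication for ordering
  properties, n = 200 for coefficient recovery, 2000 replicates for test
  calibration, and n = 500 for the noise-free precision check.

## Known limitations

- The simulator's parameters are calibrated to *summary statistics* of one
  published cohort, not fitted to patient-level data; absolute regression
  coefficients from simulated cohorts need not match published equations,
  though their structure (which subsets win, how weights concentrate) does.
- At n = 51 the full qualitative adjusted-r² ranking across subsets is
  intrinsically unstable: replicated simulations reproduce the reference
  ordering C₀ < C₄ < {C₀,C₄} < {C₀,C₁,C₄} in roughly 92% of cohorts, not
  always — single-cohort rankings should be read with that sampling
  variability in mind.
- With measurement noise removed entirely, weak single-point models can still
  clear the 0.799 retention bar while carrying ~3% median error: a single
  time-point cannot determine AUC exactly under between-subject parameter
  diversity.
- In-sample MAPE flatters any equation fitted and scored on the same cohort;
  the cross-validated MAPE is the honest counterpart and is consistently
  slightly larger.
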