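# taclss

Limited-sampling-strategy (LSS) development and validation for **extended-release
tacrolimus** exposure monitoring in pediatric kidney transplant recipients, with
CYP3A5 pharmacogenetics and a synthetic steady-state pharmacokinetic cohort
generator.

## The problem

Tacrolimus has a narrow therapeutic window, and the routine monitoring marker —
the pre-dose trough C₀ — correlates poorly with true drug exposure. The exposure
measure that matters is the area under the concentration–time curve over one
once-daily dosing interval, AUC₀₋₂₄ (ng·h/mL), estimated from a full six-sample
profile (C₀, C₁, C₂, C₄, C₁₂, C₂₄) by the linear trapezoid rule. Full profiles
are impractical in children, so clinicians use *limited-sampling strategies*:
linear equations

    AUC₀₋₂₄ ≈ β₀ + β₁·C₀ + β₂·C₁ + β₃·C₄   (and other subsets of C₀…C₄)

fitted by ordinary least squares, retained when adjusted r² > 0.799, compared by
Akaike/BIC weights, and judged clinically by the absolute prediction error
APE(%) = 100·|LSS-AUC − trapezoidal AUC|/trapezoidal AUC (acceptable below 15%)
and by Bland–Altman limits of agreement.

Dose requirements are strongly pharmacogenetic: carriers of a functional
CYP3A5*1 allele ("expressors", genotypes \*1/\*1 and \*1/\*3 at SNP rs776746)
clear tacrolimus faster and need roughly 1.5–2× higher weight-normalized daily
doses (TAC-D, mg/kg) than \*3/\*3 non-expressors. The package reproduces the
accompanying genetics: allele frequencies, Hardy–Weinberg goodness of fit, and
expressor-contrast tests (ANOVA, Fligner–Killeen, Mann–Whitney U).

Because patient-level data are rarely shareable, the pipeline is driven by a
**synthetic cohort generator**: a two-compartment oral steady-state model with
genotype-dependent clearance, log-normal between-subject and inter-occasion
variability, trough-targeted dose titration emulating therapeutic drug
monitoring, and immunoassay-like measurement error — with analytic ground-truth
AUC (1000·dose/CL) carried alongside for recovery tests.

## Who it is for

Clinical pharmacologists and biostatisticians developing or auditing LSS
equations for therapeutic drug monitoring, and methodologists who want a
controlled test bed where the true exposure of every "patient" is known.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_exposure_metrics.py
python analysis/03_cyp3a5_genetics.py
python analysis/04_fit_lss_models.py
python analysis/05_validate_lss.py --seed 1
python analysis/06_render_report.py
```

Output of the model-building step (seed 1):

```
15 candidate models, 4 retained (adj r2 > 0.799) -> results/lss_models.csv
  model  7  adj r2 0.8743  MAPE  4.6%  AICw 0.005  BICw 0.014  AUC = 13.64 + C0*10.87 + C4*11.19
  model 12  adj r2 0.8988  MAPE  3.9%  AICw 0.712  BICw 0.843  AUC = 8.816 + C0*11.8 + C1*1.716 + C4*8.926
  model 13  adj r2 0.8838  MAPE  5.2%  AICw 0.021  BICw 0.025  AUC = 8.049 + C0*11.94 + C2*1.501 + C4*9.227
  model 15  adj r2 0.8966  MAPE  3.8%  AICw 0.263  BICw 0.119  AUC = 9 + C0*11.76 + C1*1.759 + C2*-0.08199 + C4*8.976
best by AIC weight: model 12 (C0-C1-C4)
```

Reading this: of the 15 subset regressions of trapezoidal AUC₀₋₂₄ on
{C₀, C₁, C₂, C₄}, four clear the adjusted-r² retention bar — the C₀+C₄ pair,
both three-point equations, and the full four-point model. The three-point
C₀-C₁-C₄ equation carries ~71% of the Akaike weight (the probability of being
the best retained model) with an in-sample median APE of 3.9%: three morning
samples recover the full 24-h exposure within clinical tolerance. The genetics
step prints the expressor contrast (TAC-D 0.151 vs 0.091 mg/kg, Mann–Whitney
p = 2.4×10⁻⁵), and the validation step scores the fitted equation together with
published pediatric three-point equations, adding Bland–Altman limits and a
stratified 5-fold cross-validated MAPE.

The same stages are available as a CLI (`taclss simulate | exposure | pgx |
lss fit | lss validate | run | report`) for custom cohorts in the documented
CSV contract.

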