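# iohexolpk

Population-pharmacokinetic estimation of glomerular filtration rate (GFR)
in dogs from sparse iohexol sampling, with Monte-Carlo selection of the
best sampling times per patient.

## The problem

Iohexol plasma clearance is a reference method for measuring GFR, but the
classical protocol needs many blood samples over several hours. If a
population pharmacokinetic (Pop-PK) model of iohexol is available, a
single dog's clearance can be estimated from one to three well-chosen
samples by empirical-Bayes (MAP) estimation — and *which* samples are best
depends on the dog's covariates (kidney-disease status, serum creatinine).
This package implements that workflow end to end for veterinary
pharmacologists and PK methodologists:

- a two-compartment IV-bolus structural model with log-normal
  inter-individual variability and proportional residual error,

  φᵢ = A θ exp(ηᵢ),  ηᵢ ~ N(0, Ω),  Yᵢⱼ = f(tᵢⱼ; φᵢ) + b·f·εᵢⱼ,

  with the covariate model
  ln Cl = ln θ_Cl + θ₁·1[CKD+] + θ₂·(creatinine − c₀) + η_Cl;
- MAP/empirical-Bayes estimation of a dog's random effects from sparse
  concentrations by minimising the penalised objective
  Σₜ [(yₜ−f)²/g² + ln g²] + η′Ω⁻¹η (damped Gauss–Newton, multi-start
  fallback);
- a design optimiser that simulates 5000 replicate profiles per covariate
  combination and scores every 1/2/3-point combination K on the 30–180 min
  grid by MSE_K = mean (η̂_Cl − η*_Cl)², the squared log-scale distance
  between estimated and true clearance;
- non-compartmental clearance (Dose/AUC, linear-up/log-down with terminal
  extrapolation) and Bland–Altman agreement as the comparator;
- a Laplace-approximation NLME fitter (`TwoCompartmentNLME` /
  `NLMEResults`, statsmodels-style) to estimate the population parameters
  from new cohorts, with SEs, AIC/BIC and per-dog EBEs;
- a synthetic-cohort generator (49 dogs: 29 CKD−, 20 CKD+, five samples at
  5/15/60/90/180 min after a 64.7 mg/kg bolus) and VPC summaries.

The packaged default parameters (`iohexolpk/data/canine_iohexol.yaml`) are
the published canine estimates: θ_Cl = 0.00212 L/min/kg,
θ_V1 = 0.163 L/kg, θ_V2 = 0.058 L/kg, θ_Q = 0.0034 L/min/kg,
θ₁ = −0.379, θ₂ = −0.421 dl/mg, ω = (0.208, 0.248, 0.199), b = 0.0617.

## Worked example

Estimate a healthy dog's GFR from two samples (90 and 120 min; µg/ml):

```
$ iohexolpk ebe --ckd 0 --creatinine 0.98 --obs "90:180.5,120:140.2"
{
  "eta": {
    "cl": -0.6377929148686837,
    "v1": -0.18996658929543284,
    "v2": -0.11988659570822281
  },
  "clearance_L_min_kg": 0.001377008198777034,
  "gfr_ml_min_kg": 1.377008198777034,
  "objective": 20.362150753723405,
  "converged": true,
  "n_iterations": 34
}
```

The concentrations are high for a healthy dog, so the MAP random effect on
clearance is strongly negative (η_Cl = −0.64) and the estimated GFR,
1.38 ml/min/kg, is well below the healthy typical value of
≈2.6 ml/min/kg at this creatinine — this dog filters like a CKD patient.

Rank single sampling times for a CKD+ dog with creatinine 2.25 mg/dl:

```
$ iohexolpk optimize-design --ckd 1 --creatinine 2.25 --n 2000 --seed 42 \
      --max-samples 1 --out designs.csv
INFO iohexolpk: best 1-sample design: 180 (MSE 0.00775)
```

`designs.csv` lists all six candidate times ranked by MSE_K (here
180 > 150 > 120 > 90 > 60 > 30 min from best to worst): for an azotaemic
dog the single sample should be drawn as late as possible, matching the
published recommendation. For a healthy, low-creatinine dog
(`--ckd 0 --creatinine 0.98`) the same command ranks 90 and 120 min at the
top — a statistical near-tie, consistent with the published advice that
either time works.

Other subcommands: `simulate` (synthetic cohort CSV), `nca`, `agree`
(Bland–Altman), `fit` (Laplace NLME), `reproduce-tables`. Python API
mirrors the CLI: `estimate_ebe`, `best_times_for_dog`, `nca_clearance`,
`TwoCompartmentNLME.from_dataframe(...).fit().summary()`, ….

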