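# egfrkit

Development and evaluation of glomerular filtration rate (GFR)
estimation models for chronic kidney disease (CKD) cohorts.

Measured GFR (mGFR, e.g. by ⁹⁹ᵐTc-DTPA renal dynamic imaging) is too
costly for routine care, so clinicians estimate GFR (eGFR) from serum
filtration markers and demographics. `egfrkit` implements three such
estimators and everything needed to develop and validate them on a
patient cohort:

1. **A revised 4-variable CKD-EPI-style equation** (age, sex, serum
   creatinine Scr, serum cystatin C Scys) — a sex-stratified piecewise
   multiplicative model

   eGFR = I · min(Scr/κ_scr, 1)^α₁ · max(Scr/κ_scr, 1)^α₂ ·
   min(Scys/κ_scys, 1)^β₁ · max(Scys/κ_scys, 1)^β₂ · f_age^Age

   with marker knots κ and negative log–log slopes α, β. The shipped
   constant set has intercepts 122 (female) / 107 (male), knots
   0.7 / 0.9 mg/dL (Scr) and 0.9 mg/L (Scys), and age factors
   0.995 / 0.996 per year.
2. **A revised 9-variable equation** adding BMI, blood urea nitrogen
   (BUN, as a power term), albumin, uric acid and hemoglobin as
   auxiliary multiplicative factors (intercepts 154 / 103).
3. **A 9-variable neural network** — 9 inputs → 4 Leaky-ReLU
   (α = 0.1) hidden units → 1 linear output, trained by mini-batch SGD
   on MSE, implemented with explicit matrices so that an exported flat
   weight file reproduces every prediction with plain arithmetic.

Around the estimators the package provides: the OLS development
pipeline on the log scale with exhaustive grid search for the spline
knots; the standard evaluation triad — bias (median of eGFR − mGFR),
precision (IQR of the difference), P30 (% of estimates within ±30% of
mGFR) — with subject-level percentile-bootstrap 95% CIs (2000
resamples) and paired tests (Wilcoxon signed-rank for bias, sign-swap
permutation for precision, McNemar for P30), overall and within mGFR
strata; and a synthetic CKD cohort generator with an exactly known
multiplicative GFR–marker law so the whole pipeline is testable without
patient data. See `docs/methods.md` for the modelling details.

## Worked example

Run the full study design — simulate a cohort of 2000 under the
9-variable generating law, split temporally at 2014-12-31, develop both
equations, train the network, evaluate on the validation half:

```python
from egfrkit import RunConfig, SyntheticCohortSpec, revised_ckdepi_9var, run

cfg = RunConfig(
    simulate=SyntheticCohortSpec(n=2000,
                                 generating_equation=revised_ckdepi_9var()),
    split_mode="temporal", temporal_cutoff="2014-12-31",
    out_dir="demo_run", seed=7)
out = run(cfg)        # writes equations, ANN weights, report, manifest
```

The overall rows of `demo_run/report.csv` from this exact run:

```
        model   n   bias  bias_ci_low  bias_ci_high  precision    p30  p30_ci_low  p30_ci_high  p_bias  p_precision  p_p30
4var_equation 644 -1.273       -2.630         0.171     21.154 79.658      76.553       82.609     NaN          NaN    NaN
9var_equation 644 -0.633       -2.109         0.458     19.047 84.627      81.832       87.267   0.027        0.000    0.0
     9var_ann 644 -0.778       -2.239         0.206     19.538 84.938      82.143       87.578   0.006        0.055    0.0
```

Reading: all three models have small bias (mL/min/1.73 m²; the CI
columns are bootstrap 95% limits); the 9-variable models — which see
the auxiliary variables that this synthetic law actually uses — gain
about 5 percentage points of P30 accuracy over the 4-variable equation
(84.9% and 84.6% vs 79.7%), and the McNemar comparison against the
4-variable reference is highly significant (`p_p30` < 0.001). The
manifest records the seeds, the development/validation counts
(1356/644) and the grid-selected knots.

The same pipeline runs from the shell: `egfrkit run --config run.yaml`,
plus subcommands `simulate`, `estimate`, `develop`, `ann-train`,
`ann-predict` and `evaluate` for the individual stages
(`egfrkit --help`).

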