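# Methods

## The estimation problem

Serum concentrations of endogenous filtration markers (creatinine,
cystatin C) depend inversely on GFR plus non-GFR determinants (muscle
mass, inflammation, ...). eGFR models map markers and covariates to the
measured GFR scale (mL/min/1.73 m²). This package implements the three
model families it studies — two piecewise multiplicative equations and
a small neural network — together with the development pipeline and the
evaluation protocol, and a synthetic cohort generator that makes every
stage testable end to end.

## Piecewise multiplicative equations

Per sex the model is

    eGFR = I · min(Scr/κ_s, 1)^α_lo · max(Scr/κ_s, 1)^α_hi
             · min(Scys/κ_c, 1)^β_lo · max(Scys/κ_c, 1)^β_hi
             · f_age^Age · Π aux_terms

Auxiliary terms are per-unit factors c^x (BMI, albumin, uric acid,
hemoglobin) or powers x^e (BUN). The min/max form is algebraically
identical to enumerating the four ≤/> branch combinations printed in
the conventional presentation of these equations and is continuous at
the knots by construction (both branches contribute exactly 1 at
x = κ), which eliminates branch-boundary bugs; the boundary convention
is therefore immaterial. The engine evaluates exactly the constants in
its JSON fixture; the two shipped constant sets are stored in
`src/egfrkit/data/` in the same format the fitting pipeline emits.

Units: creatinine mg/dL (an optional read-time flag converts µmol/L
input by ÷88.4), cystatin C mg/L, BUN mg/dL, albumin g/dL, uric acid
mg/dL, hemoglobin g/dL. Hemoglobin is deliberately documented in g/dL
(values ≈ 12): the magnitudes of the shipped per-unit factors
(1.012^HGB, 1.027^HGB) are only sensible for g/dL-scale values, and a
"g/L" label sometimes attached to such data appears to be a units typo.

## Equation development

After a natural-log transform of mGFR, Scr, Scys and BUN the model is
linear: ln mGFR regressed on the two-segment linear splines
min/max(ln(marker/κ), 0), age, and (for the 9-variable set) BMI,
ln BUN, albumin, uric acid, hemoglobin. Fits are ordinary least squares
(via statsmodels), fully stratified by sex — separate intercepts,
slopes, age and auxiliary factors — because every published constant of
this family differs by sex. Exponentiating the coefficients yields the
multiplicative equation; the exp/log round trip is exact to 1e-12 and
is tested.

Knots are selected by exhaustive grid search minimising the pooled
log-scale residual sum of squares: a sex-specific creatinine knot and a
single cystatin knot shared by both sexes (the shipped constant sets
use one cystatin knot). Default grids: Scr 0.5–1.5 mg/dL, Scys
0.6–1.4 mg/L, both in steps of 0.1. Ties break toward the smaller
knot; candidates yielding singular designs are skipped with a warning.
The 9-variable fit inherits the knots selected under the 4-variable
design (the two shipped sets share identical knots); this is a
configurable override. The selection criterion and inheritance rule are
design choices of this package — the procedure is the simplest one
consistent with the family's structure. Note that knot *location* is
only weakly identified when the slope change across the knot is small
(the male 4-variable set changes by just 0.066), so grid-search
recovery is only asserted for laws with a pronounced kink.

Display rounding (`rounded_equation`): intercepts to integers, other
constants to three decimals; the engine itself always uses unrounded
values unless the rounded fixture is requested.

## The neural network

Architecture is fixed at 9 inputs → 4 hidden Leaky-ReLU units
(negative-side slope 0.1) → 1 linear output; 49 parameters in total.
It is implemented from first principles (explicit matrices, manual
backpropagation, seeded `numpy` RNG) because the exported flat weight
file must reproduce predictions by plain arithmetic — e.g. in a
spreadsheet — and tests demand bit-level control of the forward pass
and gradients (analytic gradients are verified against central finite
differences to 1e-4).

Preprocessing and training defaults (all exposed in `TrainConfig`):
z-scoring of the eight continuous inputs with development-set
statistics recomputed after outlier removal; sex passed as 0/1
unscaled; outlier rule |z| > 3 on any continuous variable including the
target; MSE loss; learning rate 0.01; batch size 32; up to 2000 epochs
with early stopping on a 10% held-out fraction (patience 50, best
weights restored); uniform fan-in-scaled initialization. Training is
bit-reproducible given the seed. The target may be regressed on the
identity scale (default) or as ln mGFR (`target_scale="log"`), and
skewed inputs may be log-transformed before z-scoring
(`log_inputs=("scr", "scys", "bun")`); the log options mirror the
transforms under which the GFR–marker relation is near-linear, and the
heavy right tail of raw creatinine otherwise compresses most subjects
into a sliver of the z-scored axis that four hidden units approximate
poorly. The pipeline's default training recipe therefore uses the log
target and log marker inputs; the identity/raw default of `TrainConfig`
is retained for the plain z-scoring recipe. Reported predictions are
floored at 1 mL/min/1.73 m² to avoid nonphysical non-positive
estimates; the floor is part of the documented prediction contract and
of the flat-file evaluation.

## Evaluation protocol

For per-subject differences d = eGFR − mGFR: bias = median(d),
precision = IQR(d), P30 = 100 · mean(|d| ≤ 0.3·mGFR). Quantiles use
linear interpolation between order statistics (the numpy default; the
convention is a parameter). 95% CIs are subject-level percentile
bootstrap intervals, 2000 resamples by default, seeded.

Paired comparisons against a reference model:

* **Bias** — two-sided Wilcoxon signed-rank on the per-subject
  difference of differences d₁ − d₂ (the most direct paired reading;
  |d₁| − |d₂| is available behind a flag). For ≤ 25 non-zero pairs the
  null is computed exactly by dynamic programming over doubled
  midranks, which handles ties that closed-form exact methods cannot;
  above that, the normal approximation with tie correction.
* **Precision** — paired sign-swap permutation test: the model labels
  are swapped within subject with probability ½; statistic
  T = IQR(d₁) − IQR(d₂); two-sided p with the add-one correction,
  2000 permutations by default. Agrees with exhaustive enumeration for
  small n (tested at n = 12).
* **P30** — McNemar on the discordant within-30% indicators: exact
  binomial when b + c < 25, chi-square with continuity correction
  otherwise.

Strata: overall, mGFR < 60, ≥ 60, and the finer < 30 / 30–59 / 60–89 /
≥ 90 split, boundaries left-closed. Empty strata are reported as
absent, not zero. Both stratifications can be produced so either
subgroup reading of a result is available.

## Synthetic cohorts

The generator emulates a single-center CKD referral cohort: 57.3% male;
age 55.6 ± 14.5 y truncated to [18, 95]; mGFR 71.0 ± 27.4 truncated to
[5, 180]; BMI 24.0 ± 3.6; albumin 3.9 ± 0.5 g/dL; uric acid
6.7 ± 2.1 mg/dL; hemoglobin 12.3 ± 2.3 g/dL correlated 0.3 with GFR;
BUN lognormal around a power law in GFR (slope −0.5 on the log scale,
sample-mean calibrated to 20.9 mg/dL).

The markers encode an exactly known law. A latent true GFR g is drawn
so that the *recorded* mGFR = g · exp(δ), δ ~ N(0, `gfr_noise_sd`,
default 0.2) — lognormal measurement error of the reference method —
matches the target marginal moments (lognormal moment correction of
the latent mean/SD). The total marker log-contribution required by the
generating equation, T = ln g − ln I − age/aux terms, is split between
cystatin C (share w ~ Beta(8, 8)) and creatinine, plus a compensated
marker-specific lognormal noise u (`marker_noise_sd`, default 0.2,
scaled to the marker log scale) added to one marker and subtracted from
the other; each marker is then recovered by exactly inverting its
two-branch power law. Consequently `equation(markers) == g` holds
identically and the only noise between response and prediction is δ.

This construction is deliberate: if instead the markers were noised
while the recorded mGFR stayed fixed, the regression residual would be
correlated with the regressors (an errors-in-variables design) and OLS
recovery of the generating exponents would be attenuated by tens of
percent — no tolerance could certify the fitting pipeline. With noise
in the response, recovery is unbiased and the parameter-recovery tests
are sharp. The compensated marker noise and the random share give both
markers realistic, partly independent variation around the law.

What the generator does *not* emulate: real non-GFR determinants that
are independent per marker (here they are compensated by
construction), informative missingness (only optional MCAR masking),
measurement-protocol drift over calendar time (visit dates are uniform
and independent of everything else), and the exact joint distribution
of a real cohort. Tests passing on these cohorts certify the
algorithms — transforms, fits, tests, bookkeeping — not clinical
performance on real patients.

## Pipeline and reproducibility

`run(RunConfig)` chains simulate/load → exclusion filtering (age < 18
plus caller-provided flags such as dialysis; clinical criteria that
cannot be computed from labs are pass-through flags) → complete-case
filtering (no imputation) → temporal (cutoff inclusive on the
development side) or seeded random split → equation development → ANN
training → stratified evaluation. One global seed derives per-stage
seeds via `numpy.random.SeedSequence([global_seed, stage_index])`; the
manifest records them with the attrition count of every step, and a
rerun with the same config is bit-identical.

Problem sizes used by the shipped checks (chosen as the package's
standard desk-scale study conditions): parameter recovery n = 5000 ×
20 seeds; knot recovery n = 2000 with response noise 0.05 and a planted
slope change of 0.4; the network-vs-equation comparison 1000
development / 800 validation subjects × 10 seeds under the 9-variable
generating law; bootstrap coverage 200 simulations of n = 80 at
B = 500.

## Known limitations

* Knot search assumes the grid brackets the truth; weak kinks are not
  localizable at desk-scale n (see above).
* The exact Wilcoxon null is O(n · ΣR) via DP — fine for the n ≤ 25
  regime it serves; larger samples use the normal approximation.
* The permutation and bootstrap p-values/CIs are Monte-Carlo estimates;
  their resolution is bounded by 1/(n_perm + 1) and B.
* The network's width is configurable but only the 9→4→1 shape is
  exercised by tests; there is no hyperparameter search.
* A fitted equation with a non-negative marker slope (possible on
  degenerate data) cannot be represented — the family requires
  non-positive exponents and construction fails loudly.
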