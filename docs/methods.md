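# Methods

## The problem

Critically ill patients on continuous-infusion piperacillin/tazobactam show
extreme between-patient variability in piperacillin exposure; the same
regimen can leave one patient subtherapeutic and push another into the
toxicity range. `pipuq` implements the two prediction routes used in this
setting — a machine-learning route that maps routinely available covariates
to a concentration, and a mechanistic population-pharmacokinetic (PopPK)
route — and, crucially, attaches a *calibrated predictive distribution* to
the ML point prediction so that target-attainment probabilities can be
reported instead of a bare number.

## Quantile Ensemble

Three quantile regressors are trained on the same features: one at the
median (the regression output μ̃) and two at levels `0.5 ± p/2`, where the
coverage `p` is a hyperparameter (defaults: 0.80 for the *new*/a-priori
model, 0.82 for the *prev*/a-posteriori model). Under a Gaussian assumption
the spread of the two outer predictions identifies the standard deviation:

    σ̃ = (ỹ_U − ỹ_L) / (2·√2·erf⁻¹(p))

Because σ̃ is recomputed per sample, the method is heteroscedastic: each
patient gets an individual uncertainty. Any learner that minimises the
pinball loss at a prescribed level satisfies the contract; the reference
implementation is scikit-learn's gradient-boosted trees with the quantile
objective. Independent quantile learners can cross (ỹ_U ≤ ỹ_L); σ̃ is then
floored at 1e−6 mg/L and a warning is logged.

All downstream inferences are Gaussian quantile algebra: centered intervals
`[Q((1−p)/2), Q((1+p)/2)]` and the mass between two bounds
`½[erf((y_U−μ̃)/(σ̃√2)) − erf((y_L−μ̃)/(σ̃√2))]`, which also yields the
sub-/therapeutic/supra-therapeutic category probabilities.

## Calibration metrics (ADCE / DCE) and sharpness

For a nominal level `p`, `C(p)` is the fraction of observations inside their
centered `p`-interval (PICP with inclusive bounds). Sweeping `p` over the
grid `i/S, i = 0..S` (default `S = 1000`):

    DCE  = (2/S) Σ (C(i/S) − i/S)        signed: + conservative, − overconfident
    ADCE = (2/S) Σ |C(i/S) − i/S|        average miscalibration; |DCE| ≤ ADCE

With the inclusive endpoints the attainable extreme is `(S+1)/S`, slightly
above 1. At `p = 1` the interval is the limit `μ ± ∞·σ`: infinite (coverage
1) whenever σ > 0, and still zero-width in the degenerate σ = 0 case — this
limit convention is what makes the degenerate closed form
`ADCE = (S+1)/S, DCE = −(S+1)/S` exact. The sweep is computed in one sorted
pass over the standardised residuals `|y−μ̃|/σ̃` rather than S+1 PICP calls.
Sharpness is the mean and *population* (divide-by-N) standard deviation of
the σ̃ vector; a zero std identifies a homoscedastic model, such as the
constant-σ baseline built from training residuals.

## Population PK model

Two compartments with parallel first-order and Michaelis–Menten elimination,
both acting on the central compartment (the published model names the
structure but not the ODEs; this is the standard pharmacometric reading):

    dA1/dt = R(t) − (CL/V)·A1 − Vmax·C/(Km+C) − (Q/V)·A1 + (Q/Vp)·A2
    dA2/dt = (Q/V)·A1 − (Q/Vp)·A2,    C = A1/V

Covariates: `CL = TVCL·(CLcr/100)·(W/70)^0.75`, `V = TVV·(W/70)`,
`Vp = TVVp·(W/70)`, `Q = TVQ·(W/70)^0.75`; Km and Vmax carry none.
Typical values: TVCL 9 L/h, TVV 6.18 L, TVVp 11.17 L, TVQ 15.61 L/h,
Km 37.09 mg/L, Vmax 353.57 mg/h.

Numerics: LSODA (stiff-capable) with rtol 1e−8 and integration restarted at
every infusion-rate breakpoint, so the rate discontinuities never cross a
solver step; the state is always propagated to the exact segment boundary.
At steady state the peripheral compartment carries no net flux, so the
concentration solves `rate = CL·C + Vmax·C/(Km+C)`; the right side is
strictly increasing from 0, giving a unique root found by Brent's method
(bracket `[0, rate/CL + Km + 1]`, doubled until it brackets; residual
tolerance ~1e−9 relative). The a-priori predictor is this solve at the
covariate-model parameters — deterministic, no residual uncertainty.

The published 95% parameter intervals are not used in deterministic
prediction; between-patient dispersion enters only through the synthetic
generator's IIV (below). Bayesian MAP estimation of individual parameters is
out of scope: individual estimates are accepted as inputs.

## Clinical layer

- Renal formulas: Cockcroft–Gault on actual body weight (the "adjusted"
  variant is not specified in the source; ABW is the default, documented),
  4-variable IDMS-traceable MDRD (coefficient 175 — the contemporary
  standard; the 186 variant is a one-line change), CKD-EPI 2009. Missing
  measured CLcr is replaced by the weighted combination `(CG + 2·MDRD)/3`.
- Site dosing (piperacillin component, 4000 mg/0.5 h load always): GUH
  <15 mL/min → 333.33 mg/h, 15–29 → 500, ≥30 → 666.67; UMCG <20 → 333.33,
  20–39 → 333.33 for the first 24 h then 500, ≥40 → 500.
- Therapeutic window on total plasma: `lower = 4·MIC/(1−bf)`,
  `upper = 112/(1−bf)`; defaults MIC 16 mg/L, binding fraction 0.30 →
  91.43 / 160 mg/L. Category boundaries are `≥ lower` and `< upper` for
  observed and predicted concentrations alike.
- Classification metrics are one-vs-rest precision, specificity,
  sensitivity, F1 and support from the 3×3 confusion matrix; a class absent
  from the truth reports NaN sensitivity with a warning.

## Synthetic cohort generator

The generator is a stated world, not a tuning knob. Covariates are drawn
from distributions matched to the published site medians/IQRs — normal for
anthropometrics (sd = IQR/1.349), log-normal for skewed labs (log-sd =
ln(q3/q1)/1.349, median preserved). Creatinine clearance is *not* drawn
independently: it is proportional to each patient's Cockcroft–Gault estimate
(so it co-varies with age, weight, sex and serum creatinine), rescaled to
the site median and multiplied by a log-normal factor of log-sd 0.25 — a
modeling choice, since the true covariate correlations are not published.
Temperature, urine creatinine, hemoglobin and red cells are not tabulated in
the source cohorts; realistic ICU values were chosen once and documented in
the code.

Concentrations: individual PK parameters are the covariate model times
log-normal IIV (CV 30% on CL, 25% on V/Vp/Q — magnitudes are generator
choices; the source model reports only parameter CIs), the regimen follows the site
protocol, and samples are drawn every 24 h (the 6 a.m. steady-state draw);
each patient contributes 1..n_days records uniformly (default n_days = 3,
reproducing the published median of 2 samples/patient, IQR 1–3). "True"
concentrations default to the analytic steady state of the rate active at
the sample time — the samples are steady-state material by design, and this
makes the zero-noise self-consistency with the a-priori predictor *exact* —
with the full ODE available as `method="ode"` (agreeing to ≲0.1% by day 3).
Observations add proportional (CV 15%) plus additive (sd 2 mg/L) residual
error, floored at 0.1 mg/L. A single seed fans out into named substreams
(cohort, records, iiv, residual, missingness, split, hetero), so each
component is independently reproducible.

Missingness is injected completely at random at the published per-feature
rates (e.g. urine creatinine 39/752); imputation reproduces the study rules:
previous/next-value fill within patient for low-missingness features, the
weighted CG/MDRD formula for CLcr, mean or −999 sentinel for urine
creatinine and temperature, and dropping (with a reported count) of rows
that remain incomplete. The patient-level split takes ⌈25%⌉ of patients with
≥2 records, stratified by record count; the a-priori view zeroes the
previous-concentration link, the a-posteriori view drops each test patient's
first record.

What a green test establishes: correctness of the pipeline and the
statistical behaviour of the estimators under the stated generative model.
What it does not: clinical performance — the generator has no within-day
covariate dynamics, no RRT/ECMO physiology, no correlated lab panels beyond
the renal axis, and its ML signal is by construction the PK model's own
covariates.

## Metric conventions

ME = mean(predicted − observed). Percentage errors divide by the
*prediction*: MdPE = median((obs − pred)/pred)·100, MdAPE the absolute
version — the only convention consistent with every published (ME, MdPE)
sign pair. Log-scale variants use natural logs. Clinical acceptability
follows the Struys criteria: MdAPE ≤ 30% and MdPE ∈ [−20%, 20%] on the
natural scale, boundaries inclusive. Bias compensation subtracts a reference
ME from the predictions, recentring the mean error to zero.

## Known limitations

- The Gaussian predictive family is an assumption; heavy-tailed or skewed
  error structure would miscalibrate the tails even at ADCE ≈ 0.
- Quantile crossing is handled by flooring, not by rearrangement.
- The homoscedastic baseline is a stand-in for a Gaussian-process contrast,
  not a GP.
- The synthetic world shares its PK model with the a-priori predictor, so
  PopPK-vs-ML comparisons on synthetic data favour PopPK by construction and
  are not evidence about real cohorts.
- %fT>MIC (time above MIC) is deliberately not computed.
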