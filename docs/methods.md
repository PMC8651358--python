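# Methods

## The process model

Diabetic retinopathy severity is modelled as a progressive
continuous-time Markov chain on five states: 1 no retinopathy, 2 mild
NPDR, 3 moderate NPDR, 4 severe NPDR, 5 PDR.  Three structural
assumptions define the chain:

* **Irreversibility.** The generator is strictly upper triangular; a
  recorded improvement in the data is treated as grading noise and
  clamped by the running maximum of observed stages (the per-cohort
  count of clamped visits is reported in the cleaning metadata).
* **Stage skipping.** All ten forward transitions q_rs (r < s) carry
  their own baseline intensity, so the latent process can pass through
  several stages between two visits and panel observation can show
  apparent multi-stage jumps.
* **Absorbing PDR.** Row five of the generator is zero; visits recorded
  after a patient first reaches PDR are retained in the data but
  contribute no likelihood intervals.

Covariates act proportionally on all intensities with one shared
coefficient per covariate: `q_rs(z) = exp(θ_rs + Σ_k β_k (z_k − c_k))`.
The centering constants c_k are stored in the model object; continuous
covariates (age, diabetes duration, HbA1c, blood pressure) default to
cohort means and indicators (Hispanic, female, hypertension) to zero,
so `exp(θ_rs)` is interpretable as the intensity for a non-Hispanic
patient at mean covariates.  Predictions accept covariates on the
original scale.  Shifting a centering constant while moving θ by
β·shift describes the same process; the likelihood is invariant to the
convention (tested).

## Panel likelihood

Stages are interval censored: only the state at each visit time is
known.  Because time-dependent covariates are frozen at the value
observed at the start of each inter-visit interval, each interval is a
homogeneous chain and its transition law is a single matrix exponential
`P = exp(Q(z_j) Δ_j)`.  The log-likelihood conditions on each patient's
first observed state and sums `log P[s_j, s_{j+1}]` over consecutive
visit pairs; the baseline stage distribution is not modelled.  An
interval that begins in PDR contributes nothing; a recorded regression
(impossible under the model) raises an error naming the patient, which
is why stage clamping precedes fitting.

**Estimation.** Parameters are optimized as unconstrained log
intensities plus covariate coefficients by L-BFGS-B, with box bounds
θ ∈ [−12, 3] (an intensity of e^−12 ≈ 6·10⁻⁶/yr is zero at any
relevant horizon; a θ pinned at the bound triggers a boundary warning)
and β ∈ [−6, 6].  Baseline intensities initialize at crude rates —
observed direct-transition counts over total time at risk, floored at
10⁻³ for unobserved transitions — and coefficients at zero.
Convergence uses a relative likelihood-change tolerance of 1e-9 with a
cap of 1000 iterations; exhausting the cap raises an error.  The
covariance matrix is the inverse numerical Hessian at the optimum
(finite differences); if it is not positive definite a warning is
emitted and interval-based inference is disabled.  Hazard-ratio tests
and 95% CIs are Wald on the log scale.

**Gradients.** The exact likelihood gradient is computed with the
Fréchet-derivative adjoint of the matrix exponential: for each
interval, the exponential of the block matrix `[[Aᵀ, W], [0, Aᵀ]]`
(A = QΔ, W the indicator of the observed matrix entry) simultaneously
yields the interval probability and the sensitivity of its observed
entry to every generator entry, from which the chain rule gives the
whole gradient in one batched operation.  The gradient agrees with
central finite differences to ~1e-7 (tested).

**Matrix exponentials.** All exponentials of interval generators are
evaluated with a vectorized scaling-and-squaring Padé(13) routine
batched over intervals, cross-checked against `scipy.linalg.expm` to
1e-12 over a range of norms.  Scaling-and-squaring (rather than a
spectral closed form) matters here because the upper-triangular
generator can have repeated diagonal entries, where eigendecomposition
is singular.  Probabilities are cleaned of roundoff (tiny negatives
clipped, exact zeros below the diagonal).

## Sojourn times and derived quantities

The expected time in state r from t₀ integrates the survival of the
state's exit hazard λ_r(t) = Σ_{s>r} q_rs(z(t)), which is piecewise
constant under the covariate schedule.  With segment rates λ_k over
lengths Δ_k,

    S = Σ_k [ Π_{j<k} e^(−λ_j Δ_j) ] · (1 − e^(−λ_k Δ_k)) / λ_k ,

with the Taylor limit Δ_k − λ_k Δ_k²/2 used below λ_k Δ_k < 1e-8 to
avoid 0/0.  After a patient's last visit the covariate vector is
carried forward to the integration horizon (default 20 years,
configurable).  The truncation remainder is reported as a diagnostic:
the survival remaining at the horizon and the tail bound
`surv(horizon)/λ_last`, which for a constant rate is exactly the
truncated mass (tested).

Sojourn-time sensitivity to a covariate recomputes S with the covariate
shifted by +1 on every segment and reports both the percent and the
absolute reduction; for a constant schedule and shared hazard ratio h
the percent reduction is exactly (1 − 1/h)·100, a closed form used as a
test oracle.  The probability of reaching PDR within a window is the
(r, 5) entry of the segment-product transition matrix over that window.
Cohort-level tables average these per-patient quantities; the "±SD"
of the time-averaged intensity matrix is the across-patient standard
deviation of per-patient length-weighted averages of q_rs(t) over
observed follow-up (with the ethnicity indicator forced to
non-Hispanic and time-independent covariates held at their means) —
the dispersion convention is recorded in output metadata because other
conventions (over calendar time, pooled) are defensible.

Confidence intervals for derived probabilities use a parametric
bootstrap: parameter vectors are resampled from the asymptotic normal
at the MLE (default 1000 draws, seeded) and the 2.5th/97.5th
percentiles of the recomputed quantity reported.

## Cohort cleaning and imputation

Eligibility requires at least 3 visits, at least 2 years of follow-up,
and a baseline stage below PDR.  Missing follow-up HbA1c values are
filled by last observation carried forward and missing baseline values
by next observation carried backward; a patient with no HbA1c at all is
an error.  Missing diabetes durations are imputed by OLS on baseline
HbA1c, systolic and diastolic blood pressure ("baseline BP" is taken
as both components), and the comorbidity indicators available in the
table (dyslipidemia, chronic kidney disease, myocardial infarction,
cerebrovascular accident); constant predictor columns are dropped as
uninformative, genuinely collinear designs are an error, and negative
predictions are floored at 0 years.  Visit dates are re-origined so
each patient's first visit is t = 0; time is real-valued years and
covariate segments are half-open [t_j, t_{j+1}).

## The synthetic cohort generator

The generator emulates the cohort the analysis targets, with defaults
fixed at the study conditions: 230 patients; baseline stage mix
28.3/31.7/26.1/13.9% over states 1–4; age ~ N(56.0, 10.0); 68.7%
Hispanic; 62.2% female; 80.4% hypertensive; diabetes duration ~
N(13.1, 7.5) truncated at 0.8 years; baseline HbA1c ~ N(9.7, 2.4)
truncated to (5.4, 16.8).  The HbA1c path adds a linear drift of
−0.15%/yr plus N(0, 0.8) visit noise, truncated to (4, 20) — chosen to
reproduce the published cohort-mean decline from ≈9.7% to ≈8.2% over
ten years.  Visits are annual with ±0.2-year uniform jitter over a
follow-up drawn uniformly from 2–10 years.  True baseline intensities
default to the published at-mean-covariates matrix (0.209, 0.142,
0.097, 0.172 on the main diagonal of transitions, plus the skip rates
down to q₁₅ = 0.0004); true hazard ratios to age 0.99/yr, diabetes
duration 1.02/yr, Hispanic 1.31.  The HbA1c hazard ratio is not
published anywhere; the default 1.10 per point is an assumption
bracketed from the published sojourn-versus-HbA1c curve (5.9 vs 5.4
years for 7% vs 8%) and is flagged as such in the truth record.
Sex, blood pressure and anti-VEGF counts are generated with zero true
effect so covariate selection has true negatives to remove.
Missingness is completely at random: 15% of visit HbA1c values
(never all of a patient's) and 10% of diabetes durations.

Latent trajectories are simulated by competing exponentials within each
constant-covariate segment — exact in distribution for
piecewise-constant intensities and fully independent of the
matrix-exponential engine, so the two implementations cross-validate
each other (empirical interval frequencies agree with the analytic law
within 3 binomial standard errors in the tests).

**What the generator does not emulate:** informative visit timing,
death and other competing risks, stage-grading measurement error,
anti-VEGF-induced regression, DME dynamics, or non-random missingness.
Passing tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to their violation in real
charts.

## Validation protocol and problem sizes

Because the source cohort is not available, the package validates by
parameter recovery: ten cohorts of 500 patients (annual jittered visits
over a fixed 6-year follow-up, missingness disabled so the experiment
measures the estimator rather than the imputation rules) are simulated
from the published final model and refit with covariates age, diabetes
duration, Hispanic and HbA1c.  Averaged over the ten refits, hazard
ratios recover to within ±0.01 (age, duration) and ±0.10 (Hispanic),
and the four main-diagonal intensities to within 10% relative error.
Recovered intensities are evaluated at the generating reference
covariates (age 56.0, duration 13.1, HbA1c 9.7, non-Hispanic), which
makes the comparison invariant to each fit's centering constants; the
realized cohort-mean HbA1c sits below the baseline reference because of
the downward drift, so evaluating at realized means would conflate the
centering convention with estimator error.

Selection behaviour is probed with 20 replicates (n = 500) containing
one strong covariate (true hazard ratio 1.5) and one null covariate.
The strong covariate is retained in all replicates.  The null covariate
is dropped in 17/20: AIC removes a true null only when its deviance
change is below 2, an event of probability P(χ²₁ < 2) ≈ 0.843, so
~84% is the expected long-run rate of the procedure itself, and the
observed 85% is consistent with it.

Oracle checks use independent routes: the panel likelihood against a
high-accuracy solution of the Kolmogorov forward equations (agreement
to 1e-6), interval probabilities against 200,000 simulated trajectories
(3 binomial SEs), and piecewise sojourn times against adaptive
quadrature of the survival function (1e-8).

## Known limitations

* Covariate effects are shared across transitions by design; the model
  cannot express stage-specific hazard ratios.
* No misclassification (hidden-Markov) layer: grading noise is handled
  by monotone clamping, which biases toward the more severe reading.
* The likelihood treats progression-date visits as ordinary panel
  observations, not exact jump times.
* Wald intervals and the parametric bootstrap rely on asymptotic
  normality; they can be optimistic for rare transitions whose
  intensities sit near the boundary.
* Ten baseline intensities on five states are weakly identified for
  skip transitions in small cohorts; expect boundary warnings for
  q₁₄/q₁₅-type rates and interpret them as "no information", not as
  evidence the rate is zero.
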