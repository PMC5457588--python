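# Methods

## The measurement and the model

The package implements a sensor-based frailty assessment built on a single
20-second motor task: the participant, seated, flexes and extends the
dominant elbow as fast and as fully as possible while angular-rate sensors on
the forearm and upper arm record angular velocity.  The elbow angular
velocity (forearm minus upper-arm channel) is segmented into
flexion/extension cycles and summarised by eight parameters that map onto
the physical frailty phenotype: **speed** (mean per-cycle velocity range,
deg/s — slowness), **flexibility** (mean per-cycle flexion range, deg),
**power** (mean per-cycle product of acceleration range and velocity range,
deg²/s³), **rise time** (mean time to peak velocity, s), **moment** (mean
per-cycle peak elbow torque, Nm — weakness), **speed variability** (CV of
per-cycle velocity ranges, % — motor inconsistency), **speed reduction**
(percent change of the mean per-cycle velocity range from the first to the
last 5 s, negative when slowing — muscle fatigue / exhaustion), and
**flexion number** (cycle count in 20 s).

Two instruments are built on these parameters, both against the Fried
phenotype (non-frail / pre-frail / frail) as gold standard:

1. a **categorical index**: a proportional-odds (cumulative-logit) ordinal
   regression P(Y ≤ k | x) = σ(α_k + xᵀβ) over the UEF parameters (moment as
   its natural log) plus demographics, with the category order
   non-frail < pre-frail < frail.  Under this orientation a positive
   coefficient is protective (e.g. speed) and a negative one is a risk
   factor (e.g. BMI);
2. a **continuous score** on [0, 1], built Framingham-style: each scored
   variable is cut into three categories at the midpoints of its
   frailty-group means W, a category is worth
   round(β_risk (W − W_ref) / B) integer points with
   B = |β_age| × 4 years (one point = the risk of a 4-year age increase),
   and the summed points are normalised by the maximum attainable total.

## Cycle segmentation and numerical choices

The segmentation rule is not prescribed by the protocol, so the package
states one: candidate boundaries are positive-going zero crossings of a
4th-order Butterworth low-pass-filtered copy of the elbow velocity (default
cutoff 3 Hz, zero-phase); boundaries closer than 0.25 s are merged; candidate
cycles whose raw velocity range falls below max(20 deg/s, 10 % of the trial
median range) are discarded — an all-noise or all-zero trace therefore yields
zero cycles rather than an error.  A partial cycle at either edge of the
trial counts when it spans at least half the median cycle duration, which
keeps the count symmetric under time reversal and makes a noise-free train at
frequency f yield round(20 f) cycles.  All per-cycle quantities are computed
from the unfiltered series.

Elbow angle is obtained by per-cycle trapezoidal integration of the velocity
with a linear detrend inside each cycle; without the detrend, gyroscope bias
makes the integral drift without bound.  Channel bias can alternatively be
removed from an initial rest window (`rest_window_s`); the default is 0 s
because the standard trial starts moving immediately.

The elbow moment is I × peak unsigned angular acceleration (deg/s² converted
to rad/s²), with I from Winter-style anthropometry:
I = (m·0.022) · (h·0.254·0.827)² for body mass m (kg) and stature h (m) —
forearm+hand mass fraction, segment length fraction of stature, and radius of
gyration fraction, all configurable.  Acceleration comes from a central
difference of the raw velocity, so wideband sensor noise inflates peak
acceleration (and hence moment and power) systematically; this is a stated
property of the extraction, not corrected, because the published definitions
operate on the measured signal.

Speed reduction assigns each cycle to the first/last 5-s window by its
midpoint time; a cycle straddling a window edge is thus counted exactly once.
Fewer than two cycles leave variability and reduction as NaN (flagged
missing) while the remaining parameters are still computed.

## Ordinal fitting

The proportional-odds likelihood is maximised by damped Newton iterations
(analytic gradient and Hessian, step-halving on the log-likelihood,
convergence at max-norm of the score < 1e-8, at most 100 iterations) on
internally standardised predictors; estimates, the observed-information
covariance and the AIC are mapped back to the original scale exactly.  The
iteration starts from the closed-form intercept-only solution, so an
intercept-only fit reproduces the cumulative logits of the empirical
proportions to machine precision.  Constant or collinear columns raise a
`SingularDesignError` naming the offending columns; diverging coefficients
(complete separation) raise a `ConvergenceError` naming the predictor.  The
implementation is cross-checked in the test suite against statsmodels'
ordinal model, which is never used as the implementation.

Ties in `classify` break toward the more frail category, so a screening
instrument errs toward sensitivity.

## Index-development pipeline

The five development steps are reproduced as composable operations:
Shapiro–Wilk normality per parameter with a log transform recorded only when
the raw test rejects (p < 0.05), all values are positive, and the transformed
test does not reject; box-plot outliers (1.5 × IQR) reported per frailty
group but never removed; univariate proportional-odds screening at p < 0.05;
VIF = 1/(1 − R²) with a collinearity flag above 10 (exact collinearity
reported as infinite); forward stepwise selection by AIC with ties broken by
declaration order, and `forced_out` to exclude a flagged collinear variable
before selection — the procedure the original analysis used for the
speed/power pair.  Note that plain AIC forward selection admits a
conditionally-null predictor with probability ≈ 0.16 (ΔAIC < 2 ⇔ χ²₁ < 2),
so "exactly one of a collinear pair enters" is only guaranteed when the pair
is resolved at the VIF step.

Cross-validation uses random folds stratified by frailty category (with only
45 frail subjects in the reference composition, unstratified folds can lack
frail members, leaving a fold AUC undefined); fold sizes differ by at most
one overall and within each category.  Per fold the model is refitted on the
other k−1 folds and the held-out fold is scored: AUC for pre-frailty ranks
p(pre-frail) + p(frail) for (pre-frail ∪ frail) vs non-frail; AUC for frailty
ranks p(frail) for frail vs rest; accuracy defaults to 3-class arg-max
accuracy (a dichotomised variant is available).  `roc_auc` is the
Mann–Whitney statistic (concordant + half of tied pairs), identical to
trapezoidal integration of the empirical ROC curve.

## Points score details

Rounding is half away from zero (a deterministic reading of "nearest
integer").  Values falling exactly on a category cutoff go to the
higher-risk category.  β_risk is the fitted coefficient's magnitude signed by
the variable's group-mean gradient (risk grows toward the frail end), which
guarantees non-negative, monotone points; when the conditional coefficient
sign contradicts the marginal trend — which collinearity among the fatigue
measures can and does produce — the magnitude is kept and a warning emitted.
A variable whose three group means are equal scores 0 everywhere and is
excluded from the normalising maximum; group means that are non-monotone
across the three groups make the midpoint construction ill-defined and raise
an error naming the variable (BMI frequently triggers this in small cohorts,
since its group contrast is below a fifth of its SD).  Age and sex are not
scored; age contributes only through the base constant.  The normalisation
is by the maximum attainable points, giving a floor of exactly 0 rather than
the 0.1 floor quoted for the original instrument, whose normalisation
constant was not published; the orientation is fixed as higher = frailer.

## The synthetic cohort

No UEF recordings are deposited, so the generator states a world with the
published cohort's structure: 352 subjects apportioned 132/175/45 across
non-frail/pre-frail/frail (largest-remainder apportionment of the group
proportions; a multinomial draw is available), per-group truncated-normal
demographics with the published means and SDs (age floored at the ≥ 60
inclusion criterion, MMSE capped at 30, BMI floored above 10) and the
published female fractions (61/66/73 %).  BMI is sampled directly — it is
the model covariate — and weight derived as bmi·(h/100)², so the two are
always consistent; the weight profile moments are therefore nominal.  The
MMSE cap sits within one SD of the group means, so sampled MMSE means are
0.4–0.6 points below the nominal values; tests account for this by comparing
against truncated-normal expectations.

Per-group motion parameters were not published; the defaults state a
monotone frailty gradient in the directions the index coefficients imply:
cycle frequency 1.10/1.00/0.85 Hz, velocity amplitude 260/200/140 deg/s,
fatigue decline 8/15/25 % per trial, cycle-jitter CV 5/8/12 % for
non-frail/pre-frail/frail, all configurable.  A trial is a sine cycle train
at the subject's frequency with per-cycle amplitude = base amplitude ×
linear fatigue ramp × (1 + jitter), plus 3 deg/s white noise on the forearm
channel and a 2 deg/s noise-only upper-arm channel.  The fatigue ramp is
anchored at the centres of the first and last 5-s windows (A(t) =
A₀·(1 − d·(t − 2.5)/15)), so a configured decline d maps to an extracted
speed reduction of exactly −100·d % under the window-midpoint rule; a naive
0→20 s ramp would instead give −15.4 % for d = 0.2.  Range of motion is not
an independent dial: for this waveform ROM = amplitude/(π·frequency), and
the profile `rom_mean` fields document that implied value.

What the generator does not emulate: non-sinusoidal cycle shapes (real
maximal-pace flexion has flatter velocity plateaus), sensor-to-segment
misalignment, trunk-motion crosstalk beyond white noise, drift/1/f sensor
noise, and within-trial pacing strategies.  Consequently speed and
flexibility are intrinsically collinear here (both driven by amplitude), the
synthetic world is considerably more separable than the real cohort
(cross-validated AUCs ≈ 0.95 vs the published ≈ 0.8), and a green
discrimination test establishes that the pipeline recovers structure the
generator put in — not that the instrument performs at any particular level
on real patients.  Reproducing the published real-data headline numbers is
explicitly out of scope.

## Reproducibility

Every stochastic operation takes an explicit seed; identical (config, seed)
pairs give bit-identical cohorts, traces and fold assignments.  CLI runs
write the serialised config and its hash next to each primary output.
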