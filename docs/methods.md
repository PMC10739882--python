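# Methods

`asymrpe` re-implements, as a tested pipeline on synthetic data with known
ground truth, an analysis of asymmetric reward-prediction-error (RPE)
coding in intracranial high-frequency activity (HFA): an interval-timing
task with dual asymmetric staircases, trial-level RPE derivation from a
logistic value model, a mixed-model ladder for reaction-time adaptation,
window-wise encoding models of feedback-locked HFA with four-category
channel classification, and lagged directed connectivity between the
dorsomedial prefrontal cortex (dMPFC) and insula (INS). This note records
the models, the generator that stands in for patient data, the numerical
choices, and what the tests do and do not establish.

## Task model and staircase dynamics

Agents reproduce a 1 s interval; a response within the current tolerance
*t* (ms) of the target wins (+100 points), otherwise loses (−100).
Separate staircases per difficulty adjust *t* after each valenced
outcome — easy: −3 ms on wins / +12 ms on losses; hard: −12 / +3 — and
the tolerance in effect is clamped to [15, 200] ms (or [15, 400],
configurable). A zero-drift argument pins long-run accuracy at
`loss_step / (win_step + loss_step)`: 80% easy, 20% hard.

Two deliberate dynamics choices:

* **The internal staircase level is not clamped** (only the tolerance in
  effect is). If the level itself is clamped at the floor, the −12 ms
  down-step is truncated there, the walk acquires an upward bias, and a
  stationary SD-60 ms timer wins ~29% of hard trials instead of ~20%.
  With a free level the equilibrium survives at the bound: simulated
  hard-block accuracy is 20.1% with a ~2.8-point between-agent SD,
  against the patients' reported 19.5 ± 2.6%. A guard margin of 600 ms
  beyond the bounds keeps the level from drifting indefinitely when an
  agent's equilibrium is unreachable; the margin is deep enough that
  ordinary sub-floor excursions never feel it (a shallow guard caps those
  excursions and biases the clamped rate upward by about half a point).
* **Staircase burn-in** (`TaskConfig.staircase_burnin`, default 15 trials
  per condition — the task's own training count) initializes the
  staircase at the agent's performance level before recorded blocks, as
  the training phase does for participants. Near the floor the staircase
  mixes slowly (the sub-floor level wanders with near-zero drift), so
  clamped-rate *measurements* (the acceptance script and the clamping
  tests) equilibrate with a long burn-in (20000 trials, ~0.1 s per
  agent); starting a 150-trial recording at an arbitrary tolerance
  (e.g. 30 ms) otherwise biases the estimate upward by 1–2 percentage
  points.

Neutral outcomes (optional 12% of trials) and omitted responses deliver
no valenced feedback and leave the staircase untouched; omissions are
labeled `missing`, not treated as losses. Behavioral trial rejection
removes missing RTs, RTs outside [0.5, 1.5] s, and RTs more than 3
session-SDs from the session mean.

## Value model and RPEs

Per agent, win probability is a maximum-likelihood logistic function of
tolerance fit over the whole session, excluding neutral trials. Expected
value is `EV = 2·p_win − 1`; the signed RPE is `reward − EV` with reward
+1/0/−1 for win/neutral/loss; its positive part, negative part, and
absolute value give pRPE, nRPE and uRPE. The identities
`pRPE − nRPE = sRPE`, `pRPE + nRPE = uRPE`, `pRPE·nRPE = 0` hold exactly
by construction and are asserted over full sessions. No
temporal-difference learning is modeled: the tolerance cue is visible on
every trial, so value is a static function of tolerance. Complete
separation of the logistic fit is detected by perfect classification and
flagged, with coefficients clamped to ±50.

## Mixed-model engine

All inference runs through one wrapper around statsmodels `MixedLM`:

* ML (not REML) wherever fits are compared; AIC counts fixed effects,
  random (co)variances and the residual variance (lme4-style), and LRT
  degrees of freedom difference the same totals — adding a correlated
  by-subject random slope alongside one fixed slope therefore costs 3 df.
* Fixed-effect p-values are Wald tests on the normal approximation. At
  the few-subject scale of the synthetic studies this is close to, but
  slightly more liberal than, Kenward–Roger/Satterthwaite corrections;
  null-calibration tests bound the practical consequence (the
  asymmetric-vs-null LRT's rejection rate at α = 0.05 runs a few points
  above nominal at 5 subjects while remaining KS-uniform overall).
* Likelihood comparisons are protected against optimizer artifacts in
  two ways: nested fits warm-start from their null (so the full model
  can never land below it), and ladder fits take the best likelihood
  across several optimizers (`multi_start`), so null and full model get
  equal optimization effort. Without this, LRT statistics showed both
  spurious zeros and negative values.
* A full random covariance that fails to converge or goes non-positive
  falls back to a diagonal structure, flagged on the result.
* The robust option winsorizes standardized marginal residuals at ±2.5
  (MAD scale) and refits to convergence — a Huber-type response
  winsorization that leaves clean Gaussian fits essentially unchanged
  (< 0.1 SE shift in tests) while bounding the leverage of heavy tails.

## RT-adaptation ladder

RT change is modeled per Table-style ladder from intercept-only to the
asymmetric-RPE model, with by-subject random intercepts and previous-RT
slopes, treatment coding of the previous outcome with *win* as
reference, and the previous trial's RPEs as predictors. The first trial
of each block and trials following a missing (or rejected) trial
contribute no rows. The value and salience models share a parameter
count and are compared by AIC only. The synthetic behavioral cohort uses
mean-reverting agents (`rt_i` reverts toward the target with AR
coefficient 0.25, giving the observed previous-RT effect of about
−0.75) with optional planted RPE-dependent slowing; planted
+0.02 s/unit-pRPE slowing is recovered in coefficient and sign, with
≥90% detection at 10 subjects × 300 trials.

## Synthetic neural generator

Channels carry a ground-truth coding category — pRPE, nRPE, sRPE, uRPE or
none — realized as signed gains `(g_p, g_n)` (regular nRPE coding means
HFA *falls* as negative surprises grow; inverted polarities flip the
signs; uRPE channels share the sign on both gains). The feedback-locked
envelope is `(g_EV·EV + g_p·pRPE + g_n·nRPE)·K(t)` plus AR(1) noise
(coefficient 0.5 per 25 ms step, unit stationary SD), where `K` is a
unit-peak Gaussian bump at 275 ms (INS) or 300 ms (dMPFC) with 75 ms
width. Envelopes are generated directly in baseline z-units so fitted
coefficients and generative gains share a scale. Default study
conditions: 4 blocks × 75 trials, gain scale 0.5 z, category mix 30%
pRPE / 30% uRPE / 10% nRPE / 10% sRPE / 20% unresponsive, mostly regular
polarity except nRPE (67% inverted), electrode positions drawn from
region-specific Gaussian clouds.

The optional raw path renders envelopes as
`(1 + 0.25·env)·bandnoise(70–150 Hz) + 1/f + white` at 1 kHz, so log band
power is approximately linear in the envelope. Single-trial 50 ms power
estimates are intrinsically noisy (a one-taper window contributes a few
degrees of freedom), so round-trip fidelity is assessed on trial
averages, where the recovered window profile correlates with the true
envelope profile at r > 0.9; regression analyses pool across trials and
are insensitive to this single-trial noise floor.

What the generator does **not** emulate: non-Gaussian timing dynamics
(fatigue, drift), volume conduction or shared noise across channels,
epileptiform artifacts, task-evoked broadband shifts unrelated to RPE,
and any anterior/posterior gradients within a region. Passing tests
therefore establish that the pipeline recovers the model it assumes, not
that patient recordings obey that model.

## HFA extraction

Multitaper power in 10 Hz sub-bands centered 70–150 Hz (50 ms windows,
`n_cycles = 0.05·f`, time-bandwidth 2 — the minimum usable DPSS
concentration, giving ±20 Hz smoothing), natural-log transformed, on a
25 ms grid. Baseline statistics are the bootstrap-averaged mean and SD of
pre-stimulus (−0.25 to −0.05 s) log power over 500 trial resamples; each
sub-band is z-scored with its own baseline statistics and the sub-band
z-series are then averaged. The averaged series has SD below 1 (the
sub-bands are only partially independent); per-sub-band z-scores are the
standardized quantity, and the standardization property is tested there.
For synthetic cohorts the pre-feedback segment serves as the baseline —
the generator emits stationary background before feedback, which is what
the pre-stimulus window provides in the recorded task. Sliding windows
average 50 ms spans stepping 25 ms over 0–0.6 s post-feedback, half-open
`[start, start+50)`, 23 windows.

## Encoding models and channel classification

Per region and window, three mixed models predict single-trial HFA:
value (sRPE + EV), salience (uRPE + EV), asymmetric (nRPE + pRPE + EV),
each with subject-level random intercepts and slopes (full covariance,
diagonal fallback) and channel-within-subject intercepts and slopes as
independent variance components. Models are compared by AIC only;
fixed-effect p-values are Benjamini–Hochberg corrected across windows per
term. Channel-level *conditional* coefficients (fixed effect + subject +
channel BLUP deviations, normal-approximation SEs that combine the
fixed-effect variance with the conditional covariance of the deviations)
give each channel a coefficient time course.

Classification uses the shared four-category decision table on the two
RPE-magnitude terms: only pRPE significant → pRPE channel (regular if
the peak coefficient is positive); only nRPE → nRPE (regular if
negative); both with opposite peak signs → sRPE; both with matching
signs → uRPE (increasing/decreasing); neither → unresponsive. "Peak" is
the largest-|coefficient| significant window, which also resolves
channels straddling the sRPE/uRPE boundary.

Significance decisions, however, are **not** taken from the conditional
p-values across windows. Wherever a term has no between-channel variance
the BLUP collapses onto the region fixed effect, and "any window
p < 0.05" then inherits the fixed effect's chance significances — on
all-null cohorts every channel ends up flagged. Instead, each channel is
tested on its own trials (per-window OLS of its windowed HFA on the
asymmetric predictors): a term is significant if its own p-values
survive a BH step-up across the 23 windows, and the channel is
responsive at all only if the joint F test of (pRPE, nRPE) survives the
same step-up — a single gate that keeps the null flag rate at the
nominal α. Peak windows and signs still come from the conditional
series. On the default cohort this recovers ≥ 90% of categories with
matching polarity and flags unresponsive channels at ~5%.

Category statistics follow the group-level recipe: per-subject,
per-region category proportions (subjects lacking a region excluded),
Wilcoxon signed-rank between regions per category with FDR over the four
tests, then Kruskal–Wallis across categories on region-averaged
proportions with FDR-corrected pairwise signed-rank contrasts; a
multinomial logistic regression of category on electrode (x, y, z) with
uRPE as reference tests for spatial gradients (sparse categories are
dropped). The rankit transform Φ⁻¹((rank − ½)/n) is available as the
normality sensitivity analysis.

## Directed connectivity

Per INS–dMPFC pair and trial, Pearson correlations between the dMPFC
series and the INS series shifted by −400…+400 ms in 25 ms steps
(positive lag = INS leads), computed on the 25 ms grid over 0–1.0 s
post-feedback (configurable; only overlapping samples are used, lags
with under 8 overlapping samples are dropped). Raw r (not Fisher-z) is
the modeled response. Per lag, a mixed model `r ~ EV + pRPE + nRPE` with
a subject random intercept and pair-within-subject intercept and slopes
as variance components (subject-level random slopes are not identifiable
at the few-subject scale and are omitted); fixed-effect p-values are
FDR-corrected across lags per term. Peak lags maximize the absolute
conditional coefficient (ties resolve to the most negative lag). Pair
categorization reuses the channel decision table, with significance from
pair-own regression tests (per-lag OLS + BH across lags, joint F gate)
for the same reason as for channels. Planted +75 ms pRPE-modulated
couplings are recovered with the correct category and a peak lag within
one grid step for ≥ 90% of pairs, and unmodulated (but coupled) pairs
are flagged at ~5%.

The coupling generator mixes a lag-shifted latent process into the
dMPFC series under a unit-variance constraint
(`a·latent + √(1−a²)·noise`, `a = base + m·X` clipped to ±0.98), so the
per-trial correlation is *linear* in the modulators. A variance-scaling
gain (`gain·latent + noise`) was rejected: correlation then saturates in
the gain, and planted pRPE modulation leaks into a spurious positive
nRPE coefficient because pRPE-zero trials are exactly the nRPE-positive
trials. The latent decorrelates over ~25 ms; much smoother latents let
the short-window normalization redistribute modulation into side lobes
at large lags that compete with the true peak.

## Problem sizes and calibration checks

The validation suite runs everything at desk scale, chosen as the
smallest sizes at which the relevant effects are comfortably identified:
behavioral power and null calibration at 10 × 300 and 5 × 150
subject×trial cohorts (40 and 150 replicates); encoding recovery on
4-subject × 8-channel cohorts (AIC selection across 12 cohorts at the
kernel-peak window; coefficient recovery on a uniformly sRPE-coding
cohort; category recovery on the default mix); connectivity on five
2-subject × 14-pair cohorts (60 planted pairs) plus 250 standalone null
pairs for the responsiveness false-positive rate. The acceptance script
reports the staircase-clamped hard-block win rate for 20 equilibrated
SD-60 ms observers × 150 recorded trials.

## Known limitations

* Wald and LRT inference is asymptotic in subjects; at 2–5 synthetic
  subjects the tests run slightly liberal. Between-region and
  between-category nonparametric tests need several subjects to have any
  resolution.
* Conditional-coefficient SEs ignore the covariance between the fixed
  estimate and the BLUP deviations; the own-data significance tests, not
  these SEs, carry the classification decisions.
* The generator's linearity (envelope and coupling both linear in the RL
  variables) matches the fitted models by construction;
  model-comparison results on synthetic data cannot speak to
  misspecification in real recordings.
* Replication against the study's deposited behavioral data is out of
  scope for the offline test suite; the interfaces accept any trial
  table with the documented columns.
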