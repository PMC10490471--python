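# Methods

`phasicvns` re-implements, as a tested and reusable pipeline, the analysis
chain of a combined pupillometry/MEG experiment on phasic, event-related
transcutaneous auricular vagus nerve stimulation (taVNS): subjects perform
an emotional Stroop task (EST) and a passive pupillary-light-reflex task
(PLRT) under active and sham stimulation, and the analysis asks how
stimulation changes single-trial accuracy, pupil dynamics, light-reflex
kinematics, and low-frequency oscillatory power.  Because no recordings
ship with the package, a seeded synthetic-data generator produces inputs
carrying the same statistical structure, and every stage is validated
against the generator's ground truth.

## Synthetic study

The default `StudyDesign` mirrors a within-subject crossover: 29 subjects,
six EST blocks of 20 face/word trials (half congruent) per stimulation
arm, 20 PLRT flash trials per arm, pupil sampled at 500 Hz, MEG-like
channels at 1000 Hz, stimulation delivered as 500 ms trains of 30 Hz
pulses (15 pulses) locked to stimulus onset.

**Behavior.** Single-trial accuracy is drawn from the logistic mixed model
the analysis later fits: log-odds
`intercept + trial·β_trial + face·β_face + intensity_c·β_int +
stim·β_stim + congr·β_congr + stim·congr·β_ix + u₀ + u_s·stim +
u_c·congr`, with per-subject random effects `u ~ N(0, diag(0.8, 0.3,
0.3)²)`.  The default coefficients are the analysis targets β_congruency
= 0.92 (odds ratio 2.51), β_stimulation = 0.44 (OR 1.55), β_trial = 0.005
(OR 1.005), β_face = 0.06, β_intensity = −0.24, β_interaction = 0.02; the
intercept 2.2 puts baseline accuracy near 90 %, typical for this task.
Reaction times follow a linear mixed model with a −54 ms congruency shift
and a −0.49 ms/trial practice slope.  Stimulation intensities are drawn
per subject and arm around 1.91 ± 0.24 mA.

**Pupil traces.** Each subject-arm is one continuous 500 Hz recording in
raw recorder units (4000 ≙ rest, 400 units per generated z-unit):

- a *smooth physiological background*: one dominant hippus oscillation
  (0.5 z at 1.3 Hz, amplitude jittered per session) plus slow (<0.1 Hz)
  arousal drift.  The background is deliberately band-limited with a
  single dominant component: recorded pupil traces are smooth because
  recorders filter on-line, and sample-to-sample changes are then set by
  bounded physiological slopes.  This is what makes robust
  dilation-speed thresholding separable — blink spikes are orders of
  magnitude above any physiological slope.  White sensor noise is
  modeled as negligible (a `noise_sd` field exists for sensitivity
  studies and defaults to zero);
- *stimulus-locked components*: a luminance-driven constriction to each
  EST face and, in the PLRT, the parametric light reflex described
  below, plus a gamma-shaped task-evoked dilation (peak ~1.3 s
  post-stimulus) whose amplitude carries the congruency (+0.07 z on
  incongruent trials) and stimulation (+0.135 z under taVNS) effects;
- *hippus suppression* around each stimulus: the reflex and the
  orienting response quiet the hippus, modeled as a cosine-ramped
  attenuation to 10–40 % starting late in the pre-stimulus fixation
  period.  Without it, constriction slopes stack on hippus peaks and the
  robust threshold flags genuine reflex samples;
- *blink artifacts*: with per-trial probability 0.15 (default), a
  100–400 ms missing run flanked by 2–4 spike samples (1–3 z downward)
  on each edge — exactly the morphology the two-pass cleaning targets.
  The injected spike mask is returned as ground truth.

**Light-reflex template.** The constriction is a gamma(3) CDF in time:
exactly zero before constriction start with C² continuity, rising to the
peak depth −A six rise-constants later, then redilating exponentially.
The gamma-CDF second derivative has a smooth interior minimum at
`x = 2 − √2` rise-constants after start; the template positions this
acceleration minimum exactly at the latency parameter, because the
extraction stage defines reflex onset as the most negative acceleration.
Defaults: sham latency 170.83 ms, taVNS delay +27.09 ms, depth 2.2 z
(×0.925 under taVNS), rise constant 200 ms, redilation constant 2.8 s.
Ground-truth kinematics are computed numerically from the noiseless
template on a fine grid with the same derivative conventions the
extraction uses.

**MEG-like signals.** Per channel: 1/f background plus band-limited
oscillations — theta/low-alpha (4–8 Hz) on frontal-midline (FM) channels,
alpha (8.5–13 Hz) on occipital-midline (OM) channels — whose
post-stimulus amplitude is scaled by condition (power ratios: FM ×1.25
under taVNS, ×1.15 on incongruent trials; OM ×0.80 under taVNS).  Each
stimulation pulse adds a 4 ms biphasic transient at 50× the signal SD on
all channels (both arms are electrically stimulated).  Pulse onsets are
emitted as a marker table; the artifact-free signal is retained for
energy-reduction tests.

What the generator does **not** emulate: gaze-dependent pupil
foreshortening, eye movements, realistic MEG forward fields or sensor
covariance, heartbeat/blink components in the MEG, or non-stationary
arousal drifts correlated across tasks.  Passing tests therefore
demonstrate algorithmic correctness under the stated noise model, not
performance on arbitrary real recordings — in particular, the cleaning
false-flag and latency-recovery figures assume smooth, band-limited
physiological noise (see Limitations).

## Pupil preprocessing

Epochs span −2…5 s (EST) or −2…7 s (PLRT) around stimulus onset; the
onset sample belongs to post-stimulus time.  Trials with more than 50 %
missing samples are rejected; subjects with more than 50 % rejected trials
in any condition cell are excluded wholly.

Cleaning is the two-pass robust procedure standard in pupillometry.  The
*dilation speed* at each sample is the larger of the backward and forward
absolute difference quotients (endpoints use their single neighbor;
missing samples propagate).  Pass 1 removes samples whose speed exceeds
`median + 2.5 · MAD` of the speed series.  A trend line is then formed by
linearly interpolating the gaps and smoothing with a 100 ms centered
moving average (window shrinking at the edges, so no phase shift); pass 2
removes samples whose absolute deviation from the trend exceeds a MAD
threshold computed on the deviation series with the same constant 2.5.
The deviation pass skips half a smoothing window at the trace edges,
where the shrinking-window trend is biased.  Removed samples become
missing; interior gaps are filled by linear interpolation; leading and
trailing gaps stay missing and count toward the 50 % rule.  Strict
inequalities are used throughout, so a constant trace (MAD = 0) loses no
samples.

Cleaned epochs are z-scored with the pooled mean/SD of all retained
samples of the subject-session (the scope is configurable; nothing in the
procedure pins it), decimated to 100 Hz, and baseline-corrected to the
mean of the 200 ms before stimulus onset.  The baseline subtraction is
applied after decimation so the baseline-window mean of the output is
exactly zero; for band-limited traces the two orders are numerically
equivalent.  Decimation is plain subsampling — the 100 ms trend smoothing
and the smooth noise model leave no energy near the 50 Hz output Nyquist.

Known trade-off: plain linear gap interpolation leaves slope kinks at gap
edges.  Re-running the cleaning on its own output flags a small number of
those kink samples (≤0.5 % of a blink-rich trace).  Alternatives
(slope-matched fills, smoothing the junctions) would either alter samples
the cleaning never flagged or depart from the linear-interpolation
convention, so the kinks are accepted and documented.

## Light-reflex kinematics

All metrics are extracted from the per-subject, trial-averaged,
preprocessed trace.  The peak constriction is the most negative value
after stimulus onset; reflex onset is the most negative acceleration
between stimulus onset and that peak ("the first period" of the second
derivative — the acceleration minimum of a constriction necessarily
precedes its amplitude minimum).  Velocities come from central finite
differences (`edge_order=2`); constriction velocities are computed on
[onset, peak] inclusive, dilation velocities on (peak, end].  Optional
pre-smoothing is off by default so analytic inputs are recovered exactly.
Traces whose leading/trailing samples are missing are trimmed before
extraction; interior missing samples are an error (clean first).

On noiseless templates the latency is recovered to within one sample and
the amplitude to <0.2 %.  With 0.1 z-per-trial physiological noise, the
20-trial session average recovers latency within 10 ms essentially
always, because trial averaging and the flash-locked hippus suppression
leave only slow drift near the onset.  Against *white* noise of the same
SD the acceleration-argmin convention is not usable at that precision —
the second derivative amplifies high frequencies faster than any
admissible smoothing can suppress them without biasing the onset.  This
is a property of the convention, not of the implementation.

## Stimulation-artifact interpolation and filtering

Ten milliseconds after each pulse marker are blanked (overlapping blanks
merge; 15 pulses × 10 ms = 150 ms per train).  Each gap is filled by
autoregressive prediction: Burg-method AR fits on 25 ms of context on
each side (order = context/4, capped at 8 — Burg guarantees a stable
model, and predictions are additionally clamped to twice the context
range so a near-unit-root fit cannot run away), forward and backward
predictions cross-faded linearly across the gap.  A gap with too little
context on both sides falls back to linear interpolation with a warning.
Non-gap samples are bit-identical before filtering.

The filter chain is zero-phase (forward–backward) Butterworth, 4th order
per pass: high-pass 1 Hz, low-pass 60 Hz, band-stop 49–51 Hz, in that
order.  Epochs (−2…5 s) are decimated to 250 Hz by subsampling (safe
after the 60 Hz low-pass) and baseline-corrected over the 200 ms before
onset; per-channel per-trial baseline means are retained for the
baseline-comparison analysis.

## Spectral estimation

Power spectra use a Hann-tapered FFT of the 500 ms directly after
stimulus onset — the window free of interpolated stimulation gaps at its
end.  The window's native resolution is 2 Hz; the transform is zero-padded
to place bins exactly on the 2–14 Hz, 0.5 Hz grid (spectral
interpolation; padding factor = rate/0.5 samples).  Sensor groups (FM,
OM) are averaged before statistics.  Time-frequency representations use
complex Morlet wavelets (5 cycles) on the same frequency grid, decimated
to 40 ms bins, with bins closer than half a wavelet length (lowest
frequency) to either epoch edge flagged as contaminated.  The decibel
baseline is `10·log10(power / mean baseline power)` per frequency, with
the reference averaged over trials so single-trial fluctuations do not
leak into it; the default window is −500…−200 ms.

## Mixed models

Gaussian linear mixed models are fitted with statsmodels `MixedLM` (REML
for estimation, ML refits for likelihood-ratio tests), with a fallback to
random intercepts when a random-slope structure fails.  The optimizer's
strict convergence flag is treated as informational: a finite fit at a
boundary optimum is used and annotated.

Logistic mixed models are fitted by an in-house Laplace approximation,
in two stages.  First, a fast profiled scheme finds the variance
parameters: for each candidate covariance (Cholesky-parameterized), the
fixed effects and all per-subject random effects are jointly maximized by
Newton iterations with block elimination (penalized IRLS; the objective
is strictly concave, so with step halving this is globally convergent and
fully vectorized across subjects), and the Laplace deviance at the joint
mode is minimized over the variance parameters by L-BFGS.  Second,
because profiling ignores the dependence of the Laplace curvature term on
the fixed effects — which attenuates estimates for strongly binary data —
the fixed effects are refined against the full Laplace objective at the
selected variance parameters.  Wald covariance comes from the numeric
observed information over the full (fixed effects + variance) parameter
vector, whose inverse fixed-effect block carries the variance-parameter
uncertainty; this matches the convention of standard mixed-model
software, and on shared datasets the estimates and standard errors agree
with `lme4::glmer` to a few percent (the package's test suite checks
this through an `Rscript` cross-fit).  Degenerate outcomes (constant
response, divergent coefficients) raise a separation error.

Likelihood-ratio chi-squares for individual predictors come from nested
ML fits with the term dropped; the statistic is floored at zero.
Interactions are resolved by nested-coding models (`outcome ~ covariates
+ C(outer) + C(outer):inner`, random intercepts) reporting the inner
effect at each outer level; p values use a normal approximation to the t
reference distribution — no Satterthwaite degrees of freedom are
computed, and results are labeled accordingly.

## Cluster-based permutation testing

Per-point statistics (paired t across subjects, mixed-model LRT
chi-square, or a continuous predictor's t) are thresholded at an
uncorrected per-point α = 0.05 on the statistic's asymptotic null
(two-sided t; one-sided χ²).  Contiguous suprathreshold runs form
clusters whose mass is the summed statistic; signed statistics form
positive and negative clusters separately.  The null distribution is the
largest absolute cluster mass under within-subject permutation —
condition-label sign flips for paired designs, unit-level label shuffles
within subject for trial-level predictors.  When the sign-flip group has
no more than `n_perm` elements it is enumerated exhaustively (with a
warning), making tiny-design p values exact.  Cluster p values are
`count(null ≥ |mass|)/n_perm`, ties counted toward the null, floored at
`1/n_perm` (0.0001 at the default 10,000 permutations).  Non-converged
per-point fits carry NaN and are subthreshold; more than 20 % of them
aborts the analysis.

Cluster effect sizes follow the paired Cohen's d convention: `d_avg` is
the d of per-subject values averaged across the cluster, `d_max` the
largest per-point d inside it with its location; no ordering between the
two is implied.  For time-frequency maps the same machinery runs on 3-D
cells (sensor × frequency × time) with 8-neighborhood adjacency in the
frequency-time plane plus declared sensor neighbors, restricted to
600–5000 ms post-stimulus so interpolated stimulation periods are never
compared with clean data.  Under null simulations the family-wise error
sits within [0.03, 0.07] at nominal 0.05, and on 1-D paired data the
significant clusters coincide with `mne.stats.permutation_cluster_1samp_test`
run with the same threshold.

Permuting one predictor of a multi-predictor model while holding
covariates fixed is an approximation (no exact scheme exists for
interactions); this is the documented default, and the limitation is
inherited from the field's standard practice.

## Cross-task prediction

Stimulation deltas (taVNS − sham) are computed per subject and point for
spectra and pupil series; subjects missing an arm are dropped listwise.
Cluster-averaged deltas become subject-level predictors of the other
task's delta profile.  With one delta per subject and point the per-point
random-intercept model reduces to a regression across subjects, so the
per-point statistic is the predictor's OLS t; CBPT permutes the tested
predictor's subject assignment while covariate predictors stay fixed.
Significant clusters report the average beta inside them, on the raw
scale (a standardization flag is available but off by default).

## Problem sizes in the validation suite

The shipped tests scale the study down so the full suite runs on one CPU
in well under half an hour: behavior-recovery uses 100 replicates of 200
subjects × 80 trials; CBPT calibration 200 null replicates × 500
permutations at n = 20; cleaning validation ~600 trials; latency recovery
500 session averages; AR interpolation 100 seeded gaps.  The acceptance
script (`scripts/acceptance.py`) re-runs the same computations at similar
sizes from a single command-line seed.

## Known limitations

- The cleaning specificity and latency precision reported by the tests
  hold under the generator's smooth-noise model; traces dominated by
  white sensor noise would show a several-percent false-flag rate (an
  intrinsic property of median+MAD thresholding of near-Gaussian speed
  distributions) and unusable acceleration-based latencies.
- The binomial fitter's likelihood is a Laplace approximation; for very
  small clusters-per-subject counts adaptive quadrature would be more
  accurate.
- Satterthwaite degrees of freedom are not implemented; nested-model
  p values use a normal approximation and are flagged.
- The per-point LMM permutation engine refits statsmodels models in a
  Python loop; it is intended for modest grids and permutation counts,
  while paired-t permutation paths are fully vectorized.
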