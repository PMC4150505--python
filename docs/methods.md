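# Methods

## Model

Blood pressure is estimated per beat from pulse transit time (PTT, the
ECG-R-peak → PPG-pulse-peak interval within one cardiac cycle) as

    BP = a·PTT + b + c·VPTT + d·(PTTV − PTTV0)

with `PTT` the trailing W-beat mean (W = 5), `VPTT = (PTT − PTT0)/PTT0`, and
`PTTV` the sample standard deviation of the successive PTT differences of
the trailing window. `PTT0` (mean PTT) and `PTTV0` (mean rolling PTTV) are
measured once per subject during a seated calibration session. Units: PTT in
ms throughout; `a` in mmHg/ms, `b` in mmHg, `c` in mmHg (multiplies a
dimensionless ratio), `d` in mmHg/ms. SBP and DBP carry fully independent
coefficient sets. Setting `c = d = 0` recovers the linear baseline
`BP = a·PTT + b`, evaluated on the same 5-beat mean so the two models are
directly comparable.

The model assumes (i) a locally affine PTT–pressure relation per subject
over the measured range, (ii) that short-window PTT variability is a usable
surrogate for the autonomic activity that moves diastolic pressure
independently of transit time, and (iii) stationarity of the subject's
calibration between the calibration and estimation sessions.

### Window conventions

A window parameter W = 5 means 5 PTT values and hence 4 successive
differences; PTTV uses the sample SD with denominator 3 (one fewer than the
number of differences). The convention in which W counts the *differences*
(6 PTT values) is selectable via `RunConfig.pttv_convention="5_differences"`.
VPTT is computed from the window *mean*, matching the decision to average 5
measurements before applying the model. A series of n beats yields
`n − W + 1` feature windows.

## Signal processing

Both channels are smoothed by a centered moving average whose duration (10
ms default) is rounded to the nearest odd sample count (3 samples at 250
Hz); edges shrink the half-width symmetrically so no phase shift or length
change occurs anywhere.

R-peaks: the detection statistic is the smoothed squared first difference of
the filtered ECG; candidate peaks must exceed an adaptive threshold (median
+ 6·MAD of the statistic) and respect a 250 ms refractory period, and each
candidate is refined to the local ECG maximum within ±60 ms (earliest sample
on ties). PPG peaks: within each R-R interval the search window is
(R + 100 ms, min(R + 600 ms, next R)); the window argmax is accepted only as
a strict interior local maximum, so flat signals and out-of-window pulses
yield unmatched cycles. Pairing is injective by construction.

A recording is rejected ("large fluctuation") when it has fewer than 10
matched beats, a PTT coefficient of variation above 0.2, or more than 20 %
of cardiac cycles unmatched; all three thresholds are configurable.

## Calibration

Compensation constants `c, d` are population-level: a least-squares fit over
one pooled point per (subject, session) — the session's feature summary
(mean PTT over all beats, mean rolling PTTV) against its resolved cuff
reference. Two design choices matter here:

* **Subject fixed effects (default).** Between-subject pressure offsets of
  several mmHg SD otherwise act as correlated noise on a regression whose
  informative contrasts (posture shifts, session-to-session variability
  changes) are within-subject; with a single shared intercept the estimated
  `c, d` were effectively noise in simulation, and the compensated model
  performed no better than the linear baseline. One intercept per subject
  isolates the within-subject contrasts. The single-intercept design
  remains available (`population_design="plain"`) and is the one under
  which exact parameter recovery on shared-law cohorts is verified.
* **Scope.** By default each subject's `c, d` come from a
  leave-one-subject-out fit (honest evaluation); `pooled` uses everyone.

Given `c, d`, each subject's `a, b` solve the 2×2 system through the sitting
and standing calibration points. Because the reference state is defined from
the sitting session, the sitting equation reduces to `BP = a·PTT + b` and
the sitting point is interpolated exactly. The solve is refused when the
postural PTT separation is under 2 ms (half a sample period at 250 Hz; the
system is ill-conditioned below sensor resolution). The linear baseline is
calibrated from the same two points with the compensation terms removed.

Within one subject VPTT is an affine function of the window-mean PTT, so `a`
and `c` are separately identified only through between-subject spread in
`PTT0`; their individual values are weakly determined while their combined
prediction is robust, and the per-subject re-calibration of `a, b` absorbs
any misallocation. `d` is the genuinely distinct compensation parameter.

## Measurement-acceptance protocol

Each session takes two cuff readings; per pressure type, a first-two
difference < 5 mmHg accepts the first reading, a difference in [5, 10] mmHg
requires a third reading and accepts the mean of three, and a difference
> 10 mmHg discards the session's reference (boundaries 5 and 10 take the
third-reading path). SBP and DBP are resolved independently and a session is
discarded if either type is. A subject is analyzable only when all three
sessions pass both this rule and the waveform fluctuation check.

## Evaluation

Agreement is session-level — the mean of the per-beat estimates against the
single resolved cuff reference — since the oscillometer yields one value per
session. Reported per model × pressure type: mean ± SD of the differences
(sample SD, n−1), limits of agreement at mean ± 1.96·SD, squared Pearson
correlation, and the least-squares regression line. Plots (Bland–Altman,
scatter) are side artifacts; all numbers come from the report objects.

## Synthetic cohorts

No recorded dataset is distributed, so validation rests on a generator whose
structure matches the model's assumptions while its parameters are known:

* **Beats.** R-R intervals from a per-subject heart rate (70 ± 7 bpm) with
  25 ms white jitter.
* **PTT.** Baseline 210 ± 20 ms; standing shifts it −15 ± 3 ms
  (hydrostatic); the estimation-test session adds a slow drift of SD 6 ms.
  On top: a Mayer-band sinusoid (10 s period, 5 ms amplitude) and white
  beat-to-beat jitter (2.5 ms). Session-dependent variability gains
  (standing 1.6×, estimation-test uniform on [0.5, 2]) scale both sources.
  The split matters: over a 5-beat window the 0.1 Hz sinusoid is locally a
  linear ramp and contributes almost nothing to PTTV (which is exactly zero
  on any arithmetic progression), so VPTT excursions come from the sinusoid
  and drift while PTTV contrast comes from the jitter. Without
  jitter-coupled gains, `d` is unidentifiable at session level.
* **Pressure.** Per-beat SBP/DBP follow each subject's own law — default
  population slopes a = −0.45 (SBP) / −0.20 (DBP) mmHg/ms, compensation
  c = −8, d = 0.2 (SBP, weakly coupled) and c = −20, d = 2.5 (DBP, strongly
  variability-coupled) — evaluated on the *same* rolling features the
  estimator computes, against the subject's sitting reference. Sitting
  pressure targets (115 ± 8 / 72 ± 6 mmHg) track baseline PTT across
  subjects with slope `a`, as cross-sectional physiology does; `shared_law`
  cohorts give every subject identical coefficients, the condition under
  which pooled regression has a unique recoverable truth. Beats before the
  first complete window inherit the first window's pressure.
* **References.** Cuff readings are the session-level true BP plus 2 mmHg-SD
  oscillometer noise, rounded to 0.1 mmHg, duplicated per the protocol (a
  third reading is drawn whenever the first two land in the [5, 10] band).
* **Waveforms.** ECG as unit Gaussian bumps (SD 10 ms) at beat times, PPG as
  raised-cosine pulses (300 ms width) peaking at `R + PTT`, both quantized
  to the sample grid (250 Hz); optional white noise at a stated SNR. These
  morphologies have unambiguous single maxima per cycle, which is the point:
  detection is scored against truth, not against morphology realism.

What the generator does *not* emulate: dicrotic notches and PPG waveform
shape, motion artifacts, baseline wander, respiratory modulation,
arrhythmias, sensor drift, or any nonlinearity of the PTT–BP relation.
Passing tests therefore demonstrate correctness of the pipeline and
recoverability of the model under its own assumptions — not clinical
accuracy on recorded data.

## Numerical limitations

* **Quantization floor.** At 250 Hz, rendered peak positions are exact grid
  points, so each recovered PTT is within half a sample (2 ms) of truth and
  a window mean within 2 ms. This propagates to pressure as roughly
  `|a|·2 ms + |c|·2 ms/PTT0 + |d|·(PTTV perturbation)`; the last term
  dominates for strongly variability-coupled laws because quantization
  perturbs successive differences by up to a full sample period. For the
  default DBP law (d = 2.5) the per-beat floor is several mmHg even on
  noise-free waveforms; session means largely cancel it. End-to-end tests
  assert bounds derived from this arithmetic rather than a flat constant.
* **Problem sizes.** Tests and the acceptance script use 60 s sessions for
  rendered-waveform work and the protocol's full 3-minute sessions where
  beat counts drive precision (the noisy `c, d` recovery), with cohorts of
  4–31 subjects and 20 replicate cohorts for the model comparison; these
  sizes keep the whole validation under a minute while leaving every
  conclusion seed-stable.
* **Degenerate inputs.** Flat signals yield empty detections with warnings,
  not exceptions; zero-variance correlation inputs raise a dedicated error;
  single-session evaluations report n = 1 with the correlation left
  undefined; rank-deficient population designs raise an error naming the
  degenerate columns; argmax ties resolve to the earliest sample.
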