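# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic benchmark does and does not
establish about real recordings.

## Signals and conventions

All channels are uniformly sampled (default 62.5 Hz, i.e. 16 ms per
sample, the rate of ventilator serial-port acquisition); sample *i* of a
channel occurs at `t0 + i/fs`. EAdi is in μV and non-negative, Paw in
cmH2O around a PEEP baseline, flow in L/min. Event times are reported in
seconds on the recording clock; extracting the end-of-mode analysis window
(default 300 s — the stable last 5 minutes of a ventilation trial) advances
`t0` so reported times remain comparable across windows. Cycling-off sign
convention: pneumatic minus neural cycle-off, positive = late, negative =
early.

## Neural breath model

A neural effort is characterized by its onset, EAdi peak, and neural
cycle-off defined as the first post-peak decay to 70% of peak prominence
(the same criterion a neurally controlled ventilator uses to cycle off).
Neural inspiratory time Ti_n runs onset → 70%-decay point; this matches the
cycle-off definition and keeps the two timing errors complementary. Neural
expiratory time Te_n runs cycle-off → next onset, so the last breath of a
window has no Te_n and contributes only its trigger error.

## Detection

EAdi is smoothed with a centered moving average (48 ms ≈ 3 samples). The
tonic baseline is a sliding 10th-percentile filter (10 s window): COPD
patients can have non-zero tonic diaphragm activity, so thresholds are
relative to a tracked baseline, never to zero. Peaks come from prominence
peak-picking with a floor of `max(min_peak_uV, 8·σ̂)` where σ̂ is the
noise SD estimated from the median absolute first difference — this keeps
the detector amplitude-invariant yet immune to noise bumps — and a minimum
peak separation of 0.5 s.

Timing refinements matter at 16 ms resolution:

- Threshold crossings (the 10% onset level, the 70% cycle-off level, the
  Paw trigger and cycle-off levels) are interpolated linearly between
  samples.
- Onset and pneumatic trigger are reported as the *baseline intercept* of
  the locally fitted rising slope at the crossing, because a raw threshold
  crossing is systematically late by `threshold/slope` (tens of ms for
  typical rise times). Samples at the baseline itself are excluded from the
  slope fit.
- Peak amplitude is refined by intersecting the local rise and decay
  secants around the maximum sample: the true burst peak generally falls
  between samples, and the resulting amplitude underestimate would bias the
  70% cycle-off level and hence its crossing time. Under noise
  (σ̂ ≥ 2% of prominence) this refinement is replaced by a local raw
  maximum minus the expected noise-maximum bias.

Pneumatic events: a trigger is a sustained (≥3-sample) rise above
PEEP + 1.0 cmH2O; cycle-off is the descent below PEEP + 25% of the driving
pressure. Both thresholds are configurable; the defaults tolerate
0.5 cmH2O of Paw noise. PEEP is taken from recording metadata when present,
otherwise estimated as the mode of Paw rounded to 0.5 cmH2O; a flat Paw
under auto-estimation is an error (no pressurization), while a flat Paw
against a known PEEP is simply zero assists.

A quality gate refuses analysis when fewer than 10 breaths are detected or
the median peak prominence is below 1.0 μV (configurable): recordings with
EAdi too weak for reliable segmentation should be excluded rather than
scored.

## Matching and scoring

Each trigger is assigned to the neural breath whose interval
`[onset − 0.1 s, next onset − 0.1 s)` contains it; the 0.1 s lead absorbs
detection jitter for triggers essentially coincident with an onset. A
trigger deeper into expiration than cycle-off + Te_n/2 with no EAdi burst
under the assist is an auto-trigger (the split between "very late trigger"
and "auto-trigger" is not observable from timing alone; the fraction is
configurable). An assist spanning two or more EAdi peaks is a
multiple-EAdi event; a breath with two or more assigned triggers is a
double-trigger; one-to-one pairs are matched and unassisted efforts are
wasted. Every event lands in exactly one breath record — a property the
test suite checks against exhaustive enumeration.

Per-breath error combines |trigger error| and |cycle-off error| by their
mean (default) or maximum (configurable), each component capped at 100%,
so a matched breath can never outweigh a dissociated one and the per-breath
error lives on the same 0–100 scale as the 100% assigned to asynchronies.
The NeuroSync index is the plain mean over breaths; the decoupled variant
drops wasted efforts before averaging and is the regressor used against
wasted-effort counts. The 20% synchrony box uses non-strict inequalities;
the density grid bins matched breaths on a fixed ±100% grid with 5% bins.
All parameter defaults and overrides are embedded in every report.

## Statistics

Friedman's test (scipy) compares modes within subjects; fully tied blocks
return statistic 0, p = 1. Dunn's post hoc uses the Friedman rank sums,
z = (R_a − R_b)/√(nk(k+1)/6), with Dunn's Bonferroni-style critical level
α/(k(k−1)/2) and no further adjustment. Normality uses the
D'Agostino–Pearson omnibus K² (n ≥ 8 enforced). The exponential fit
y = a·e^{bx} is nonlinear least squares in original y-space (log-linear
fitting would down-weight exactly the high-wasted-effort points of
interest) initialized from the log-linear solution on y > 0 points; r² is
computed against the mean-y baseline, and an all-zero y is reported as a
degenerate fit rather than an error.

## The simulator

The generator emulates a COPD-like non-invasive ventilation recording, not
any particular patient: quasi-periodic EAdi bursts (Gaussian-jittered
period and amplitude), a tonic baseline, mode-dependent trapezoidal
pressurization, PEEP, additive Gaussian noise (EAdi clipped at 0), and
injected asynchronies with mutually exclusive per-breath labels (priority
wasted > double > multiple-EAdi). The flow channel is a first-order
response to driving pressure, generated for completeness but never
analyzed (tidal volumes are unreliable under mask leak and are out of
scope).

Burst morphology: linear rise from tonic to peak over 75% of Ti_n, then a
baseline-anchored exponential decay that returns exactly to the tonic level
75% of the way through expiration, with the time constant solved (Brent's
method) so the 70%-of-prominence crossing falls exactly at onset + Ti_n.
The anchored form was chosen over a plain exponential because quiet
expiration does return EAdi to its tonic level, and because an identifiable
baseline is what makes sub-sample onset oracles meaningful; when expiration
is too short for the anchored solution the decay falls back to a plain
truncated exponential with the same 70% crossing. Cycling-off error is
injected relative to the neural 70% point, matching the error definition
downstream. Assist release is modeled as an immediate pressure drop;
detected pneumatic cycle-off is therefore within one sample of truth by
construction rather than tracking an expiratory decay shape.

Default study conditions (chosen once, from the clinical ranges of the
modeled setting): respiratory rate 22–24 breaths/min, Ti_n 0.9 s, peak
EAdi 25 μV (CV 15%), tonic 1.5 μV, PS 10 cmH2O above PEEP 5 cmH2O, rise
time 0.15 s, noise 0.5 μV and 0.2 cmH2O. The NAVA-like preset uses trigger
delay 50 ± 15 ms and cycling-off error 12 ± 6 ms with no wasted efforts;
the PSV-like preset uses 150 ± 40 ms, −95 ± 22 ms (early cycling), 4.3%
wasted efforts and sparse auto-/double-/multiple-EAdi events.

Closed-loop mode replaces the wasted-effort coin flip with a mechanism: a
trigger attempt arriving while the machine is still insufflating for the
previous effort (or within a 0.25 s expiratory refractory) gets no assist.
Sweeping injected cycling-off degradation under this rule makes wasted
efforts emerge from dyssynchrony itself, reproducing the characteristic
convex relationship (flat below ~20% error, steep above) between the
decoupled index and wasted-effort counts. A runaway assist is clamped
before the next burst's peak so the unassisted effort reads as wasted
rather than as a multiple-EAdi event.

What the simulator does *not* model: respiratory mechanics (resistance,
compliance, intrinsic PEEP), mask-leak pneumatics, flow-triggering
behavior, non-Gaussian EMG noise, cardiac artifacts, or electrode-position
effects. Passing the suite therefore demonstrates that the analysis
recovers known event timing and classifications from waveforms with the
stated morphology and noise — not that it is robust to every artifact of
bedside recordings.

## Problem sizes and tolerances

Tests and the acceptance script use 300 s recordings (18 750 samples, ~110
breaths) for recovery checks, 60–120 s for structural checks, and a
36-cell injected-parameter grid (trigger delay 0–200 ms × cycling-off
error ±100 ms × wasted probability 0–0.1) at a shared seed so the breath
pattern is paired across cells. Detector accuracy is asserted to one
sample period (16 ms); recovered mean timing errors to 16 ms; wasted
counts to 95% binomial bounds; index monotonicity to a 0.05-point slack.
Matching is verified against exhaustive enumeration on 1000+ random
instances of up to 6×6 events; Friedman decisions against the exact
within-block permutation distribution at n = 5 × 3.
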