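# Methods

## Signal model and assumptions

A piezoelectric sheet sensor under the bedsheet measures one channel of
bed micromotion, digitised at 100 Hz into signed 24-bit integers
(−8,388,608 … +8,388,607).  Three physiological sources occupy
well-separated frequency bands and are treated as additive: respiratory
motion (0.08–0.5 Hz), gross body movement (2–3 Hz), and the
ballistocardiogram (4–11 Hz).  The central assumptions of the method are

* apneas and hypopneas appear as **relative** reductions of respiratory
  amplitude lasting tens of seconds;
* the absolute amplitude is unstable — it jumps with body posture and
  sensor coupling — so no absolute threshold can work;
* heartbeats are visible as short wide-band wavelets whose timing carries
  the cyclic bradycardia–tachycardia pattern that accompanies apneas.

## Decomposition

Each component is the input filtered by a 4th-order Butterworth band-pass
applied forward–backward (`sosfiltfilt`), i.e. zero phase: a dip in the
respiration envelope is not delayed relative to the raw signal, so event
boundaries are preserved.  The forward–backward pass squares the
magnitude response; one octave outside each passband the rejection
exceeds 40 dB.  The input is reflect-padded by three time constants of
the low band edge before filtering.

The **movement mask** flags samples whose 1-s moving RMS of the
movement-band component exceeds 5× the recording-wide median of that RMS
series.  The mask does not delete signal; it only marks envelope grid
points as invalid (below) so that movement artifacts can neither mimic
nor interrupt respiratory events undetected.  An identically quiet
movement band yields an empty mask.

## Event detection

* **Log amplitude**: `a(t) = ln(|resp(t)| + ε)` with ε = 1 sensor unit
  (one ADC count).  ε prevents −∞ at zero crossings and is negligible
  against physiological amplitudes (thousands of counts); the log
  converts multiplicative amplitude changes into additive offsets.
* **Envelopes**: on a 1-s grid, the fast (10 s window) and slow (120 s
  window) envelopes are the **nearest-rank 95th percentile** of the
  unmasked samples in the centered window: sort ascending, take the
  ⌈0.95 m⌉-th value.  Nearest rank (rather than an interpolated
  percentile) is exactly reproducible by a brute-force oracle, which the
  tests exploit.  The 95th-percentile point tracks the upper envelope
  while discarding outliers of < 5 % incidence.  A grid point is valid
  only if ≥ 50 % of each nominal window is unmasked and inside the
  recording; invalid points carry NaN.
* **Windows**: 10 s spans 2–3 breaths at the typical 15 breaths/min, so
  the fast envelope follows breath-by-breath amplitude; 120 s spans the
  pre-event baseline across one or two apnea cycles, so the slow envelope
  holds the reference level across an event but follows posture changes
  within ~1 min.  Both are exposed as parameters.
* **Threshold**: a depth of `d` percent corresponds to a log separation
  of `−ln(1 − d/100)`; the default 30 % gives ln 1.43 ≈ 0.357.
* **Durations**: maximal runs of consecutive valid grid points above
  threshold become candidates; a candidate is an event iff its duration
  (run length × grid step) lies in [10 s, 70 s].  Runs longer than the
  cap are rejected whole — sustained drops (posture-related amplitude
  loss) are exactly what the cap is meant to exclude, and splitting them
  would manufacture events.  Invalid grid points split runs; there is no
  merging across gaps.
* **REI** = events / TRT hours.  TRT is the full recording; movement
  periods are not subtracted from the denominator.

A practical consequence of the envelope geometry: the detected duration
of a planted rectangular dip is shorter than its nominal duration by
roughly the fast window plus the taper (≈ 11–14 s, mildly
threshold-dependent), because the fast envelope holds the baseline while
any near-baseline breath remains inside its window.

## Heartbeats and CVHR

Beats are peaks of the BCG energy envelope (RMS in a 0.2-s moving
window) above 0.3× the envelope's 95th percentile, with a 0.4-s
refractory period; beats inside the movement mask are dropped.  Interval
editing rejects intervals outside 300–2000 ms or deviating > 30 % from a
7-beat running median.  An externally measured R-R series (two-column
text: beat time, interval) passes through the same editing.

Valid intervals are resampled to a 2-Hz tachogram (linear
interpolation), smoothed by a 10-s moving average.  **Dips** are local
minima with prominence ≥ max(100 ms, 4× a robust SD of the tachogram
noise) and width 10–120 s near the dip base.  The noise SD is estimated
from the residual against a 15-s running median — short enough to track
the dips themselves, so dense dip trains do not inflate their own
detection threshold.  **Trains** are runs of ≥ 3 dips with spacing
25–130 s and neighbouring spacing ratio in [0.5, 2]; Fcv counts only
dips belonging to trains, per hour of TRT.  All constants sit in
`CvhrParams`.

## Calibration

`grid_search` evaluates every (depth, min duration, max duration) cell —
1 % depth steps over 10–60 %, duration candidates {10, 20, 30} ×
{40 … 120} s — and maximises Pearson r between per-subject REI and
reference AHI (TRT denominator).  Envelopes are parameter-independent
and computed once per subject.  Ties are broken deterministically:
smaller depth, then wider duration band, then scan order.  The search is
exhaustive by construction; the best r equals the maximum over the
trace.

A note on identifiability: when detection is nearly noise-free, REI is an
affine function of AHI at *every* depth below the planted dip depth, so
the correlation objective is extremely flat across a wide plateau and
the located optimum within that plateau is decided by which sub-scored
spells fire at each threshold.  The optimum becomes informative exactly
when the data contain amplitude variability spread across the search
range — which real sheet-sensor data do.

## Evaluation

* Pearson r via the standard product-moment formula; constant input is an
  error, not NaN.
* Incremental regression: OLS of AHI on REI, then on REI + Fcv; partial
  F = ((RSS₁−RSS₂)/1)/(RSS₂/(n−3)) against F(1, n−3).
* AUC is the Mann–Whitney concordance probability with ties counted ½,
  computed from midranks; its 95 % CI uses the DeLong variance with a
  logit transform (clipped to [0,1]; a zero variance collapses the CI to
  the point estimate).  The variance matches R pROC's DeLong
  implementation; pROC's default CI differs only by omitting the logit
  transform.
* Optimal cutoff: candidates are midpoints between adjacent distinct
  scores; predicted-positive means score ≥ cutoff; the candidate
  maximising min(sensitivity, specificity) wins — "balancing" read
  literally — with the Youden index and then the lower cutoff as tie
  breaks.
* Binary metrics (sensitivity, specificity, accuracy, PPA, NPA) are kept
  at full precision; display rounding is half-up to one decimal.  A
  metric with a zero denominator is `None`, never 0.
* Four-level metrics: accuracy = trace/total; off-by-k shares are
  fractions of the *misclassified*; per-class sensitivity is the share
  of each reference class predicted as itself, per-class specificity the
  share of non-members identified as non-members.
* Severity bands: AHI < 5 / 5–15 / 15–30 / ≥ 30 and REI < 9 / 9–14 /
  14–24 / ≥ 24, boundary values always to the higher class.

## Synthetic data generator

`simulate_subject` builds, per subject and from one integer seed:

* a respiration carrier (0.25 Hz, amplitude 30,000 counts) multiplied by
  a posture factor (multiplicative jumps at exponential intervals, mean
  1800 s, log-uniform factors 0.5–2.0, cumulative factor clipped to
  [0.2, 5]) and an event gate (depth 60 %, durations U(25, 65) s, 3-s
  raised-cosine tapers, placed by a thinned Poisson process with a 10-s
  minimum recovery gap and intensity corrected for dead time) — the
  taper makes the planted log-envelope depth equal −ln(1 − d/100) at
  plateau, so threshold arithmetic is exact;
* **sub-scored breathing-instability spells** — amplitude sags below the
  scoring depth that every sleeper shows: a severity-independent
  population (0.45/h, depths U(30, 62) %) and a severity-linked
  population (0.06 per event/h, depths U(40, 58) %), durations
  U(12, 55) s.  These make the depth threshold a real operating choice:
  lower thresholds admit spell false positives, which is what the grid
  search trades off;
* a BCG wavelet train (Gaussian-windowed 8-Hz tone, σ = 0.1 s, amplitude
  10,000) at beat times generated from RR = 1000 ± 50 ms with planted
  CVHR dips (200 ms deep, width ≈ 0.8× event duration, anchored at event
  ends) and, when enabled, PLM dip trains (150 ms, every 30 s, in 5-min
  episodes every 30 min) with accompanying 0.8-s movement mini-bursts;
* movement bursts (band-limited 2–3 Hz noise, 6/h, 2–5 s) and white
  sensor noise (SD 1500 counts = 5 % of the respiratory amplitude);
* integer quantisation with a saturation check against the 24-bit range.

Cohorts draw per-subject event rates from a configurable distribution
(default log-normal, median 13/h, σ = 1.4, capped at 60/h — matching the
spread of a clinical referral population); per-subject seeds are
`master + 1 + index`.  In simulation the subject is treated as asleep
throughout, so AHI_TST = AHI_TRT = the planted rate.

**What the generator does not emulate**: realistic BCG waveform
morphology (I-J-K complexes), apnea subtypes (obstructive vs central),
respiratory rate drift, REM/NREM structure, electrode-free signal
dropout, or arousal-related breath-size overshoot after events.  Passing
round-trip tests therefore demonstrates the internal consistency of the
pipeline under the stated signal model, not clinical performance on
patients.

## Problem sizes

Cohort checks use 20 subjects × 3-h recordings with reference AHI spread
evenly over 0–60/h at clean settings (60 % event depth, 5 % noise); the
PLM check uses one 6-h recording (posture shifts disabled there to
isolate the PLM effect on REI vs Fcv); scale-invariance uses a 1-h
recording at ×0.1 and ×10 amplitude, asserting identical event counts
and boundaries within one envelope grid step (the ε inside the log
transform breaks exact scale equivariance at the last digit, which can
move a boundary crossing by one grid cell).  These sizes keep a full
reproduction run around a minute on one CPU.

## Known limitations

* The exact envelope windows and the BCG beat-interval method of the
  original device are not published; the 10-s/120-s windows and the
  energy-envelope beat picker are this package's design, exposed as
  parameters.
* CVHR constants follow the published cyclic-dip family of detectors but
  are a reimplementation, not a port.
* With a near-noise-free cohort the grid-search optimum is only loosely
  pinned (see Calibration above); on such data any depth between the
  spell range and the planted depth is effectively equivalent.
* The four-level REI bands (9/14/24) were fitted by the original study
  to its clinical population; on synthetic cohorts they are reproduced
  as given, not re-derived.
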