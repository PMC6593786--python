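# Methods

This note documents the models, signal-processing choices and synthetic
data behind `gesturesync`, and what the test suite does and does not
establish about real recordings.

## The measurement model

A narration session is a 30-s warm-up followed by alternating 60-s blocks
with and without delayed auditory feedback (DAF). Time runs in seconds
from session start and every interval — gesture events and schedule
blocks — is half-open `[start, end)`, so block boundaries and event
offsets are never double-counted. An event is assigned the condition
active at its *onset*; the literature this package serves does not state a
rule for events straddling a block boundary, and onset-labelling is the
simplest deterministic choice.

For each annotated gesture event the package measures four kinematic
anchors and one speech anchor:

* **peak velocity** — argmax of hand speed over the event;
* **peak acceleration** — argmax of acceleration on `[onset, t_peak_vel]`;
* **peak deceleration** — argmin of acceleration on `[t_peak_vel, offset)`;
* **onset** — the annotated event onset;
* **peak pitch** — maximum voiced F0 inside the event window, with one
  symmetric ±250 ms widening if the window is fully unvoiced.

The synchrony offset for anchor *a* is

    D_a = (t_a − t_peak_pitch) · 1000  [ms],

negative when the anchor precedes the pitch peak. One pitch peak is
shared by all four anchors of an event, so within a record
`D_onset ≤ D_peak_acc ≤ D_peak_vel ≤ D_peak_dec` always holds.

Constraining peak acceleration before, and peak deceleration after, the
velocity peak makes the anchor ordering an invariant rather than an
accident of the data; ties go to the earlier sample everywhere.

## Signal processing

* **Position filtering.** Each position axis is low-pass filtered with a
  first-order Butterworth at 33 Hz before differentiation. The filter is
  run forward and backward (zero-phase): anchor *times* are the measurand,
  and a causal single pass would delay every anchor by a constant and
  bias every D. The two-pass gain at the cut-off is |H|² = 1/2.
* **Differentiation.** Speed is the Euclidean norm of per-axis central
  differences (second-order accurate, symmetric, hence no timing bias);
  acceleration and jerk are successive central differences of speed.
  Endpoints use one-sided differences.
* **Jerk summary.** Mean |jerk| per event, z-scored across the dataset's
  events with the sample SD (ddof = 1); zero-variance sets return zeros
  with a warning, a lone event has no defined z-score.
* **Resampling.** Pitch tracks are linearly interpolated onto the 240 Hz
  motion grid (1 sample per 4.1667 ms). F0 is undefined while unvoiced,
  so interpolation never bridges an unvoiced span: a resampled frame is
  voiced only when its bracketing native samples are directly adjacent
  voiced frames. Nothing is extrapolated beyond the recorded span.
* **Amplitude envelope.** Modulus of the analytic (Hilbert) signal,
  zero-phase low-passed at 10 Hz, resampled to 240 Hz, min-max scaled to
  [0, 1] per recording ("scaled Hilbert units"). The 10 Hz smoothing
  keeps syllable-rate rhythm (~4–5 Hz) while removing pitch-rate ripple;
  the cited extraction script's exact parameters are not published, so
  this is a documented default.

## Inferential analyses

All models share one family: a linear model with categorical fixed
effects and a random intercept per participant, fitted by **maximum
likelihood** (never REML — the model ladders are compared with
likelihood-ratio tests on fixed effects, which REML invalidates).
Estimation is statsmodels `MixedLM`; an independent brute-force
profile-likelihood maximizer in the test suite checks the estimates to
three significant figures. Noiseless or single-group designs make the ML
iteration degenerate; such fits fall back to the exact OLS solution with
the group variance pinned at 0 and are flagged.

* **Coupling strength, confirmatory:** |D_peak_vel| of beat gestures,
  condition vs. intercept-only (LRT, α = .025).
* **Coupling strength, exploratory (SDD):** the sample SD of D per
  participant × condition × gesture type × anchor cell, over the three
  peak anchors. Cells with one observation contribute no row (the SD of
  one observation is undefined, and SD = 0 would fake perfect coupling).
  Sequential ladder: +condition, +gesture type, +anchor (α = .05).
  The reported degrees of freedom of each LRT are the actual parameter
  difference of the compared fits.
* **Entrainment:** D stacked long over the four anchors (one row per
  anchor per event); ladder anchor, +condition, +interaction. The
  condition coefficient is the entrainment shift. NO DAF is the reference
  level throughout, so positive coefficients mean later timing under DAF.

  The four stacked rows of one event share a single offset draw (one
  pitch peak per event), so the stacked model's naive SE understates the
  sampling variance of the condition coefficient by roughly a factor two.
  The model is still fitted and reported in stacked form, but an
  *event-clustered* SE — from refitting the additive model on per-event
  mean D — accompanies it, and the recovery tests use that clustered SE.
* **SD–mean correlation:** Pearson r between per-participant SD and mean
  of D_peak_vel within a condition, t on n−2 df, Fisher-z 95% CI.
* **Leave-two-out robustness:** the chosen analysis is refitted on all
  C(n, 2) datasets that exclude one pair of participants; exclusions that
  lose a condition entirely are flagged and removed from the denominator
  of the significant fraction.

## Cross-wavelet coherence

The continuous analysis relates hand speed to the speech envelope with an
analytic Morlet transform (ω₀ = 6, the standard choice that balances time
and frequency resolution) on a geometric period grid of 12 voices per
octave spanning 0.125–8 s. Coherence uses the usual smoothing operator —
a Gaussian time window whose width equals the scale, and a 0.6-octave
boxcar across scales — because unsmoothed wavelet coherence is
identically 1; the constructor rejects degenerate smoothing windows.

Significance is Monte Carlo against independent white-noise surrogate
pairs of the observed length (250 simulations by default), with the
plus-one estimator `p = (1 + #{surrogate ≥ observed}) / (1 + n)` so the
smallest attainable p is 1/251 and the test is finite-sample valid. The
surrogate model and the smoothing operator are configurable; white noise
mirrors the default of the R package family this analysis follows.

Per-condition series are built by z-scoring each schedule block
("trial") and concatenating blocks of the same condition. Concatenation
creates artificial discontinuities, so the cone of influence (e-folding
distance √2·s) is applied around every trial boundary, not just the
series edges. Band summaries average the per-period time-averaged
coherence over fast (0.2–0.5 s), medium (0.5–2 s) and slow (2–6 s)
periods — half-open `[lo, hi)`, a partition of [0.2, 6) — either raw or
restricted to periods significant at p < .05. Band-level inference reuses
the mixed-model ladder (time scale, +condition, +interaction).

In the pipeline the speed and envelope series are decimated from 240 Hz
to 24 Hz (FIR, zero-phase) before the transform: the analysis bands start
at 0.2-s periods (5 Hz), far below the 12 Hz decimated Nyquist, and the
decimation makes the 250-surrogate Monte Carlo tractable.

## The synthetic generator

The generator is the package's study stand-in, not a curve-fit to any
dataset. Defaults encode the study conditions: 10 participants, gesture
rate 21/min split 0.46/0.45/0.09 over beat/iconic/undefined, stroke
durations beat 573 ± 256 ms and iconic 840 ± 430 ms, and per-type,
per-condition offset Normals — beat 7 (230) ms NO DAF vs. 34 (193) DAF,
iconic −31 (379) vs. 37 (295). The "undefined" category has no published
offsets; it uses (0, 300) ms. Participants receive a Normal(0, 50 ms)
timing intercept. Condition affects only the offset distribution, never
the gesture rate, which isolates the effects under test. The default
session length is 600 s; `SyntheticConfig.study_scale()` (160 s) matches
the original per-participant narration budget (~26 beat events each) and
is what the recovery tests and the acceptance script use.

Strokes are Gaussian speed bells (closed-form anchors: peak velocity at
the bell center, acceleration extrema at the inflection points ±σ_g),
placed by a thinned Poisson process without overlap and integrated into
the position trace; the F0 accent hump is placed at
`t_peak_vel − D/1000` inside a voiced span, and the envelope superposes
syllable-rate (4.5 Hz) and phrase-rate (0.3 Hz) periodicity with
event-locked bursts (a decoupled negative control is a config switch).
Event times snap to the 240 Hz grid, so recovery tolerances are stated in
samples: with all generative SDs at zero, every pipeline-estimated D
equals its ground-truth offset within ±1 sample (4.17 ms).

What the generator does *not* emulate: real articulation (no formants,
no intelligible audio), pitch-tracker errors, annotation disagreement
between raters, two-handed gesturing, or drift in the motion tracker.
Passing recovery tests therefore show that the *pipeline and models* are
correct and unbiased under the assumed generative structure — not that
the assumptions hold in any particular recording. One realistic artefact
is retained: when a large offset draw pushes the pitch accent outside the
event window and its ±250 ms extension, the event loses its speech anchor
and is excluded (logged), exactly as unvoiced windows are in real data.

## Numerical choices and degenerate inputs

* Ties in every argmax/argmin go to the earlier sample.
* Duplicate motion timestamps collapse last-wins; non-monotone time is a
  format error.
* Unknown annotation labels map to "undefined" (the category exists in
  the coding scheme) with a warning; inverted intervals are dropped.
* LRT χ² is clamped at 0 against optimizer jitter; comparing a model to
  itself gives χ² = 0, p = 1.
* Coherence is clipped to [0, 1]; zero-variance trials are dropped before
  concatenation; flat (zero-speed) events yield no anchors and are
  excluded with a log entry.
* Problem sizes in the shipped tests and the acceptance script: 20
  record-level replicates for the recovery checks, 50 white-noise seeds ×
  250 surrogates for the Monte-Carlo size check, 10 participants × 160-s
  sessions for the end-to-end pipeline run. These sizes give the Monte
  Carlo bounds quoted in the tests comfortable margins.

## Known limitations

* The entrainment model inherits the stacked-row dependence discussed
  above; consumers should quote the event-clustered SE.
* White-noise surrogates are a weaker null than AR(1) for strongly
  autocorrelated series; the surrogate model is configurable but only
  white noise ships.
* The pitch-peak search window (the event itself, one widening) is a
  documented convention; the upstream literature does not pin it down.
* `MixedLM` occasionally converges onto the variance boundary; the
  wrapper detects non-finite fits and falls through to other optimizers,
  but boundary solutions (group variance exactly 0) are legitimate
  outcomes on small group counts.
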