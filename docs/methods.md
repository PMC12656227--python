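# Methods

`tapagree` implements a complete measurement-and-validation pipeline for the
10 s Finger Tapping Test (FTT) recorded simultaneously by two instruments: a
high-speed camera tracking finger vertical position (nominally 240 Hz) and a
finger-mounted inertial measurement unit (IMU) recording linear acceleration
(nominally 100 Hz).  The scientific question is one of *method comparison*:
how interchangeably do the two instruments measure the number of taps and
the inter-tap interval (ITI)?  This note records the models, the defaults,
the numerical choices, and what the synthetic validation does and does not
establish.

## Synthetic cohort model

Real paired FTT recordings of this kind are rarely shareable, so the package
carries a first-class generator whose defaults define the study conditions
used throughout the tests and the acceptance script:

- **Design.** 20 subjects x 2 hands x 6 trials x 10 s = 240 trial pairs.
  Half the subjects belong to a `control` group, half to a `fibromyalgia`
  group.
- **Tapping rate.** Each subject draws a rate once per cohort,
  `N(group mean, 0.4 Hz)` clipped to the physiological 4-8 Hz band, so
  trials within a subject correlate (a subject-level random effect that the
  agreement ICC and the mixed model both rely on).  Group presets: control
  6 Hz with ITI coefficient of variation (CV) 0.08; fibromyalgia 5 Hz with
  CV 0.15.  The direction (slower, more variable tapping with fibromyalgia)
  follows the motor-control literature; the magnitudes are this package's
  choice of realistic values, not measured quantities.
- **Inter-tap intervals.** Lognormal, parameterized by mean `1/rate` and the
  group CV, redrawn below a 0.05 s physiological floor.  The lognormal gives
  positive support and the right skew typical of motor timing.
- **Position waveform.** Each tap cycle lifts the finger with a raised-cosine
  ramp of fixed 25 ms duration, dwells at the trial's lift amplitude
  (0.03 m +- 20% across trials), and falls with the mirrored ramp, so every
  surface contact is a locally *symmetric* minimum at height 0.  The fixed
  ramp time matters: if the ramp scaled with the cycle period (e.g. a pure
  raised cosine per cycle), unequal adjacent ITIs would make the valley
  asymmetric and the nearest sample to the true contact would not always be
  the sampled extremum, breaking the half-sample-period recovery guarantee
  the detector is validated against.
- **Acceleration waveform.** An analytic template rather than a numerical
  derivative: a symmetric raised-cosine impact transient (+-10 ms support,
  height 1.5x the ramps' peak kinematic acceleration) at each contact, plus
  a shallow negative deceleration bowl between contacts scaled like the
  mid-flight acceleration `2 pi^2 A / T^2`.  The bowl is supported strictly
  outside the impact-pulse windows: any asymmetric slope under the pulse can
  flip the sampled maximum to the farther grid point when the true event
  falls microseconds from the midpoint between samples.  Differentiating the
  position waveform directly was rejected because any lift profile with a
  mid-cycle dwell leaves a prominent plateau between its negative lobes that
  the prominence-based detector would report as a spurious tap.
- **Double-peak artifact.** With probability `artifact_prob` (default 0.10)
  per cycle, a secondary spike of 40-70% relative height appears 20-50 ms
  after the contact spike — the known IMU failure mode that the detector's
  0.120 s distance rule must suppress.
- **Sensor noise.** Additive white Gaussian noise, SD = 2% of the lift
  amplitude (position) or of the impact height (acceleration) by default.
- **Clocks.** Each stream draws an independent uniform start offset in
  [0, 0.5] s, plus a fixed 0.05 s recording lead-in (a contact with no
  samples before it is unobservable), so the two streams genuinely disagree
  until event-based synchronization.

## Detection

Contacts are position minima (the stream is negated first) and acceleration
maxima, filtered by two criteria: minimum topographic prominence of 20% of
the stream's total amplitude (max - min), and minimum inter-event distance
of 0.120 s — just below the 0.125 s ITI of the fastest physiological rate.
Prominence is the standard topographic definition: peak height minus the
higher of the two base minima, each base taken between the peak and the
nearest strictly higher sample (or the signal end).  The distance rule is
resolved greedily in descending prominence order with earlier time breaking
ties; this is deterministic, favors dominant events, and suppresses the
double-peak artifact.  On plateaus the first sample of the run is the
candidate, so quantized data detect deterministically.  Position maxima
(flight apexes) are detected as metadata but feed no metric.

The implementation is validated against an independent O(n^2) brute-force
oracle (full local-maximum enumeration, exhaustive base search, same greedy
rule) on 1000 random signals, and against `scipy.signal.find_peaks` for the
prominence-threshold stage.

## Synchronization and metrics

Each contact series is shifted so its own first contact sits at t = 0, and
a closed [0, 10] s window is retained — a tap exactly on the boundary
counts, which keeps counts bit-stable.  Streams keep their native rates; no
resampling occurs, and residual event-timing error is bounded by half a
sampling interval (~2 ms at 240 Hz, 5 ms at 100 Hz).  Per trial the tap
count (first tap included) and the ITIs are reduced to mean and sample
(n-1) SD.  A trial needs at least two taps in *both* methods to yield an
ITI; otherwise it is flagged invalid and excluded from every downstream
statistic, with the decision logged per trial.  This >=2-taps-per-method
rule is the package's convention for trial validity.  Subject x hand scores
are arithmetic means over the hand's valid trials.

## Agreement battery

All differences are oriented IMU - video.  On the subject x hand scores:

- **Normality gate.** Lilliefors test (Kolmogorov-Smirnov against a normal
  with estimated mean/SD; p from the small-sample table with interpolation,
  via statsmodels).  Non-parametric limits are *selected* when p < 0.05, but
  both variants are always computed and reported.  If the differences are
  exactly constant the gate is undefined (reported as null) and the
  parametric branch, which degenerates cleanly, is selected.
- **Parametric Bland-Altman.** bias = mean(d), LoA = bias +- 1.96 SD(d),
  CIs from Var(bias) = s^2/n and Var(LoA) = s^2 (1/n + 1.96^2/(2(n-1)))
  with the t(n-1) quantile; RPC = 1.96 SD.
- **Non-parametric Bland-Altman.** bias = median, LoA = empirical 2.5th /
  97.5th percentiles with linear interpolation between order statistics
  (documented because at n = 40 the LoA are sensitive to the quantile
  convention); CIs are percentile intervals over 5000 bootstrap resamples of
  subject x hand units; RPC = 1.45 IQR, which estimates 1.96 SD under
  normality.  The IQR convention is a deliberate choice — non-parametric RPC
  has no single standard definition.
- **Proportional bias.** OLS of d on the per-unit mean m, two-sided t test
  on the slope.
- **ICC(A,1).** Two-way ANOVA, absolute agreement, single measures (McGraw
  & Wong): `(MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))`, with
  a percentile-bootstrap CI over unit resamples (undefined resamples are
  redrawn; more than 50% undefined aborts).  Exact-agreement inputs yield
  exactly 1 — float residue in the sums of squares is snapped to zero.

Bootstraps resample subject x hand rows (the analysis unit), not individual
trials.  Every stochastic step consumes a named child generator spawned
from the run's master seed, so one seed fixes every artifact byte-for-byte.

## Trial-level model and power

At the trial level the 240 differences are modelled as
`d_ij = b0 + b1 (m_ij - mean(m)) + u_i + e_ij` by REML (statsmodels
MixedLM), with a subject random intercept (optionally subject x hand).  The
regressor is centred so the intercept reads as bias at average magnitude;
the marginal mean of d is reported separately since "mean bias" is
ambiguous between the two.  A zero random-intercept variance degrades
gracefully to OLS with a logged note; constant differences are reported as
degenerate with both SDs at zero.

ICC sample size uses the Walter-Eliasziw-Donner approximation
`n = ceil(1 + 2 (z_{1-a'} + z_{power})^2 k / ((k-1) ln^2 C0))` with
`C0 = (1 + k r0/(1-r0)) / (1 + k r1/(1-r1))`; the default is one-sided
(testing that the ICC exceeds a minimum acceptable value) with k = 2
measurements per subject, and the inverse of the same formula gives achieved
power.  For r0 = 0.75, r1 = 0.90, alpha = 0.05, 80% power and k = 2 this
evaluates to 26 subjects.

## Numerical choices

- Distance-rule comparisons use a 1 ns slack (12 samples at 100 Hz is not
  exactly 0.12 in binary).
- The window boundary uses the same 1 ns tolerance on the closed interval.
- CSV round-trips use pandas' `float_precision="round_trip"` parser so
  write -> read -> write is byte-idempotent.
- Quantiles everywhere are the linear-interpolation ("type 7") convention.
- NaN/inf are serialized as JSON null; the report validates against the
  schema shipped at `tapagree/schemas/report.schema.json`.

## Problem sizes used in validation

The test suite validates calibration by simulation at sizes chosen to make
each property statistically identifiable: detector-oracle equivalence on
1000 random signals of up to 1000 samples; ICC bootstrap coverage over 500
replicates of 100 units at 1000 resamples; Lilliefors type-I error over
2000 null replicates at n = 20; mixed-model slope coverage over 200
replicates of 50 subjects x 12 trials; and the power formula on a 60-spec
grid.  The perfect-sensor recovery check uses the noise- and artifact-free
cohort with the ITI floor raised to 0.130 s, just above the detector's
0.120 s refractory distance: 100% event recovery is only well-posed when
true events are farther apart than the distance the detector is allowed to
merge over (the 0.120 s criterion itself presumes physiological ITIs of
0.125 s and up).

## What the synthetic validation does not show

The generator emulates the geometry the detector relies on (symmetric
contacts, dominant impact spikes, the double-peak artifact, multi-rate
clocks, start offsets) but not real-world nuisances: sensor drift, axis
misalignment and gravity leakage, amplitude fatigue within a trial, missed
or partial contacts, soft-surface damping, or camera digitization error
beyond white noise.  Passing the suite therefore demonstrates that the
*measurement pipeline and statistics* are correct and calibrated, not that
any particular hardware pair agrees; with near-ideal synthetic sensors the
between-method differences are tiny and the agreement statistics sit near
their perfect-agreement limits, unlike the modest biases real instruments
produce.  Drift correction and adaptive detection thresholds are explicitly
out of scope.
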