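# Methods

## Scope and data model

`strokemetrics` analyses multi-sensor recordings of the tennis forehand:
a racket-mounted 6-DOF IMU (3-axis gyroscope, ±4000 dps), three 3-axis
accelerometers (±200 g) at the racket, wrist and elbow, one
grip-pressure channel and two surface-EMG channels over the forearm
extensor (ECR) and flexor (FCR) muscle groups.  A session is a uniformly
sampled CSV stream plus a JSON metadata sidecar (player id, group,
handedness, preferred grip position, spin condition).  All sessions are
resampled onto a common working grid (default 8333 Hz, linear
interpolation) before analysis; for left-handed players the gyroscope
and racket-accelerometer x-axes are negated so that swing direction is
comparable across the cohort.

Because no public recordings exist for this kind of instrumented
protocol, the package ships a first-class synthetic generator
(`strokemetrics.synthgen`) whose outputs carry exact ground truth, and
every downstream stage is validated against that truth.

## Stroke detection and phase segmentation

Ball impact is the first sample at which the racket z-axis (perpendicular
to the string bed) reaches 20 g; the signed channel is thresholded by
default with a configuration switch for |z|, since impact polarity
depends on sensor mounting.  A 0.5 s refractory period suppresses
re-detections inside the impact ring-down (ball-feed intervals are far
longer in practice), and each retained impact is windowed to ±1 s with
the impact at the exact centre sample.

Within a window the stroke phases are located on two derived series:

* **racket-head acceleration** `‖(ax, ay, az)‖` (g).  Preparation starts
  at the first pre-impact sample above 1 g and follow-through ends at the
  first post-impact sample below 1 g.  Both crossings must be sustained
  for ≥ 10 ms to reject single-sample noise (the threshold alone is not
  debounced at 8 kHz), and the follow-through search starts at +0.05 s so
  the impact transient itself cannot end the stroke.
* **swing-path angle** `atan2(x, z)` in degrees.  −90° corresponds to
  acceleration toward the racket's bottom edge — the pause before the
  forward swing.  The acceleration phase starts at the *latest* pre-impact
  upward crossing of −90°: incidental backswing crossings earlier in the
  window are not the forward-swing pause.  The two-argument arctangent is
  deliberate; the quotient form has open range (−90°, 90°) and can never
  attain −90°.  If no crossing exists the pre-impact minimum of the angle
  is used and the result flagged.

Each phase is split into early/late halves at its temporal midpoint.

The 1 g and 20 g thresholds assume *dynamic* (gravity-free) acceleration
with a near-zero rest baseline; a gravity-inclusive accelerometer would
idle near 1 g and make the preparation threshold meaningless.  This is a
modeling convention of this package and the generator follows it.

## EMG envelope and MVC normalization

EMG amplitude uses rectify-and-smooth: zero-phase order-8 Butterworth
high-pass at 10 Hz, full-wave rectification, zero-phase order-8
Butterworth low-pass at 10 Hz.  "Order 8" is the design order of each
pass; forward–backward application (SciPy `sosfiltfilt`, second-order
sections for numerical stability at cutoff/Nyquist ratios near 10/8333)
doubles the effective order and cancels phase lag.  Envelope undershoot
is clipped at zero because muscle-activity amplitude is nonnegative.  On
a unit sinusoid in the passband the envelope converges to the rectified
mean 2/π, which the tests verify analytically.

Grip and EMG references come from three 5 s seated maximal-grip trials:
the trial with the highest grip value wins (first trial on ties) and the
middle two seconds of its grip trace and EMG envelopes are averaged.
Stroke curves are expressed in percent of these references; dynamic
values routinely exceed 100 %MVC because an isometric reference does not
bound activity during a fast stroke.  Grip strength "at impact" reads the
normalized raw grip trace at t = 0 (the grip channel is slow; no
filtering is applied to it).

## Shock transmission

Impact shock is quantified in the 15–400 Hz band: a zero-phase low-pass
at 400 Hz removes string vibration and a zero-phase high-pass at 15 Hz
removes gross arm motion (order 4 per pass by default; the band edges are
the physiologically motivated defaults and configurable).  **Each
accelerometer axis is filtered first and the vector magnitude taken
afterwards.**  The order matters: the filters are linear on axis signals,
so an attenuated copy of the racket transient remains an attenuated copy
and the transmission ratio is preserved essentially exactly (measured
recovery error ≈ 0.1 %), whereas filtering the rectified magnitude series
folds swing and contaminant components into the peak (measured error
≈ 10 %, double the generator's own tolerance).  The post-impact peak is
the maximum |·| over t ∈ [0, min(0.5 s, follow-through end)]; transmission
is `100 − ((A_racket − A_x)/A_racket × 100) = 100·A_x/A_racket` percent.
Wrist/elbow channels may be absent (as for 3 of 40 players in the kind of
study emulated); those strokes carry availability flags and are excluded
from shock comparisons only.

## 1-D SnPM inference

Curve variables (racket face-angle rate = gyroscope y, racket-head
acceleration, grip %, ECR %, FCR %) are compared over the whole ±1 s
window.  The experimental unit is the **player mean curve** (strokes are
averaged within player per spin condition first); curves are decimated to
a 401-node grid by default (101 in the desk-scale drivers) before
permutation testing, and the decimation is recorded in the results.

The non-parametric test forms the pointwise t field (pooled-variance
two-sample, or paired-difference one-sample) and controls the familywise
error rate with the permutation distribution of max |t| over the grid:
group-label relabelings for two-sample tests, sign flips of the
difference curves for paired tests.  All distinct rearrangements are
enumerated exactly when their count is ≤ 10,000 (C(n_a+n_b, n_a) or 2^n);
otherwise random rearrangements are drawn with the identity included.
The critical value is the conservative (1 − α) quantile: the smallest
null value whose upper-tail count is at most ⌊αN⌋, with exact permutation
ties merged at a 10⁻⁹ relative tolerance.  Two-sided permutation nulls
contain structural ties (complementary relabelings and ±sign patterns
yield identical max-|t|), and merging them is what actually guarantees
FWER ≤ α under enumeration; a plain quantile index does not.  A
consequence the tests pin down: at α = 0.05, 3-vs-3 two-sample and n = 4
paired designs cannot reach significance at all (minimum attainable
two-sided p is 0.10 and 0.125), and the threshold is reported as +∞.
Clusters are maximal supra-threshold runs; t > 0 means the first input's
mean is higher.  No cluster-mass p-values are reported — only the
supra-threshold intervals and their directions.

The parametric route thresholds the same t field with the 1-D
random-field-theory excursion approximation (smoothness estimated from
normalized residual gradients, Euler-characteristic density for the t
field, two-sided).  It exists for the standard decision rule: when the
parametric and non-parametric significance masks disagree, the data are
treated as non-Gaussian and the non-parametric result is reported.  The
full RFT machinery (cluster-level inference, non-sphericity) is out of
scope.

Discrete scalar outcomes use a Lilliefors normality test — the KS
distance to a normal with estimated mean/SD, with a seeded Monte-Carlo
null (each simulated sample re-standardised by its own estimates) —
branching to paired/two-sample t-tests when normality is not rejected at
0.05 and to Wilcoxon signed-rank/rank-sum otherwise, all two-sided.  For
samples too small to test (n < 4) the parametric branch is used and the
normality p reported as NaN.  No multiple-comparison correction is
applied across the scalar table; every test runs at α = 0.05 and the
output names the test used so readers can judge.

## The synthetic generator

`generate_stroke` builds a recording whose ground truth is exact on the
sample grid:

* the racket-head acceleration magnitude follows a smooth swing hump that
  jumps above 1 g exactly at the programmed preparation-onset sample and
  falls below 1 g exactly at the follow-through-end sample;
* the swing-path angle ramps monotonically from a backswing value
  (−150°) through −90° exactly at the programmed acceleration onset to a
  terminal angle at impact; group/spin-specific terminal angles (4.3°,
  20.0°, 5.2°, 6.8°) reproduce the qualitative ordering in which
  experienced players brush far more on topspin;
* the impact transient is an exponentially decaying 150 Hz cosine
  (e-folding 15 ms ≪ 0.5 s, so "peak after impact" is unambiguous)
  starting at the impact sample with peak > 20 g on the z-axis;
* wrist and elbow carry the *raw* racket transient scaled by attenuation
  ratios (elbow < wrist, both in (0, 1)) — attenuation is modeled as
  frequency-flat, so the ratio is preserved exactly after the pipeline's
  own band-limit — plus a 2.5 Hz arm-motion sinusoid and an 800 Hz
  string-vibration burst that the 15–400 Hz filter removes;
* EMG channels are 20–450 Hz band-limited Gaussian noise bursts confined
  to programmed windows; grip pressure is a smooth burst peaking at
  impact;
* channels are clipped to the hardware ranges and optionally carry
  additive Gaussian measurement noise (defaults: 0.02 g accelerometer,
  2 dps gyroscope, 0.005 grip, 0.02 EMG in sensor units — small relative
  to signal scales, as for modern MEMS parts).

`generate_cohort` assembles two groups × two spin conditions with
per-player trait variation (attenuations ≈ N(0.2, 0.03) wrist and
N(0.04, 0.008) elbow, clipped; impact peaks uniform on 40–60 g; ≈ 7.5 %
left-handed players), three MVC trials per player, and optional group
effects.  Effect curves are injected additively into a named raw channel
around each impact for the second group; for EMG channels the offset is
delivered as an 80 Hz carrier scaled by π/2 so the downstream envelope
rises by approximately the requested amount (an additive DC offset would
be removed by the 10 Hz high-pass).  An all-zero effect gives a null
cohort in which both groups follow the identical distribution.

What the generator does **not** emulate: racket modal dynamics and
frequency-dependent transmission, ball flight and spin, inter-channel
cross-talk, sensor drift and clock skew between devices, and the human
variability of real technique.  Passing tests therefore demonstrate that
the *pipeline* recovers what it claims to measure under controlled
conditions — not that real recordings are this clean.

## Problem sizes and numerical choices

The drivers and tests run at desk scale by choice: cohorts of 4–8
players per group, 1–3 strokes per condition, 2 kHz generator rate (the
generator requires > 1 kHz; sample-exact segmentation tests use the full
8333 Hz default), 101-node SnPM grids, and 512–1000 permutations for
Monte-Carlo nulls.  The FWER calibration simulation uses 300 null
cohorts of 8 smooth-Gaussian player-mean curves per group.  Determinism:
every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical
recordings and tables.  Degenerate inputs are handled explicitly:
zero-variance grids give t = 0 (paired identical inputs ⇒ no clusters),
undefined swing-path samples carry the previous angle forward,
zero-length phases yield flagged empty halves, and permutation designs
too small for the requested α report an infinite threshold rather than a
spuriously finite one.

## Known limitations

* The impact-alignment convention (first 20 g crossing) ignores
  between-player differences in racket-head acceleration build-up; all
  curves are aligned on that single event.
* The parametric RFT threshold uses the stationary 1-D approximation
  with a single global smoothness estimate.
* Scalar tests are numerous and uncorrected by design; interpret the
  table, not single stars.
* Grip-position comparisons ingest Continental-grip players but exclude
  them from testing (group sizes are never adequate for that grip).
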