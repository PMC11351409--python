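# Methods

This note documents the computational procedure, the assumptions behind
each step, the tunable parameters with their defaults, and the known
limitations.  Formulas and defaults here are the ones implemented in
`src/qvor/`; nothing below is device- or vendor-specific.

## 1. Input model

A recording is a pair of uniformly sampled angular-velocity series — head
and eye, in °/s — from a sinusoidal vHIT paradigm: qVVOR (earth-fixed
target, expected gain ≈ 1) or qVORS (head-fixed target, expected gain
≈ 0.35).  The reference protocol is a 17 s recording at 250 samples/s with
the head oscillated at a metronome-paced 0.75 Hz over a 30–40° arc, giving
a peak head velocity of (arc/2)·2π·f ≈ 82 °/s for a 35° arc.  These sizes
are package defaults, not requirements: any rate and duration ≥ 13 s that
covers the analysis window is accepted, and `validate_trace` only *warns*
when the peak velocity is far from the protocol value.

Sign convention: compensatory eye movement opposes the head, so the raw
regression slope is negative; gains are reported as slope magnitudes.

## 2. Pipeline stages

### 2.1 Trimming and analysis window

The first and last 1 s are discarded (start-up and slow-down transients),
then the analysis keeps the half-open window **[8 s, 13 s)** of original
recording time (5 s, i.e. 3.75 periods at 0.75 Hz).  The window is
half-open so that adjacent windows would partition a recording without
overlap, and boundary comparisons carry a 1 ns tolerance so that
floating-point time stamps at exactly 8.000 s or 12.996 s are classified
deterministically.  Timestamps are never re-zeroed; all intervals are
reported in original recording time.

Parameters: `AnalysisWindow(start_s=8.0, end_s=13.0)`; trim of 1 s per
end.  Shorter windows raise variance; windows overlapping the trimmed
transients bias gain downward.

### 2.2 Desaccading

Quick phases and catch-up saccades violate the slow-phase linear model and
must be excluded before regression.  Two complementary mechanisms:

1. **Acceleration threshold.**  Eye acceleration is computed with central
   differences (`np.gradient`); samples with |dė/dt| > **4000 °/s²** are
   seeds, each padded by **±40 ms** to cover the low-acceleration crest of
   the saccade, and overlapping intervals are merged.  Sinusoidal
   slow-phase acceleration peaks near 2π·f·v̂ ≈ 400 °/s² under the
   protocol, an order of magnitude below the threshold, so pure slow
   phases are never flagged.
2. **Robust residual rejection.**  After the threshold pass, the
   zero-intercept fit is iterated: samples whose residual exceeds
   **k = 3** × 1.4826 × MAD(residuals) are dropped and the fit repeated,
   up to `max_iter = 10` passes or until the slope changes by
   < `1e-6`.  The scale estimate is floored at **0.5 °/s** so that
   noiseless traces (MAD = 0) do not reject everything.  Setting
   `max_iter=1` with `residual_k=inf` disables rejection entirely and
   reproduces the closed-form slope exactly; the test suite uses this to
   check the implementation against an independent oracle at 1e-9.

An `EstimationError` is raised if fewer than `min_retained = 50` samples
survive per direction.

Parameters (`DesaccadeParams`): `accel_threshold=4000 °/s²`,
`pad_ms=40`, `residual_k=3`, `residual_floor_dps=0.5 °/s`,
`max_iter=10`, `convergence_tol=1e-6`, `min_retained=50`.

### 2.3 Direction split

Gain is asymmetric in disease, so it is estimated separately for rightward
(head velocity > +deadband) and leftward (< −deadband) motion.  The
**±10 °/s deadband** excludes turnaround samples, where velocities are
small, the signal-to-noise ratio is poor, and the zero-intercept model
contributes almost no information (the fit weights samples by h²).  For an
82 °/s sinusoid the deadband discards ~6 % of samples per half-cycle.

### 2.4 Gain estimation

The slow-phase gain is the magnitude of the zero-intercept least-squares
slope of eye velocity on head velocity over the retained samples of one
direction:

    g = | Σ hᵢ eᵢ / Σ hᵢ² |

The zero intercept encodes the physiological constraint that zero head
velocity implies zero compensatory eye velocity; a free intercept would
absorb drift and spontaneous nystagmus into the offset and is deliberately
not offered.  Diagnostics returned per fit: retained sample count, raw
slope, residual SD, convergence flag.

### 2.5 Frequency estimation

The achieved oscillation frequency is estimated from head velocity:
Hann-windowed periodogram zero-padded to `2^ceil(log2(8n))`, peak bin
refined first by parabolic interpolation of log power, then by bounded
continuous maximization of the DFT power (`scipy.optimize.minimize_scalar`)
within one bin of the peak.  A zero-crossing estimate is computed as a
cross-check; a discrepancy above **0.05 Hz** logs a warning (not an error,
since zero-crossing counts are quantized to ±0.1 Hz over a 5 s window and
routinely trip the check on clean data).

## 3. Suppression indices

From a subject's qVVOR/qVORS pair (gains g with side subscripts R/L):

- unilateral, per side: `SI_side = g_VORS,side / g_VVOR,side`
- asymmetry, per test: `Asym = min(g_R, g_L) / max(g_R, g_L)`
- bilateral: `SI_b = (mean(g_VORS) · Asym_VORS) / (mean(g_VVOR) · Asym_VVOR)`

All indices are fractions in [0, ~1]: 0 is perfect suppression.  The
bilateral index satisfies `SI_b ≤ ½(SI_R + SI_L)/Asym_VVOR` (proved
algebraically, asserted as a property test).  Guards: a qVVOR gain below
**0.2** makes the ratio unstable and flags the result
(`QVVOR_GAIN_FLOOR`); subjects with an impulsive HIMP gain < **0.7** on
either side fail the inclusion screen (strict inequality) and are excluded
before sinusoidal analysis.  A packaged normative table
(`src/qvor/data/normative_si.csv`, percentiles 5–95 for left, right and
bilateral SI) places any observed SI in a healthy-reference band; exact
percentile ties resolve to the percentile label.

## 4. Cohort statistics

Implemented as thin, explicit wrappers over `scipy.stats` so every test is
named and its assumptions stated:

- normality: one-sample Kolmogorov–Smirnov against a normal fitted by
  sample mean/SD (n ≥ 5);
- achieved frequency vs the 0.75 Hz metronome target: Wilcoxon signed-rank
  by default (t-test optional), n ≥ 6, degenerate when all differences
  are zero;
- sex contrast: Welch-free two-sample t-test via `ttest_ind`; the reported
  effect is mean(second group) − mean(first group) in sorted label order
  (F, M → male − female);
- age groups: Levene (center="mean") for variance homogeneity plus
  one-way ANOVA across decade bins (≤20, 21–30, …, >80) with ≥ 2 subjects;
- percentiles: `np.percentile` with linear interpolation.

## 5. Synthetic data: what it emulates, and what it does not

The generator produces recordings and cohorts with exact ground truth so
that recovery can be tested end to end.

**Single trace** (`TraceSimConfig`): head velocity is a pure cosine at the
achieved frequency with protocol peak amplitude; eye velocity is
−g(direction)·head (direction-specific true gains supported), plus
raised-cosine saccade pulses arriving as a Poisson process (rate per
second; peak 100–300 °/s, duration 30–80 ms; pulse sign follows head
direction for VORS — anti-compensatory catch-ups — and is random for
VVOR), plus Gaussian sensor noise (SD 3 °/s).  All randomness flows from
one integer seed; identical seeds give bit-identical traces.

**Cohort** (`CohortSimConfig`, defaults): 83 subjects, 41 female; age
drawn from decade bins with probabilities 8:19:9:11:10:15:9:2 over the
ranges [15, 20] … [81, 90]; gains drawn from truncated normals per
quantity (HIMP gains truncated below at 0.7 — the simulated cohort is
*post-screening* by construction); left/right gains of a subject drawn
with correlation **0.75** (physiological symmetry; independent draws would
understate asymmetry correlation and depress the bilateral SI);
multiplicative sex factors **0.270/0.295** (F) and **0.319/0.295** (M)
applied to qVORS gains, with weighted mean ≈ 1 so marginal means are
preserved; achieved-frequency error N(+0.075, 0.02²) Hz modelling
examiner overshoot of the metronome; saccade rates 0.5 /s (VVOR) and
2.0 /s (VORS).

Deliberately **not** modelled: blink artifacts and tracking dropouts,
gaze-position dependence of gain, phase lag between head and eye,
non-sinusoidal head trajectories, age-dependent gain drift, and any
correlation between saccade rate and gain.  Saccade shape (raised cosine)
and rate are stated assumptions, not fits to recordings.

## 6. Numerical choices

- Half-open window and 1 ns boundary tolerance (see 2.1).
- Zero-intercept regression in closed form; no matrix solve, no intercept.
- MAD scale floored at 0.5 °/s to keep robust rejection defined on clean
  signals.
- Spectral refinement: parabolic interpolation seeds a bounded continuous
  optimization, so the estimate is not quantized to the FFT grid.
- Percentile placement uses exact-match tolerance 1e-12 before banding.
- Cohort seeds for per-trace generators are drawn below 2³¹ so they remain
  valid across integer-width conventions.

## 7. Limitations

- Gain is a single linear slope per direction; nonlinear or
  velocity-dependent VOR behaviour is averaged over.
- The 5 s window assumes stationarity; fatigue or attention drift within a
  recording is not detected.
- The normative table is a fixed reference; it is not re-estimated from
  user data and applies to the 0.75 Hz sinusoidal protocol only.
- The simulator validates recovery of the *model it generates*; agreement
  with real goggle recordings must be established separately on clinical
  data.
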