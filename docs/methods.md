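# Methods

This note records the models, conventions and numerical choices behind
`beltsense`, in enough detail to reproduce every number the package
computes.

## Signal derivation

The pre-processing chain, applied to uniformly sampled accelerometer (g)
and gyroscope (rad/s) streams:

1. **Denoising** — a width-3 median filter (removes single-sample spikes
   without distorting band-limited motion) followed by a third-order
   Butterworth low-pass at 20 Hz. The sampling rate must exceed 40 Hz.
2. **Gravity/body split** — a third-order Butterworth low-pass at 0.3 Hz
   gives the gravity component; the body component is defined as the
   residual, so the two reconstruct the denoised signal exactly.
3. **Jerk** — `np.gradient` scaled by the sampling rate: central
   differences in the interior, one-sided at the ends, so all channels
   keep the input length and stay window-aligned. Applied to body
   acceleration and (as "angular acceleration") to the denoised angular
   speed.
4. **Magnitudes** — per-sample Euclidean norm of each triaxial signal.
5. **Frequency channels** — per 128-sample window, the one-sided FFT
   magnitude `|rfft(w)|[:64] / 128` (DC kept, Nyquist bin dropped,
   normalized by window length so spectral features are scale-stable).
   No taper is applied. The 7 signals with frequency versions are body
   acceleration (XYZ and magnitude), body jerk (XYZ and magnitude),
   angular speed (XYZ and magnitude) and angular-acceleration magnitude;
   gravity and the angular-acceleration XYZ triplet stay time-only.

All filters run zero-phase (forward–backward, `sosfiltfilt`), which
assumes offline processing; this avoids group delay between channels at
the cost of being non-causal. Zero-phase filtering needs at least 13
samples; shorter inputs are rejected with a message naming the stage.

Default sampling rate is 100 Hz (a 128-sample window spans 1.28 s); all
filters are designed from cutoffs in Hz, so other rates work unchanged.
Units are fixed by convention: acceleration in g, angular speed in rad/s,
conversions belong at the I/O boundary. Device frame: +X down the body
when standing, +Z forward, +Y to the wearer's left.

## The 561-feature enumeration

Per window the feature bank computes, in a frozen order published by
`feature_names()`:

| block | per signal | signals | total |
|---|---|---|---|
| time XYZ | mean/std/mad/max/min/energy/iqr/entropy ×3, sma, AR(4) ×3, corr ×3 = 40 | 5 | 200 |
| time magnitude | the scalar stats + sma + AR(4) = 13 | 5 | 65 |
| freq XYZ | scalar stats ×3, sma, maxFreqInd/meanFreq/skewness/kurtosis ×3, 14 band energies ×3 = 79 | 3 | 237 |
| freq magnitude | 13 scalar spectral stats | 4 | 52 |
| angles | body-signal window means and unit axes vs gravity mean | — | 7 |
| | | | **561** |

Band energies use a fixed partition of the 64-bin spectrum: eight 8-bin
bands, four 16-bin bands and two 24-bin bands (1-based inclusive ranges,
e.g. 1–8 … 57–64, 1–16 … 49–64, 1–24, 25–48). A 12-band (8+16 only)
partition would not land on 561; the 14-band partition is the established
convention for this feature family and closes the count exactly.

`range` and `rms` are implemented and oracle-tested as feature functions
but are not part of the frozen 561 enumeration — no enumeration containing
them reaches the canonical total.

Conventions that pin down every value:

- `std` uses the population (1/N) form; `energy` is the mean square,
  `rms` its square root.
- `sma` carries a 1/N in addition to the 1/3 axis average, making it
  window-length invariant (standardization absorbs the constant anyway).
- `entropy` is Shannon entropy in nats of the weights `|s_i| / Σ|s_j|`,
  with 0·log 0 = 0 and an all-zero window defined as 0.
- `iqr` uses linear-interpolation quantiles.
- `autoregression` is 4th-order Burg without demeaning, positive-AR-sign
  convention (`x_t ≈ a₁x_{t−1}+…`), via `statsmodels`; constant windows
  (where the lattice recursion degenerates) return zeros.
- `correlation` is Pearson; a constant channel gives 0 by definition.
- `skewness`/`kurtosis` are the population moment ratios m₃/m₂^1.5 and
  m₄/m₂² (non-excess); constant windows give 0.
- `maxFreqInd` is the 0-based argmax (first on ties); `meanFreq` weights
  1-based bin indices by the spectrum.
- `angle(u, v) = atan2(‖u×v‖, u·v)` in radians; zero vectors give 0.

Window labels are the majority per-sample label, ties broken by the
earliest label in the window. Standardization is mean / population-std
per feature, fit on training windows only; zero-variance features get
scale 1 and are flagged.

## Activity recognition

A scikit-learn random forest (100 trees, unlimited depth, √p features per
split, seeded) on standardized vectors. Stratified 10-fold CV operates at
the window level: folds are class-stratified, and within each fold the
standardizer and forest see training windows only. LOPO CV holds out one
subject per fold and supports re-aggregating pooled predictions by any
subject attribute. F1 is reported weighted-by-support (headline) and
macro, with the full confusion matrix. Window-level 10-fold splitting
means temporally adjacent (50 % overlapping) windows of one bout can fall
on both sides of a fold; that is inherent to window-level CV and is the
reason pooled scores exceed LOPO scores.

## Posture

Attitude angles come from the acceleration direction (formulas in the
README); the ϕ expression uses |Acc_z| in a ratio of magnitudes, so
axis-aligned inputs land exactly on 0°/90° and ϕ stays in [0°, 90°].
Whole-recording assessment computes angles on the 0.3 Hz gravity
component, so brief body motion does not flip the verdict sample to
sample. The good-posture policy (|ψ| ≤ 10°, ϕ ∈ [80°, 90°]) is an
explicit, configurable rule object: the tolerances are policy choices,
not physiology, and tightening them can only increase the poor-posture
rate (tested). The improvement rate between two session blocks is
`100 · (rate_without − rate_with) / rate_without`, undefined at a zero
baseline.

## Waistline

The peak counter detrends the trace linearly, smooths it with a 3-sample
moving average, rescales by the robust (5th–95th percentile) range, and
counts upward crossings of 60 % that follow a visit below 40 %
(Schmitt trigger). Noise below the 20 % hysteresis band cannot create or
destroy counts, and both thresholds and the cycle-free gate (smoothed
amplitude must exceed 4× the smoothing-residual noise estimate) are
ratios, so the count is invariant to amplitude scaling and baseline
drift. Insertion depth is `count × pitch` (pitch 0.6 cm, configurable per
belt) and the waistline is `belt_length − insertion − offset`, with
`offset` a per-belt calibration constant absorbing the buckle geometry.

Counting whole teeth quantizes the depth to the pitch, so on noiseless
traces |estimate − truth| ≤ 0.6 cm at any depth. With the belt starting
at an arbitrary alignment within a tooth (the generator's
`tooth_phase_cm`, drawn uniformly in evaluation runs), the expected mean
absolute error is 0.2 cm; with the alignment fixed at a tooth boundary it
is 0.3 cm. The hardware's measured error on a physical belt reflects
blade/magnet noise that is deliberately not simulated; the package
verifies the algorithm's resolution bound instead. Only a single
monotone insertion event is modeled; insertion and removal are
indistinguishable from a scalar count, and session segmentation is left
to the caller.

## Intervention engine

A pure state machine stepped on strictly increasing timestamps. Posture
is consulted only while the recognized activity is `sit`; poor posture
sustained ≥ 5 s (debounce) fires one vibration event, a continuous
sit/lie streak ≥ 30 min fires a walk-prompt notification, each cause has
a 60 s refractory period, and leaving the triggering state resets its
timer. All constants are configuration with these defaults. Event counts
are monotone non-increasing in debounce and refractory, and replay is
bit-identical — both tested. The device radio link is abstracted as the
returned event list.

## Synthetic data generator

Activity kinematics are stylized on purpose: each activity is a gravity
orientation in the device frame plus phase-randomized sinusoids and white
noise, not a biomechanical simulation. Static postures differ by gravity
direction (stand upright, sit pitched 15° forward, lie with gravity along
+Z); locomotion differs by cadence and amplitude (walk 1.8 Hz, stairs
1.5 Hz with up/down asymmetry, run 2.8 Hz, each with one harmonic).
Accelerometer noise is 0.025–0.08 g depending on activity.

Subjects are drawn once per population: amplitude gain (log-normal,
σ = 0.2), a cadence offset shared by all locomotion (σ = 0.15 Hz),
baseline belt tilt (pitch σ = 8°, roll σ = 6°) and a noise scale
(log-normal, σ = 0.3). A single `heterogeneity` factor scales all four
spreads; at 0 all subjects are clones. This heterogeneity is what makes
LOPO evaluation harder than pooled k-fold, qualitatively mirroring
physique and gender differences across real wearers.

The default evaluation population is 17 subjects with one bout per
activity; the package uses 12.8–20 s bouts (10–30 windows per bout) as
its standard problem size, which is ample for the structural and ordering
claims it tests. Because the class structure is separable by construction,
passing scores certify the pipeline (no leakage, correct fold bookkeeping,
features that carry class information), **not** real-world recognition
accuracy: real belt data adds transitions between activities, non-
stationary noise, soft-tissue artifacts and far more within-class
variety. Note also that the magnitude of an oscillating body-acceleration
signal peaks at twice the cadence (rectification), so cadence checks
belong on the per-axis spectra.

The magnetometer generator renders one raised-cosine pulse per fully
crossed tooth at an insertion speed of 5 cm/s on a constant baseline,
with optional white noise and a configurable initial tooth alignment
(default: aligned to a tooth boundary).

## Known limitations

- Offline, zero-phase processing only; no streaming/causal mode.
- Window-level k-fold CV shares bouts between train and test folds by
  design; use LOPO for cross-subject claims.
- The posture thresholds are fixed cutoffs, not hysteresis bands; a
  deployed device might debounce at the angle level too.
- The waistline counter assumes one monotone insertion; mixed
  insert/remove sessions need prior segmentation.
- Synthetic subjects share one template set; the generator cannot create
  the confusions real heterogeneous populations show (e.g. slow running
  vs fast walking in the same person).
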