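# Methods

## Data model and conventions

A *session* is one horse at one gait (trot or canter) in one run
(before or after the training session); it holds one or more corridor
*passages*, each with time-synchronized streams from up to nine IMUs:
specific force (m/s², gravity included) and angular velocity (rad/s) in
the sensor frame, and unit orientation quaternions rotating the sensor
frame into the global frame. Quaternions are scalar-first Hamilton;
q and −q are identified (canonicalized to non-negative scalar part).
The global frame is right-handed with +Z up and g = 9.81 m/s². The
sensor x axis is aligned with the segment's longitudinal axis, which on
the cannons is the limb axis used for the twist decomposition.
Sampling rate is arbitrary on input; synthetic data default to 128 Hz.

## Kinematic channels

Per sensor: `acc_x/y/z`, `gyro_x/y/z` (raw sensor frame); `acc_vert`
and `acc_horiz` from a_g = R(q)·acc − g·ẑ (vertical component, and the
norm of the two horizontal components — one channel, which is also yaw-
invariant); `angle_xv/yv/zv` = arccos of each rotated axis' vertical
component, unsigned in [0°, 180°]; and for cannons the signed swing and
twist angles of q_rel = q_ref⁻¹ ⊗ q factored as q_swing ⊗ q_twist with
the twist about sensor x. That yields 13 channels for cannons and 11
otherwise. Choices worth noting:

* **Gravity is removed before resolving components**, so a static
  sensor reads zero whatever its attitude; `acc_vert` is then a
  movement signal comparable across sensor placements.
* **Swing–twist reference** is the per-recording mean attitude
  (normalized quaternion mean — adequate for within-passage attitude
  spreads), making the limb-angle channels drift-free without an
  external calibration pose. Twist is signed by the right-hand rule
  about +x; swing by the sign of its axis' sensor-y component (ties
  to +). A 180° rotation exactly orthogonal to the twist axis has no
  defined twist: it is reported as 0 with a degeneracy flag.

## Stride segmentation

The sternum's `acc_vert` is filtered with a 4th-order low-pass
Butterworth at 3 Hz, applied forward–backward (zero phase) so peak
times are not lagged; the effective magnitude response is that of an
8th-order filter, which is immaterial because only peak locations are
used. Local maxima are accepted greedily in amplitude-descending
order; a candidate closer than 0.75 × the current period estimate to an
accepted peak is rejected. The period estimate is initialized from the
dominant spectral frequency in 0.5–3 Hz (error if no periodicity is
found there) and updated as the running median of accepted inter-peak
intervals, ignoring gaps beyond 1.5 × the initial estimate so missed
peaks cannot inflate it. A stride is the half-open sample window
between consecutive accepted peaks. Peaks within half a period of the
record edges are flagged `edge_truncated` and excluded from stride
windows; all sensors of a passage are segmented with the sternum-derived
boundaries. An automated QC report (per-stride flags, period CV,
pass/warn verdict with warn at CV > 15%) replaces a manual check of the
segmentation plot.

## Stride comparison

Each stride of each channel is resampled to 100 points by monotone
piecewise-cubic (PCHIP) interpolation over [0, 100%] of the stride.
Strides of a run are pooled across the run's passages into one group
per channel; the group reference is the stride minimizing RMSD to the
pointwise group mean (ties to the lowest index). Indicators:

* `intra_before` / `intra_after`: mean CC and RMSD of a run's strides
  against their own reference, the reference itself excluded (it would
  contribute exact 1.0/0.0 values);
* `inter`: after-run strides against the *before*-run reference (the
  anchored direction used by the screen); the symmetric direction is
  stored as `inter_sym` but not screened.

CC is undefined for a zero-variance stride and propagates as NaN; RMSD
is always computed. Stride duration (mean peak-to-peak interval per
run) is carried as its own indicator. Per horse there is one value per
(channel, indicator, scope): the mean over all strides of both
passages.

## Smoothness

SPARC and LDLJ-A are computed per stride on raw-time samples, not on
the 100-point normalized strides: smoothness lives on a true time/
frequency axis. For SPARC the magnitude spectrum is taken by FFT after
zero-padding to the next power of two ≥ 4 × the segment length,
normalized by its maximum, and the discrete arc length
Σ √((Δf/fc)² + ΔV̂²) is accumulated over the grid up to fc = 10 Hz.
One linearly interpolated spectrum sample is appended at exactly fc, so
the Δf/fc terms always sum to exactly 1 and SPARC ≤ −1 is an identity
rather than an approximation (without it, the bound can fail for short
segments whose last FFT bin falls short of fc). A constant (DC-only)
signal is the continuum limit of a perfectly smooth movement and
returns −1 exactly; an all-zero signal has no spectrum to normalize and
is an error. SPARC is also computed on the angular-velocity norm,
which is invariant to how the sensor is mounted.

LDLJ-A uses the gravity-free global acceleration restricted to the
stride, a_peak = max ‖a_g − ā‖ after removing the segment-mean vector,
jerk by central differences, and trapezoidal integration of ‖jerk‖²;
the duration/a²peak prefactor is the only unit-consistent reading of
the dimensionless jerk and makes LDLJ invariant to amplitude scaling.
Constant acceleration (zero a_peak or zero jerk integral) is flagged
degenerate rather than returning a number.

## Screening

One paired Wilcoxon signed-rank test per indicator key (gait, sensor,
channel, indicator type) across horses: CC and RMSD pair intra-before
with inter values (the intra comparison is the built-in null: within a
run the training session cannot have caused differences); SPARC, LDLJ
and stride duration pair before with after run values. Zero
differences are dropped, tied absolute differences get average ranks,
and the two-sided p-value is exact by enumeration over all 2ⁿ sign
assignments for n ≤ 15 pairs (normal approximation with continuity and
tie corrections above). Left/right cannon sensors are pooled by
per-horse averaging before testing (configurable). No multiple-testing
correction is applied by default, matching common practice for
hypothesis *screening*; a Benjamini–Hochberg option exists. Reported
significance bands are p < 0.01 and 0.01 ≤ p < 0.05. CC keys are
*retained* only if significant **and** the across-horse mean of the
pre-training intra-run CC exceeds 0.80 — an indicator that cannot
reproduce itself before training cannot evidence a training effect;
retention never adds keys beyond the significant set.

## Synthetic gait generator

The generator emulates the measurement design, not horse biomechanics:
each sensor location gets a harmonic series (5 harmonics, amplitude
ratio 0.35 between successive harmonics) of the stride frequency for
its global-frame acceleration and for small oscillations of its
attitude about a location-specific mean (trunk/head: a few degrees;
cannons: ±35° swing about the lateral axis and ±8° twist, so the
swing/twist channels are informative). Default stride frequencies are
1.4 Hz (trot) and 1.8 Hz (canter) — typical equine values. Limb
phases follow the diagonal pairing at trot and the footfall sequence of
a right-lead canter; canter adds extra harmonic-1 trunk pitch.
Orientation trajectories are composed exactly (mean attitude ∘
oscillation), angular velocity is derived from the quaternion
trajectory by central differences, and the sensor-frame acceleration is
the inverse-rotated (generating acceleration + gravity) plus white
sensor noise — so with zero noise, resolving the measured acceleration
back to the global frame and removing gravity reproduces the stored
generating signal to machine precision (asserted at 1e-9).

Realism terms, each with its default study condition:

* stride-timing jitter: Gaussian, SD 2% of the period (so the 75%
  spacing rule is non-trivially exercised);
* stride-to-stride motor variability: a smooth per-stride amplitude
  modulation (SD 5%) and per-harmonic waveform phase noise (SD 0.05
  rad), interpolated across stride onsets. Real gait never repeats to
  within sensor noise; without this term the indicator screen would
  resolve arbitrarily small procedural asymmetries (see *Calibration*);
* sensor noise: 0.5 m/s² and 0.05 rad/s white;
* per-horse traits: a log-normal amplitude factor (SD 10%) and small
  phase offsets, drawn from (seed, horse) only, so a horse keeps its
  waveform across runs and pairing is meaningful.

The sternum's vertical-acceleration harmonics carry zero phase, so the
filtered-signal peaks coincide with the generator's stride onsets and
segmentation can be scored against ground truth (stored per session
with the generating signals).

The training effect has three independent knobs applied to after-runs
only: `shape_delta` shifts the phases of harmonics h ≥ 2 by 2·δ·h rad —
a shift linear in h including h = 1 would be a pure time translation
that re-segmentation removes, so only higher harmonics are moved,
changing waveform shape (CC) while leaving the segmentation anchor
fixed; `amp_delta` scales amplitudes by 1 + δ (RMSD); and
`roughness_delta` adds 8–12 Hz band-limited content to the generating
accelerations and attitude oscillations with SD = δ × the clean
channel SD (SPARC/LDLJ). What the generator does **not** model: ground
reaction forces, a rider, soft-tissue artifact, sensor drift or
misalignment, gait irregularity beyond stationary jitter. Passing
tests therefore demonstrate the correctness and statistical behaviour
of the *pipeline*, not biomechanical validity on real horses.

## Calibration of the screen, and experiment sizes

The intra-vs-inter design has a small intrinsic bias: the reference
stride is selected as most central within the before-run group, so
before-run strides are on average slightly closer to it than
independent after-run strides, even under the null. The bias is O(1/N)
in the group's stride count and scales with the stride-to-stride
variability, while the paired test's resolution scales with the same
variability over √N — with realistic motor variability and the default
design (two 10 s passages per run, ≈ 34 strides per group) it sits
below the test's resolution, and the measured type-I rate of the screen
is ≈ 0.05–0.07 at α = 0.05 (asserted within [0.02, 0.08] over 200
seeded herds). With white sensor noise only, per-horse indicator
estimates become precise enough to resolve the bias and the screen
over-rejects; that regime is unrealistically clean, which is why motor
variability is part of the generator's default conditions.

Replicated experiments (calibration: 200 herds; power: 50 herds;
stride recovery: 50 passages) run on canter with a two-sensor subset
(sternum + left forelimb cannon) and otherwise the full design (10
horses, 2 passages × 10 s per run) — the screen's statistics are
per-key, so restricting the sensor set shrinks the experiment without
changing any key's behaviour. `scripts/acceptance.py` uses 60/30
replicates for the same two experiments; both sizes give binomial
standard errors well inside the asserted bands.

## Numerical details and degenerate inputs

* Butterworth filtering requires fs > 2 fc and a signal longer than
  3 × the filter order; SPARC requires fs > 2 fc and ≥ 8 samples;
  LDLJ ≥ 8 samples.
* PCHIP requires ≥ 4 samples per stride; endpoints are preserved and
  linear data are reproduced exactly.
* Reference-stride ties break to the lowest row index; Wilcoxon
  all-zero differences give a degenerate p = 1 flag; fewer than 5
  complete pairs is an error, and keys missing a scope are skipped with
  a warning.
* Recording containers store floats with 17 significant digits (CSV) or
  natively (HDF5), so write-then-load is bit-exact; loaders validate
  quaternion norms (tolerance 1e-6), stream lengths and location codes
  and name the offending sensor/field in errors.
* End-to-end runs are deterministic in (config, seed): RNG substreams
  are derived from (seed, horse, run, passage).

## Known limitations

* The 11/13-channel accounting treats the horizontal acceleration as a
  single planar-norm channel; other decompositions (two signed
  horizontal components) would change the count.
* The screen tests each key marginally; keys derived from the same
  strides are strongly dependent, so the *number* of significant keys
  in one herd has high variance even under the null.
* The generator's harmonic waveforms are a caricature of equine
  kinematics; absolute SPARC/LDLJ levels on synthetic data should not
  be compared with values measured on real horses.
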