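# Methods

## The assessment and what is computed

A participant steers an avatar along a predefined 30 s path on screen by
moving one **target joint**; paired accelerometers bracket every relevant
joint of the tested extremity plus the trunk. Selective voluntary motor
control (SVMC) is summarized by two interval-scaled outcomes:

* **Target-joint accuracy.** The target-joint angle is mapped to the avatar
  position `p(t) = 100·(θ(t) − aROM_min)/(aROM_max − aROM_min)`, clipped to
  [0, 100]. The score is the time average of
  `|p(t) − p*(t)| / σ_path(t)`, where `p*` is the target path and `σ_path(t)`
  is the per-timepoint SD, across a neurologically intact adult reference
  cohort, of the deviation from that same path. Standardizing per timepoint
  expresses error relative to local path difficulty: segments that are hard
  even for adults have larger σ and are penalized less.
* **Involuntary movements.** For every monitored non-target channel the angle
  trace is differentiated (deg/s) and scored as the time average of
  `|d_c(t) − μ_c(t)| / σ_c(t)` against the adult mean and SD derivative
  traces. Using the derivative means a participant who cannot assume or hold
  a prescribed starting posture is not penalized — only *changes* in posture
  count. Standardizing against the adult **mean** (not zero) avoids
  penalizing physiological co-movement (e.g. knee flexion accompanying hip
  flexion). Channel errors are averaged within joint units (both trunk
  channels → one trunk unit; flexion+rotation of one hip → one hip unit),
  and unit means are averaged with equal weight into one score. The target
  channel is always excluded.

Both outcomes are non-negative, zero only for perfect tracking / exactly
adult-mean movement, and scale-equivariant in the deviations.

## Angle estimation from paired accelerometers

Movement in this game is slow (bench measurements put movement-induced
accelerations at a few percent of g), so the accelerometer reading is treated
as the gravity direction. A sensor's inclination within a measurement plane
is the two-argument arctangent of two axis components; the default sagittal
(`xy`) convention reads 0° with the sensor y-axis anti-parallel to the
acting acceleration of a hanging limb (reading `(0, −1, 0)` g) and ±90° when
perpendicular. A joint channel is the pointwise **distal − proximal**
inclination of its sensor pair: any rotation common to both sensors — i.e.
compensatory movement of everything proximal to the joint — cancels
algebraically and cannot steer the avatar. Trunk channels pair the trunk
sensor with a virtual gravity reference (zero trace).

The per-channel pair assignments, measurement planes, steering signs,
joint-unit grouping, and range-of-motion caps live in one editable JSON
table per extremity (`svmckit/data/channels_{le,ue}.json`). The shipped
tables are the package's own reconstruction: the deployed instrument's exact
per-joint formulas are not public, so the table deliberately isolates that
uncertainty in one data file. The lower-extremity table uses 11 sensors
(trunk + upper/lower thigh, upper/lower shank, foot per side) and yields 10
channels; the upper-extremity table yields 12 channels. Upward-steering
directions for the upper extremity (which of abduction/adduction etc. maps
to "up") are not publicly specified; defaults are abduction, elbow flexion,
supination, wrist extension, finger extension, each overridable per channel
via the table's `sign`.

## Processing chain and numerical choices

1. **Resampling.** The hardware transmits at 29 Hz (~70% of the time) or
   58 Hz (~30%). All processing runs at a uniform 29 Hz — the dominant
   native rate; down-sampling the 58 Hz stretches by linear interpolation
   avoids inventing data.
2. **Ill-conditioned samples.** When the in-plane gravity component falls
   below 0.05 g the arctangent is noise-dominated; such samples are flagged,
   the series is unwrapped (period 360°), and gaps up to 0.5 s are bridged
   by linear interpolation. Longer gaps mark the channel missing for the
   session rather than failing it.
3. **Filtering.** Zero-phase (forward–backward) 2nd-order Butterworth
   low-pass, default cutoff 3 Hz: voluntary joint movement lives below
   ~3 Hz. The exact deployed filter is not public; type, order and cutoff
   are parameters so it can be swapped in.
4. **Derivative.** Central differences in the interior, one-sided at the
   ends (`numpy.gradient`); a constant trace maps to exactly 0 deg/s.
5. **Analysis window.** Of the 30 s recording the first 25 s are scored; the
   final 5 s exist to keep participants playing to the end. Both numbers are
   parameters (whether the discarded tail lies inside or after the 30 s is
   ambiguous in the source material; the conservative first-25-of-30 reading
   is the default).

## Calibration (cap, then prune)

A 10 s active-ROM recording gives raw extrema. The span is capped at the
joint's maximum — hip 45°, knee 90°, ankle 90°; shoulder 70°, elbow 110°,
forearm 135°, wrist 135°; fingers uncapped — applied symmetrically about the
measured midpoint (the least-biased truncation when only a maximum span is
specified). Then 5° are pruned off each end. A joint is **playable** iff the
remaining span reaches 20°. Pruning is specified for the lower extremity and
applied to both extremities by default (disable via `prune_deg=0`). If the
capped span cannot survive pruning, the capped bounds are retained and the
joint is flagged unplayable with a reason, keeping `arom_min < arom_max`
invariant. Unplayable joints are excluded from scoring (the CLI exits with a
machine-readable error).

## Target path

The path is a fixed shape spanning the central 90% of the calibrated range,
realized as the band [5, 95]%. The built-in waypoint set (a stand-in for the
deployed game's exact shape) reaches ≤10% and ≥90% within 30 s.
Interpolation is shape-preserving cubic Hermite (PCHIP) rather than a
natural cubic spline: PCHIP cannot overshoot its waypoints, so the generated
path provably stays inside the band — with a natural spline that invariant
would have to be enforced by clipping, which destroys smoothness. Paths are
pure functions of their inputs (same waypoints or seed → bit-identical
output).

## The normative reference

`NormativeReference.fit` estimates, from ≥2 processed adult sessions on the
identical path grid: `σ_path(t)` (SD across adults of avatar deviation,
computed on the clipped positions — the values that actually steered the
game), and per monitored channel `μ_c(t)`, `σ_c(t)` of the derivative. All
SDs use ddof=1 and are floored at `sd_floor` (default 0.5 native units:
percent for the path, deg/s for derivatives) so a near-deterministic
reference cannot produce unbounded scores. Channels enter the reference only
if present in every fitting session.

Standardization order is pointwise-then-average (each timepoint standardized
before time-averaging); an average-then-standardize variant is available via
`accuracy_score(..., method="aggregate")` for sensitivity analysis.

**Calibration identity.** If a cohort member's derivative trace is drawn
from the same per-timepoint Gaussian as the reference, its expected channel
error is `E|Z| = √(2/π) ≈ 0.798` — the built-in "unimpaired" baseline level
that the acceptance script reproduces on a 1000-adult synthetic cohort.

## Age normalization

Raw scores are z-transformed against peers: for children and patients the
peer group is the neurologically intact children whose **integer** age lies
within ±1 year of the participant's integer age (age 7.2 → peers with
integer ages 6, 7, 8); intact adults are normalized against the whole adult
group. z = (score − peer mean)/peer SD with ddof=1, so positive z = worse
than peer average. A z-score is withheld (with a reason) when fewer than 3
peers exist or the peer SD is zero.

## Missing channels

Sensor failure marks individual channels missing, not the session. The
default policy drops missing channels, averaging units over their available
members and dropping empty units. A `fail` strategy raises instead, and
externally imputed values can be supplied directly in the per-channel error
map (the published pipeline used multiple imputation on its clinical data;
re-implementing that belongs with the statistical analysis of real cohorts,
not here).

## Simulator: what it emulates, and what it does not

The simulator generates ground-truth kinematics and renders them as raw
streams:

* **Target tracking** — the inverse avatar mapping applied to the path,
  delayed by `tracking_lag_s` and perturbed by smoothed (≤2 Hz) Gaussian
  noise of SD `tracking_noise_sd` percent.
* **Mirror movements** — contralateral homologue derivative =
  `mirror_gain` × target derivative (integrated into the angle excursion).
* **Synergies** — per-channel gains coupling other joints to the target.
* **Trunk sway** — sinusoid of amplitude `trunk_sway_amp` at
  `trunk_sway_hz`, 90° phase offset between the lateral and ventral planes.
* **Tremor** — optional sinusoid added to the target channel.
* **Sensor model** — each sensor's orientation is the signed chain sum of
  proximal channel angles in the sagittal and frontal planes
  (R_z(α)·R_x(β)); the reading is gravity in that frame plus white noise.
  Default noise SD is **0.005 g**, chosen so the processed channel noise at
  constant posture (~0.19° SD) matches the instrument's bench static
  precision (0.16°); it is a parameter. Timestamps alternate 29/58 Hz
  segments with gamma-distributed durations whose means give a 0.7/0.3
  expected time split.
* **Cohort priors** (synthetic, tunable; they exercise the scorer and do not
  model populations): intact adults get minimal gains; intact children get a
  mirror gain `U(0.15, 0.6)·clip((12 − age)/6, 0, 1)` — mirror movements are
  physiological in young children and fade by roughly age 10–12 — so the
  generator carries a recoverable age effect; patients get elevated,
  heterogeneous gains on all components.

What passing tests on simulated data show: the pipeline recovers angles it
itself could have measured (quasi-static, single-plane-dominant movement),
ranks injected impairment correctly, and reproduces its statistical
identities. What they do not show: robustness to movement-induced
(centripetal/tangential) accelerations beyond the noise term, soft-tissue
artifact, sensor misplacement, magnetic or thermal drift, or realistic
multi-plane coupling of real limbs. The ground-truth impairment summary
used for recovery tests (`composite_impairment`) is the total non-target RMS
angular velocity relative to the target's — a pure kinematic quantity
independent of the scoring path.

## Problem sizes used in tests and the acceptance script

Reference cohorts of 30 simulated adults (the recruitment target of the
original reference group); dose–response means over 20 seeds per mirror
gain; parameter recovery over 50 simulated patients; the Gaussian
calibration identity on a 1000-member synthetic cohort with 50 held-out
members; sampling statistics over 600 s of timestamps. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while keeping a
full run in seconds.

## Known limitations

* The channel tables, path shape, and upper-extremity steering directions
  are reconstructions; deployments must reconcile them with the instrument's
  actual conventions (all are data-file edits, not code changes).
* The two-plane orientation model ignores cross-plane coupling beyond the
  R_z·R_x composition; large simultaneous excursions in both planes bias the
  sagittal extraction slightly (sub-degree at the amplitudes the game
  elicits).
* Scores for real cohorts require a reference database recorded with the
  same path, rate, and filter settings; references are versioned JSON and
  refuse to score mismatched grids.
* Statistical modeling of score tables (mixed models, bootstrap CIs) is out
  of scope; the tidy CSV output is designed to feed such tools directly.
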