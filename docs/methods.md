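# Methods

## Problem and model

During learning walks, a naïve *Cataglyphis* ant repeatedly turns about
its body axis (pirouettes) and, during the longest stopping phase of each
pirouette, gazes toward the nest entrance. If the gaze direction is set by
a magnetic compass, rotating the horizontal component of the geomagnetic
field (GMF) by θ should rotate the gazed-at goal to the *fictive nest*:
the nest position rotated by θ about the ant's position at the moment the
coil field switches on.

The pipeline reduces each ant to (at most) three angles — the longest-stop
gaze of one pirouette before switch-on relative to the nest, and of one
pirouette after switch-on relative to the nest and to the fictive nest —
and asks, per experiment, whether each angle sample is significantly
directed and whether its mean points at the goal (mapped to 180°).

## Conventions

- **Arena frame**: x east, y north, cm; origin at the platform center
  (nest tube exit). Azimuths clockwise from +y in [0, 360).
- **Field frame**: X toward magnetic north, Y east, Z down (µT);
  declination positive clockwise/eastward, inclination positive downward.
  The two frames share the clockwise angle convention, so an arena bearing
  is directly comparable to a declination.
- **Alteration sign**: θ > 0 rotates magnetic north eastward (clockwise
  viewed from above). `kinematics.fictive_nest` uses the same sign, so
  field rotation and goal rotation are one parameter.
- **Gaze** is the azimuth of the thorax→mandible body axis; whether the
  original analyses used a head-based axis is unknown, and the two
  digitized landmarks define the body axis exactly. Frames with coincident
  landmarks carry no axis; they are flagged and excluded from
  heading-based computations, never dropped from the track.
- **Relative gaze** `(heading − bearing(mandible→goal) + 180) mod 360`:
  the goal bearing is taken from the mandible position, matching the
  mandible→nest vector used for the fictive-nest construction.

## Coil-field design

Rotating a horizontal field of magnitude `B_H` by θ without changing its
magnitude requires a horizontal coil field forming an isosceles triangle
with the original and rotated vectors:

    B_coil = 2 · B_H · sin(|θ|/2),

directed along azimuth θ/2 + 90° (θ > 0) relative to the GMF horizontal
direction. θ = 180° gives `2·B_H` pointing south; θ = +120° gives
`2·cos 30°·B_H`. Because "coil orientation" is ambiguous between the coil
*axis* (parallel to the generated field) and the coil *frame* (the winding
plane, perpendicular to it), `CoilPlan` reports both angles to the
north–south line; for θ = +120° these are 30° (axis) and 60° (frame).

`verify_alteration` compares a measured before/after pair on four checks:
declination shift vs θ, horizontal magnitude, vertical component, and
total intensity (angle tolerance and µT tolerance supplied by the caller).
In the bundled +120° reference measurements the realized shift is 117.6°
and the horizontal magnitude grew by about 1.7 µT, so that pair passes at
(3°, 2 µT) but not at (3°, 1 µT) — tolerances must reflect realistic
field-work imperfection. The bundled after-180° row is internally
inconsistent (a positive X component alongside a ~180° displayed
declination, presumably a sensor-orientation artifact) and is not used for
numeric verification.

## Stopping-phase detection

A stopping phase is a maximal frame window in which

1. every frame's forward (thorax) speed is ≤ a threshold,
2. every heading lies within ±`gaze_tol` (default 10°) of the **window's
   circular-mean** heading, and
3. the window spans ≥ `min_duration` (default 100 ms), counting
   inter-frame spans: frames [s, e] last (e − s)/fps, so 6 frames are the
   minimum at 50 fps (5 frames = 80 ms do not qualify).

Constancy is measured against the window mean rather than frame-to-frame
increments: it bounds the total excursion around one direction, is
order-independent, and is directly checkable by brute-force enumeration —
the test suite verifies exact agreement (identical maximal windows) with
an independent all-windows oracle on random tracks. Whether the original
analyses measured constancy per-frame or against a mean is not stated;
this choice is recorded as an assumption. The forward-speed threshold is
likewise unreported; the default is 0.5 cm/s, configurable and echoed in
every output. No separate angular-speed cap is applied by default (gaze
constancy already bounds rotation); an optional cap exists.

Implementation note: within each maximal run of slow, non-degenerate
frames, candidate ends for each start are pruned by the necessary
condition that all headings of a qualifying window lie pairwise within
2×`gaze_tol`; survivors are checked exactly, and maximality is enforced by
a sweep that keeps only windows not contained in an earlier-starting,
farther-reaching qualifying window. Ties in the longest-phase choice go to
the earliest start.

## Circular statistics

- Mean direction µ = atan2(ΣsinΘ, ΣcosΘ), resultant R, mean resultant
  r = R/n. A numerically zero resultant leaves µ undefined (reported NaN).
- **Rayleigh test**: Z = n·r²,
  p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), clipped to [0, 1]. At n = 15
  the approximation reproduces 3-decimal published p-values and holds a
  4.7–5.3% empirical type-I rate (10⁴ uniform replicates, seeded).
- **95% CI for µ** (Zar's two-branch formula, χ²₁ = 3.841459):
  r ≤ 0.9: d = arccos(√(2n(2R² − nχ²₁) / (R²(4n − χ²₁))));
  r > 0.9: d = arccos(√(n² − (n² − R²)·e^{χ²₁/n}) / R).
  The interval is suppressed as unreliable when the sample is not
  significantly directed at α = 0.05 or the arccos argument leaves [0, 1]
  (low concentration). Published CIs from commercial software may use a
  different internal method, so the implementation is validated by
  coverage simulation (≈95% coverage of the true mean at n = 15, κ = 8)
  rather than against printed bounds.
- **Mardia–Watson–Wheeler**: combined sample ranked with midranks for
  ties (the original software's tie policy is unknown), uniform scores
  β = 2π·rank/N, W = 2[(C₁²+S₁²)/n₁ + (C₂²+S₂²)/n₂]. p = exp(−W/2)
  (χ², 2 df) for samples of ≥ 10 each, otherwise seeded Monte-Carlo
  permutation; Monte-Carlo agrees with exhaustive enumeration at
  n₁ = n₂ = 4. A fully tied combined sample is degenerate and reported as
  W = 0, p = 1 with a flag.
- Histograms use half-open 10° bins [k·10, (k+1)·10).

## Pipeline decisions

- "Before" pirouette = the **last** annotated pirouette ending before
  switch-on (the natural reading of an ambiguous protocol sentence);
  "after" = the first starting at/after switch-on. Both must have a mean
  mandible position ≥ 5 cm from the nest (configurable).
- The switch-on frame is the first frame with t ≥ switch-on time.
- A before/fictive control block is computed alongside the three standard
  blocks; under a real alteration it should be undirected, which makes it
  a useful simulator sanity check. It is an extension, labeled as such.
- No multiple-testing correction is applied (matching field practice for
  this design); α = 0.05 is echoed in the report.
- Ants failing any stage (no qualifying pirouette, no stop, no body axis)
  are excluded from the affected blocks with machine-readable reasons;
  block n + stage exclusions always equals the ant count.

## Synthetic data

The generator emulates the *statistical structure the analysis assumes*,
at desk scale: 50-fps tracks on a 60 × 60 cm platform, nest at center;
per ant one (configurable) pirouette per epoch at sites 8–20 cm from the
nest; coil switch-on at 6 s; tracks of roughly 300–500 frames. Each
pirouette holds one designated longest stop (240–360 ms) whose heading is
the mandible→goal bearing plus a von Mises(0, κ) error — goal = nest
before switch-on, fictive nest after — and uniform-heading decoy stops
(120–180 ms). Stop positions jitter by 0.002 cm (well under the speed
threshold); headings jitter by 0.4° SD. Between stops the heading sweeps
in 15–45° steps with a guaranteed ≥ 20° jump into and out of each stop, so
the designed stop windows are exactly the maximal constant-gaze windows —
detection recovers them frame-exactly, which the tests assert against the
emitted ground truth.

Default κ = 2.0 per epoch puts the population mean resultant near 0.70,
inside the concentration range reported for real experiments (r ≈ 0.5–0.8
at n = 15); recovery and calibration tests use κ = 8 where high
concentration is the point. All draws flow through one seeded generator;
regeneration is byte-identical.

What the simulator does **not** emulate: digitization noise and dropped
frames, body-axis vs head-axis discrepancies, path-integration drift,
inhomogeneous coil fields, or any within-pirouette structure beyond
stops-plus-sweeps. Passing recovery tests therefore show that the
*analysis chain* is correct and calibrated under its own assumptions —
not that real ants satisfy those assumptions.

A geometric property worth noting (it also holds in the field data's
favor): the angular offset between nest-relative and fictive-nest-relative
gaze equals θ only on a measure-zero set of ant positions, so fictive-goal
clustering cannot be mimicked by a simple bimodal (nest/anti-nest)
response; the suite verifies the offset ≠ θ for essentially all simulated
ants.

## Numerical choices

- Angles are canonicalized to [0, 360); wrap artifacts (−0° → 360°) are
  guarded. Internal computation is double precision; reported angles are
  rounded to 3 decimals in TSV output only.
- Declination of a purely vertical field is flagged undefined, not
  defaulted.
- Track CSV I/O uses fixed 6-decimal formatting and is lossless at that
  precision (write→read→write is byte-stable).
- Problem sizes in the test battery (random-track oracle comparisons,
  10⁴-replicate calibration, 100 replicate experiments per alteration
  angle, 50-replicate detection rate in the acceptance script) were chosen
  to give stable statistics at interactive runtimes.

## Known limitations

- The published mean directions, CI bounds and W statistics of the
  original experiments cannot be recomputed here without the deposited raw
  angle data; they are covered by identity checks (Z = n·r², p formulas)
  on constructed samples plus the property battery above. One published
  (Z, r) pair is internally inconsistent with Z = n·r² and is excluded
  from those checks.
- The heuristic pirouette detector (`kinematics.detect_pirouettes`) is a
  labeled convenience; analysis pirouettes are expected to be manual
  annotations.
- Image-to-platform scale calibration is assumed done upstream: tracks
  arrive in cm.
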