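# magwalk

Analysis pipeline for **learning-walk pirouettes under geomagnetic-field
alteration** — the behavioral assay used to test whether desert ants
(*Cataglyphis*) read a magnetic compass while calibrating their navigation
systems.

Naïve *Cataglyphis* ants perform learning walks around their nest
entrance, repeatedly turning in place (pirouettes) and stopping to gaze
back at the invisible nest hole. When a Helmholtz coil rotates the
horizontal component of the geomagnetic field (GMF) by an angle θ, a
magnetically guided ant should instead gaze at the **fictive nest** — the
nest position rotated by θ about the ant. `magwalk` implements the full
chain from digitized video tracks to that inference, for people running or
re-analyzing such experiments:

- **Field geometry** (`magwalk.fieldgeom`): conversions between component
  (X north, Y east, Z down, µT) and declination/inclination/intensity
  forms; coil design `B_coil = 2·B_H·sin(θ/2)` (θ=180° → `2·B_H`,
  θ=+120° → `2·cos 30°·B_H`); superposition and before/after verification
  against magnetometer readings.
- **Track model & kinematics** (`trackmodel`, `kinematics`): 50-fps
  mandible/thorax tracks in cm; gaze = azimuth of the thorax→mandible
  axis; relative gaze `(heading − bearing(mandible→goal) + 180) mod 360`
  so that perfect goal fixation reads 180°; fictive-nest construction by
  rotating the mandible→nest vector at coil switch-on; pirouette selection
  (last before / first after switch-on, ≥ 5 cm from the nest).
- **Stopping phases** (`stops`): maximal windows with no forward movement
  and constant gaze (±10° around the window's circular mean, ≥ 100 ms);
  the longest stop per pirouette carries the analyzed gaze direction.
- **Circular statistics** (`circstats`): mean direction µ and resultant
  length r; Rayleigh uniformity test `Z = n·r²` with
  `p = exp(√(1+4n+4(n²−R²)) − (1+2n))`; Zar's 95% CI for µ with a
  low-concentration reliability rule; Mardia–Watson–Wheeler uniform-scores
  two-sample test (`W`, χ² with 2 df or seeded permutation); 10° binning.
- **Pipeline & simulator** (`pipeline`, `synthetic`): per-ant results and
  experiment-level summaries (before/nest, after/nest, after/fictive,
  before/fictive control, before-vs-after MWW); a ground-truth generator
  of von Mises goal-directed gaze for calibration and recovery tests.

## Worked example

Simulate a 15-ant experiment with a 180° alteration and analyze it:

```sh
$ magwalk simulate --out demo/data --seed 42
wrote 15 ants to demo/data (seed=42, version=0.1.0)
$ magwalk analyze --data demo/data --out demo/out
after/fictive: n=15 r=0.717 Z=7.722 p=0.000 mu=160.9 deg
wrote demo/out/report.json and demo/out/report.tsv
```

The after-switch-on gaze directions, re-expressed relative to the fictive
nest, are significantly directed (Rayleigh Z = 7.722, p < 0.001) with mean
direction µ = 160.9°, i.e. clustered near the 180° goal mark — the
signature of magnetically guided gazing. `report.json` holds the four
summary blocks, per-ant gaze angles, 10°-bin histograms, exclusions with
reasons, and the seed/version/config echo.

Coil design for a +120° alteration of a measured GMF:

```sh
$ magwalk fieldplan --theta 120 --gmf-x 26.551 --gmf-y 0.015 --gmf-z 37.955
```

reports `b_coil = 45.988` µT (= 2·cos 30° × the 26.551 µT horizontal
component), the coil-field azimuth 150° (coil frame 60° from the
north–south line), and a predicted altered field with declination 120.03°
and unchanged horizontal magnitude and vertical component.

Quick circular summary of an angle list (one angle per line, degrees):

```sh
$ magwalk stats demo/angles.txt     # -> n=5, r=0.975, Z=4.757, p=0.0027,
                                    #    mu=179.2, 95% CI [165.1, 193.2]
```

## Layout

```
src/magwalk/        fieldgeom, trackmodel, kinematics, stops, circstats,
                    pipeline, synthetic, cli (+ bundled magnetometer fixture)
tests/              unit + property tests, oracle modules, acceptance battery
scripts/acceptance.py
docs/methods.md     model, conventions, parameter choices, limitations
```
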