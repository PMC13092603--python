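# rsaplan

Anatomy-scaled lateralization planning for reverse total shoulder
arthroplasty (rTSA), evaluated on synthetic patient cohorts.

## The problem

A reverse shoulder prosthesis swaps the joint's ball and socket: a
glenosphere is fixed to the scapula and a cup to the humerus.  The classic
(medialized) design moves the center of rotation onto the glenoid face,
which helps the deltoid but slackens the remaining posterosuperior rotator
cuff — the infraspinatus and teres minor lose tension and external rotation
suffers.  Lateralized designs push the joint line back out, typically with a
bone graft (or metal augment) between the baseplate and the eroded glenoid.

The planning question this package quantifies: **how thick should that graft
be for a given patient, and does the patient's own humeral head size (HHS)
predict it?**  The package:

1. generates synthetic pathologic shoulder anatomies (head size, glenoid
   erosion, version/inclination, humeral subluxation, diagnosis mix),
2. takes the pre-operative measurements a surgeon would (best-fit and
   osteotomy-level HHS, subluxation %, vault loss, erosion depth,
   glenoid orientation),
3. plans five implantation strategies per patient — four lateralized
   configurations differing in baseplate position and meta-epiphyseal tilt,
   plus one medialized high-mobility configuration — solving for the graft
   thickness that restores the native (premorbid) greater-tuberosity
   position, and classifying each glenoid as centered or decentered with the
   extra `(MGT - CRD) / 2` adjustment for decentered ones,
4. computes muscle–tendon lengths (deltoid, subscapularis, infraspinatus,
   teres minor) before and after implantation with a sphere-wrapping
   obstacle model, and
5. runs the cohort statistics: Friedman tests with Kendall's W across the
   five strategies, pairwise Wilcoxon signed-rank tests, Pearson
   correlations of head size against graft thickness and muscle length, and
   a small-vs-large head (47 mm osteotomy-HHS cut) group comparison.

## Worked example

Run the full pipeline on the default 83-patient cohort (seed 0):

```bash
rsaplan all --out run
```

(about 12 s; equivalently `rsaplan generate/measure/plan/muscles/stats/report`
stage by stage).  For the first patient the workup and plans are:

| quantity | P000 |
|---|---|
| best-fit HHS | 42.3 mm |
| osteotomy HHS | 40.6 mm |
| subluxation | 57.7 % |
| vault loss / erosion | 1.2 % / 1.1 mm |
| inclination / retroversion | 10.1 / 17.1 deg |

| strategy | overlap graft (mm) | centering | total lateralization (mm) |
|---|---|---|---|
| 1 centered, 135 NSA | 15.35 | decentered | 31.80 |
| 2 flush, 135 NSA | 15.03 | decentered | 31.29 |
| 3 flush, 145 NSA | 16.74 | decentered | 34.73 |
| 4 flush, 155 NSA | 18.69 | decentered | 38.61 |
| 5 medialized, 42 mm +2 ecc | 0.00 | decentered | 0.00 |

Post-operative muscle length as percent of native (neutral pose, P000):

| muscle | s1 | s2 | s3 | s4 | s5 |
|---|---|---|---|---|---|
| deltoid | 107.5 | 108.4 | 110.2 | 111.6 | 105.9 |
| infraspinatus | 100.0 | 99.8 | 99.7 | 99.6 | 82.6 |
| subscapularis | 101.0 | 100.9 | 101.3 | 101.7 | 83.8 |
| teres minor | 97.6 | 96.8 | 96.7 | 96.7 | 76.8 |

Cohort-level results from the same run (`run/report.md`, `run/stats.json`):

- Strategy choice dominates muscle length: Friedman chi2(4) = 295.5
  (infraspinatus, neutral pose), p = 1.0e-62, Kendall W = 0.89; teres minor
  W = 0.88; subscapularis W = 0.98 — all "large" concordance.
- Every patient keeps all four muscles within +/-20 % of native under the
  four lateralized strategies (100 %); no patient does under the medialized
  strategy 5 (0 %), whose posterior cuff drops to 74–84 % of native.
- Best-fit HHS predicts the overlap graft: r = 0.81 (very strong) on the
  noisy default cohort, r > 0.99 on a noiseless cohort where head size is
  the only geometric variation.
- Large heads (osteotomy HHS >= 47 mm) need a thicker median graft than
  small heads: 22.9 mm (IQR 20.5–24.3, n = 36) vs 18.2 mm
  (IQR 17.2–20.4, n = 47).

Note on graft magnitude: with this template geometry (face-centered
glenosphere, inlay cup 3 mm liner), restoring the premorbid tuberosity
takes ~15–25 mm of lateralization.  Real systems recover much of that
inside the humeral component, so clinical graft thicknesses are smaller;
all between-strategy and between-patient comparisons are unaffected by this
constant offset (see `docs/methods.md`, Limitations).

## Reproduction

Everything is seeded and byte-deterministic:

```bash
rsaplan all --out run --seed 0          # default spec, n = 83
python scripts/acceptance.py --seed 0 --out targets.json
pytest tests                            # includes the acceptance criteria
```

`targets.json` contains the configuration arithmetic
(`{"t1": 5.5, "t2": 9.5, "t3": 135, "t4": 145}` as `{"value", "n"}`
records): inferior glenosphere overhang of the 38/27 mm and 42/27 mm + 2 mm
eccentric configurations, and the effective neck-shaft angles of the 20- and
10-degree tilted stems.

A run directory contains `cohort.csv`, per-patient geometry under
`points/`, `measurements.csv`, `plans.csv`, `muscle_lengths.csv`,
`stats.json`/`stats.csv`, `report.md`, plus `config_snapshot.json` and
`run.log` recording exactly what was run.

## Package layout

- `synthetic_cohort` — seeded cohort generator and the anatomy data model
- `anatomy_geometry` — scapular frame, sphere fits, osteotomy HHS, erosion,
  subluxation, glenoid orientation
- `implant_config` — the five-strategy catalog and component placement
- `lateralization_planner` — overlap solver (closed form + bisection),
  graft profile (MGT/CRD), centering classification, full plans
- `muscle_model` — sphere-obstacle wrapping, arm poses, length changes
- `cohort_stats` — Friedman/Kendall W, Wilcoxon, Pearson, group summaries
- `io_cli` — pipeline stages, file formats, `rsaplan` command line
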