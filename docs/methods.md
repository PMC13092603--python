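# Methods

This document states the model, its assumptions, and its parameters in the
package's own terms.  All lengths are millimetres, all angles degrees.

## Coordinate frame

Every anatomy lives in (or is measured through) a canonical right-shoulder
scapular frame:

- origin: glenoid center landmark;
- +x lateral, along the Friedman line (glenoid center to trigonum
  scapulae, negated);
- +y superior, orthogonalized within the plane spanned with the inferior
  scapular angle;
- +z anterior (right-handed completion).

Left shoulders are handled by `mirror_anatomy` (an involutive z-flip).
`build_scapular_frame` raises `GeometryError` for collinear landmarks.  All
measurements are rigid-transform invariant: the frame is built from the
patient's own landmarks and everything is expressed in frame coordinates
before differencing.

## Synthetic cohort generator

`CohortSpec` defaults define the study conditions (n = 83, seed 0):

- humeral head size (HHS = best-fit diameter): 40–56, median 49;
- diagnosis mix OA / CTA / MRCT = 23 / 31 / 29, CTA gets a Hamada grade
  (>= 2 with probability 0.8);
- subluxation 24–88 % (50 % = centered), vault loss 0–54 %, posterior
  erosion 0–11 mm, inclination -15–28, retroversion 0–33;
- pathology severity is rank-correlated (0.5) and, by default, conditioned
  on diagnosis (e.g. MRCT erodes less, CTA/OA more);
- measurement noise: isotropic Gaussian, sd 0.5 on digitized points.

Anatomy is a template scaled by `s = HHS / 49`: scapular landmarks, glenoid
rim, a spherical humeral head (radius `HHS/2`) sampled over its articular
hemisphere, anatomical neck plane, greater tuberosity, shaft axis, and four
muscle origin/insertion sites (deltoid, subscapularis, infraspinatus, teres
minor).  Pathology is applied as: posterior wedge erosion hinged at the AP
midline plus a uniform recession component, and posterior head translation
`(subluxation% - 50)/100 x diameter`.

`CohortSpec.noiseless()` zeroes the noise and collapses every pathology
range to its global median while *retaining the HHS range* — head size
becomes the only geometric variation, which makes size-vs-graft
relationships exact.

## Pre-operative measurements

- `fit_sphere`: algebraic least-squares initialization refined by
  Levenberg–Marquardt on the geometric residual; `best_fit_hhs = 2r`.
- `osteotomy_hhs`: chord diameter `2 sqrt(r^2 - d^2)` of the head sphere at
  the anatomical neck plane (`GeometryError` if the plane misses the head).
- Glenoid orientation: SVD plane fit of the glenoid face; inclination and
  retroversion are the arctangents of the face normal's superior and
  posterior components against the lateral axis.
- Subluxation: posterior offset of the fitted head center, mapped to
  percent of head diameter around 50 %.
- Erosion depth / vault loss: lateral-offset difference between the
  premorbid and current glenoid surfaces on matched grids, in frame
  coordinates; vault loss is erosion over the vault depth.

## Implant model

Fixed catalog of five strategies sharing a 155-degree meta-epiphyseal stem,
27 mm baseplate (0 inclination, 5 retroversion), 3 mm liner, 19 mm
osteotomy height, and -20 humeral retroversion:

| id | baseplate | tilt | effective NSA | glenosphere | overhang |
|---|---|---|---|---|---|
| 1 | centered | 20 | 135 | 38 | 5.5 |
| 2 | flush inferior | 20 | 135 | 38 | 5.5 |
| 3 | flush inferior | 10 | 145 | 38 | 5.5 |
| 4 | flush inferior | 0 | 155 | 38 | 5.5 |
| 5 | flush inferior | 0 | 155 | 42 + 2 ecc | 9.5 |

- effective NSA = stem NSA - meta-epiphyseal tilt;
- inferior overhang = (glenosphere - baseplate)/2 + eccentric offset;
- "flush inferior" centers the plate one plate-radius (13.5) above the
  inferior rim; "centered" uses the superior/inferior rim midpoint;
- the baseplate normal is the lateral axis rotated by the plate's
  inclination and retroversion;
- the glenosphere center (center of rotation, COR) sits on the lateralized
  baseplate plane: `base + (graft + offset) n - ecc * SI`; strategy 5's COR
  is face-centered (no graft allowed, `lateralization_mode = "none"`);
- the humerus is repositioned by a pure translation that brings the cup
  center onto the COR; the cup center lies at
  `c = (1 - DRR) * R_glenosphere + liner` along the implant articular axis,
  which is the shaft axis rotated by the effective NSA and humeral
  retroversion.

## Lateralization planning

- **Overlap graft**: the graft thickness at which the implanted greater
  tuberosity returns to its premorbid lateral position.  Because the GT is
  affine in the graft, a closed form exists; `solve_overlap_bisection` is
  an independent numerical check (they agree to < 1e-6).
- **Graft profile**: the gap between the lateralized baseplate plane and
  the eroded glenoid face, sampled over the plate footprint (8-ring disk
  grid) with inverse-distance interpolation of the sampled face.  MGT is
  the maximum, CRD the negative of the central value (signed: a graft
  everywhere means CRD < 0).  Footprint samples beyond the sampled glenoid
  (true plate overhang) are skipped; an uncovered plate center raises
  `GeometryError`.
- **Centering**: centered iff subluxation in [45, 55] %, vault loss < 5 %,
  erosion < 2 mm, and not (CTA with Hamada >= 2); CTA without a Hamada
  grade is a validation error.
- **Additional lateralization** for decentered glenoids:
  `(MGT - CRD) / 2` (linear in both arguments);
  total = overlap graft + additional.

## Muscle model

Muscle paths are straight segments that wrap around one spherical obstacle
(the fitted native head pre-op; the glenosphere post-op) using the
tangent–arc closed form; a 20k-node graph-geodesic oracle in the test suite
bounds its error below 0.5 %.  Poses apply abduction (about +z), then
forward flexion (about -x), then axial rotation about the rotated shaft, to
the humeral side.  The neutral pose is fixed at 0 flexion / 0 rotation /
20 abduction; the CT pose is the identity.  Lengths are reported as percent
of the same-pose native length, with +/-10 % and +/-20 % band flags
(an operating range proxy for the muscle's force–length curve).

The muscle stage implants each lateralized strategy at its
*anatomic-overlap* graft by default (`RunConfig.muscle_lateralization =
"overlap"`); `"total"` instead implants the decentered-adjusted total.

## Statistics

- Friedman test across strategies per muscle and pose (k >= 3 required);
  Kendall's W = chi2 / (n (k - 1)), with a tie-corrected from-ranks
  variant; W classes: < 0.1 negligible, < 0.3 small, < 0.5 moderate,
  else large (boundaries go up).
- Pairwise Wilcoxon signed-rank (exact for n <= 25, zero differences
  dropped; degenerate all-zero pairs flagged; optional Holm adjustment).
- Pearson r with strength bands (|r| <= 0.3 weak, 0.5 moderate, 0.7
  strong, 0.9 very strong, else excellent; boundary to the lower band) and
  Fisher-z power.
- Group summaries split at 47 mm osteotomy HHS; medians and IQRs use
  linear-interpolation quantiles; an empty group reports `None`.

## Limitations

- **Graft magnitude scale.** With the template's face-centered glenosphere
  and inlay cup, full premorbid-tuberosity restoration needs ~15–25 mm of
  lateralization; commercial systems recover much of this within the
  humeral component, so clinical grafts are thinner.  The offset is
  constant per patient-strategy and cancels from every comparative result
  (correlations, orderings, group differences).  Related: the signed CRD
  makes the decentered adjustment approximately equal to the central graft,
  so totals roughly double the overlap value; the muscle stage therefore
  implants the overlap graft by default.
- One wrapping obstacle per muscle; no scapular or thoracic wrapping, no
  soft-tissue tension model beyond the length bands.
- Glenoid erosion is a planar wedge + uniform recession; no biconcavity.
- The generator's template is a single parametric shape; inter-patient
  shape variation beyond size, pathology and noise is not modeled.
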