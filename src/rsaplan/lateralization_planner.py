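"""Overlap-based baseplate lateralization planning.

The planning principle: superpose the pre-operative and implant-configured
humerus until the most lateral point of the greater tuberosity (GT)
coincides in the anterior view (i.e. match the medial-lateral GT
coordinate only), and read off the glenoid-side graft thickness that
achieves the overlap.  Negative values mean the baseplate must be reamed
below the native joint line rather than grafted.

Across the baseplate footprint the required graft is non-uniform whenever
the glenoid is eroded asymmetrically: the maximal graft thickness (MGT) is
the largest standoff between plate and bone, and the central reaming depth
(CRD) is the negative of the graft thickness at the plate center (CRD > 0
means the center must be reamed).  Shoulders are classified as centered
when subluxation lies in [45, 55] %, vault loss < 5 % and erosion < 2 mm;
cuff-tear-arthropathy shoulders with Hamada grade >= 2 and osteoarthritic
shoulders with > 2 mm erosion are decentered.  Decentered shoulders
receive additional lateralization (MGT - CRD) / 2 on top of the overlap
graft; centered shoulders take the overlap graft directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import GeometryError, RsaPlanError, ValidationError
from .synthetic_cohort import PatientAnatomy, _disk_grid
from .anatomy_geometry import MeasurementSet, build_scapular_frame, measure_all
from .implant_config import ImplantConfiguration, place_baseplate, place_glenosphere_and_humerus


@dataclass
class LateralizationPlan:
    strategy_id: int
    overlap_graft_mm: float
    max_graft_thickness_mm: float
    central_reaming_depth_mm: float   # = -central graft thickness
    centering_class: str              # {centered, decentered}
    additional_lateralization_mm: float
    total_lateralization_mm: float


def _post_gt_ml(anatomy: PatientAnatomy, config: ImplantConfiguration, g: float,
                ml: np.ndarray, origin: np.ndarray) -> float:
    placement = place_glenosphere_and_humerus(anatomy, config, lateralization_mm=g)
    gt_post = anatomy.greater_tuberosity_point + placement.humeral_translation
    return float((gt_post - origin) @ ml)


def solve_overlap_lateralization(anatomy: PatientAnatomy, config: ImplantConfiguration,
                                 native_reference: str = "premorbid") -> float:
    """Graft thickness g such that the post-implant GT medial-lateral
    coordinate equals the native one.  ``native_reference`` selects the
    erosion-corrected premorbid GT (default) or the current pathologic GT.

    The GT response to g is affine (slope = lateral component of the
    baseplate normal), so the solve is closed-form; see
    :func:`solve_overlap_bisection` for the independent slow route.
    """
    if config.lateralization_mode == "none":
        return 0.0
    frame = build_scapular_frame(anatomy.scapular_landmarks)
    ml, origin = frame.medial_lateral_axis, frame.origin
    if native_reference == "premorbid":
        target = float((anatomy.premorbid_gt_point - origin) @ ml)
    elif native_reference == "current":
        target = float((anatomy.greater_tuberosity_point - origin) @ ml)
    else:
        raise ValidationError(f"unknown native_reference: {native_reference}")
    f0 = _post_gt_ml(anatomy, config, 0.0, ml, origin)
    f1 = _post_gt_ml(anatomy, config, 1.0, ml, origin)
    slope = f1 - f0
    if slope <= 1e-9:
        raise RsaPlanError("non-monotone GT response to lateralization (internal inconsistency)")
    return (target - f0) / slope


def solve_overlap_bisection(anatomy: PatientAnatomy, config: ImplantConfiguration,
                            native_reference: str = "premorbid",
                            lo: float = -60.0, hi: float = 60.0, tol: float = 1e-9) -> float:
    """Bisection fallback for the overlap solve (dual-route verification)."""
    if config.lateralization_mode == "none":
        return 0.0
    frame = build_scapular_frame(anatomy.scapular_landmarks)
    ml, origin = frame.medial_lateral_axis, frame.origin
    target = float(((anatomy.premorbid_gt_point if native_reference == "premorbid"
                     else anatomy.greater_tuberosity_point) - origin) @ ml)
    f = lambda g: _post_gt_ml(anatomy, config, g, ml, origin) - target
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise GeometryError("bisection bracket does not contain the overlap solution")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def graft_profile(anatomy: PatientAnatomy, config: ImplantConfiguration,
                  overlap_graft_mm: float, n_rings: int = 8) -> tuple:
    """(MGT_mm, CRD_mm): graft thickness between the lateralized baseplate
    plane and the eroded glenoid face, evaluated over the baseplate
    footprint.  MGT is the maximum, CRD the negative of the central value.

    Footprint samples beyond the sampled glenoid coverage (a plate can
    genuinely overhang a small glenoid) are skipped; the plate center must
    be covered.
    """
    placement = place_baseplate(anatomy, config)
    n = placement.baseplate_normal
    plane_pt = placement.baseplate_center + overlap_graft_mm * n
    frame = build_scapular_frame(anatomy.scapular_landmarks)
    v1 = frame.superior_inferior_axis - (frame.superior_inferior_axis @ n) * n
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(n, v1)

    surf = np.asarray(anatomy.glenoid_surface.points, dtype=float)
    # local (y, z) chart of the face in frame coordinates for interpolation
    fc = frame.to_frame_coords(surf)
    cover_y = (fc[:, 1].min(), fc[:, 1].max())
    cover_z = (fc[:, 2].min(), fc[:, 2].max())

    def surface_x(yq: float, zq: float) -> Optional[float]:
        tol = 0.75  # mm beyond sampled extent treated as uncovered
        if not (cover_y[0] - tol <= yq <= cover_y[1] + tol
                and cover_z[0] - tol <= zq <= cover_z[1] + tol):
            return None
        d2 = (fc[:, 1] - yq) ** 2 + (fc[:, 2] - zq) ** 2
        k = min(6, len(fc))
        idx = np.argpartition(d2, k - 1)[:k]
        w = 1.0 / (d2[idx] + 1e-12)
        return float(np.sum(fc[idx, 0] * w) / np.sum(w))

    r_bp = config.baseplate_diameter_mm / 2.0
    samples = _disk_grid(n_rings) * r_bp
    thicknesses, central = [], None
    for a, b in samples:
        q = plane_pt + a * v1 + b * v2
        qf = frame.to_frame_coords(q)[0]
        t = 0.0
        ok = True
        for _ in range(3):  # fixed-point ray cast along -n (n is near-lateral)
            foot = frame.to_frame_coords(q - t * n)[0]
            sx = surface_x(foot[1], foot[2])
            if sx is None:
                ok = False
                break
            t = (qf[0] - sx) / float(n @ frame.medial_lateral_axis)
        if not ok:
            continue
        thicknesses.append(t)
        if a == 0.0 and b == 0.0:
            central = t
    if central is None or not thicknesses:
        raise GeometryError("baseplate footprint lies outside the glenoid surface coverage")
    return float(np.max(thicknesses)), float(-central)


def classify_centering(measurements: MeasurementSet, diagnosis: str,
                       hamada_grade: Optional[int]) -> str:
    """'centered' or 'decentered' per the subluxation / vault-loss /
    erosion / Hamada rule (band [45, 55] inclusive, < and > strict)."""
    if diagnosis == "CTA" and hamada_grade is None:
        raise ValidationError("CTA shoulders require a Hamada grade for centering classification")
    centered = (45.0 <= measurements.humeral_subluxation_pct <= 55.0
                and measurements.vault_loss_pct < 5.0
                and measurements.erosion_depth_mm < 2.0)
    if diagnosis == "CTA" and hamada_grade is not None and hamada_grade >= 2:
        centered = False
    if diagnosis == "OA" and measurements.erosion_depth_mm > 2.0:
        centered = False
    return "centered" if centered else "decentered"


def additional_lateralization(mgt_mm: float, crd_mm: float) -> float:
    """Extra lateralization for decentered shoulders: (MGT - CRD) / 2,
    with CRD signed (positive = central reaming required)."""
    return (mgt_mm - crd_mm) / 2.0


def plan(anatomy: PatientAnatomy, config: ImplantConfiguration,
         measurements: Optional[MeasurementSet] = None,
         measure_fn: Callable = measure_all) -> LateralizationPlan:
    """Run the full planning chain: overlap solve -> graft profile ->
    centering classification -> conditional additional lateralization.

    Strategies without lateralization (the medialized Grammont) return a
    plan with every lateralization field at zero, class still recorded.
    """
    if measurements is None:
        measurements = measure_fn(anatomy)
    centering = classify_centering(measurements, anatomy.diagnosis, anatomy.hamada_grade)
    if config.lateralization_mode == "none":
        return LateralizationPlan(config.strategy_id, 0.0, 0.0, 0.0, centering, 0.0, 0.0)
    g = solve_overlap_lateralization(anatomy, config)
    mgt, crd = graft_profile(anatomy, config, g)
    extra = additional_lateralization(mgt, crd) if centering == "decentered" else 0.0
    return LateralizationPlan(
        strategy_id=config.strategy_id,
        overlap_graft_mm=g,
        max_graft_thickness_mm=mgt,
        central_reaming_depth_mm=crd,
        centering_class=centering,
        additional_lateralization_mm=extra,
        total_lateralization_mm=g + extra,
    )
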