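"""Scapular coordinate frame and pre-operative anatomical measurements.

Implements the standard 3D glenohumeral workup used for arthroplasty
planning: a Friedman-line scapular frame, least-squares sphere fit of the
native articular surface (best-fit humeral head size, BFHHS), the head
diameter at the anatomical-neck osteotomy plane, glenoid version and
inclination, posterior humeral subluxation, and erosion / vault-loss
quantification against a premorbid reference surface.

Sign conventions (canonical right-shoulder frame): retroversion positive
posterior, inclination positive superior, subluxation 50 % = centered with
larger values posterior.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._geom import unit
from .errors import GeometryError
from .synthetic_cohort import GlenoidSurface, PatientAnatomy


@dataclass
class ScapularFrame:
    origin: np.ndarray
    medial_lateral_axis: np.ndarray   # Friedman line, pointing lateral
    superior_inferior_axis: np.ndarray
    scapular_plane_normal: np.ndarray  # anterior positive

    def to_frame_coords(self, points: np.ndarray) -> np.ndarray:
        R = np.stack([self.medial_lateral_axis, self.superior_inferior_axis,
                      self.scapular_plane_normal])
        return (np.atleast_2d(points) - self.origin) @ R.T


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float

    @property
    def best_fit_hhs(self) -> float:
        return 2.0 * self.radius


@dataclass
class MeasurementSet:
    glenoid_inclination_deg: float
    glenoid_retroversion_deg: float
    humeral_subluxation_pct: float
    vault_loss_pct: float
    erosion_depth_mm: float
    best_fit_hhs_mm: float
    osteotomy_hhs_mm: float


def build_scapular_frame(landmarks: dict) -> ScapularFrame:
    """Construct the scapular frame from the trigonum, inferior angle and
    glenoid center.  The medial-lateral axis runs along the Friedman line
    (trigonum -> glenoid center); the plane normal points anterior for a
    right shoulder in the canonical convention."""
    tri = np.asarray(landmarks["trigonum"], dtype=float)
    inf = np.asarray(landmarks["inferior_angle"], dtype=float)
    gc = np.asarray(landmarks["glenoid_center"], dtype=float)
    ml_vec = gc - tri
    cross = np.cross(inf - tri, gc - tri)
    if np.linalg.norm(cross) < 1e-9 * max(np.linalg.norm(ml_vec), 1.0):
        raise GeometryError("scapular landmarks are collinear or degenerate")
    ml = unit(ml_vec)
    normal = unit(cross)
    si = np.cross(normal, ml)
    return ScapularFrame(origin=gc, medial_lateral_axis=ml,
                         superior_inferior_axis=si, scapular_plane_normal=normal)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------
def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere: algebraic (linear) fit followed by geometric
    refinement of sum((|p - c| - r)^2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise GeometryError("sphere fit needs at least 4 points in 3D")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts ** 2, axis=1)
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 4:
        raise GeometryError("points are coplanar or otherwise degenerate for a sphere fit")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))
    if r0 <= 0:
        raise GeometryError("degenerate sphere fit (non-positive radius)")

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    out = optimize.least_squares(resid, np.append(c0, r0), method="lm", xtol=1e-14, ftol=1e-14)
    c, r = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return SphereFit(center=c, radius=r, rms_residual=rms)


def osteotomy_hhs(points: np.ndarray, neck_plane: tuple) -> float:
    """Diameter of the circle where the anatomical-neck plane cuts the
    best-fit head sphere: 2 sqrt(r^2 - d^2) with d the center-plane distance."""
    fit = fit_sphere(points)
    plane_pt, plane_n = (np.asarray(v, dtype=float) for v in neck_plane)
    d = abs(float((fit.center - plane_pt) @ unit(plane_n)))
    if d >= fit.radius:
        raise GeometryError(f"osteotomy plane misses the fitted sphere (d={d:.2f} >= r={fit.radius:.2f})")
    return 2.0 * float(np.sqrt(fit.radius ** 2 - d ** 2))


# ---------------------------------------------------------------------------
# glenoid and humeral measurements
# ---------------------------------------------------------------------------
def measure_glenoid_orientation(frame: ScapularFrame, glenoid_points: np.ndarray) -> tuple:
    """Best-fit plane orientation of the glenoid face, reported as
    (inclination_deg, retroversion_deg); 0/0 = normal along the ML axis."""
    pts = np.asarray(glenoid_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise GeometryError("glenoid orientation needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise GeometryError("glenoid points are collinear")
    n = vt[2]
    if n @ frame.medial_lateral_axis < 0:
        n = -n
    nx = float(n @ frame.medial_lateral_axis)
    ny = float(n @ frame.superior_inferior_axis)
    nz = float(n @ frame.scapular_plane_normal)
    inclination = float(np.degrees(np.arctan2(ny, nx)))
    retroversion = float(np.degrees(np.arctan2(-nz, nx)))
    return inclination, retroversion


def measure_subluxation(frame: ScapularFrame, head_fit: SphereFit) -> float:
    """Percentage of the head diameter lying posterior to the scapular
    plane through the glenoid center; 50 % = centered."""
    d_ant = float((head_fit.center - frame.origin) @ frame.scapular_plane_normal)
    pct = 50.0 + 100.0 * (-d_ant) / head_fit.best_fit_hhs
    return float(np.clip(pct, 0.0, 100.0))


def measure_erosion_and_vault_loss(premorbid: GlenoidSurface, current: GlenoidSurface) -> tuple:
    """(erosion_mm, vault_loss_pct): maximal and mean medial recession of
    the current vs. premorbid face along the ML axis, the latter as a
    percentage of the premorbid vault depth.  Requires matched surfaces
    sampled at the same transverse (y, z) locations."""
    pre = np.asarray(premorbid.points, dtype=float)
    cur = np.asarray(current.points, dtype=float)
    if pre.shape != cur.shape:
        raise GeometryError("premorbid and current glenoid surfaces have mismatched sampling")
    if not np.allclose(pre[:, 1:], cur[:, 1:], atol=1e-6):
        raise GeometryError("glenoid surfaces are not expressed in the same frame/grid")
    recession = np.clip(pre[:, 0] - cur[:, 0], 0.0, None)
    erosion = float(recession.max())
    vault_loss = float(recession.mean()) / premorbid.vault_depth_mm * 100.0
    return erosion, vault_loss


def measure_all(anatomy: PatientAnatomy) -> MeasurementSet:
    """Full pre-operative workup of one anatomy (current, pathologic state)."""
    frame = build_scapular_frame(anatomy.scapular_landmarks)
    fit = fit_sphere(anatomy.humeral_head_points)
    inc, retro = measure_glenoid_orientation(frame, anatomy.glenoid_surface.points)
    # difference the surfaces in the patient's own scapular frame so the
    # workup is invariant under rigid transforms of the whole anatomy
    pre = anatomy.true_pathology.premorbid_glenoid
    cur = anatomy.glenoid_surface
    erosion, vault = measure_erosion_and_vault_loss(
        GlenoidSurface(frame.to_frame_coords(pre.points), pre.vault_depth_mm),
        GlenoidSurface(frame.to_frame_coords(cur.points), cur.vault_depth_mm))
    return MeasurementSet(
        glenoid_inclination_deg=inc,
        glenoid_retroversion_deg=retro,
        humeral_subluxation_pct=measure_subluxation(frame, fit),
        vault_loss_pct=vault,
        erosion_depth_mm=erosion,
        best_fit_hhs_mm=fit.best_fit_hhs,
        osteotomy_hhs_mm=osteotomy_hhs(anatomy.humeral_head_points, anatomy.anatomical_neck_plane),
    )
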