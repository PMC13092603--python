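"""Muscle-tendon paths by sphere-obstacle wrapping.

Each muscle-tendon unit (middle deltoid, infraspinatus, teres minor,
subscapularis) is modeled as the shortest path from a scapula-fixed origin
to a humerus-fixed insertion that does not penetrate the joint obstacle:
the native humeral head sphere pre-operatively, or the glenosphere/liner
construct after implantation.  For a single convex sphere the shortest
path is the classic tangent - great-circle arc - tangent construction in
the plane spanned by the two endpoints and the sphere center; length is
the sum of the straight tangent segments and the arc.

Poses are applied as rigid rotations of the humerus about the current
center of rotation (native head center, or glenosphere center), in the
order abduction (about the anterior axis), forward flexion (about the
lateral axis), then axial rotation (about the resulting shaft direction).
The synthetic cohort is generated in its acquisition pose, which serves as
the 0/0/0 reference; the standardized neutral position is 0 deg flexion,
0 deg rotation, 20 deg abduction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geom import X_LATERAL, Z_ANTERIOR, rotation_about_axis, unit
from .errors import GeometryError, ValidationError
from .synthetic_cohort import MUSCLES, PatientAnatomy
from .anatomy_geometry import fit_sphere
from .implant_config import ImplantConfiguration, ImplantPlacement


@dataclass(frozen=True)
class SphereObstacle:
    center: np.ndarray
    radius: float
    name: str = "obstacle"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError(f"obstacle {self.name} must have positive radius")


@dataclass(frozen=True)
class MuscleDefinition:
    name: str
    origin: np.ndarray
    insertion: np.ndarray
    obstacle_set: tuple  # ordered SphereObstacles

    def __post_init__(self):
        if np.allclose(self.origin, self.insertion):
            raise ValidationError(f"muscle {self.name}: origin equals insertion")


@dataclass(frozen=True)
class ArmPose:
    forward_flexion_deg: float = 0.0
    rotation_deg: float = 0.0       # external positive
    abduction_deg: float = 0.0
    pose_label: str = "ct_pose"

    def __post_init__(self):
        angles = (self.forward_flexion_deg, self.rotation_deg, self.abduction_deg)
        if self.pose_label == "neutral" and angles != (0.0, 0.0, 20.0):
            raise ValidationError("the neutral pose is exactly 0/0/20 deg")


CT_POSE = ArmPose(0.0, 0.0, 0.0, "ct_pose")
NEUTRAL_POSE = ArmPose(0.0, 0.0, 20.0, "neutral")


@dataclass
class MusclePath:
    waypoints: np.ndarray
    length_mm: float
    wrapped: list = field(default_factory=list)  # one flag per obstacle


# ---------------------------------------------------------------------------
# single-sphere shortest-path wrapping
# ---------------------------------------------------------------------------
def _wrap_segment(p: np.ndarray, q: np.ndarray, obs: SphereObstacle,
                  arc_step_deg: float = 5.0):
    """Shortest obstacle-avoiding route for one straight segment.

    Returns (waypoints list excluding p, segment length, wrapped flag).
    """
    c, r = obs.center, obs.radius
    vp, vq = p - c, q - c
    dp, dq = np.linalg.norm(vp), np.linalg.norm(vq)
    chord = q - p
    chord_len = float(np.linalg.norm(chord))

    # distance from sphere center to the *segment*
    t = float(np.clip((c - p) @ chord / chord_len ** 2, 0.0, 1.0))
    if np.linalg.norm(p + t * chord - c) >= r - 1e-12:
        return [q], chord_len, False

    gamma = float(np.arccos(np.clip(vp @ vq / (dp * dq), -1.0, 1.0)))
    alpha_p = float(np.arccos(np.clip(r / dp, -1.0, 1.0)))
    alpha_q = float(np.arccos(np.clip(r / dq, -1.0, 1.0)))
    phi = gamma - alpha_p - alpha_q
    if phi <= 0.0:  # tangent lines clear the sphere after all
        return [q], chord_len, False

    e1 = vp / dp
    perp = vq - (vq @ e1) * e1
    if np.linalg.norm(perp) < 1e-9:  # p, c, q collinear: pick a deterministic plane
        seed = X_LATERAL if abs(e1 @ X_LATERAL) < 0.9 else Z_ANTERIOR
        perp = seed - (seed @ e1) * e1
    e2 = unit(perp)

    def on_circle(angle_from_p: float) -> np.ndarray:
        return c + r * (np.cos(angle_from_p) * e1 + np.sin(angle_from_p) * e2)

    a0 = alpha_p                  # tangent point leaving p
    a1 = gamma - alpha_q          # tangent point reaching q
    n_arc = max(2, int(np.ceil(np.degrees(phi) / arc_step_deg)) + 1)
    arc_pts = [on_circle(a) for a in np.linspace(a0, a1, n_arc)]
    length = float(np.sqrt(dp ** 2 - r ** 2) + np.sqrt(dq ** 2 - r ** 2) + r * phi)
    return arc_pts + [q], length, True


def wrap_path(origin: np.ndarray, insertion: np.ndarray,
              obstacles: Sequence[SphereObstacle]) -> MusclePath:
    """Shortest origin-to-insertion path not penetrating any obstacle,
    obstacles processed in the given anatomical order."""
    origin = np.asarray(origin, dtype=float)
    insertion = np.asarray(insertion, dtype=float)
    for obs in obstacles:
        for label, pt in (("origin", origin), ("insertion", insertion)):
            if np.linalg.norm(pt - obs.center) <= obs.radius - 1e-9:
                raise GeometryError(f"{label} lies inside obstacle '{obs.name}'")
    waypoints = [origin, insertion]
    lengths = [float(np.linalg.norm(insertion - origin))]
    wrapped_flags = []
    for obs in obstacles:
        new_wp, new_len, hit = [waypoints[0]], [], False
        for i in range(len(waypoints) - 1):
            seg_wp, seg_len, seg_hit = _wrap_segment(waypoints[i], waypoints[i + 1], obs)
            new_wp.extend(seg_wp)
            new_len.append(seg_len)
            hit = hit or seg_hit
        waypoints, lengths = new_wp, new_len
        wrapped_flags.append(hit)
    return MusclePath(waypoints=np.asarray(waypoints),
                      length_mm=float(np.sum(lengths)), wrapped=wrapped_flags)


# ---------------------------------------------------------------------------
# anatomy-level muscle lengths
# ---------------------------------------------------------------------------
def pose_rotation(pose: ArmPose) -> np.ndarray:
    """Humeral rotation matrix for a pose, applied about the current center
    of rotation.  Order: abduction, forward flexion, axial rotation."""
    R = rotation_about_axis(Z_ANTERIOR, pose.abduction_deg)
    R = rotation_about_axis(-X_LATERAL, pose.forward_flexion_deg) @ R
    shaft = R @ np.array([0.0, -1.0, 0.0])
    R = rotation_about_axis(-shaft, pose.rotation_deg) @ R
    return R


def joint_obstacle(anatomy: PatientAnatomy,
                   placement: Optional[ImplantPlacement] = None,
                   config: Optional[ImplantConfiguration] = None) -> SphereObstacle:
    """The wrapping obstacle for the joint state: fitted native head sphere
    pre-operatively, glenosphere post-operatively."""
    if placement is None:
        fit = fit_sphere(anatomy.humeral_head_points)
        return SphereObstacle(fit.center, fit.radius, "native head")
    if config is None:
        raise ValidationError("post-operative obstacle needs the implant configuration")
    return SphereObstacle(placement.glenosphere_center,
                          config.glenosphere_diameter_mm / 2.0, "glenosphere")


def muscle_lengths(anatomy: PatientAnatomy, pose: ArmPose = CT_POSE,
                   placement: Optional[ImplantPlacement] = None,
                   config: Optional[ImplantConfiguration] = None) -> dict:
    """Per-muscle wrapped path lengths (mm) for one joint state and pose.

    Scapula-fixed origins stay put; humerus-fixed insertions receive the
    implant translation (post-op) and the pose rotation about the current
    center of rotation.
    """
    obstacle = joint_obstacle(anatomy, placement, config)
    cor = obstacle.center
    R = pose_rotation(pose)
    out = {}
    for name in MUSCLES:
        origin = np.asarray(anatomy.muscle_sites[name]["origin"], dtype=float)
        insertion = np.asarray(anatomy.muscle_sites[name]["insertion"], dtype=float)
        if placement is not None:
            insertion = insertion + placement.humeral_translation
        insertion = cor + R @ (insertion - cor)
        out[name] = wrap_path(origin, insertion, [obstacle])
    return out


def percent_change(native_len: float, postop_len: float) -> float:
    """Post-operative length as a percentage of the native length
    (100 % = unchanged)."""
    if native_len <= 0:
        raise ValidationError("native muscle length must be positive")
    return 100.0 * postop_len / native_len


def blix_band_check(percents: dict, band_halfwidth_pct: float) -> dict:
    """Flag each muscle as inside the functional band
    100 +/- band_halfwidth_pct (e.g. 10 or 20)."""
    if band_halfwidth_pct <= 0:
        raise ValidationError("band halfwidth must be positive")
    return {name: abs(p - 100.0) <= band_halfwidth_pct for name, p in percents.items()}
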