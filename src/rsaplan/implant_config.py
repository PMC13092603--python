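"""Implant strategy catalog and component placement.

Five reverse-shoulder implantation strategies are modeled with a single
modular meta-epiphyseal (155 deg) stemless inlay system, so that only the
neck-shaft angle (via medial implant tilt), the baseplate height (centered
vs. flush-inferior) and the lateralization philosophy vary:

1. classic Frankle-type     135 deg, centered baseplate, overlap-lateralized
2. hybrid Frankle-type      135 deg, flush baseplate, overlap-lateralized
3. hybrid                   145 deg, flush baseplate, overlap-lateralized
4. lateralized Grammont     155 deg, flush baseplate, overlap-lateralized
5. classic Grammont         155 deg, flush baseplate, 42 mm + 2 mm eccentric
                            glenosphere, high-mobility liner, no lateralization

Strategies 1-4 use a 27 mm baseplate with a concentric 38 mm glenosphere
(inferior overhang 5.5 mm); strategy 5 uses the 42 mm + 2 mm eccentric
glenosphere (overhang 9.5 mm).  All baseplates are implanted at 0 deg
inclination / 5 deg retroversion in the Friedman-based scapular frame.
Liner stability ratio and depth-radius ratio are carried as catalog
constants; liner thickness is fixed at 3 mm.

The humeral component is positioned per the CT-pose convention: the native
bone orientation is preserved and the implant stack-up only translates the
humerus so its liner cup is concentric with the glenosphere.  The cup
center sits along the implant articular axis (oriented by the effective
NSA and -20 deg humeral retroversion about the shaft axis) at
(1 - DRR) * glenosphere_radius + liner_thickness from the metaphyseal cut,
which is taken at the anatomical neck (nominal osteotomy height 19 +/- 2 mm).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._geom import rotation_about_axis, unit
from .errors import GeometryError, ValidationError
from .synthetic_cohort import PatientAnatomy
from .anatomy_geometry import build_scapular_frame


@dataclass(frozen=True)
class ImplantConfiguration:
    strategy_id: int
    name: str
    meta_epiphyseal_nsa_deg: float = 155.0
    meta_epiphyseal_tilt_deg: float = 0.0
    liner_type: str = "standard"            # {standard, high_mobility}
    liner_thickness_mm: float = 3.0
    liner_stability_ratio_pct: str = "147"  # catalog metadata (strings allow "<147")
    depth_radius_ratio: str = "0.44"
    baseplate_diameter_mm: float = 27.0
    baseplate_position: str = "centered"    # {centered, flush_inferior}
    baseplate_inclination_deg: float = 0.0
    baseplate_retroversion_deg: float = 5.0
    glenosphere_diameter_mm: float = 38.0
    eccentric_offset_mm: float = 0.0        # inferior
    lateralization_mode: str = "overlap_based"  # {overlap_based, none}
    humeral_osteotomy_height_mm: float = 19.0   # nominal, +/- 2 mm
    humeral_retroversion_deg: float = -20.0
    glenosphere_center_offset_mm: float = 0.0   # sphere center vs. baseplate face

    def __post_init__(self):
        if self.glenosphere_diameter_mm < self.baseplate_diameter_mm:
            raise ValidationError("glenosphere cannot be smaller than the baseplate")
        if not (0.0 <= self.meta_epiphyseal_tilt_deg <= self.meta_epiphyseal_nsa_deg):
            raise ValidationError("meta-epiphyseal tilt must lie in [0, NSA]")
        if abs(self.humeral_osteotomy_height_mm - 19.0) > 2.0:
            raise ValidationError("humeral osteotomy height outside the 19 +/- 2 mm window")

    @property
    def effective_nsa_deg(self) -> float:
        return effective_nsa(self.meta_epiphyseal_nsa_deg, self.meta_epiphyseal_tilt_deg)

    @property
    def inferior_overhang_mm(self) -> float:
        return inferior_overhang(self.glenosphere_diameter_mm,
                                 self.baseplate_diameter_mm, self.eccentric_offset_mm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effective_nsa_deg"] = self.effective_nsa_deg
        d["inferior_overhang_mm"] = self.inferior_overhang_mm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ImplantConfiguration":
        d = {k: v for k, v in d.items() if k not in ("effective_nsa_deg", "inferior_overhang_mm")}
        return cls(**d)


@dataclass
class ImplantPlacement:
    baseplate_center: np.ndarray
    baseplate_normal: np.ndarray
    glenosphere_center: np.ndarray          # center of rotation
    humeral_translation: np.ndarray         # native -> post-implant (CT-pose convention)
    inferior_overhang_mm: float

    @property
    def humeral_transform(self) -> np.ndarray:
        """4x4 rigid transform mapping native humerus coordinates to the
        post-implant position (pure translation under the CT-pose convention)."""
        T = np.eye(4)
        T[:3, 3] = self.humeral_translation
        return T


def effective_nsa(meta_nsa_deg: float, tilt_deg: float) -> float:
    """Effective neck-shaft angle: meta-epiphyseal NSA minus medial tilt."""
    if tilt_deg < 0:
        raise ValidationError("medial tilt must be non-negative")
    if tilt_deg > meta_nsa_deg:
        raise ValidationError("medial tilt cannot exceed the meta-epiphyseal NSA")
    return meta_nsa_deg - tilt_deg


def inferior_overhang(glenosphere_d_mm: float, baseplate_d_mm: float, eccentric_mm: float) -> float:
    """Inferior glenosphere overhang beyond the baseplate rim."""
    if glenosphere_d_mm < baseplate_d_mm:
        raise ValidationError("glenosphere cannot be smaller than the baseplate")
    if eccentric_mm < 0:
        raise ValidationError("eccentric offset must be non-negative")
    return (glenosphere_d_mm - baseplate_d_mm) / 2.0 + eccentric_mm


def strategy_catalog() -> list:
    """The five built-in implantation strategies."""
    return [
        ImplantConfiguration(1, "classic Frankle-type 135 centered",
                             meta_epiphyseal_tilt_deg=20.0, baseplate_position="centered"),
        ImplantConfiguration(2, "hybrid Frankle-type 135 flush",
                             meta_epiphyseal_tilt_deg=20.0, baseplate_position="flush_inferior"),
        ImplantConfiguration(3, "hybrid 145 flush",
                             meta_epiphyseal_tilt_deg=10.0, baseplate_position="flush_inferior"),
        ImplantConfiguration(4, "lateralized Grammont 155 flush",
                             meta_epiphyseal_tilt_deg=0.0, baseplate_position="flush_inferior"),
        ImplantConfiguration(5, "classic Grammont 155 medialized flush",
                             meta_epiphyseal_tilt_deg=0.0, baseplate_position="flush_inferior",
                             liner_type="high_mobility", liner_stability_ratio_pct="<147",
                             depth_radius_ratio="<0.45", glenosphere_diameter_mm=42.0,
                             eccentric_offset_mm=2.0, lateralization_mode="none"),
    ]


def catalog_to_json(configs=None) -> str:
    configs = strategy_catalog() if configs is None else configs
    return json.dumps({"version": 1, "strategies": [c.to_dict() for c in configs]},
                      indent=2, sort_keys=True)


def catalog_from_json(text: str) -> list:
    data = json.loads(text)
    return [ImplantConfiguration.from_dict(d) for d in data["strategies"]]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------
def _surface_x_at(points: np.ndarray, y: float, z: float) -> float:
    """ML coordinate of the glenoid face at transverse location (y, z),
    by inverse-distance interpolation of the sampled surface."""
    pts = np.asarray(points, dtype=float)
    d2 = (pts[:, 1] - y) ** 2 + (pts[:, 2] - z) ** 2
    i = np.argmin(d2)
    if d2[i] < 1e-12:
        return float(pts[i, 0])
    w = 1.0 / (d2 + 1e-12)
    k = min(6, len(pts))
    idx = np.argpartition(d2, k - 1)[:k]
    return float(np.sum(pts[idx, 0] * w[idx]) / np.sum(w[idx]))


def place_baseplate(anatomy: PatientAnatomy, config: ImplantConfiguration) -> ImplantPlacement:
    """Position the baseplate on the (current, eroded) glenoid face.

    Superior-inferior: midpoint of the highest and lowest glenoid points
    (centered) or with the plate's inferior edge on the inferior rim
    (flush_inferior).  Antero-posterior: midpoint of the most anterior and
    most posterior points.  Orientation: 0 deg inclination / 5 deg
    retroversion in the scapular frame.
    """
    lm = anatomy.scapular_landmarks
    for key in ("superior_rim", "inferior_rim", "anterior_rim", "posterior_rim"):
        if key not in lm:
            raise GeometryError(f"missing glenoid rim landmark: {key}")
    frame = build_scapular_frame(lm)
    si, ml, ant = frame.superior_inferior_axis, frame.medial_lateral_axis, frame.scapular_plane_normal

    y_sup = float(lm["superior_rim"] @ si)
    y_inf = float(lm["inferior_rim"] @ si)
    if config.baseplate_position == "centered":
        y_bp = 0.5 * (y_sup + y_inf)
    elif config.baseplate_position == "flush_inferior":
        y_bp = y_inf + config.baseplate_diameter_mm / 2.0
    else:
        raise ValidationError(f"unknown baseplate_position: {config.baseplate_position}")
    z_bp = 0.5 * (float(lm["anterior_rim"] @ ant) + float(lm["posterior_rim"] @ ant))

    x_bp = _surface_x_at(anatomy.glenoid_surface.points, y_bp, z_bp)
    center = frame.origin + x_bp * ml + y_bp * si + z_bp * ant
    normal = unit(
        rotation_about_axis(ant, config.baseplate_inclination_deg)
        @ rotation_about_axis(si, config.baseplate_retroversion_deg) @ ml)
    return ImplantPlacement(baseplate_center=center, baseplate_normal=normal,
                            glenosphere_center=center.copy(),
                            humeral_translation=np.zeros(3),
                            inferior_overhang_mm=config.inferior_overhang_mm)


def implant_articular_axis(anatomy: PatientAnatomy, config: ImplantConfiguration) -> np.ndarray:
    """Unit axis from the humeral cup toward the glenosphere center, set by
    the effective NSA about the scene's anterior axis and the humeral
    retroversion about the shaft axis (native orientation, CT pose)."""
    shaft_dir = unit(np.asarray(anatomy.humeral_shaft_axis[1], dtype=float))
    nsa = config.effective_nsa_deg
    e = rotation_about_axis([0.0, 0.0, -1.0], nsa) @ shaft_dir
    # negative retroversion tips the articular axis posteriorly (rotation
    # about the proximal shaft direction)
    return unit(rotation_about_axis(-shaft_dir, config.humeral_retroversion_deg) @ e)


def cup_center_offset_mm(config: ImplantConfiguration) -> float:
    """Distance from the metaphyseal cut plane to the liner cup (sphere)
    center along the implant axis.  The cup depth is DRR * R, so the sphere
    center sits (1 - DRR) * R beyond the liner rim, which stands one liner
    thickness proud of the cut."""
    drr = float(config.depth_radius_ratio.lstrip("<"))
    r_gs = config.glenosphere_diameter_mm / 2.0
    return (1.0 - drr) * r_gs + config.liner_thickness_mm


def place_glenosphere_and_humerus(anatomy: PatientAnatomy, config: ImplantConfiguration,
                                  lateralization_mm: float = 0.0) -> ImplantPlacement:
    """Complete placement for one strategy at a given graft lateralization.

    The center of rotation is the baseplate center pushed laterally along
    the baseplate normal by (glenosphere center offset + lateralization)
    and shifted inferiorly by any eccentric offset.  The humerus then
    translates so its cup center lands on the glenosphere center.
    """
    if lateralization_mm > 0 and config.lateralization_mode == "none":
        raise ValidationError(f"strategy {config.strategy_id} does not accept lateralization")
    base = place_baseplate(anatomy, config)
    frame = build_scapular_frame(anatomy.scapular_landmarks)
    cor = (base.baseplate_center
           + (config.glenosphere_center_offset_mm + lateralization_mm) * base.baseplate_normal
           - config.eccentric_offset_mm * frame.superior_inferior_axis)

    neck_pt = np.asarray(anatomy.anatomical_neck_plane[0], dtype=float)
    e = implant_articular_axis(anatomy, config)
    cup_center_native = neck_pt + cup_center_offset_mm(config) * e
    translation = cor - cup_center_native
    return ImplantPlacement(baseplate_center=base.baseplate_center,
                            baseplate_normal=base.baseplate_normal,
                            glenosphere_center=cor,
                            humeral_translation=translation,
                            inferior_overhang_mm=config.inferior_overhang_mm)
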