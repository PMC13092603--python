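"""Synthetic CT-like shoulder cohort generator.

Real pre-operative CT cohorts of arthroplasty candidates are rarely
shareable, so this module generates parametric right-shoulder anatomies
whose scalar distributions emulate a typical degenerative cohort: best-fit
humeral head size (HHS) median 49 mm (range 40-56), posterior humeral
subluxation 24-88 %, glenoid vault loss 0-54 %, erosion depth 0-11 mm, and
an osteoarthritis / massive cuff tear / cuff-tear-arthropathy diagnosis mix
of roughly 23/31/29 in 83 shoulders.

The generative model is a fixed mean-shape landmark template expressed in a
canonical right-shoulder scapular frame (origin at the glenoid center,
+x lateral along the Friedman line, +y superior, +z anterior).  Every
glenohumeral dimension of the template scales affinely with the sampled
head diameter -- the generator's mechanism for the anatomical premise that
head size scales predictably with overall glenohumeral size.  Pathology is
applied on top of the scaled template:

* glenoid erosion: a posterior wedge recession of the glenoid face along
  the medial-lateral axis (hinging at the antero-posterior midline, the
  classic Walch-B-type wear pattern) plus an optional uniform recession
  component so that sampled vault loss and maximal erosion depth can be
  honoured jointly;
* humeral subluxation: a posterior translation of the humeral head center
  equal to (subluxation% - 50%) x head diameter;
* attachment-site jitter: truncated Gaussian noise (clipped at 3 sigma).

Left shoulders are mirrored into the canonical right-side frame at
generation time; the ``side`` label records original handedness.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import optimize, stats

from ._geom import rotation_about_axis, mirror_z
from .errors import ValidationError

REF_HHS_MM = 49.0  # template is authored at this head diameter

DIAGNOSES = ("OA", "MRCT", "CTA")

# Per-diagnosis (min, median, max) decentering parameters for a typical
# degenerative cohort; used when ``condition_on_diagnosis`` is enabled.
_DIAGNOSIS_PATHOLOGY = {
    "subluxation_pct": {"OA": (24.0, 64.0, 88.0), "MRCT": (41.0, 57.0, 78.0), "CTA": (40.0, 62.0, 85.0)},
    "vault_loss_pct": {"OA": (0.0, 13.0, 54.0), "MRCT": (0.0, 2.0, 14.0), "CTA": (5.0, 10.0, 29.0)},
    "erosion_mm": {"OA": (0.0, 4.0, 11.0), "MRCT": (0.0, 1.0, 3.0), "CTA": (2.0, 4.0, 10.0)},
}

# ---------------------------------------------------------------------------
# mean-shape template, all lengths in mm at REF_HHS_MM (scale s = hhs / 49)
# ---------------------------------------------------------------------------
TEMPLATE = {
    "trigonum": np.array([-100.0, 0.0, 0.0]),
    "inferior_angle": np.array([-78.0, -120.0, 0.0]),
    "glenoid_halfheight": 18.0,        # superior-inferior semi-axis
    "glenoid_halfwidth": 13.5,         # antero-posterior semi-axis
    "glenoid_dish_depth": 2.0,         # concavity of the articular face
    "vault_depth": 25.0,               # premorbid glenoid vault depth
    "head_center_offset": 1.5,         # head center sits r - 1.5 lateral
    # greater tuberosity offset from head center, in units of head radius
    "gt_offset_per_radius": np.array([0.95, -0.20, 0.05]),
    "neck_axis": np.array([np.cos(np.radians(45.0)), np.sin(np.radians(45.0)), 0.0]),
    "neck_distance_per_radius": 0.283,  # anatomical neck plane offset / r
    "shaft_point_offset": np.array([4.0, -30.0, 0.0]),
    "shaft_direction": np.array([0.0, -1.0, 0.0]),
    # muscle origins (scapula-fixed) and insertion offsets from head center
    "muscle_origins": {
        "deltoid": np.array([2.0, 36.0, 2.0]),
        "infraspinatus": np.array([-70.0, -25.0, -15.0]),
        "teres_minor": np.array([-45.0, -50.0, -12.0]),
        "subscapularis": np.array([-70.0, -20.0, 12.0]),
    },
    "muscle_insertion_offsets": {
        "deltoid": np.array([12.0, -110.0, 0.0]),
        "infraspinatus": np.array([20.0, 3.0, -16.0]),
        "teres_minor": np.array([19.0, -8.0, -16.0]),
        "subscapularis": np.array([18.0, -3.0, 17.5]),
    },
    "head_points": 200,       # articular point-cloud size
    "glenoid_rings": 10,      # concentric sampling rings of the face grid
}

MUSCLES = tuple(TEMPLATE["muscle_origins"])


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------
Range = tuple  # (min, median, max)


@dataclass
class CohortSpec:
    """Sampling specification for one synthetic cohort.

    Ranges are (min, median, max) triples; each is matched by a scaled Beta
    distribution with fixed concentration so the printed median and bounds
    are honoured with bounded support.
    """

    n_patients: int = 83
    seed: int = 0
    diagnosis_mix: dict = field(default_factory=lambda: {"OA": 23 / 83, "MRCT": 31 / 83, "CTA": 29 / 83})
    hhs_range_mm: Range = (40.0, 49.0, 56.0)
    subluxation_range_pct: Range = (24.0, 61.0, 88.0)
    vault_loss_range_pct: Range = (0.0, 8.0, 54.0)
    erosion_range_mm: Range = (0.0, 3.0, 11.0)
    inclination_range_deg: Range = (-15.0, 7.0, 28.0)
    retroversion_range_deg: Range = (0.0, 9.0, 33.0)
    noise_sd_mm: float = 0.5
    hamada_ge2_prob: float = 0.8
    pathology_rank_corr: float = 0.5
    condition_on_diagnosis: bool = True

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        tot = sum(self.diagnosis_mix.get(d, 0.0) for d in DIAGNOSES)
        if set(self.diagnosis_mix) - set(DIAGNOSES):
            raise ValidationError(f"diagnosis_mix has unknown keys: {set(self.diagnosis_mix) - set(DIAGNOSES)}")
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"diagnosis_mix proportions must sum to 1 (got {tot!r})")
        for name in ("hhs_range_mm", "subluxation_range_pct", "vault_loss_range_pct",
                     "erosion_range_mm", "inclination_range_deg", "retroversion_range_deg"):
            lo, med, hi = getattr(self, name)
            if not (lo <= med <= hi):
                raise ValidationError(f"{name} must satisfy min <= median <= max (got {(lo, med, hi)})")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")

    @classmethod
    def noiseless(cls, n_patients: int = 83, seed: int = 0) -> "CohortSpec":
        """The pure-scaling configuration: no attachment jitter and all
        sampled parameters pinned at their global medians, so head size is
        the only source of geometric variation.  Used to isolate the
        affine-scaling law of the template."""
        base = cls()
        collapse = lambda r: (r[1], r[1], r[1])
        return cls(
            n_patients=n_patients,
            seed=seed,
            diagnosis_mix=base.diagnosis_mix,
            subluxation_range_pct=collapse(base.subluxation_range_pct),
            vault_loss_range_pct=collapse(base.vault_loss_range_pct),
            erosion_range_mm=collapse(base.erosion_range_mm),
            inclination_range_deg=collapse(base.inclination_range_deg),
            retroversion_range_deg=collapse(base.retroversion_range_deg),
            noise_sd_mm=0.0,
            condition_on_diagnosis=False,
        )

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        for k, v in d.items():
            if k.endswith(("_mm", "_pct", "_deg")) and isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class GlenoidSurface:
    """A sampled glenoid articular face: (N, 3) points in the canonical
    frame plus the vault depth used for percentage bone-loss reporting."""

    points: np.ndarray
    vault_depth_mm: float


@dataclass
class TruePathology:
    """Generator ground truth retained for validation of the measurement
    operators (not available for real anatomies)."""

    subluxation_pct: float
    vault_loss_pct: float          # realized, from the sampled recession field
    erosion_depth_mm: float        # maximal medial recession
    central_recession_mm: float    # recession at the glenoid center
    premorbid_glenoid: GlenoidSurface
    head_radius_mm: float
    head_center: np.ndarray
    premorbid_head_center: np.ndarray
    glenoid_inclination_deg: float
    glenoid_retroversion_deg: float


@dataclass
class PatientAnatomy:
    patient_id: str
    side: str                      # {"left", "right"}; coordinates are canonical right
    diagnosis: str                 # {"OA", "MRCT", "CTA"}
    hamada_grade: Optional[int]    # 1-5, CTA only
    scapular_landmarks: dict       # trigonum, inferior_angle, glenoid_center, 4 rim points
    humeral_head_points: np.ndarray
    glenoid_surface: GlenoidSurface
    anatomical_neck_plane: tuple   # (point, unit normal)
    greater_tuberosity_point: np.ndarray
    premorbid_gt_point: np.ndarray  # erosion-corrected overlap reference
    humeral_shaft_axis: tuple      # (point, unit direction)
    muscle_sites: dict             # name -> {"origin": p, "insertion": p}
    true_pathology: TruePathology

    @property
    def hhs_mm(self) -> float:
        return 2.0 * self.true_pathology.head_radius_mm


# ---------------------------------------------------------------------------
# bounded sampling: Beta matched to (min, median, max)
# ---------------------------------------------------------------------------
_BETA_CONCENTRATION = 4.0  # a + b; mild spread with bounded support


def _beta_shape_for_median(m_norm: float, conc: float = _BETA_CONCENTRATION) -> tuple:
    m = float(np.clip(m_norm, 0.02, 0.98))
    f = lambda a: stats.beta.ppf(0.5, a, conc - a) - m
    a = optimize.brentq(f, 1e-3, conc - 1e-3, xtol=1e-10)
    return a, conc - a


def sample_range(rng_or_u, rng_range: Range, *, as_uniform: bool = False) -> float:
    """Draw one value from the Beta distribution matched to the range.

    ``rng_or_u`` is either a Generator (draw fresh) or, when ``as_uniform``
    is set, a uniform [0, 1] quantile (used for copula-correlated draws).
    """
    lo, med, hi = (float(v) for v in rng_range)
    if hi - lo < 1e-12:
        return med
    u = float(rng_or_u) if as_uniform else float(rng_or_u.uniform())
    a, b = _beta_shape_for_median((med - lo) / (hi - lo))
    return lo + (hi - lo) * float(stats.beta.ppf(u, a, b))


def _correlated_uniforms(rng: np.random.Generator, k: int, rank_corr: float) -> np.ndarray:
    """Gaussian-copula uniforms with the given Spearman rank correlation."""
    rho = 2.0 * np.sin(np.pi * rank_corr / 6.0)  # Pearson rho giving that rank corr
    cov = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    z = np.linalg.cholesky(cov) @ rng.standard_normal(k)
    return stats.norm.cdf(z)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def _disk_grid(n_rings: int) -> np.ndarray:
    """Concentric-ring sampling of the closed unit disk, (N, 2)."""
    pts = [(0.0, 0.0)]
    for j in range(1, n_rings + 1):
        rad = j / n_rings
        m = 6 * j
        ang = 2.0 * np.pi * np.arange(m) / m
        pts.extend(zip(rad * np.cos(ang), rad * np.sin(ang)))
    return np.asarray(pts)


def _recession_field(z: np.ndarray, eps: float, u0: float, halfwidth: float) -> np.ndarray:
    """Medial recession (mm) at antero-posterior coordinate z: uniform
    component u0 plus a posterior wedge reaching eps at the posterior rim."""
    w = np.clip(-np.asarray(z, dtype=float) / halfwidth, 0.0, 1.0)
    return u0 + (eps - u0) * w


def sample_patient(rng: np.random.Generator, spec: CohortSpec, index: int = 0) -> PatientAnatomy:
    """Draw one synthetic anatomy.  The rng state advances deterministically."""
    diagnosis = str(rng.choice(DIAGNOSES, p=[spec.diagnosis_mix.get(d, 0.0) for d in DIAGNOSES]))
    side = "left" if rng.uniform() < 0.5 else "right"

    hamada = None
    if diagnosis == "CTA":
        hamada = int(rng.integers(2, 6)) if rng.uniform() < spec.hamada_ge2_prob else 1

    hhs = sample_range(rng, spec.hhs_range_mm)
    r = hhs / 2.0
    s = hhs / REF_HHS_MM

    if spec.condition_on_diagnosis:
        subl_rng = _DIAGNOSIS_PATHOLOGY["subluxation_pct"][diagnosis]
        vault_rng = _DIAGNOSIS_PATHOLOGY["vault_loss_pct"][diagnosis]
        eros_rng = _DIAGNOSIS_PATHOLOGY["erosion_mm"][diagnosis]
    else:
        subl_rng, vault_rng, eros_rng = (spec.subluxation_range_pct,
                                         spec.vault_loss_range_pct, spec.erosion_range_mm)
    u_subl, u_vault, u_eros = _correlated_uniforms(rng, 3, spec.pathology_rank_corr)
    subluxation = sample_range(u_subl, subl_rng, as_uniform=True)
    vault_loss_target = sample_range(u_vault, vault_rng, as_uniform=True)
    erosion = sample_range(u_eros, eros_rng, as_uniform=True)
    inclination = sample_range(rng, spec.inclination_range_deg)
    retroversion = sample_range(rng, spec.retroversion_range_deg)

    T = TEMPLATE
    A = T["glenoid_halfheight"] * s
    B = T["glenoid_halfwidth"] * s
    vault_depth = T["vault_depth"] * s

    # --- glenoid face: dished ellipse, tilted by version/inclination -------
    grid = _disk_grid(T["glenoid_rings"])
    y = A * grid[:, 0]
    z = B * grid[:, 1]
    x = T["glenoid_dish_depth"] * s * (grid[:, 0] ** 2 + grid[:, 1] ** 2)
    R_g = rotation_about_axis([0, 0, 1], inclination) @ rotation_about_axis([0, 1, 0], retroversion)
    pre_points = np.stack([x, y, z], axis=1) @ R_g.T

    # wedge + uniform erosion honouring both sampled erosion depth and
    # sampled vault loss where geometrically feasible
    mean_w = float(np.mean(np.clip(-pre_points[:, 2] / B, 0.0, 1.0)))
    target_mean = vault_loss_target / 100.0 * vault_depth
    if erosion < 1e-12:
        u0 = 0.0
    else:
        u0 = float(np.clip((target_mean - mean_w * erosion) / max(1.0 - mean_w, 1e-9), 0.0, erosion))
    rec = _recession_field(pre_points[:, 2], erosion, u0, B)
    cur_points = pre_points.copy()
    cur_points[:, 0] -= rec
    realized_vault_loss = float(np.mean(rec)) / vault_depth * 100.0

    # rim landmarks on the current (eroded) face: grid rows were built so
    # the ring extremes land exactly on the semi-axes
    def _rim(py, pz):
        base = np.array([T["glenoid_dish_depth"] * s * (py ** 2 + pz ** 2), A * py, B * pz]) @ R_g.T
        base[0] -= float(_recession_field(np.array([base[2]]), erosion, u0, B)[0])
        return base

    landmarks = {
        "trigonum": T["trigonum"] * s,
        "inferior_angle": T["inferior_angle"] * s,
        "glenoid_center": np.zeros(3),
        "superior_rim": _rim(1.0, 0.0),
        "inferior_rim": _rim(-1.0, 0.0),
        "anterior_rim": _rim(0.0, 1.0),
        "posterior_rim": _rim(0.0, -1.0),
    }

    # --- humerus ------------------------------------------------------------
    head_center_pre = np.array([r - T["head_center_offset"] * s, 0.0, 0.0])
    posterior_offset = (subluxation - 50.0) / 100.0 * hhs
    head_center = head_center_pre + np.array([-u0, 0.0, -posterior_offset])

    neck_u = T["neck_axis"]
    d_neck = T["neck_distance_per_radius"] * r
    dirs = _fibonacci_directions(4 * T["head_points"])
    cap = dirs[dirs @ neck_u <= T["neck_distance_per_radius"]][: T["head_points"]]
    radii = np.full(len(cap), r)
    if spec.noise_sd_mm > 0:
        radii = radii + np.clip(rng.normal(0.0, spec.noise_sd_mm, len(cap)),
                                -3.0 * spec.noise_sd_mm, 3.0 * spec.noise_sd_mm)
    head_points = head_center + cap * radii[:, None]

    gt_point = head_center + T["gt_offset_per_radius"] * r
    premorbid_gt = head_center_pre + T["gt_offset_per_radius"] * r
    shaft = (head_center + T["shaft_point_offset"] * s, T["shaft_direction"].copy())

    muscle_sites = {}
    for name in MUSCLES:
        origin = T["muscle_origins"][name] * s
        insertion = head_center + T["muscle_insertion_offsets"][name] * s
        if spec.noise_sd_mm > 0:
            jitter = lambda: np.clip(rng.normal(0.0, spec.noise_sd_mm, 3),
                                     -3.0 * spec.noise_sd_mm, 3.0 * spec.noise_sd_mm)
            origin = origin + jitter()
            insertion = insertion + jitter()
            if name != "deltoid":  # keep cuff insertions on/outside the head surface
                v = insertion - head_center
                dist = np.linalg.norm(v)
                min_dist = r + 0.5 * s
                if dist < min_dist:
                    insertion = head_center + v / dist * min_dist
        muscle_sites[name] = {"origin": origin, "insertion": insertion}

    truth = TruePathology(
        subluxation_pct=subluxation,
        vault_loss_pct=realized_vault_loss,
        erosion_depth_mm=erosion,
        central_recession_mm=u0,
        premorbid_glenoid=GlenoidSurface(pre_points, vault_depth),
        head_radius_mm=r,
        head_center=head_center,
        premorbid_head_center=head_center_pre,
        glenoid_inclination_deg=inclination,
        glenoid_retroversion_deg=retroversion,
    )
    return PatientAnatomy(
        patient_id=f"P{index:03d}",
        side=side,
        diagnosis=diagnosis,
        hamada_grade=hamada,
        scapular_landmarks=landmarks,
        humeral_head_points=head_points,
        glenoid_surface=GlenoidSurface(cur_points, vault_depth),
        anatomical_neck_plane=(head_center + d_neck * neck_u, neck_u.copy()),
        greater_tuberosity_point=gt_point,
        premorbid_gt_point=premorbid_gt,
        humeral_shaft_axis=shaft,
        muscle_sites=muscle_sites,
        true_pathology=truth,
    )


def generate_cohort(spec: CohortSpec) -> list:
    """Generate ``spec.n_patients`` anatomies; identical spec (including
    seed) yields a bit-identical cohort."""
    rng = np.random.default_rng(spec.seed)
    return [sample_patient(rng, spec, i) for i in range(spec.n_patients)]


def mirror_anatomy(a: PatientAnatomy) -> PatientAnatomy:
    """Reflect an anatomy across the scapular plane (the left/right mirror);
    involutive, and used to bring externally supplied left shoulders into
    the canonical right-side convention."""
    flip = lambda p: mirror_z(np.asarray(p))
    truth = a.true_pathology
    return PatientAnatomy(
        patient_id=a.patient_id,
        side="right" if a.side == "left" else "left",
        diagnosis=a.diagnosis,
        hamada_grade=a.hamada_grade,
        scapular_landmarks={k: flip(v) for k, v in a.scapular_landmarks.items()},
        humeral_head_points=flip(a.humeral_head_points),
        glenoid_surface=GlenoidSurface(flip(a.glenoid_surface.points), a.glenoid_surface.vault_depth_mm),
        anatomical_neck_plane=(flip(a.anatomical_neck_plane[0]), flip(a.anatomical_neck_plane[1])),
        greater_tuberosity_point=flip(a.greater_tuberosity_point),
        premorbid_gt_point=flip(a.premorbid_gt_point),
        humeral_shaft_axis=(flip(a.humeral_shaft_axis[0]), flip(a.humeral_shaft_axis[1])),
        muscle_sites={k: {"origin": flip(v["origin"]), "insertion": flip(v["insertion"])}
                      for k, v in a.muscle_sites.items()},
        true_pathology=TruePathology(
            subluxation_pct=truth.subluxation_pct,
            vault_loss_pct=truth.vault_loss_pct,
            erosion_depth_mm=truth.erosion_depth_mm,
            central_recession_mm=truth.central_recession_mm,
            premorbid_glenoid=GlenoidSurface(flip(truth.premorbid_glenoid.points),
                                             truth.premorbid_glenoid.vault_depth_mm),
            head_radius_mm=truth.head_radius_mm,
            head_center=flip(truth.head_center),
            premorbid_head_center=flip(truth.premorbid_head_center),
            glenoid_inclination_deg=truth.glenoid_inclination_deg,
            glenoid_retroversion_deg=truth.glenoid_retroversion_deg,
        ),
    )
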