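import dataclasses

import numpy as np
import pytest

from rsaplan._geom import rotation_about_axis, unit
from rsaplan.anatomy_geometry import build_scapular_frame
from rsaplan.errors import ValidationError
from rsaplan.implant_config import (ImplantConfiguration, catalog_from_json,
                                    catalog_to_json, cup_center_offset_mm,
                                    effective_nsa, implant_articular_axis,
                                    inferior_overhang, place_baseplate,
                                    place_glenosphere_and_humerus,
                                    strategy_catalog)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------
def test_catalog_reproduces_every_cell():
    cat = {c.strategy_id: c for c in strategy_catalog()}
    assert sorted(cat) == [1, 2, 3, 4, 5]
    assert [cat[i].meta_epiphyseal_tilt_deg for i in range(1, 6)] == [20, 20, 10, 0, 0]
    assert [cat[i].effective_nsa_deg for i in range(1, 6)] == [135, 135, 145, 155, 155]
    assert [cat[i].inferior_overhang_mm for i in range(1, 6)] == [5.5, 5.5, 5.5, 5.5, 9.5]
    assert cat[1].baseplate_position == "centered"
    for i in (2, 3, 4, 5):
        assert cat[i].baseplate_position == "flush_inferior"
    for i in range(1, 5):
        assert (cat[i].glenosphere_diameter_mm, cat[i].eccentric_offset_mm,
                cat[i].liner_type, cat[i].lateralization_mode) == (38.0, 0.0, "standard",
                                                                   "overlap_based")
    assert (cat[5].glenosphere_diameter_mm, cat[5].eccentric_offset_mm,
            cat[5].liner_type, cat[5].lateralization_mode) == (42.0, 2.0, "high_mobility",
                                                               "none")
    for c in cat.values():
        assert c.meta_epiphyseal_nsa_deg == 155.0
        assert c.liner_thickness_mm == 3.0
        assert c.baseplate_diameter_mm == 27.0
        assert (c.baseplate_inclination_deg, c.baseplate_retroversion_deg) == (0.0, 5.0)
        assert c.humeral_retroversion_deg == -20.0
        assert c.humeral_osteotomy_height_mm == 19.0


def test_effective_nsa():
    assert effective_nsa(155.0, 20.0) == 135.0
    assert effective_nsa(155.0, 10.0) == 145.0
    assert effective_nsa(155.0, 0.0) == 155.0
    with pytest.raises(ValidationError):
        effective_nsa(155.0, -5.0)
    with pytest.raises(ValidationError):
        effective_nsa(155.0, 160.0)


def test_inferior_overhang():
    assert inferior_overhang(38.0, 27.0, 0.0) == 5.5
    assert inferior_overhang(42.0, 27.0, 2.0) == 9.5
    assert inferior_overhang(27.0, 27.0, 0.0) == 0.0
    with pytest.raises(ValidationError):
        inferior_overhang(25.0, 27.0, 0.0)
    with pytest.raises(ValidationError):
        inferior_overhang(38.0, 27.0, -1.0)


def test_config_validation():
    with pytest.raises(ValidationError):
        ImplantConfiguration(1, "bad", glenosphere_diameter_mm=20.0)
    with pytest.raises(ValidationError):
        ImplantConfiguration(1, "bad", humeral_osteotomy_height_mm=25.0)
    # the printed tolerance window is allowed
    ImplantConfiguration(1, "ok", humeral_osteotomy_height_mm=17.0)


def test_catalog_json_roundtrip():
    text = catalog_to_json()
    again = catalog_from_json(text)
    assert again == strategy_catalog()
    assert catalog_to_json(again) == text


# ---------------------------------------------------------------------------
# baseplate placement
# ---------------------------------------------------------------------------
def test_centered_baseplate_at_si_midpoint(small_cohort):
    cfg = strategy_catalog()[0]
    for a in small_cohort:
        frame = build_scapular_frame(a.scapular_landmarks)
        p = place_baseplate(a, cfg)
        y = float(p.baseplate_center @ frame.superior_inferior_axis)
        y_mid = 0.5 * (a.scapular_landmarks["superior_rim"] +
                       a.scapular_landmarks["inferior_rim"]) @ frame.superior_inferior_axis
        assert abs(y - y_mid) < 1e-9


def test_flush_baseplate_rim_arithmetic(small_cohort):
    cfg = strategy_catalog()[1]
    for a in small_cohort:
        frame = build_scapular_frame(a.scapular_landmarks)
        p = place_baseplate(a, cfg)
        y = float(p.baseplate_center @ frame.superior_inferior_axis)
        y_inf = float(a.scapular_landmarks["inferior_rim"] @ frame.superior_inferior_axis)
        assert abs(y - (y_inf + 13.5)) < 1e-9


def test_flush_strictly_inferior_to_centered(small_cohort):
    centered, flush = strategy_catalog()[0], strategy_catalog()[1]
    for a in small_cohort:
        frame = build_scapular_frame(a.scapular_landmarks)
        y_c = float(place_baseplate(a, centered).baseplate_center
                    @ frame.superior_inferior_axis)
        y_f = float(place_baseplate(a, flush).baseplate_center
                    @ frame.superior_inferior_axis)
        assert y_f < y_c  # glenoid SI height (36 mm scaled) exceeds the 27 mm plate


def test_baseplate_normal_orientation(small_cohort):
    cfg = strategy_catalog()[0]
    a = small_cohort[0]
    frame = build_scapular_frame(a.scapular_landmarks)
    p = place_baseplate(a, cfg)
    expected = unit(rotation_about_axis(frame.scapular_plane_normal, 0.0)
                    @ rotation_about_axis(frame.superior_inferior_axis, 5.0)
                    @ frame.medial_lateral_axis)
    np.testing.assert_allclose(p.baseplate_normal, expected, atol=1e-6)
    assert abs(np.linalg.norm(p.baseplate_normal) - 1.0) < 1e-9


def test_missing_rim_landmark_error(small_cohort):
    from rsaplan.errors import GeometryError
    a = small_cohort[0]
    lm = {k: v for k, v in a.scapular_landmarks.items() if k != "posterior_rim"}
    broken = dataclasses.replace(a, scapular_landmarks=lm)
    with pytest.raises(GeometryError, match="posterior_rim"):
        place_baseplate(broken, strategy_catalog()[0])


# ---------------------------------------------------------------------------
# glenosphere + humerus placement
# ---------------------------------------------------------------------------
def test_one_mm_lateralization_moves_gt_one_mm(small_cohort):
    cfg = strategy_catalog()[0]
    for a in small_cohort[:3]:
        p0 = place_glenosphere_and_humerus(a, cfg, 4.0)
        p1 = place_glenosphere_and_humerus(a, cfg, 5.0)
        gt0 = a.greater_tuberosity_point + p0.humeral_translation
        gt1 = a.greater_tuberosity_point + p1.humeral_translation
        np.testing.assert_allclose(gt1 - gt0, p0.baseplate_normal, atol=1e-9)


def test_gt_affine_in_lateralization(small_cohort):
    cfg = strategy_catalog()[2]
    a = small_cohort[1]
    frame = build_scapular_frame(a.scapular_landmarks)
    ml = frame.medial_lateral_axis
    xs = []
    for g in (0.0, 7.0, 14.0):
        p = place_glenosphere_and_humerus(a, cfg, g)
        xs.append(float((a.greater_tuberosity_point + p.humeral_translation) @ ml))
    slope = float(place_baseplate(a, cfg).baseplate_normal @ ml)
    assert abs((xs[1] - xs[0]) / 7.0 - slope) < 1e-9
    assert abs((xs[2] - xs[1]) / 7.0 - slope) < 1e-9
    assert slope > 0


def test_strategy5_cor_on_baseplate_plane(small_cohort):
    cfg = strategy_catalog()[4]
    a = small_cohort[0]
    p = place_glenosphere_and_humerus(a, cfg, 0.0)
    assert abs((p.glenosphere_center - p.baseplate_center) @ p.baseplate_normal) < 1e-9
    # eccentric offset shifts the COR 2 mm inferior
    frame = build_scapular_frame(a.scapular_landmarks)
    si = frame.superior_inferior_axis
    assert abs((p.glenosphere_center - p.baseplate_center) @ si + 2.0) < 1e-9


def test_lateralization_rejected_for_medialized_strategy(small_cohort):
    cfg = strategy_catalog()[4]
    with pytest.raises(ValidationError):
        place_glenosphere_and_humerus(small_cohort[0], cfg, 1.0)


def test_tilt_planar_trig_oracle(small_cohort):
    """GT position vs. tilt matches a hand-built 2D trigonometric model in
    the scapular plane (humeral retroversion zeroed so the articular axis
    stays in-plane), and 20 deg tilt is more lateral / less distal."""
    a = small_cohort[0]
    base = strategy_catalog()[3]  # 155, flush
    tilted = dataclasses.replace(base, meta_epiphyseal_tilt_deg=20.0)
    gt = {}
    for cfg in (base, tilted):
        cfg0 = dataclasses.replace(cfg, humeral_retroversion_deg=0.0)
        p = place_glenosphere_and_humerus(a, cfg0, 0.0)
        cor = p.glenosphere_center
        # planar closed form: e = Rz(-nsa) applied to the shaft direction
        nsa = np.radians(cfg0.effective_nsa_deg)
        shaft = np.array([0.0, -1.0, 0.0])
        e = np.array([shaft[0] * np.cos(nsa) + shaft[1] * np.sin(nsa),
                      -shaft[0] * np.sin(nsa) + shaft[1] * np.cos(nsa), 0.0])
        np.testing.assert_allclose(implant_articular_axis(a, cfg0), e, atol=1e-9)
        expected_gt = (cor - (np.asarray(a.anatomical_neck_plane[0])
                              + cup_center_offset_mm(cfg0) * e)
                       + a.greater_tuberosity_point)
        np.testing.assert_allclose(a.greater_tuberosity_point + p.humeral_translation,
                                   expected_gt, atol=1e-9)
        gt[cfg.effective_nsa_deg] = expected_gt
    assert gt[135.0][0] > gt[155.0][0]   # more lateral
    assert gt[135.0][1] > gt[155.0][1]   # less distal


def test_humeral_transform_is_pure_translation(small_cohort):
    p = place_glenosphere_and_humerus(small_cohort[0], strategy_catalog()[0], 3.0)
    T = p.humeral_transform
    np.testing.assert_allclose(T[:3, :3], np.eye(3))
    np.testing.assert_allclose(T[:3, 3], p.humeral_translation)


def test_distalization_flush_exceeds_centered(small_cohort):
    """Inferior GT shift vs. native is larger for the flush baseplate than
    the centered one at equal NSA, on every synthetic patient."""
    centered, flush = strategy_catalog()[0], strategy_catalog()[1]
    for a in small_cohort:
        frame = build_scapular_frame(a.scapular_landmarks)
        si = frame.superior_inferior_axis
        d = {}
        for cfg in (centered, flush):
            p = place_glenosphere_and_humerus(a, cfg, 0.0)
            gt_post = a.greater_tuberosity_point + p.humeral_translation
            d[cfg.baseplate_position] = float((a.greater_tuberosity_point - gt_post) @ si)
        assert d["flush_inferior"] > d["centered"]
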