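"""Anthropometric scaling: BSIP prediction, the anisotropic morphology
matrix, ribcage ellipsoid dilation, glenoid orientation, and PCSA."""

import math

import numpy as np
import pytest

from shoulderelbow import kinematics as K
from shoulderelbow import scaling as SC
from shoulderelbow.scaling import (SubjectAnthropometry, arm_mass_sensitivity,
                                   dilate_ellipsoids, glenoid_angles,
                                   adapt_glenoid, muscle_percentage,
                                   scale_bsip, scale_morphology, scale_pcsa,
                                   scale_subject, scaling_matrix,
                                   _solve_dilation, _rodrigues)
from shoulderelbow.model_core import is_rotation, validate_model

MALE = SubjectAnthropometry("male", 1.86, 85.5, 0.37)
FEMALE = SubjectAnthropometry("female", 1.86, 85.5, 0.37)


# ----------------------------------------------------------------------
# BSIP
# ----------------------------------------------------------------------

def test_arm_mass_predictions_by_gender():
    assert scale_bsip(MALE).arm_mass == pytest.approx(3.5055, abs=1e-10)
    assert scale_bsip(FEMALE).arm_mass == pytest.approx(2.9925, abs=1e-10)


def test_humerus_length_fraction_of_stature():
    b = scale_bsip(MALE)
    assert b.length["humerus"] == pytest.approx(27.0 / 177.0 * 1.86)
    assert b.inertia_t["humerus"] == pytest.approx(
        (0.315 * b.length["humerus"]) ** 2 * b.mass["humerus"])


def test_forearm_split_62_38():
    b = scale_bsip(MALE)
    forearm = b.mass["ulna"] + b.mass["radius"]
    assert b.mass["ulna"] == pytest.approx(0.62 * forearm)
    assert b.mass["radius"] == pytest.approx(0.38 * forearm)


def test_arm_mass_sensitivity_closed_form():
    assert arm_mass_sensitivity(MALE) == pytest.approx(1.1696, abs=1e-4)
    a100 = SubjectAnthropometry("male", 1.86, 100.0, 0.37)
    assert arm_mass_sensitivity(a100) == pytest.approx(1.0)
    assert arm_mass_sensitivity(FEMALE) == arm_mass_sensitivity(MALE)


def test_arm_mass_monotone_in_body_mass():
    masses = [scale_bsip(SubjectAnthropometry("male", 1.86, w, 0.37)).arm_mass
              for w in (50.0, 70.0, 90.0, 110.0)]
    assert np.all(np.diff(masses) > 0)


# ----------------------------------------------------------------------
# morphology
# ----------------------------------------------------------------------

def test_scaling_matrix_identity_for_generic_subject(model):
    g = SC.generic_anthropometry(model)
    sm = scaling_matrix(g, model)
    assert np.allclose(sm.S, np.eye(3))


def test_scaling_matrix_height_enters_z_only(model):
    g = SC.generic_anthropometry(model)
    a = SubjectAnthropometry(g.gender, 2.2, g.weight, g.shoulder_width)
    sm = scaling_matrix(a, model)
    assert sm.diag[2] == pytest.approx(2.2 / g.height)
    assert sm.diag[0] == pytest.approx(1.0)


def test_scaled_shoulder_width_is_exact(model):
    g = SC.generic_anthropometry(model)
    a = SubjectAnthropometry(g.gender, g.height, g.weight, 0.44)
    sm = scaling_matrix(a, model)
    m2 = scale_morphology(model, sm)
    aa_x = m2.segments["scapula"].landmark("AA").position[0]
    assert 2.0 * aa_x == pytest.approx(0.44)


def test_uniform_doubling_doubles_distances(model):
    sm = SC.ScalingMatrix(2.0 * np.eye(3))
    m2 = scale_morphology(model, sm)
    for seg in model.segments:
        for lm in model.segments[seg].landmarks:
            lm2 = m2.segments[seg].landmark(lm.name)
            assert np.allclose(lm2.position, 2.0 * lm.position)


# ----------------------------------------------------------------------
# ellipsoid dilation
# ----------------------------------------------------------------------

def test_unit_sphere_dilation_closed_form():
    d = _solve_dilation(np.array([2.0, 0, 0]), np.zeros(3),
                        np.array([1.0, 1.0, 1.0]))
    assert d == pytest.approx(1.0, abs=1e-12)


def test_identity_scaling_reproduces_stored_ellipsoids(model):
    sm = SC.ScalingMatrix(np.eye(3))
    d_ts, d_ai, e_ts, e_ai = dilate_ellipsoids(model, sm)
    assert np.allclose(e_ts.axes, model.ts_ellipsoid.axes, atol=1e-12)
    assert np.allclose(e_ai.axes, model.ai_ellipsoid.axes, atol=1e-12)


@pytest.mark.parametrize("sx,sz", [(0.5, 0.5), (0.8, 1.1), (1.0, 1.0),
                                   (1.5, 1.2), (2.0, 2.0)])
def test_dilation_root_admissible_with_tiny_residual(model, sx, sz):
    """An admissible real root (all semi-axes positive) exists across the
    anisotropic scaling range; the substitution residual is < 1e-10.
    Shrinking scalings legitimately give negative dilations."""
    sm = SC.ScalingMatrix(np.diag([sx, sx, sz]))
    d_ts, d_ai, e_ts, e_ai = dilate_ellipsoids(model, sm)
    for d, e, lmn in ((d_ts, e_ts, "TS"), (d_ai, e_ai, "AI")):
        assert np.all(e.axes > 0)
        p = sm.S @ model.point_ref(lmn, "scapula")
        assert abs(e.residual(p)) < 1e-10


# ----------------------------------------------------------------------
# glenoid
# ----------------------------------------------------------------------

def test_generator_angle_round_trip(model):
    gi, gv = glenoid_angles(model)
    assert gi == pytest.approx(7.0, abs=1e-6)
    assert gv == pytest.approx(-5.0, abs=1e-6)


def test_adapt_measure_round_trip(model):
    m2 = adapt_glenoid(model, 15.0, -2.0)
    gi, gv = glenoid_angles(m2)
    assert gi == pytest.approx(15.0, abs=1e-6)
    assert gv == pytest.approx(-2.0, abs=1e-6)
    # isometry about the rotation center (the humeral head / cone apex)
    hh = model.point_ref("HH", "scapula")
    assert (np.linalg.norm(m2.glenoid.GC.position - hh)
            == pytest.approx(np.linalg.norm(model.glenoid.GC.position - hh),
                             abs=1e-12))


def test_zero_delta_leaves_glenoid_unchanged(model):
    gi, gv = glenoid_angles(model)
    m2 = adapt_glenoid(model, gi, gv)
    assert np.allclose(m2.glenoid.GC.position, model.glenoid.GC.position,
                       atol=1e-12)


@pytest.mark.parametrize("angle", [-0.5, 0.3, 1.2])
def test_rodrigues_operator_is_rotation(angle, rng):
    axis = rng.normal(0, 1, 3)
    axis /= np.linalg.norm(axis)
    assert is_rotation(_rodrigues(axis, angle))


# ----------------------------------------------------------------------
# muscle percentage / PCSA
# ----------------------------------------------------------------------

def test_muscle_percentage_at_generic_bmi():
    assert 100 * muscle_percentage(MALE) == pytest.approx(77.67, abs=0.005)
    assert 100 * muscle_percentage(FEMALE) == pytest.approx(67.36, abs=0.005)


def test_muscle_percentage_decreasing_in_bmi_male():
    vals = [muscle_percentage(
        SubjectAnthropometry("male", 1.80, bmi * 1.80 ** 2, 0.37))
        for bmi in (15, 20, 25, 30, 35, 40)]
    assert np.all(np.diff(vals) < 0)


def test_out_of_range_bmi_warns_and_clamps():
    skinny = SubjectAnthropometry("male", 2.0, 40.0, 0.37)  # BMI 10
    with pytest.warns(UserWarning):
        v = muscle_percentage(skinny)
    at12 = muscle_percentage(SubjectAnthropometry("male", 2.0,
                                                  12.0 * 4.0, 0.37))
    assert v == pytest.approx(at12)


def test_pcsa_override_is_exact(model):
    g = SC.generic_anthropometry(model)
    a = SubjectAnthropometry(g.gender, g.height, g.weight, g.shoulder_width,
                             pcsa_overrides={"supraspinatus": 10.42})
    m2, factors = scale_pcsa(model, a)
    assert m2.muscle("supraspinatus").pcsa == 10.42
    assert m2.muscle("deltoid_middle").pcsa == pytest.approx(
        model.muscle("deltoid_middle").pcsa)


def test_invalid_anthropometry_rejected():
    with pytest.raises(ValueError):
        SubjectAnthropometry("male", 1.0, 85.5, 0.37)
    with pytest.raises(ValueError):
        SubjectAnthropometry("male", 1.8, 250.0, 0.37)
    with pytest.raises(ValueError):
        SubjectAnthropometry("male", 1.8, 80.0, 0.37,
                             pcsa_overrides={"x": -1.0})


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def test_identity_scaling_is_identity(model):
    g = SC.generic_anthropometry(model)
    m2, report = scale_subject(model, g)
    assert m2 == model
    assert np.allclose(report.scale_diag, 1.0)


def test_female_report_uses_female_bsip_column(model):
    a = SubjectAnthropometry("female", 1.60, 60.0, 0.33)
    m2, report = scale_subject(model, a)
    assert report.bsip.mass["humerus"] == pytest.approx(
        2.2 / 100.0 * 60.0)
    assert report.bsip.length["humerus"] == pytest.approx(
        24.3 / 161.0 * 1.60)
    assert report.r_m_subject < report.r_m_generic


def test_scaled_reference_pose_satisfies_constraints(model):
    a = SubjectAnthropometry("female", 1.65, 62.0, 0.34,
                             glenoid_inclination=15.0)
    m2, _ = scale_subject(model, a)
    phi = K.ribcage_residuals(m2.reference_pose, m2)
    assert max(abs(phi[0]), abs(phi[1])) < 1e-10
    assert validate_model(m2).violations == []
    gi, _ = glenoid_angles(m2)
    assert gi == pytest.approx(15.0, abs=1e-6)
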