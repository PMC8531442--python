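"""Obstacle-set wrapping geometry and the two moment-arm definitions."""

import math

import numpy as np
import pytest

from shoulderelbow import kinematics as K
from shoulderelbow import muscle_paths as MP
from shoulderelbow.muscle_paths import wrap_cylinder, wrap_sphere


# ----------------------------------------------------------------------
# sphere
# ----------------------------------------------------------------------

def test_sphere_miss_gives_straight_chord():
    p1, p2 = np.array([-2.0, 2.0, 0]), np.array([2.0, 2.0, 0])
    arc, L, engaged = wrap_sphere(p1, p2, np.zeros(3), 1.0)
    assert not engaged
    assert np.isclose(L, 4.0)
    assert len(arc) == 0


def test_sphere_symmetric_wrap_matches_closed_form():
    """Symmetric endpoints at distance d: length 2 sqrt(d^2-r^2) + r theta
    with theta = gamma - 2 acos(r/d), gamma the endpoint central angle."""
    r = 1.0
    p1, p2 = np.array([-2.0, 0.5, 0]), np.array([2.0, 0.5, 0])
    _, L, engaged = wrap_sphere(p1, p2, np.zeros(3), r, n_arc=64)
    assert engaged
    d = np.linalg.norm(p1)
    gamma = math.acos(p1 @ p2 / d ** 2)
    theta = gamma - 2 * math.acos(r / d)
    assert np.isclose(L, 2 * math.sqrt(d * d - r * r) + r * theta,
                      atol=1e-12)


def test_sphere_wrap_is_tangent_and_on_surface():
    p1, p2 = np.array([-2.0, 0.3, 0.4]), np.array([1.5, 0.6, -0.2])
    arc, L, engaged = wrap_sphere(p1, p2, np.zeros(3), 1.0, n_arc=32)
    assert engaged
    assert np.allclose(np.linalg.norm(arc, axis=1), 1.0, atol=1e-12)
    # C1 tangency at both junctions
    assert abs(arc[0] @ (p1 - arc[0])) < 1e-10
    assert abs(arc[-1] @ (p2 - arc[-1])) < 1e-10


def test_sphere_length_continuous_as_radius_shrinks():
    p1, p2 = np.array([-2.0, 0.5, 0]), np.array([2.0, 0.5, 0])
    radii = np.linspace(1.2, 0.01, 40)
    lengths = [wrap_sphere(p1, p2, np.zeros(3), r)[1] for r in radii]
    assert np.all(np.diff(lengths) <= 1e-12)      # shrinking never lengthens
    assert np.isclose(lengths[-1], 4.0, atol=1e-6)  # limit: the chord


def test_sphere_endpoint_inside_raises_with_muscle_name():
    with pytest.raises(ValueError, match="deltoid"):
        wrap_sphere([0.1, 0, 0], [2, 0, 0], np.zeros(3), 1.0,
                    muscle="deltoid")


# ----------------------------------------------------------------------
# cylinder
# ----------------------------------------------------------------------

def test_cylinder_parallel_miss_is_straight():
    axis = np.array([0, 0, 1.0])
    p1, p2 = np.array([2.0, 0, -1.0]), np.array([2.0, 0, 1.0])
    arc, L, engaged = wrap_cylinder(p1, p2, np.zeros(3), axis, 1.0)
    assert not engaged and np.isclose(L, 2.0)


def test_cylinder_planar_reduction_equals_circle_solution():
    """Endpoints in a plane perpendicular to the axis reduce to the 2-D
    circle wrap, which is the sphere solution in that plane."""
    r = 1.0
    p1, p2 = np.array([-2.0, 0.5, 0]), np.array([2.0, 0.5, 0])
    _, L_s, _ = wrap_sphere(p1, p2, np.zeros(3), r)
    axis = np.array([0, 0, 1.0])
    Ls = [wrap_cylinder(p1, p2, np.zeros(3), axis, r, side=s)[1]
          for s in ("left", "right")]
    assert np.isclose(min(Ls), L_s, atol=1e-12)


def test_cylinder_arc_monotone_in_radius():
    axis = np.array([0, 0, 1.0])
    p1, p2 = np.array([-2.0, 0.5, -0.5]), np.array([2.0, 0.5, 0.8])
    lengths = [wrap_cylinder(p1, p2, np.zeros(3), axis, r, side="right")[1]
               for r in (0.6, 0.8, 1.0, 1.2)]
    assert np.all(np.diff(lengths) > 0)


def test_cylinder_helical_length_exceeds_chord():
    axis = np.array([0, 0, 1.0])
    p1, p2 = np.array([-2.0, 0.5, -1.0]), np.array([2.0, 0.5, 2.0])
    arc, L, engaged = wrap_cylinder(p1, p2, np.zeros(3), axis, 1.0)
    assert engaged
    assert L > np.linalg.norm(p2 - p1)
    # arc points lie on the cylinder surface
    assert np.allclose(np.hypot(arc[:, 0], arc[:, 1]), 1.0, atol=1e-12)


# ----------------------------------------------------------------------
# full paths on the model
# ----------------------------------------------------------------------

def test_unwrapped_muscle_is_straight_line(model):
    mus = model.muscle("teres_minor")  # no wraps, no vias
    p = MP.muscle_path(model.reference_pose, mus, model)
    assert len(p.points) == 2
    assert np.isclose(p.length, p.straight_length)


def test_path_length_at_least_chord_with_equality_iff_unwrapped(model):
    st = K.ChainState(model, model.reference_pose)
    for mus in model.muscles:
        p = MP.muscle_path(model.reference_pose, mus, model, state=st)
        assert p.length >= p.straight_length - 1e-9
        if not p.wrapped and not mus.via_points:
            assert np.isclose(p.length, p.straight_length)


def test_path_length_lipschitz_in_elbow_flexion(model):
    mus = model.muscle("biceps_long")
    qs = np.linspace(0.0, 2.0, 60)
    L = []
    for v in qs:
        q = model.reference_pose.copy()
        q[9] = v
        L.append(MP.path_length(q, mus, model))
    steps = np.abs(np.diff(L)) / np.diff(qs)
    assert np.max(steps) < 0.2  # |dL/dq| bounded by anatomical scale [m/rad]


def test_reference_pose_path_lengths_match_golden_values(model):
    """Frozen from the first validated run of the generator geometry."""
    golden = {
        "supraspinatus": 0.13932,
        "deltoid_middle": 0.14060,
        "triceps_long": 0.28988,
        "biceps_long": 0.41100,
        "brachialis": 0.16522,
    }
    for name, expect in golden.items():
        L = MP.path_length(model.reference_pose, model.muscle(name), model)
        assert L == pytest.approx(expect, abs=5e-5), name


# ----------------------------------------------------------------------
# moment arms
# ----------------------------------------------------------------------

def test_straight_muscle_hinge_moment_arm_equals_distance(model):
    """Brachialis crosses the elbow hinge as a straight segment; both
    methods must return the geometric distance between the flexion axis
    and the muscle line."""
    q = model.reference_pose
    mus = model.muscle("brachialis")
    we = MP._excursion_column(q, mus, model, 1e-5)[9]
    st = K.ChainState(model, q)
    wg = MP._geometric_column(q, mus, model, st, st.joint_axes())[9]
    # independent oracle: distance between the two 3-D lines
    axis_dir, center, _ = st.joint_axes()[9]
    p0 = st.point_from_ref(mus.origin.position, mus.origin.frame)
    p1 = st.point_from_ref(mus.insertion.position, mus.insertion.frame)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    n = np.cross(axis_dir, u)
    dist = abs((p0 - center) @ n / np.linalg.norm(n))
    assert we == pytest.approx(dist, rel=1e-3)
    assert wg == pytest.approx(dist, rel=1e-3)


def test_non_spanned_coordinates_have_zero_moment_arm(model):
    W = MP.moment_arms(model.reference_pose, model, "excursion")
    for j, mus in enumerate(model.muscles):
        spanned = set(mus.spanned_coordinates())
        for k in range(11):
            if k not in spanned:
                assert W.W[k, j] == 0.0


def test_methods_agree_below_one_percent_over_sweep(model, abduction_traj):
    num = den = 0.0
    for i in range(0, len(abduction_traj), 2):
        q = abduction_traj.q[i]
        Wg = MP.moment_arms(q, model, "geometric").W
        We = MP.moment_arms(q, model, "excursion").W
        num += np.sum((Wg - We) ** 2)
        den += np.sum(We ** 2)
    assert math.sqrt(num / den) < 0.01


def test_moment_arms_bounded_by_anatomical_scale(model, abduction_traj):
    for q in abduction_traj.q:
        W = MP.moment_arms(q, model, "geometric").W
        assert np.max(np.abs(W)) < 0.15


def test_wrap_engagement_matches_chord_intersection(model):
    """Engagement is hysteresis-free: the deltoid wrap is active exactly
    when the straight chord penetrates the head sphere."""
    mus = model.muscle("deltoid_middle")
    w = model.wrap_object("humeral_head")
    for v in np.linspace(0.0, 2.3, 24):
        q = model.reference_pose.copy()
        q[7] = v
        st = K.ChainState(model, q)
        p = MP.muscle_path(q, mus, model, state=st)
        c = st.point_from_ref(w.center, w.attached_segment)
        o = st.point_from_ref(mus.origin.position, "scapula")
        i = st.point_from_ref(mus.insertion.position, "humerus")
        chord_hits = MP._point_seg_dist(c, o, i) < w.radius
        assert p.wrapped == chord_hits
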