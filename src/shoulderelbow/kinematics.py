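"""Bone-fixed frames, forward kinematics of the 11-coordinate chain,
ribcage constraint residuals, and joint-space trajectories.

Chain layout
------------
Eleven generalized coordinates drive the chain: q1..q3 sternoclavicular,
q4..q6 acromioclavicular, q7..q9 glenohumeral (intrinsic Euler triplets,
sequences configurable per joint), q10 elbow flexion/extension about the
ulna x-axis, q11 forearm pronation/supination about the radius z-axis.
Indices in code are 0-based (``q[9]`` is elbow flexion).

Each segment rotation is composed as ``R = R_parent @ C @ E(q_slice)``
where ``C`` is a fixed alignment rotation computed once from the reference
pose, so the chain reproduces the stored reference geometry exactly at the
reference coordinates.  This deliberately deviates from strict ISB frame
alignment: the alignment rotations absorb the anatomical offsets (including
the fixed elbow carrying angle) that an inherently aligned parameterization
cannot represent.

The thorax frame is inertial: x to the subject's right, y anterior,
z superior; gravity acts along -z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .model_core import (GenericModel, Landmark, N_COORDS, SEGMENT_DEPTH,
                         is_rotation)


# ----------------------------------------------------------------------
# elementary rotations and Euler sequences
# ----------------------------------------------------------------------

_EYE = np.eye(3)
_UNIT = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
         "z": np.array([0, 0, 1.0])}


def rot_axis(axis: str, angle: float) -> np.ndarray:
    """Elementary rotation about a coordinate axis (right-hand rule)."""
    c, s = math.cos(angle), math.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def euler_intrinsic(seq: str, angles: Sequence[float]) -> np.ndarray:
    """Intrinsic Euler rotation: R = R_a(q1) R_b(q2) R_c(q3)."""
    R = _EYE
    for ax, a in zip(seq, angles):
        R = R @ rot_axis(ax, a)
    return R


def euler_omega(seq: str, angles: Sequence[float],
                rates: Sequence[float]) -> np.ndarray:
    """Angular velocity of an intrinsic Euler sequence, expressed in the
    sequence's base frame: omega = qd1 e_a + R_a (qd2 e_b + R_b qd3 e_c)."""
    w = np.zeros(3)
    R = _EYE
    for ax, a, ad in zip(seq, angles, rates):
        w = w + ad * (R @ _UNIT[ax])
        R = R @ rot_axis(ax, a)
    return w


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])


def unskew(M: np.ndarray) -> np.ndarray:
    return np.array([M[2, 1] - M[1, 2], M[0, 2] - M[2, 0],
                     M[1, 0] - M[0, 1]]) / 2.0


def _unit(v: np.ndarray, what: str = "axis") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate geometry: zero-length {what}")
    return v / n


@dataclass
class Frame:
    """A right-handed orthonormal frame: origin + rotation (columns are
    the frame's x, y, z axes expressed in the parent frame)."""
    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        if not is_rotation(self.rotation, tol=1e-9):
            raise ValueError("frame rotation is not orthonormal / det +1")


# ----------------------------------------------------------------------
# anatomical frames (bone-fixed, from bony landmarks)
# ----------------------------------------------------------------------

def build_ulna_frame(EL, EM, HU, US) -> Frame:
    """Ulna bone-fixed frame: origin HU, x along HU->EL, y normal to the
    plane of (US, EL, EM), z completing the right-handed triad."""
    EL, EM, HU, US = (np.asarray(p, float) for p in (EL, EM, HU, US))
    x = _unit(EL - HU, "ulna x (EL-HU)")
    y = _unit(np.cross(US - EL, EM - EL), "ulna y (landmark plane)")
    z = np.cross(x, y)
    return Frame(HU, np.column_stack([x, y, z]))


def build_radius_frame(EL, US, RS) -> Frame:
    """Radius bone-fixed frame: origin EL, z along US->EL (the forearm long
    axis), y normal to the plane of (EL, RS, US), x completing the triad."""
    EL, US, RS = (np.asarray(p, float) for p in (EL, US, RS))
    z = _unit(EL - US, "radius z (EL-US)")
    y = _unit(np.cross(EL - RS, RS - US), "radius y (landmark plane)")
    x = np.cross(y, z)
    return Frame(EL, np.column_stack([x, y, z]))


def build_scapula_frame(SN, AI, TS) -> Frame:
    """Scapula bone-fixed frame attached to the spino-glenoid notch SN:
    y normal to the scapular plane, z in-plane along the spine direction,
    x completing the triad (lateral, toward the glenoid)."""
    SN, AI, TS = (np.asarray(p, float) for p in (SN, AI, TS))
    y = _unit(np.cross(SN - AI, SN - TS), "scapula y (scapular plane)")
    z = _unit(np.cross(SN - TS, y), "scapula z")
    x = np.cross(y, z)
    return Frame(SN, np.column_stack([x, y, z]))


def _clavicle_frame(SC, AC) -> Frame:
    """Clavicle frame: x along SC->AC, y horizontal-normal, z completing."""
    x = _unit(np.asarray(AC, float) - np.asarray(SC, float), "clavicle x")
    y = _unit(np.cross(_UNIT["z"], x), "clavicle y")
    z = np.cross(x, y)
    return Frame(SC, np.column_stack([x, y, z]))


def _humerus_frame(HH, HU, AA, AI) -> Frame:
    """Humerus frame: y along the shaft pointing proximally (HU->HH),
    -z the in-(scapular-)plane abduction direction, x completing the triad.
    With the glenohumeral Y-X-Y sequence this makes q8 (elevation) sweep
    the arm in the scapular plane for q7 = q9 = 0."""
    HH, HU, AA, AI = (np.asarray(p, float) for p in (HH, HU, AA, AI))
    y = _unit(HH - HU, "humerus long axis")
    u = AA - AI  # in-plane, pointing superior-lateral
    z = -_unit(u - (u @ y) * y, "humerus z (abduction direction)")
    x = np.cross(y, z)
    return Frame(HH, np.column_stack([x, y, z]))


# ----------------------------------------------------------------------
# model frame construction (called by GenericModel.build)
# ----------------------------------------------------------------------

#: (joint, rotation parent, segment, q-slice, sequence key, base point)
_CHAIN = (
    ("sc", "thorax", "clavicle", slice(0, 3), "sc", ("thorax", "SC")),
    ("ac", "clavicle", "scapula", slice(3, 6), "ac", ("clavicle", "AC")),
    ("gh", "scapula", "humerus", slice(6, 9), "gh", ("scapula", "HH")),
    ("hu", "humerus", "ulna", slice(9, 10), "x", ("humerus", "HU")),
    ("ur", "ulna", "radius", slice(10, 11), "z", ("humerus", "EL")),
)


def _joint_sequence(model: GenericModel, key: str) -> str:
    if key in ("x", "z"):
        return key
    return model.euler_sequences[key]


def build_model_frames(model: GenericModel) -> None:
    """Derive reference anatomical frames, alignment rotations and local
    coordinates; cache them on the model."""
    seg = model.segments
    SC = model.thorax_landmark("SC").position
    AC = seg["clavicle"].landmark("AC").position
    SN = seg["scapula"].landmark("SN").position
    AI = seg["scapula"].landmark("AI").position
    TS = seg["scapula"].landmark("TS").position
    AA = seg["scapula"].landmark("AA").position
    HH = seg["scapula"].landmark("HH").position
    EL = seg["humerus"].landmark("EL").position
    EM = seg["humerus"].landmark("EM").position
    HU = seg["humerus"].landmark("HU").position
    US = seg["ulna"].landmark("US").position
    RS = seg["radius"].landmark("RS").position

    frames = {
        "thorax": Frame(np.zeros(3), _EYE),
        "clavicle": _clavicle_frame(SC, AC),
        "scapula": build_scapula_frame(SN, AI, TS),
        "humerus": _humerus_frame(HH, HU, AA, AI),
        "ulna": build_ulna_frame(EL, EM, HU, US),
        "radius": build_radius_frame(EL, US, RS),
    }
    model._ref_frames = frames

    qref = model.reference_pose
    align = {}
    for joint, parent, child, sl, seqk, _base in _CHAIN:
        seq = _joint_sequence(model, seqk)
        E_ref = euler_intrinsic(seq, qref[sl])
        align[joint] = (frames[parent].rotation.T @ frames[child].rotation
                        @ E_ref.T)
    model._align = align

    # chain base points: the world reference position each segment's pose
    # is anchored to (its proximal joint center)
    base_ref = {"thorax": np.zeros(3)}
    for joint, parent, child, sl, seqk, (bseg, bname) in _CHAIN:
        base_ref[child] = model.point_ref(bname, bseg)
    model._base_ref = base_ref

    # base-point local coordinates in their carrying segment
    base_local = {}
    for joint, parent, child, sl, seqk, (bseg, bname) in _CHAIN:
        p_ref = model.point_ref(bname, bseg)
        base_local[child] = (
            bseg, frames[bseg].rotation.T @ (p_ref - base_ref[bseg]))
    model._base_local = base_local

    # segment landmark locals (exposed as BoneSegment.landmarks_local)
    for s in seg.values():
        f = frames[s.name]
        s._landmarks_local = [
            Landmark(lm.name, f.rotation.T @ (lm.position - f.origin),
                     s.name) for lm in s.landmarks]
        s._com_local = f.rotation.T @ (s.com_ref - base_ref[s.name])


def local_coords(model: GenericModel, p_ref: np.ndarray,
                 segment: str) -> np.ndarray:
    """Reference thorax-frame point -> coordinates in the segment's
    anatomical frame taken about the segment's chain base point (its
    proximal joint center), so that ``o_seg + R_seg @ local`` reproduces
    the reference position at the reference pose exactly."""
    if segment == "thorax":
        return np.asarray(p_ref, float)
    R = model._ref_frames[segment].rotation
    return R.T @ (np.asarray(p_ref, float) - model._base_ref[segment])


# ----------------------------------------------------------------------
# chain state (forward kinematics + velocities)
# ----------------------------------------------------------------------

class ChainState:
    """Pose (and optionally velocity) of every segment at coordinates q.

    Attributes
    ----------
    R : segment -> world rotation (bone anatomical frame -> thorax)
    o : segment -> world position of the segment's base point
    w : segment -> world angular velocity (zero if no rates given)
    vo : segment -> world velocity of the base point
    """

    def __init__(self, model: GenericModel, q: np.ndarray,
                 qd: Optional[np.ndarray] = None):
        if not model._built:
            model.build()
        q = np.asarray(q, float).reshape(N_COORDS)
        rates = (np.zeros(N_COORDS) if qd is None
                 else np.asarray(qd, float).reshape(N_COORDS))
        self.model = model
        self.q = q
        self.qd = rates
        self.R = {"thorax": _EYE}
        self.o = {"thorax": np.zeros(3)}
        self.w = {"thorax": np.zeros(3)}
        self.vo = {"thorax": np.zeros(3)}
        for joint, parent, child, sl, seqk, _ in _CHAIN:
            seq = _joint_sequence(model, seqk)
            C = model._align[joint]
            Rp = self.R[parent]
            E = euler_intrinsic(seq, q[sl])
            self.R[child] = Rp @ C @ E
            self.w[child] = (self.w[parent]
                             + Rp @ C @ euler_omega(seq, q[sl], rates[sl]))
            bseg, blocal = model._base_local[child]
            self.o[child] = self.point(bseg, blocal)
            self.vo[child] = self.point_velocity(bseg, blocal)

    def point(self, segment: str, local: np.ndarray) -> np.ndarray:
        """World position of a point given by segment-frame coordinates."""
        return self.o[segment] + self.R[segment] @ local

    def point_velocity(self, segment: str, local: np.ndarray) -> np.ndarray:
        return self.vo[segment] + np.cross(
            self.w[segment], self.R[segment] @ local)

    def point_from_ref(self, p_ref: np.ndarray, segment: str) -> np.ndarray:
        """World position of a point stored in reference thorax coords."""
        return self.point(segment, local_coords(self.model, p_ref, segment))

    def landmark(self, name: str, segment: str) -> np.ndarray:
        return self.point_from_ref(
            self.model.point_ref(name, segment), segment)

    def body_omega(self, segment: str) -> np.ndarray:
        """Angular velocity in the segment's own (bone-fixed) frame."""
        return self.R[segment].T @ self.w[segment]

    def joint_axes(self) -> List[Tuple[np.ndarray, np.ndarray, int]]:
        """Per generalized coordinate: (world rotation axis, world joint
        center, joint depth).  A point on a segment of depth >= the joint
        depth moves with that coordinate."""
        out = []
        for depth, (joint, parent, child, sl, seqk, (bseg, bname)) in \
                enumerate(_CHAIN, start=1):
            seq = _joint_sequence(self.model, seqk)
            base = self.R[parent] @ self.model._align[joint]
            center = self.point_from_ref(
                self.model.point_ref(bname, bseg), bseg)
            R = _EYE
            for ax, a in zip(seq, self.q[sl]):
                out.append((base @ (R @ _UNIT[ax]), center, depth))
                R = R @ rot_axis(ax, a)
        return out


def chain_state(q, model, qd=None) -> ChainState:
    return ChainState(model, q, qd)


# ----------------------------------------------------------------------
# elbow-specific operations
# ----------------------------------------------------------------------

def alignment_rotations(model: GenericModel) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed rotations aligning the ulna frame to the humerus frame and the
    radius frame to the ulna frame, evaluated at the reference pose."""
    if not model._built:
        model.build()
    return model._align["hu"], model._align["ur"]


def elbow_rotations(q10: float, q11: float, R_h: np.ndarray,
                    model: GenericModel) -> Tuple[np.ndarray, np.ndarray]:
    """Ulna and radius world rotations for a given humerus rotation:
    R_u = R_h C_hu R_x(q10),  R_r = R_u C_ur R_z(q11)."""
    C_hu, C_ur = alignment_rotations(model)
    R_u = R_h @ C_hu @ rot_axis("x", q10)
    R_r = R_u @ C_ur @ rot_axis("z", q11)
    return R_u, R_r


def forward_elbow(q10: float, q11: float, EL: np.ndarray, EM: np.ndarray,
                  model: GenericModel,
                  R_h: Optional[np.ndarray] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Forward kinematics of the elbow: world positions of the ulnar and
    radial styloids for given elbow coordinates and epicondyle positions.

    ``R_h`` is the humerus world rotation; if omitted, the reference
    orientation rotated to match the supplied epicondyles is not inferred
    and the reference humerus orientation is used.
    """
    if not model._built:
        model.build()
    if R_h is None:
        R_h = model._ref_frames["humerus"].rotation
    EL = np.asarray(EL, float)
    EM = np.asarray(EM, float)
    HU = 0.5 * (EL + EM)
    R_u, R_r = elbow_rotations(q10, q11, R_h, model)
    us_local = local_coords(model, model.point_ref("US", "ulna"), "ulna")
    rs_local = local_coords(model, model.point_ref("RS", "radius"), "radius")
    US = R_u @ us_local + HU
    RS = R_r @ rs_local + EL
    return US, RS


# ----------------------------------------------------------------------
# ribcage (scapulothoracic) constraints
# ----------------------------------------------------------------------

def ribcage_residuals(q, model: GenericModel) -> Tuple[float, float]:
    """Implicit residuals Phi_TS, Phi_AI of the two scapula-on-ribcage
    ellipsoid constraints (0 = landmark exactly on its ellipsoid)."""
    st = ChainState(model, q)
    ts = st.landmark("TS", "scapula")
    ai = st.landmark("AI", "scapula")
    return (model.ts_ellipsoid.residual(ts),
            model.ai_ellipsoid.residual(ai))


def constraint_jacobians(q, model: GenericModel) -> np.ndarray:
    """Analytic 2 x 11 Jacobian [dPhi_TS/dq; dPhi_AI/dq].

    Uses dPhi/dq_k = 2 (p - e0)^T E (axis_k x (p - c_k)) for the joint
    axes proximal to the scapula; elbow columns are structurally zero.
    """
    st = ChainState(model, q)
    axes = st.joint_axes()
    J = np.zeros((2, N_COORDS))
    for row, (lmn, ell) in enumerate((("TS", model.ts_ellipsoid),
                                      ("AI", model.ai_ellipsoid))):
        p = st.landmark(lmn, "scapula")
        g = 2.0 * ell.quadric @ (p - ell.center)
        for k, (axis, center, depth) in enumerate(axes):
            if depth <= SEGMENT_DEPTH["scapula"]:
                J[row, k] = g @ np.cross(axis, p - center)
    return J


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

@dataclass
class JointTrajectory:
    """Sampled trajectory of the generalized coordinates with finite-
    difference derivatives."""
    times: np.ndarray
    q: np.ndarray  # (n, 11)
    qd: np.ndarray = None
    qdd: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.q = np.atleast_2d(np.asarray(self.q, float))
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.qd is None:
            self.qd, self.qdd = self._derivatives()
        self.qd = np.atleast_2d(np.asarray(self.qd, float))
        self.qdd = np.atleast_2d(np.asarray(self.qdd, float))
        if not (len(self.times) == len(self.q) == len(self.qd)
                == len(self.qdd)):
            raise ValueError("trajectory arrays must have equal length")

    def _derivatives(self):
        if len(self.times) < 2:
            z = np.zeros_like(self.q)
            return z, z.copy()
        qd = np.gradient(self.q, self.times, axis=0, edge_order=2)
        qdd = np.gradient(qd, self.times, axis=0, edge_order=2)
        return qd, qdd

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"q{i+1}_deg": np.degrees(self.q[:, i])
                for i in range(N_COORDS)}
        return pd.DataFrame({"time_s": self.times, **cols})


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def elevation_angle(st: ChainState) -> float:
    """Thoraco-humeral elevation: angle between the humeral shaft
    (HH -> HU) and the downward thorax vertical, radians."""
    hh = st.landmark("HH", "scapula")
    hu = st.landmark("HU", "humerus")
    d = _unit(hu - hh, "humeral shaft")
    return math.acos(max(-1.0, min(1.0, -d[2])))


def _scapula_upward_rotation(st: ChainState, model) -> float:
    """Signed upward-rotation angle of the scapula relative to the
    reference pose, measured about the reference scapular-plane normal."""
    n = model._ref_frames["scapula"].rotation[:, 1]  # y_s at reference
    v_ref = (model.point_ref("AA", "scapula")
             - model.point_ref("AI", "scapula"))
    v = st.landmark("AA", "scapula") - st.landmark("AI", "scapula")
    v_ref = v_ref - (v_ref @ n) * n
    v = v - (v @ n) * n
    ang = math.atan2(n @ np.cross(v_ref, v), v_ref @ v)
    # sign fixed so a positive angle raises AA (upward rotation): the tip
    # velocity of v_ref under +n rotation is n x v_ref
    return ang if np.cross(n, v_ref)[2] >= 0 else -ang


def _girdle_constraints(model, q: np.ndarray, gamma: float) -> np.ndarray:
    st = ChainState(model, q)
    phi_ts = model.ts_ellipsoid.residual(st.landmark("TS", "scapula"))
    phi_ai = model.ai_ellipsoid.residual(st.landmark("AI", "scapula"))
    rho = _scapula_upward_rotation(st, model)
    return np.array([phi_ts, phi_ai, rho - gamma])


def _project_shoulder_girdle(model, q_init: np.ndarray, gamma: float
                             ) -> np.ndarray:
    """Find clavicle/scapula coordinates q[0:6] near q_init that put TS
    and AI exactly on their ellipsoids with scapular upward rotation gamma
    (radians).

    Gauss-Newton minimum-norm projection: each step solves the linearized
    constraints with the smallest coordinate correction, which converges
    to (approximately) the closest feasible point for warm starts.
    """
    q = q_init.copy()
    h = 1e-7
    for _ in range(60):
        c = _girdle_constraints(model, q, gamma)
        if np.max(np.abs(c)) < 1e-11:
            return q[:6]
        J = np.empty((3, 6))
        for k in range(6):
            qp, qm = q.copy(), q.copy()
            qp[k] += h
            qm[k] -= h
            J[:, k] = (_girdle_constraints(model, qp, gamma)
                       - _girdle_constraints(model, qm, gamma)) / (2 * h)
        try:
            step = J.T @ np.linalg.solve(J @ J.T, c)
        except np.linalg.LinAlgError:
            break
        # damped update for robustness far from the manifold
        scale = min(1.0, 0.3 / max(np.max(np.abs(step)), 1e-12))
        q[:6] -= step * scale
    c = _girdle_constraints(model, q, gamma)
    if np.max(np.abs(c[:2])) > 1e-6:
        raise RuntimeError(
            f"shoulder-girdle constraint projection failed: Phi={c[:2]}")
    return q[:6]


def _solve_gh_elevation(model, q: np.ndarray, theta: float
                        ) -> Tuple[float, float]:
    """Solve the glenohumeral plane/elevation coordinates (q[6], q[7]) so
    the thoraco-humeral elevation equals theta (radians).

    The plane coordinate is adjusted jointly (softly regularized toward
    its warm start) because at high elevation the fixed-plane sweep of a
    tilted glenohumeral axis cannot reach the target; a 1-D bracketed
    polish on q[7] then drives the residual to machine precision.
    """
    q = q.copy()

    def elev(q6, q7):
        qq = q.copy()
        qq[6], qq[7] = q6, q7
        return elevation_angle(ChainState(model, qq))

    x0 = np.array([q[6], max(q[7], 0.1)])

    def resid(x):
        return np.array([10.0 * (elev(*x) - theta),
                         0.02 * (x[0] - q[6])])

    sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        diff_step=1e-7)
    q6, q7 = sol.x

    # bracketed polish on the elevation coordinate alone
    def f(x):
        return elev(q6, x) - theta

    if abs(f(q7)) > 1e-12:
        for half_width in (0.02, 0.1, 0.4):
            lo, hi = q7 - half_width, q7 + half_width
            if f(lo) * f(hi) <= 0:
                q7 = brentq(f, lo, hi, xtol=1e-13)
                break
    if abs(elev(q6, q7) - theta) > 1e-9:
        raise RuntimeError("cannot reach requested elevation angle")
    return q6, q7


def abduction_trajectory(start_deg: float, end_deg: float, n_steps: int,
                         duration: float, model: GenericModel,
                         rhythm_ratio: float = 2.0) -> JointTrajectory:
    """Scapular-plane abduction with a minimum-jerk elevation profile and a
    linear scapulohumeral rhythm (default 2:1 glenohumeral-to-
    scapulothoracic), projected so both ribcage constraints hold exactly at
    every step.  The elbow is held at the model's carrying posture.
    """
    if not model._built:
        model.build()
    if start_deg > end_deg:
        raise ValueError("start must not exceed end")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    s = (np.zeros(1) if n_steps == 1
         else _minimum_jerk(np.linspace(0.0, 1.0, n_steps)))
    thetas = np.radians(start_deg + (end_deg - start_deg) * s)
    times = np.linspace(0.0, duration, n_steps)

    q = np.tile(model.reference_pose, (n_steps, 1))
    q[:, 9] = model.carrying_posture[0]
    q[:, 10] = model.carrying_posture[1]
    prev = q[0].copy()
    for i, th in enumerate(thetas):
        gamma = th / (1.0 + rhythm_ratio)  # scapulothoracic share
        qi = prev.copy()
        try:
            qi[:6] = _project_shoulder_girdle(model, qi, gamma)
            qi[6], qi[7] = _solve_gh_elevation(model, qi, th)
        except RuntimeError as exc:
            raise RuntimeError(f"abduction step {i}: {exc}") from exc
        q[i] = qi
        prev = qi
    if n_steps == 1 or start_deg == end_deg:
        qd = np.zeros_like(q)
        return JointTrajectory(times, q, qd, qd.copy(),
                               meta={"abduction_deg": np.degrees(thetas)})
    return JointTrajectory(times, q,
                           meta={"abduction_deg": np.degrees(thetas)})


# ----------------------------------------------------------------------
# inverse kinematics from measured landmark trajectories
# ----------------------------------------------------------------------

def fit_landmarks(measured: pd.DataFrame, model: GenericModel,
                  constraint_weight: float = 1e4,
                  verbose: bool = False) -> Tuple[JointTrajectory, float]:
    """Per-frame least-squares fit of the generalized coordinates to
    measured landmark positions (wide CSV layout: ``time_s`` plus
    ``<LANDMARK>_x/_y/_z`` columns in metres, thorax frame).

    The ribcage constraints enter in penalty form.  Returns the fitted
    trajectory and the RMS landmark residual [m].  Frames with fewer than
    three resolvable landmarks are skipped with a warning in the metadata.
    """
    if not model._built:
        model.build()
    # map measured columns to (segment, reference position)
    targets = []
    for seg in model.segments.values():
        for lm in seg.landmarks:
            if f"{lm.name}_x" in measured.columns:
                targets.append((lm.name, seg.name,
                                local_coords(model, lm.position, seg.name)))
    times, qs, skipped = [], [], []
    sqw = math.sqrt(constraint_weight)
    x0 = model.reference_pose.copy()
    resid_sum, resid_n = 0.0, 0

    for idx, row in measured.iterrows():
        pts = []
        for name, seg, loc in targets:
            p = np.array([row[f"{name}_x"], row[f"{name}_y"],
                          row[f"{name}_z"]], float)
            if np.all(np.isfinite(p)):
                pts.append((seg, loc, p))
        if len(pts) < 3:
            skipped.append(idx)
            continue

        def residuals(x):
            st = ChainState(model, x)
            r = [st.point(seg, loc) - p for seg, loc, p in pts]
            phi = ribcage_residuals(x, model)
            return np.concatenate([np.concatenate(r),
                                   [sqw * phi[0], sqw * phi[1]]])

        sol = least_squares(residuals, x0, method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        x0 = sol.x.copy()
        times.append(float(row["time_s"]))
        qs.append(sol.x)
        r = residuals(sol.x)[:-2]
        resid_sum += float(r @ r)
        resid_n += len(r)

    if not qs:
        return (JointTrajectory(np.zeros(0), np.zeros((0, N_COORDS)),
                                np.zeros((0, N_COORDS)),
                                np.zeros((0, N_COORDS)),
                                meta={"skipped": skipped}), float("nan"))
    rms = math.sqrt(resid_sum / max(resid_n, 1))
    return (JointTrajectory(np.asarray(times), np.asarray(qs),
                            meta={"skipped": skipped, "rms_m": rms}), rms)
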