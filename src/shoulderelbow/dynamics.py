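"""Lagrangian dynamics of the five-segment chain.

The Lagrangian sums, over clavicle, scapula, humerus, ulna and radius,

    L = sum_s  1/2 (m_s v_s^T v_s + w_s^T I_s w_s)  -  m_s g [0 0 1] CG_s

with v_s the center-of-mass velocity, w_s the body-frame angular velocity,
I_s the diagonal bone-frame inertia, and gravity acting along -z of the
thorax frame.  Generalized loads follow from Lagrange's equations,

    tau_k = d/dt (dL/dqdot_k) - dL/dq_k,

evaluated by central finite differences: the velocity gradient is exact
for the quadratic kinetic energy, the time derivative is a directional
difference along (qdot, qddot), and the configuration gradient uses a
small coordinate step.  This keeps the formulation robust to any model
edit at the cost of ~1e-8 relative truncation error, far below the
tolerances used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .model_core import GRAVITY, GenericModel, N_COORDS, SEGMENT_NAMES
from .kinematics import ChainState, JointTrajectory, local_coords

_H_Q = 1e-6    # configuration-gradient step [rad]
_H_QD = 1e-3   # velocity-gradient step [rad/s]; exact for quadratic T
_H_T = 1e-6    # directional time step [s]


# ----------------------------------------------------------------------
# state-level quantities
# ----------------------------------------------------------------------

def segment_com(q, model: GenericModel) -> Dict[str, np.ndarray]:
    """World centers of mass of the five segments at configuration q."""
    st = ChainState(model, q)
    return {name: st.point(name, model.segments[name]._com_local)
            for name in SEGMENT_NAMES}


def segment_com_velocities(q, qd, model: GenericModel
                           ) -> Dict[str, np.ndarray]:
    st = ChainState(model, q, qd)
    return {name: st.point_velocity(name, model.segments[name]._com_local)
            for name in SEGMENT_NAMES}


def angular_velocities(q, qd, model: GenericModel) -> Dict[str, np.ndarray]:
    """Body-frame angular velocities of the five segments."""
    st = ChainState(model, q, qd)
    return {name: st.body_omega(name) for name in SEGMENT_NAMES}


def kinetic_energy(q, qd, model: GenericModel) -> float:
    st = ChainState(model, q, qd)
    T = 0.0
    for name in SEGMENT_NAMES:
        seg = model.segments[name]
        v = st.point_velocity(name, seg._com_local)
        w = st.body_omega(name)
        T += 0.5 * (seg.mass * v @ v + w @ (seg.inertia_diag * w))
    return float(T)


def potential_energy(q, model: GenericModel) -> float:
    st = ChainState(model, q)
    V = 0.0
    for name in SEGMENT_NAMES:
        seg = model.segments[name]
        V += seg.mass * GRAVITY * st.point(name, seg._com_local)[2]
    return float(V)


def lagrangian(q, qd, model: GenericModel) -> float:
    """Augmented Lagrangian of the shoulder-elbow chain, L = T - V [J]."""
    return kinetic_energy(q, qd, model) - potential_energy(q, model)


# ----------------------------------------------------------------------
# generalized loads
# ----------------------------------------------------------------------

@dataclass
class GeneralizedLoads:
    """Left-hand side of the equations of motion for one frame, with the
    gravitational/inertial split (inertial ~ 0 for a static pose)."""
    tau: np.ndarray
    gravitational: np.ndarray
    inertial: np.ndarray
    time: float = 0.0


def _grad_V(q, model) -> np.ndarray:
    g = np.empty(N_COORDS)
    for k in range(N_COORDS):
        qp, qm = q.copy(), q.copy()
        qp[k] += _H_Q
        qm[k] -= _H_Q
        g[k] = (potential_energy(qp, model)
                - potential_energy(qm, model)) / (2 * _H_Q)
    return g


def _grad_T_q(q, qd, model) -> np.ndarray:
    g = np.empty(N_COORDS)
    for k in range(N_COORDS):
        qp, qm = q.copy(), q.copy()
        qp[k] += _H_Q
        qm[k] -= _H_Q
        g[k] = (kinetic_energy(qp, qd, model)
                - kinetic_energy(qm, qd, model)) / (2 * _H_Q)
    return g


def generalized_momentum(q, qd, model) -> np.ndarray:
    """p = dL/dqdot = dT/dqdot (central difference; exact for quadratic
    kinetic energy up to round-off)."""
    p = np.empty(N_COORDS)
    for k in range(N_COORDS):
        dp, dm = qd.copy(), qd.copy()
        dp[k] += _H_QD
        dm[k] -= _H_QD
        p[k] = (kinetic_energy(q, dp, model)
                - kinetic_energy(q, dm, model)) / (2 * _H_QD)
    return p


def generalized_loads(q, qd, qdd, model: GenericModel,
                      time: float = 0.0) -> GeneralizedLoads:
    """tau = d/dt(dL/dqdot) - dL/dq for one state, with the time
    derivative taken along the trajectory direction (qd, qdd)."""
    q = np.asarray(q, float)
    qd = np.asarray(qd, float)
    qdd = np.asarray(qdd, float)
    p_plus = generalized_momentum(q + _H_T * qd, qd + _H_T * qdd, model)
    p_minus = generalized_momentum(q - _H_T * qd, qd - _H_T * qdd, model)
    dp_dt = (p_plus - p_minus) / (2 * _H_T)
    grav = _grad_V(q, model)
    inertial = dp_dt - _grad_T_q(q, qd, model)
    return GeneralizedLoads(inertial + grav, grav, inertial, time)


def inverse_dynamics(traj: JointTrajectory, model: GenericModel
                     ) -> List[GeneralizedLoads]:
    """Generalized loads along a trajectory (one entry per frame)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return [generalized_loads(traj.q[i], traj.qd[i], traj.qdd[i], model,
                              time=traj.times[i])
            for i in range(len(traj))]


def com_accelerations(q, qd, qdd, model: GenericModel
                      ) -> Dict[str, np.ndarray]:
    """World center-of-mass accelerations by directional differencing of
    the velocity map along (qd, qdd)."""
    vp = segment_com_velocities(q + _H_T * qd, qd + _H_T * qdd, model)
    vm = segment_com_velocities(q - _H_T * qd, qd - _H_T * qdd, model)
    return {k: (vp[k] - vm[k]) / (2 * _H_T) for k in vp}


# ----------------------------------------------------------------------
# hand
# ----------------------------------------------------------------------

def add_hand_inertia(model: GenericModel) -> GenericModel:
    """Fold the hand (point mass + inertia block rigidly tied to the
    radius) into the radius segment via the parallel-axis theorem.

    The hand center of mass is placed distally along the forearm axis,
    one third of the elbow-to-wrist chord beyond the wrist midpoint.  Only
    the diagonal of the shifted inertia tensor is kept (the offset is
    nearly axial in the radius frame, so off-diagonal terms are small).
    Returns a rebuilt copy; the original model is untouched.
    """
    m = model.copy()
    m.build()
    if m.hand_mass <= 0:
        return m
    radius = m.segments["radius"]
    wrist = 0.5 * (m.point_ref("US", "ulna") + m.point_ref("RS", "radius"))
    elbow = m.point_ref("EL", "humerus")
    hand_com_ref = wrist + (wrist - elbow) / 3.0

    m_r, m_h = radius.mass, m.hand_mass
    total = m_r + m_h
    com_new = (m_r * radius.com_ref + m_h * hand_com_ref) / total

    R = m._ref_frames["radius"].rotation
    d_r = R.T @ (radius.com_ref - com_new)
    d_h = R.T @ (hand_com_ref - com_new)
    shift = lambda mass, d: mass * ((d @ d) * np.ones(3) - d ** 2)
    radius.inertia_diag = (radius.inertia_diag + shift(m_r, d_r)
                           + m.hand_inertia + shift(m_h, d_h))
    radius.mass = total
    radius.com_ref = com_new
    m.hand_mass = 0.0
    m.hand_inertia = np.zeros(3)
    m._built = False
    m.build()
    return m
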