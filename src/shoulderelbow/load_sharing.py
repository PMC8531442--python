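"""Static-optimization load sharing and glenohumeral joint reaction force.

Per frame of a motion, the over-actuated equations of motion

    tau = [ W   dPhi_TS/dq   dPhi_AI/dq ] f~,     f~ = [f^T  l_TS  l_AI]^T

are solved for the muscle-string tensions f and the two ribcage constraint
multipliers by minimizing the sum of squared muscle stresses f~^T P f~
(P diagonal, inverse squared PCSAs; a tiny regularization weight on the
multiplier entries keeps the objective strictly convex) subject to

* the 11 equality rows above,
* bounds 0 <= f <= sigma * PCSA (the maximum-stress force bound) and
  l_TS, l_AI >= 0 (the ribcage can only push),
* the glenohumeral stability constraint: the joint reaction force must
  point into a cone whose apex sits at the humeral head center and whose
  axis passes through the glenoid center; the cone is linearized into
  polyhedral facets so the problem remains a quadratic program.

The QP is solved in two stages: a feasibility phase (warm start from the
previous frame when available, otherwise bounded least squares or
trust-constr) followed by a primal active-set iteration with exact KKT
solves that terminates at the analytic optimum of the strictly convex
program (stationarity ~1e-12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, minimize

from .model_core import (GRAVITY, GenericModel, Muscle, N_COORDS,
                         SEGMENT_DEPTH)
from .kinematics import (ChainState, JointTrajectory, constraint_jacobians,
                         elevation_angle)
from .dynamics import com_accelerations, generalized_loads
from .muscle_paths import muscle_path

#: default maximum muscle stress [N/cm^2] used for the force upper bound
DEFAULT_SIGMA = 25.0
_LAMBDA_WEIGHT = 1e-9
_ARM_SEGMENTS = ("humerus", "ulna", "radius")


def max_forces(pcsa: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Maximum-stress force bounds f_max = sigma * PCSA (elementwise)."""
    pcsa = np.asarray(pcsa, float)
    if np.any(pcsa <= 0) or sigma <= 0:
        raise ValueError("PCSA values and sigma must be positive")
    return sigma * pcsa


# ----------------------------------------------------------------------
# stability cone
# ----------------------------------------------------------------------

@dataclass
class StabilityCone:
    """Linearized glenohumeral stability cone.

    A reaction force v is admissible when angle(v, axis) <= half_angle,
    encoded as ``normals @ v <= 0`` with inscribed-polyhedron facet
    normals ``n_i = u_i cos(theta) - axis sin(theta)``.
    """
    apex: np.ndarray
    axis: np.ndarray
    half_angle: float  # deg
    normals: np.ndarray  # (m, 3)

    def violation(self, v: np.ndarray) -> float:
        """Largest facet violation (<= 0 means inside)."""
        return float(np.max(self.normals @ v))


def build_stability_cone(model: GenericModel,
                         state: Optional[ChainState] = None,
                         n_facets: int = 8) -> StabilityCone:
    """Cone from the (possibly re-oriented) glenoid: apex at the humeral
    head center, axis through the glenoid center, aperture from the rim
    points' angular extents about the axis (mean over the rim)."""
    if n_facets < 4:
        raise ValueError("cone linearization needs >= 4 facets")
    if state is None:
        if not model._built:
            model.build()
        apex = model.point_ref("HH", "scapula")
        gc = model.glenoid.GC.position
        rim = [lm.position for lm in model.glenoid.rim()]
    else:
        apex = state.landmark("HH", "scapula")
        gc = state.point_from_ref(model.glenoid.GC.position, "scapula")
        rim = [state.point_from_ref(lm.position, "scapula")
               for lm in model.glenoid.rim()]
    axis = gc - apex
    na = np.linalg.norm(axis)
    if na < 1e-9:
        raise ValueError("degenerate glenoid: GC coincides with the "
                         "humeral head center")
    axis = axis / na
    if model.glenoid.cone_half_angle is not None:
        theta = math.radians(model.glenoid.cone_half_angle)
    else:
        angs = []
        for p in rim:
            v = p - apex
            nv = np.linalg.norm(v)
            if nv < 1e-9:
                raise ValueError("degenerate glenoid rim point at apex")
            angs.append(math.acos(max(-1.0, min(1.0, (v @ axis) / nv))))
        theta = float(np.mean(angs))
    # orthonormal basis perpendicular to the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    phis = np.linspace(0.0, 2 * math.pi, n_facets, endpoint=False)
    normals = np.stack([
        (math.cos(p) * u + math.sin(p) * v) * math.cos(theta)
        - axis * math.sin(theta) for p in phis])
    return StabilityCone(apex, axis, math.degrees(theta), normals)


# ----------------------------------------------------------------------
# per-frame muscle mechanics
# ----------------------------------------------------------------------

@dataclass
class FrameMechanics:
    """Everything the load-sharing QP needs at one configuration."""
    W: np.ndarray            # (11, n_strings) generalized moment arms
    B: np.ndarray            # (3, n_strings) unit-tension force on the arm
    J_con: np.ndarray        # (2, 11) ribcage constraint Jacobian
    pcsa: np.ndarray         # per string [cm^2]
    names: List[str]
    cone: StabilityCone
    jrf_passive: np.ndarray  # (3,) gravity/inertia part of the JRF


def frame_mechanics(q, qd, qdd, model: GenericModel,
                    n_facets: int = 8) -> FrameMechanics:
    """Assemble moment arms, arm-side unit force vectors, constraint
    Jacobian, stability cone and passive joint load at one state."""
    st = ChainState(model, q)
    axes = st.joint_axes()
    arm_depth = SEGMENT_DEPTH["humerus"]
    cols_W, cols_B, pcsa, names = [], [], [], []
    for mus in model.muscles:
        path = muscle_path(q, mus, model, state=st, n_arc=24)
        pts = path.points
        n = len(pts)
        forces = np.zeros_like(pts)
        for i in range(n):
            if i > 0:
                d = pts[i - 1] - pts[i]
                L = np.linalg.norm(d)
                if L > 1e-12:
                    forces[i] += d / L
            if i < n - 1:
                d = pts[i + 1] - pts[i]
                L = np.linalg.norm(d)
                if L > 1e-12:
                    forces[i] += d / L
        depths = np.array([SEGMENT_DEPTH[a] for a in path.attach])
        w = np.zeros(N_COORDS)
        for k, (axis, center, depth) in enumerate(axes):
            mask = depths >= depth
            if np.any(mask):
                r = pts[mask] - center
                w[k] = float(np.einsum(
                    "ij,ij->",
                    np.cross(np.broadcast_to(axis, r.shape), r),
                    forces[mask]))
        b = forces[depths >= arm_depth].sum(axis=0)
        for _ in range(mus.n_strings):
            cols_W.append(w)
            cols_B.append(b)
            pcsa.append(mus.pcsa / mus.n_strings)
            names.append(mus.name)

    J_con = constraint_jacobians(q, model)
    cone = build_stability_cone(model, state=st, n_facets=n_facets)

    acc = com_accelerations(q, qd, qdd, model)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    passive = np.zeros(3)
    for seg in _ARM_SEGMENTS:
        mseg = model.segments[seg].mass
        passive += mseg * (g_vec - acc[seg])
    return FrameMechanics(np.column_stack(cols_W), np.column_stack(cols_B),
                          J_con, np.asarray(pcsa), names, cone, passive)


# ----------------------------------------------------------------------
# QP
# ----------------------------------------------------------------------

@dataclass
class LoadSharingSolution:
    """Muscle-string tensions plus the two ribcage multipliers, with QP
    diagnostics and the resulting glenohumeral reaction force."""
    f: np.ndarray            # (n_strings,) [N]
    lambda_ts: float
    lambda_ai: float
    objective: float
    equality_residual: float
    kkt_residual: float
    status: str
    jrf: np.ndarray = field(default_factory=lambda: np.zeros(3))
    names: List[str] = field(default_factory=list)

    @property
    def f_tilde(self) -> np.ndarray:
        return np.concatenate([self.f, [self.lambda_ts, self.lambda_ai]])


def solve_qp(H: np.ndarray, A_eq: np.ndarray, b_eq: np.ndarray,
             lb: np.ndarray, ub: np.ndarray,
             C: Optional[np.ndarray] = None,
             d: Optional[np.ndarray] = None,
             x_warm: Optional[np.ndarray] = None
             ) -> Tuple[np.ndarray, str]:
    """Minimize x^T H x subject to A_eq x = b_eq, lb <= x <= ub and
    optional C x <= d (H diagonal positive).

    With a warm start the active-set KKT iteration is tried directly
    (one or two linear solves when the active set barely changes between
    frames); otherwise trust-constr solves the convex program and the
    active-set step polishes away the interior-point smoothing so
    stationarity holds to ~1e-10.
    """
    Hd = np.diag(H) if H.ndim == 2 else np.asarray(H, float)
    n = len(Hd)
    x = None
    ok = False
    if x_warm is not None:
        x0 = _restore_feasibility(A_eq, b_eq, lb, ub, C, d,
                                  np.clip(x_warm, lb, ub))
        if x0 is not None:
            x = _primal_active_set(Hd, A_eq, b_eq, lb, ub, C, d, x0)
            ok = x is not None
    if x is None:
        # cold start: phase-1 from the origin, then the active-set stage
        x0 = _restore_feasibility(A_eq, b_eq, lb, ub, C, d,
                                  np.clip(np.zeros(n), lb, ub))
        if x0 is not None:
            x = _primal_active_set(Hd, A_eq, b_eq, lb, ub, C, d, x0)
            ok = x is not None
    if x is None:
        x0 = np.clip(np.zeros(n), lb, np.minimum(ub, 1.0))
        constraints = [LinearConstraint(A_eq, b_eq, b_eq)]
        if C is not None and len(C):
            constraints.append(LinearConstraint(C, -np.inf, d))
        res = minimize(lambda x: x @ (Hd * x), x0,
                       jac=lambda x: 2 * Hd * x,
                       hess=lambda x: np.diag(2 * Hd),
                       method="trust-constr", constraints=constraints,
                       bounds=Bounds(lb, ub),
                       options={"gtol": 1e-9, "xtol": 1e-12,
                                "maxiter": 500, "verbose": 0})
        xr = _restore_feasibility(A_eq, b_eq, lb, ub, C, d,
                                  np.clip(res.x, lb, ub))
        x_as = (None if xr is None
                else _primal_active_set(Hd, A_eq, b_eq, lb, ub, C, d, xr))
        if x_as is not None:
            x = x_as
            ok = True
        else:
            x = np.clip(res.x, lb, ub)
            ok = res.status in (1, 2)
    if np.max(np.abs(A_eq @ x - b_eq)) > 1e-6:
        viol = np.argmax(np.abs(A_eq @ x - b_eq))
        return x, (f"infeasible: equality row {viol} residual "
                   f"{(A_eq @ x - b_eq)[viol]:.2e}")
    return x, "optimal" if ok else f"qp:{res.message}"


def _restore_feasibility(A_eq, b_eq, lb, ub, C, d, x,
                         iters: int = 6) -> Optional[np.ndarray]:
    """Phase-1: a single bounded least-squares solve of the equality rows
    augmented with slacked inequality rows (C x + s = d, s >= 0), seeded
    at the warm start.  A zero residual is a feasible point; otherwise
    the program is (numerically) infeasible and None is returned."""
    from scipy.optimize import lsq_linear
    n = len(x)
    x = np.clip(x, lb, ub)
    eq_ok = np.max(np.abs(A_eq @ x - b_eq)) < 1e-10
    if eq_ok and (C is None or not len(C) or np.all(C @ x <= d + 1e-10)):
        return x
    if C is not None and len(C):
        m = len(C)
        A = np.block([[A_eq, np.zeros((A_eq.shape[0], m))],
                      [C, np.eye(m)]])
        b = np.concatenate([b_eq, d])
        lo = np.concatenate([lb - x, np.zeros(m)])
        hi = np.concatenate([ub - x, np.full(m, np.inf)])
        shift = np.concatenate([x, np.zeros(m)])
        res = lsq_linear(A, b - A @ shift, bounds=(lo, hi),
                         tol=1e-14, lsq_solver="exact")
        y = np.clip(x + res.x[:n], lb, ub)
        if np.max(np.abs(A_eq @ y - b_eq)) < 1e-9 \
                and np.all(C @ y <= d + 1e-8):
            return y
        return None
    res = lsq_linear(A_eq, b_eq - A_eq @ x, bounds=(lb - x, ub - x),
                     tol=1e-14, lsq_solver="exact")
    y = np.clip(x + res.x, lb, ub)
    return y if np.max(np.abs(A_eq @ y - b_eq)) < 1e-9 else None


def _primal_active_set(Hd, A_eq, b_eq, lb, ub, C, d, x,
                       max_iter: int = 300) -> Optional[np.ndarray]:
    """Primal active-set method for min x^T diag(Hd) x with equality,
    box, and optional one-sided linear constraints, started at a feasible
    point.  Terminates at the exact KKT point of the strictly convex
    program; returns None only if the iteration cap is hit.
    """
    n = len(x)
    # inequality rows in g . x <= r form
    rows: List[np.ndarray] = []
    rhs: List[float] = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(-e)
        rhs.append(-lb[i])
        if np.isfinite(ub[i]):
            rows.append(e)
            rhs.append(ub[i])
    if C is not None and len(C):
        for row, r in zip(C, d):
            rows.append(np.asarray(row, float))
            rhs.append(float(r))
    G_in = np.stack(rows)
    r_in = np.asarray(rhs)
    m_eq = A_eq.shape[0]

    slack = r_in - G_in @ x
    working = list(np.where(slack < 1e-9)[0])

    for _ in range(max_iter):
        G = np.vstack([A_eq, G_in[working]]) if working else A_eq
        g = np.concatenate([b_eq, r_in[working]]) if working else b_eq
        k = G.shape[0]
        KKT = np.zeros((n + k, n + k))
        KKT[:n, :n] = np.diag(2 * Hd)
        KKT[:n, n:] = G.T
        KKT[n:, :n] = G
        try:
            sol = np.linalg.solve(KKT, np.concatenate([np.zeros(n), g]))
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(KKT, np.concatenate([np.zeros(n), g]),
                                  rcond=None)[0]
        y, nu = sol[:n], sol[n:]
        p = y - x
        if np.max(np.abs(p)) < 1e-12:
            mult = nu[m_eq:]
            if len(mult) == 0 or np.min(mult) >= -1e-10:
                return y
            j = int(np.argmin(mult))
            working.pop(j)
            continue
        # largest feasible step toward y
        alpha = 1.0
        blocker = -1
        for i in range(len(G_in)):
            if i in working:
                continue
            gp = G_in[i] @ p
            if gp > 1e-13:
                a_i = (r_in[i] - G_in[i] @ x) / gp
                if a_i < alpha - 1e-14:
                    alpha = max(a_i, 0.0)
                    blocker = i
        x = x + alpha * p
        if blocker >= 0:
            working.append(blocker)
    return None


def kkt_residual(Hd, A_eq, b_eq, lb, ub, C, d, x,
                 tol_act: float = 1e-7) -> float:
    """Stationarity residual of a candidate QP solution: the norm of the
    objective gradient projected on the free subspace (active constraint
    gradients removed by least squares)."""
    grad = 2 * Hd * x
    rows = [A_eq]
    n = len(x)
    for i in range(n):
        if x[i] - lb[i] < tol_act * max(1.0, abs(lb[i]) + 1.0) \
                or ub[i] - x[i] < tol_act * max(1.0, abs(ub[i])):
            e = np.zeros(n)
            e[i] = 1.0
            rows.append(e[None, :])
    if C is not None and len(C):
        act = d - C @ x < tol_act
        if act.any():
            rows.append(C[act])
    G = np.vstack(rows)
    coef, *_ = np.linalg.lstsq(G.T, grad, rcond=None)
    return float(np.linalg.norm(grad - G.T @ coef, np.inf))


def solve_frame(tau: np.ndarray, mech: FrameMechanics,
                sigma: float = DEFAULT_SIGMA,
                use_cone: bool = True,
                x_warm: Optional[np.ndarray] = None
                ) -> LoadSharingSolution:
    """Load-sharing QP for one frame given its generalized loads."""
    tau = np.asarray(tau, float).reshape(N_COORDS)
    n = mech.W.shape[1]
    A_eq = np.hstack([mech.W, mech.J_con.T])  # (11, n+2)
    fmax = max_forces(mech.pcsa, sigma)
    lb = np.zeros(n + 2)
    ub = np.concatenate([fmax, [np.inf, np.inf]])
    Hd = np.concatenate([1.0 / mech.pcsa ** 2,
                         [_LAMBDA_WEIGHT, _LAMBDA_WEIGHT]])
    C = d = None
    if use_cone:
        # facet rows on JRF(f) = B f + passive
        C = np.hstack([mech.cone.normals @ mech.B, np.zeros((len(
            mech.cone.normals), 2))])
        d = -(mech.cone.normals @ mech.jrf_passive)
    x, status = solve_qp(Hd, A_eq, tau, lb, ub, C, d, x_warm=x_warm)
    f = x[:n]
    jrf = mech.B @ f + mech.jrf_passive
    sol = LoadSharingSolution(
        f=f, lambda_ts=float(x[n]), lambda_ai=float(x[n + 1]),
        objective=float(x @ (Hd * x)),
        equality_residual=float(np.max(np.abs(A_eq @ x - tau))),
        kkt_residual=kkt_residual(Hd, A_eq, tau, lb, ub, C, d, x),
        status=status, jrf=jrf, names=mech.names)
    return sol


def joint_reaction_force(solution: LoadSharingSolution,
                         mech: FrameMechanics) -> np.ndarray:
    """Glenohumeral reaction force [N]: the force the humeral head applies
    on the glenoid, assembled by Newton-Euler back-substitution over the
    arm segments (muscle pulls on humerus/ulna/radius plus their
    gravitational and inertial loads)."""
    return mech.B @ solution.f + mech.jrf_passive


# ----------------------------------------------------------------------
# abduction pipeline
# ----------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Per-frame outputs of a full inverse-dynamics + load-sharing run."""
    trajectory: JointTrajectory
    abduction_deg: np.ndarray
    tau: np.ndarray            # (n, 11)
    solutions: List[LoadSharingSolution]
    body_weight: float         # N

    @property
    def jrf(self) -> np.ndarray:
        return np.stack([s.jrf for s in self.solutions])

    @property
    def jrf_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.jrf, axis=1)

    @property
    def jrf_percent_bw(self) -> np.ndarray:
        return 100.0 * self.jrf_magnitude / self.body_weight

    def to_frame(self) -> pd.DataFrame:
        names = self.solutions[0].names
        data = {"abduction_deg": self.abduction_deg,
                "time_s": self.trajectory.times}
        F = np.stack([s.f for s in self.solutions])
        # collapse strings of the same muscle group
        seen = {}
        for j, nm in enumerate(names):
            seen.setdefault(nm, []).append(j)
        for nm, idx in seen.items():
            data[f"F_{nm}_N"] = F[:, idx].sum(axis=1)
        data["lambda_TS"] = [s.lambda_ts for s in self.solutions]
        data["lambda_AI"] = [s.lambda_ai for s in self.solutions]
        jrf = self.jrf
        data["JRF_x_N"] = jrf[:, 0]
        data["JRF_y_N"] = jrf[:, 1]
        data["JRF_z_N"] = jrf[:, 2]
        data["JRF_N"] = self.jrf_magnitude
        data["JRF_pct_BW"] = self.jrf_percent_bw
        return pd.DataFrame(data)


def simulate_abduction(model: GenericModel, traj: JointTrajectory,
                       sigma: float = DEFAULT_SIGMA, use_cone: bool = True,
                       n_facets: int = 8) -> SimulationResult:
    """Full per-frame pipeline: inverse dynamics, muscle mechanics,
    load-sharing QP and joint reaction force along a trajectory."""
    from .dynamics import add_hand_inertia
    mdl = add_hand_inertia(model)
    n = len(traj)
    taus = np.empty((n, N_COORDS))
    sols: List[LoadSharingSolution] = []
    abd = np.empty(n)
    x_warm = None
    for i in range(n):
        q, qd, qdd = traj.q[i], traj.qd[i], traj.qdd[i]
        try:
            gl = generalized_loads(q, qd, qdd, mdl, time=traj.times[i])
            mech = frame_mechanics(q, qd, qdd, mdl, n_facets=n_facets)
            sol = solve_frame(gl.tau, mech, sigma=sigma, use_cone=use_cone,
                              x_warm=x_warm)
            x_warm = sol.f_tilde
        except Exception as exc:
            raise RuntimeError(f"abduction frame {i}: {exc}") from exc
        taus[i] = gl.tau
        sols.append(sol)
        abd[i] = math.degrees(elevation_angle(ChainState(mdl, q)))
    bw = model.anthropometry_generic.weight * GRAVITY
    return SimulationResult(traj, abd, taus, sols, bw)
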