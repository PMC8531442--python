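"""Obstacle-set muscle paths and moment arms.

Muscles are massless elastic strings routed origin -> via points ->
insertion.  Within one gap between consecutive fixed points at most one
analytic obstacle (sphere or cylinder) may act, following the classic
single-obstacle construction: straight tangent segments joined by a
geodesic arc, C1-continuous at the tangent points, engaged exactly when
the straight chord penetrates the obstacle.

Moment arms are available by two independent definitions:

* tendon excursion: W[k, j] = -dL_j/dq_k by central differences of the
  path length;
* geometric: the generalized force of a unit-tension string, summing
  r x f contributions of the forces the string applies at its path points
  (including arc points, attached to the obstacle's segment) about each
  joint axis.

The two agree to well under 1% on smooth paths, which the model exposes
as a built-in cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (GenericModel, Muscle, N_COORDS, SEGMENT_DEPTH,
                         WrappingObject)
from .kinematics import ChainState, local_coords

_TWO_PI = 2.0 * math.pi


@dataclass
class PolylinePath:
    """Discretized muscle path: world points, the segment each point is
    attached to, and the exact geometric length (tangent segments plus
    analytic arc lengths, not the polyline chord sum)."""
    points: np.ndarray  # (k, 3)
    attach: List[str]
    length: float
    wrapped: bool = False

    @property
    def straight_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


# ----------------------------------------------------------------------
# planar tangent geometry
# ----------------------------------------------------------------------

def _circle_tangent_point(P: np.ndarray, r: float, s: int) -> float:
    """Angle of the tangent point on a circle of radius r (origin center)
    for a line through external point P, such that travel continues around
    the circle with circulation sign s (+1 ccw / -1 cw) after leaving P."""
    d = np.hypot(P[0], P[1])
    phi = math.atan2(P[1], P[0])
    alpha = math.acos(min(1.0, r / d))
    # two candidates; pick the one whose circle tangent (direction s)
    # points away from P, i.e. aligns with Q - P
    best, best_dot = None, -np.inf
    for sign in (+1.0, -1.0):
        psi = phi + sign * alpha
        Q = r * np.array([math.cos(psi), math.sin(psi)])
        t = s * np.array([-math.sin(psi), math.cos(psi)])
        dot = (Q - P) @ t
        if dot > best_dot:
            best, best_dot = psi, dot
    return best


def _seg_dist_to_origin(P1: np.ndarray, P2: np.ndarray) -> float:
    d = P2 - P1
    L2 = d @ d
    t = 0.0 if L2 == 0 else -float(P1 @ d) / L2
    t = min(1.0, max(0.0, t))
    return float(np.hypot(*(P1 + t * d)))


def _wrap_2d(P1: np.ndarray, P2: np.ndarray, r: float, s: int
             ) -> Tuple[float, float, float, float, float]:
    """Planar circle wrap: returns (psi1, psi2, arc_angle, L1, L2) for
    tangent points at angles psi1/psi2 and straight tangent lengths L1/L2.
    """
    psi1 = _circle_tangent_point(P1, r, s)
    # leaving the circle toward P2 reverses the role: travel *into* P2
    psi2 = _circle_tangent_point(P2, r, -s)
    dpsi = (s * (psi2 - psi1)) % _TWO_PI
    Q1 = r * np.array([math.cos(psi1), math.sin(psi1)])
    Q2 = r * np.array([math.cos(psi2), math.sin(psi2)])
    return (psi1, psi2, dpsi, float(np.linalg.norm(Q1 - P1)),
            float(np.linalg.norm(P2 - Q2)))


# ----------------------------------------------------------------------
# sphere and cylinder obstacles (world coordinates)
# ----------------------------------------------------------------------

def wrap_sphere(p1: np.ndarray, p2: np.ndarray, center: np.ndarray,
                radius: float, n_arc: int = 16,
                muscle: str = "?") -> Tuple[np.ndarray, float, bool]:
    """Single-sphere obstacle wrap.

    The wrap plane contains both endpoints and the center, so the arc is a
    great-circle geodesic; the shorter circulation is taken (a sphere has
    no preferred side).  Returns (arc points excluding endpoints, exact
    path length, engaged flag).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    v1 = p1 - center
    v2 = p2 - center
    for v, tag in ((v1, "origin-side"), (v2, "insertion-side")):
        if np.linalg.norm(v) < radius - 1e-12:
            raise ValueError(f"muscle {muscle}: {tag} endpoint inside "
                             "wrapping sphere")
    if _point_seg_dist(center, p1, p2) >= radius:
        return np.zeros((0, 3)), float(np.linalg.norm(p2 - p1)), False

    ez = np.cross(v1, v2)
    nz = np.linalg.norm(ez)
    if nz < 1e-14:  # endpoints collinear with center: degenerate plane
        return np.zeros((0, 3)), float(np.linalg.norm(p2 - p1)), False
    ez /= nz
    ex = v1 / np.linalg.norm(v1)
    ey = np.cross(ez, ex)
    P1 = np.array([v1 @ ex, v1 @ ey])
    P2 = np.array([v2 @ ex, v2 @ ey])

    best = None
    for s in (+1, -1):
        psi1, psi2, dpsi, L1, L2 = _wrap_2d(P1, P2, radius, s)
        if best is None or dpsi < best[3]:
            best = (s, psi1, psi2, dpsi, L1, L2)
    s, psi1, psi2, dpsi, L1, L2 = best
    length = L1 + radius * dpsi + L2
    angles = psi1 + s * dpsi * np.linspace(0.0, 1.0, n_arc)
    arc = np.stack([center + radius * (math.cos(a) * ex + math.sin(a) * ey)
                    for a in angles])
    return arc, float(length), True


def wrap_cylinder(p1: np.ndarray, p2: np.ndarray, center: np.ndarray,
                  axis: np.ndarray, radius: float, side: str = "right",
                  n_arc: int = 16, muscle: str = "?"
                  ) -> Tuple[np.ndarray, float, bool]:
    """Single-cylinder obstacle wrap (infinite cylinder).

    Tangents are found in the cross-sectional projection; the axial
    coordinate is distributed along the developed (unrolled) path, giving
    the standard helical arc.  ``side`` selects the circulation in the
    obstacle frame ('left' = counterclockwise about the axis).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    ex = np.cross(axis, ref)
    ex /= np.linalg.norm(ex)
    ey = np.cross(axis, ex)

    def to2d(p):
        v = p - center
        return np.array([v @ ex, v @ ey]), float(v @ axis)

    P1, z1 = to2d(p1)
    P2, z2 = to2d(p2)
    for P, tag in ((P1, "origin-side"), (P2, "insertion-side")):
        if np.hypot(*P) < radius - 1e-12:
            raise ValueError(f"muscle {muscle}: {tag} endpoint inside "
                             "wrapping cylinder")
    if _seg_dist_to_origin(P1, P2) >= radius:
        return np.zeros((0, 3)), float(np.linalg.norm(p2 - p1)), False

    s = +1 if side == "left" else -1
    psi1, psi2, dpsi, L1, L2 = _wrap_2d(P1, P2, radius, s)
    arc2d = radius * dpsi
    developed = L1 + arc2d + L2
    if developed < 1e-12:
        return np.zeros((0, 3)), float(np.linalg.norm(p2 - p1)), False
    dz = z2 - z1
    length = math.hypot(developed, dz)
    za = z1 + dz * L1 / developed
    zb = z1 + dz * (L1 + arc2d) / developed
    ts = np.linspace(0.0, 1.0, n_arc)
    arc = np.stack([
        center + radius * (math.cos(psi1 + s * dpsi * t) * ex
                           + math.sin(psi1 + s * dpsi * t) * ey)
        + (za + (zb - za) * t) * axis
        for t in ts])
    return arc, float(length), True


def _point_seg_dist(c, a, b) -> float:
    d = b - a
    L2 = float(d @ d)
    t = 0.0 if L2 == 0 else float((c - a) @ d) / L2
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(a + t * d - c))


# ----------------------------------------------------------------------
# full muscle path
# ----------------------------------------------------------------------

def muscle_path(q, muscle: Muscle, model: GenericModel,
                state: Optional[ChainState] = None,
                n_arc: int = 16) -> PolylinePath:
    """World-space path of one muscle string at configuration q."""
    st = state if state is not None else ChainState(model, q)
    fixed = [(lm.frame, st.point_from_ref(lm.position, lm.frame))
             for lm in muscle.fixed_points]
    wrap_by_gap = {}
    for wname, gap in muscle.wraps:
        wrap_by_gap[gap] = model.wrap_object(wname)

    points: List[np.ndarray] = [fixed[0][1]]
    attach: List[str] = [fixed[0][0]]
    total = 0.0
    wrapped_any = False
    for gap in range(len(fixed) - 1):
        pa = points[-1]
        seg_b, pb = fixed[gap + 1]
        if gap in wrap_by_gap:
            w = wrap_by_gap[gap]
            c = st.point_from_ref(w.center, w.attached_segment)
            if w.kind == "sphere":
                arc, L, engaged = wrap_sphere(pa, pb, c, w.radius,
                                              n_arc, muscle.name)
            else:
                ax_ref = w.center + w.axis
                ax = (st.point_from_ref(ax_ref, w.attached_segment) - c)
                arc, L, engaged = wrap_cylinder(pa, pb, c, ax, w.radius,
                                                w.wrap_side, n_arc,
                                                muscle.name)
            if engaged:
                wrapped_any = True
                for p in arc:
                    points.append(p)
                    attach.append(w.attached_segment)
            total += L
        else:
            total += float(np.linalg.norm(pb - pa))
        points.append(pb)
        attach.append(seg_b)
    return PolylinePath(np.stack(points), attach, total, wrapped_any)


def path_length(q, muscle: Muscle, model: GenericModel,
                state: Optional[ChainState] = None) -> float:
    return muscle_path(q, muscle, model, state=state, n_arc=2).length


# ----------------------------------------------------------------------
# moment arms
# ----------------------------------------------------------------------

@dataclass
class MomentArmMatrix:
    """Generalized moment arms W (n_coords x n_muscles) [m]: the
    generalized force per unit string tension on each coordinate."""
    W: np.ndarray
    method: str
    muscle_names: List[str] = field(default_factory=list)


def _excursion_column(q, muscle, model, dq: float) -> np.ndarray:
    col = np.zeros(N_COORDS)
    for k in muscle.spanned_coordinates():
        qp, qm = q.copy(), q.copy()
        qp[k] += dq
        qm[k] -= dq
        col[k] = -(path_length(qp, muscle, model)
                   - path_length(qm, muscle, model)) / (2 * dq)
    return col


def _geometric_column(q, muscle, model, state: ChainState,
                      axes) -> np.ndarray:
    path = muscle_path(q, muscle, model, state=state, n_arc=24)
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
    col = np.zeros(N_COORDS)
    for k, (axis, center, depth) in enumerate(axes):
        mask = depths >= depth
        if not np.any(mask):
            continue
        r = pts[mask] - center
        col[k] = float(np.einsum("ij,ij->", np.cross(
            np.broadcast_to(axis, r.shape), r), forces[mask]))
    return col


def moment_arms(q, model: GenericModel, method: str = "excursion",
                dq: float = 1e-5) -> MomentArmMatrix:
    """Moment-arm matrix over all muscle groups at configuration q.

    ``excursion``: central-difference tendon excursion, -dL/dq.
    ``geometric``: unit-tension generalized force from the path point
    forces about the instantaneous joint axes.
    """
    q = np.asarray(q, float)
    st = ChainState(model, q)
    cols = []
    if method == "excursion":
        for mus in model.muscles:
            cols.append(_excursion_column(q, mus, model, dq))
    elif method == "geometric":
        axes = st.joint_axes()
        for mus in model.muscles:
            cols.append(_geometric_column(q, mus, model, st, axes))
    else:
        raise ValueError(f"unknown moment-arm method {method!r}")
    return MomentArmMatrix(np.column_stack(cols), method,
                           [m.name for m in model.muscles])
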