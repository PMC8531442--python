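"""Subject-specific adaptation of the generic model.

Covers the four scaling channels of a scaled-generic workflow:

* body-segment inertial parameters (BSIP) from gender/weight/height
  predictive coefficients (masses as percent of body mass, segment lengths
  as fractions of stature, gyration radii as fractions of segment length);
* skeletal morphology through an anisotropic diagonal scaling matrix
  ``S = diag(lW/lWg, lW/lWg, lH/lHg)`` built from stature and shoulder
  width (AI-to-AI distance);
* the two scapulothoracic ribcage ellipsoids, re-fitted by isotropic
  dilation of a base ellipsoid so the scaled TS and AI landmarks lie on
  their surfaces exactly (a 6th-degree polynomial root problem);
* glenoid orientation (inclination/version rotation operators) and muscle
  PCSAs via the BMI-based body muscle-percentage predictive polynomials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model_core import Ellipsoid, GenericModel
from . import kinematics as K


# ----------------------------------------------------------------------
# anthropometry
# ----------------------------------------------------------------------

@dataclass
class SubjectAnthropometry:
    """Subject data driving the scaling: gender, stature [m], body mass
    [kg], shoulder width [m] (distance between the two angulus acromialis
    landmarks), optional glenoid orientation targets [deg] and optional
    subject-specific PCSA overrides [cm^2]."""
    gender: str
    height: float
    weight: float
    shoulder_width: float
    glenoid_inclination: Optional[float] = None
    glenoid_version: Optional[float] = None
    pcsa_overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male|female, got {self.gender}")
        if not 1.2 <= self.height <= 2.3:
            raise ValueError(f"height {self.height} m outside [1.2, 2.3]")
        if not 30 <= self.weight <= 200:
            raise ValueError(f"weight {self.weight} kg outside [30, 200]")
        if not 0 < self.shoulder_width < self.height:
            raise ValueError("shoulder width must be positive and smaller "
                             "than stature")
        for k, v in self.pcsa_overrides.items():
            if not v > 0:
                raise ValueError(f"PCSA override for {k} must be > 0")

    @property
    def bmi(self) -> float:
        return self.weight / self.height ** 2


def generic_anthropometry(model: GenericModel) -> SubjectAnthropometry:
    a = model.anthropometry_generic
    return SubjectAnthropometry(a.gender, a.height, a.weight,
                                a.shoulder_width)


# ----------------------------------------------------------------------
# BSIP predictive coefficients
# ----------------------------------------------------------------------
# mass_pct: percent of body mass; length_frac: fraction of stature;
# k_t / k_l: transverse / lateral (long-axis) gyration radius as a
# fraction of the segment length.

_BSIP_COEF = {
    "male": {
        "clavicle": {"mass_pct": 0.18},
        "scapula": {"mass_pct": 0.82},
        "humerus": {"mass_pct": 2.4, "length_frac": 27.0 / 177.0,
                    "k_t": 0.315, "k_l": 0.14},
        "ulna": {"mass_pct": 0.62 * 1.7, "length_frac": 28.3 / 177.0,
                 "k_t": 0.275, "k_l": 0.11},
        "radius": {"mass_pct": 0.38 * 1.7, "length_frac": 28.3 / 177.0,
                   "k_t": 0.275, "k_l": 0.11},
    },
    "female": {
        "clavicle": {"mass_pct": 0.18},
        "scapula": {"mass_pct": 0.82},
        "humerus": {"mass_pct": 2.2, "length_frac": 24.3 / 161.0,
                    "k_t": 0.33, "k_l": 0.17},
        "ulna": {"mass_pct": 0.62 * 1.3, "length_frac": 24.7 / 161.0,
                 "k_t": 0.255, "k_l": 0.14},
        "radius": {"mass_pct": 0.38 * 1.3, "length_frac": 24.7 / 161.0,
                   "k_t": 0.255, "k_l": 0.14},
    },
}

#: gyration fraction used for the two girdle bones, whose inertias are not
#: covered by the predictive table (applied to their geometric lengths)
_GIRDLE_GYRATION = 0.30


@dataclass
class BSIPSet:
    """Predicted segment masses [kg], lengths [m] and transverse/lateral
    inertias [kg m^2] (None where the predictive table has no entry)."""
    mass: Dict[str, float]
    length: Dict[str, Optional[float]]
    inertia_t: Dict[str, Optional[float]]
    inertia_l: Dict[str, Optional[float]]

    @property
    def arm_mass(self) -> float:
        """Humerus + ulna + radius mass."""
        return (self.mass["humerus"] + self.mass["ulna"]
                + self.mass["radius"])


def scale_bsip(anthro: SubjectAnthropometry) -> BSIPSet:
    """Predict BSIP from gender, body mass and stature.

    Masses are percent-of-body-mass coefficients, lengths fractions of
    stature; transverse/lateral inertias are ``(k * length)^2 * mass``.
    The ulna and radius masses are 62% and 38% of the forearm mass.
    """
    coef = _BSIP_COEF[anthro.gender]
    mass, length, it, il = {}, {}, {}, {}
    for seg, c in coef.items():
        m = c["mass_pct"] / 100.0 * anthro.weight
        mass[seg] = m
        if "length_frac" in c:
            l = c["length_frac"] * anthro.height
            length[seg] = l
            it[seg] = (c["k_t"] * l) ** 2 * m
            il[seg] = (c["k_l"] * l) ** 2 * m
        else:
            length[seg] = None
            it[seg] = None
            il[seg] = None
    return BSIPSet(mass, length, it, il)


def arm_mass_sensitivity(anthro: SubjectAnthropometry) -> float:
    """Relative sensitivity of the arm mass to body mass, percent per kg.

    All segment masses are proportional to body mass, so the closed form
    is 100 / m_B regardless of gender.
    """
    return 100.0 / anthro.weight


# ----------------------------------------------------------------------
# morphology
# ----------------------------------------------------------------------

@dataclass
class ScalingMatrix:
    """Anisotropic diagonal scaling of thorax-frame geometry."""
    S: np.ndarray

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.S)


def scaling_matrix(anthro: SubjectAnthropometry,
                   model: GenericModel) -> ScalingMatrix:
    g = model.anthropometry_generic
    sw = anthro.shoulder_width / g.shoulder_width
    sh = anthro.height / g.height
    return ScalingMatrix(np.diag([sw, sw, sh]))


def _wrap_radius_factor(diag: np.ndarray, axis: Optional[np.ndarray]
                        ) -> float:
    """Radius scale factor for a wrapping object: the mean of the diagonal
    scale entries acting in the object's cross-sectional plane (all three
    for a sphere; axis-orthogonal weighting for a cylinder)."""
    if axis is None:
        return float(np.mean(diag))
    w = 1.0 - axis ** 2
    return float(np.sum(w * diag) / np.sum(w))


def scale_morphology(model: GenericModel, sm: ScalingMatrix
                     ) -> GenericModel:
    """Return a copy of the model with every stored reference position
    (bony landmarks, muscle attachments and via points, wrap centers and
    the base-ellipsoid center) mapped through S; wrap radii are scaled by
    the mean in-plane factor and frames are rebuilt."""
    S = sm.S
    diag = sm.diag
    m = model.copy()
    for lm in m.thorax_landmarks:
        lm.position = S @ lm.position
    for seg in m.segments.values():
        for lm in seg.landmarks:
            lm.position = S @ lm.position
        seg.com_ref = S @ seg.com_ref
    for mus in m.muscles:
        for lm in mus.fixed_points:
            lm.position = S @ lm.position
    for w in m.wrap_objects:
        w.center = S @ w.center
        w.radius = w.radius * _wrap_radius_factor(diag, w.axis)
        if w.axis is not None:
            w.axis = (S @ w.axis) / np.linalg.norm(S @ w.axis)
    for lm in (*m.glenoid.rim(), m.glenoid.GC):
        lm.position = S @ lm.position
    m.base_ellipsoid = Ellipsoid(S @ m.base_ellipsoid.center,
                                 m.base_ellipsoid.axes.copy())
    m._built = False
    return m


# ----------------------------------------------------------------------
# ribcage ellipsoid dilation
# ----------------------------------------------------------------------

def _dilation_polynomial(w: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Coefficients (highest first) of the 6th-degree polynomial in the
    dilation delta:  prod_j (a_j+d)^2 - sum_i w_i^2 prod_{j!=i} (a_j+d)^2."""
    quads = [np.array([1.0, 2 * a, a * a]) for a in axes]  # (a+d)^2
    poly = np.convolve(np.convolve(quads[0], quads[1]), quads[2])
    for i in range(3):
        others = [quads[j] for j in range(3) if j != i]
        term = np.convolve(others[0], others[1]) * w[i] ** 2
        poly = poly - np.concatenate([np.zeros(len(poly) - len(term)), term])
    return poly


def _solve_dilation(point: np.ndarray, center: np.ndarray,
                    axes: np.ndarray) -> float:
    """Dilation delta placing ``point`` exactly on the ellipsoid obtained
    by adding delta to every semi-axis.  The admissible branch (all
    semi-axes positive) carries exactly one root; among multiple positive
    roots (defensive) the smallest is taken.
    """
    w = np.asarray(point, float) - np.asarray(center, float)
    poly = _dilation_polynomial(w, np.asarray(axes, float))
    roots = np.roots(poly)
    real = roots[np.abs(roots.imag) < 1e-9].real
    valid = [d for d in np.sort(real[real > -np.min(axes) + 1e-12])
             if abs(np.sum(w ** 2 / (axes + d) ** 2) - 1.0) < 1e-6]
    if not valid:
        raise RuntimeError("ellipsoid dilation: no admissible real root "
                           "(geometrically impossible scaling)")
    positive = [d for d in valid if d > 0]
    best = min(positive) if positive else max(valid)
    # polish by Newton on f(d) = sum w^2/(a+d)^2 - 1 to machine precision
    d = best
    for _ in range(50):
        f = float(np.sum(w ** 2 / (axes + d) ** 2) - 1.0)
        fp = float(np.sum(-2.0 * w ** 2 / (axes + d) ** 3))
        if fp == 0:
            break
        step = f / fp
        d -= step
        if abs(step) < 1e-16:
            break
    if abs(np.sum(w ** 2 / (axes + d) ** 2) - 1.0) > 1e-10:
        raise RuntimeError("ellipsoid dilation: residual did not converge")
    return float(d)


def dilate_ellipsoids(model: GenericModel, sm: ScalingMatrix
                      ) -> Tuple[float, float, Ellipsoid, Ellipsoid]:
    """Dilate the base ellipsoid so the scaled TS and AI landmarks lie on
    their respective ribcage ellipsoids exactly.

    Returns (delta_TS, delta_AI, TS ellipsoid, AI ellipsoid); the dilated
    centers are ``S e0``.  Raises if no admissible root exists.
    """
    S = sm.S
    base = model.base_ellipsoid
    c = S @ base.center
    out = []
    for lmn in ("TS", "AI"):
        p = S @ model.point_ref(lmn, "scapula")
        d = _solve_dilation(p, c, base.axes)
        out.append((d, Ellipsoid(c, base.axes + d)))
    (d_ts, e_ts), (d_ai, e_ai) = out
    return d_ts, d_ai, e_ts, e_ai


# ----------------------------------------------------------------------
# glenoid orientation
# ----------------------------------------------------------------------

def _scapula_frame_ref(model: GenericModel) -> K.Frame:
    return K.build_scapula_frame(model.point_ref("SN", "scapula"),
                                 model.point_ref("AI", "scapula"),
                                 model.point_ref("TS", "scapula"))


def glenoid_angles(model: GenericModel) -> Tuple[float, float]:
    """Measured glenoid inclination and version [deg].

    Inclination: signed angle in the scapular x-z plane between z_s and
    the inferior-to-superior rim vector (SG - IG).  Version: signed angle
    in the x-y plane between y_s and the posterior-to-anterior rim vector
    (AG - PG).
    """
    f = _scapula_frame_ref(model)
    x, y, z = f.rotation.T
    v_si = (model.glenoid.SG.position - model.glenoid.IG.position)
    v_pa = (model.glenoid.AG.position - model.glenoid.PG.position)
    if np.hypot(v_si @ x, v_si @ z) < 1e-12 \
            or np.hypot(v_pa @ x, v_pa @ y) < 1e-12:
        raise ValueError("glenoid rim projection is degenerate")
    a_gi = math.degrees(math.atan2(v_si @ x, v_si @ z))
    a_gv = math.degrees(math.atan2(v_pa @ x, v_pa @ y))
    return a_gi, a_gv


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation operator n n^T + cos(a)(I - n n^T) + sin(a) [n]_x."""
    n = axis.reshape(3, 1)
    return (n @ n.T + math.cos(angle) * (np.eye(3) - n @ n.T)
            + math.sin(angle) * K.skew(axis))


def adapt_glenoid(model: GenericModel, target_inclination: float,
                  target_version: float) -> GenericModel:
    """Rotate the glenoid center and rim about the scapular y and z axes
    until the measured inclination/version equal the targets [deg].

    The two rotation operators couple weakly (an inclination rotation
    perturbs the vector components entering the version measurement), so
    the operators are applied in a fixed-point loop that converges
    quadratically; the loop exits below 1e-9 deg.

    The rotation center is the humeral head center (the stability-cone
    apex): the cone axis through the glenoid center then tilts by exactly
    the applied inclination change.
    """
    m = model.copy()
    f = _scapula_frame_ref(m)
    x, y, z = f.rotation.T
    center = m.point_ref("HH", "scapula")
    for _ in range(30):
        a_gi, a_gv = glenoid_angles(m)
        d_gi = math.radians(target_inclination - a_gi)
        d_gv = math.radians(target_version - a_gv)
        if max(abs(d_gi), abs(d_gv)) < math.radians(1e-9):
            break
        # about y_s the measured inclination is additive with the rotation
        # angle (x = y x z); about z_s the version measurement has the
        # opposite handedness (z x y = -x), hence the negated angle
        R = _rodrigues(z, -d_gv) @ _rodrigues(y, d_gi)
        for lm in (*m.glenoid.rim(), m.glenoid.GC):
            lm.position = center + R @ (lm.position - center)
    m.glenoid.inclination = float(target_inclination)
    m.glenoid.version = float(target_version)
    m._built = False
    return m


# ----------------------------------------------------------------------
# muscle architecture
# ----------------------------------------------------------------------

def muscle_percentage(anthro: SubjectAnthropometry) -> float:
    """Body muscle-percentage r_m (fraction of body composition) from the
    gender-specific BMI predictive polynomials."""
    bmi = anthro.bmi
    if not 12.0 <= bmi <= 60.0:
        warnings.warn(f"BMI {bmi:.1f} outside the predictive range "
                      "[12, 60]; evaluating at the clamped bound")
        bmi = min(max(bmi, 12.0), 60.0)
    if anthro.gender == "male":
        return 1.09 - 0.0149 * bmi + 0.00009 * bmi ** 2
    return 1.08 - 0.0203 * bmi + 0.000156 * bmi ** 2


def scale_pcsa(model: GenericModel, anthro: SubjectAnthropometry
               ) -> Tuple[GenericModel, Dict[str, float]]:
    """Scale every muscle PCSA by the subject-to-generic muscle-percentage
    ratio; subject-specific overrides replace the scaled values."""
    m = model.copy()
    r_gen = m.r_m_generic
    if r_gen is None:
        r_gen = muscle_percentage(generic_anthropometry(m))
    ratio = muscle_percentage(anthro) / r_gen
    factors = {}
    for mus in m.muscles:
        if mus.name in anthro.pcsa_overrides:
            mus.pcsa = float(anthro.pcsa_overrides[mus.name])
            factors[mus.name] = float("nan")
        else:
            mus.pcsa = mus.pcsa * ratio
            factors[mus.name] = ratio
    return m, factors


# ----------------------------------------------------------------------
# full scaling pipeline
# ----------------------------------------------------------------------

@dataclass
class ScalingReport:
    """Every factor applied during subject scaling."""
    scale_diag: np.ndarray
    bsip: BSIPSet
    delta_ts: float
    delta_ai: float
    r_m_subject: float
    r_m_generic: float
    pcsa_factors: Dict[str, float]
    glenoid_targets: Tuple[Optional[float], Optional[float]]
    hand_mass: float

    def to_dict(self) -> dict:
        return {
            "scale_diag": [float(v) for v in self.scale_diag],
            "segment_mass_kg": {k: float(v)
                                for k, v in self.bsip.mass.items()},
            "segment_length_m": {k: (None if v is None else float(v))
                                 for k, v in self.bsip.length.items()},
            "arm_mass_kg": float(self.bsip.arm_mass),
            "delta_ts_m": float(self.delta_ts),
            "delta_ai_m": float(self.delta_ai),
            "r_m_subject": float(self.r_m_subject),
            "r_m_generic": float(self.r_m_generic),
            "pcsa_factors": {k: (None if math.isnan(v) else float(v))
                             for k, v in self.pcsa_factors.items()},
            "glenoid_targets_deg": list(self.glenoid_targets),
            "hand_mass_kg": float(self.hand_mass),
        }


def _apply_bsip(model: GenericModel, bsip: BSIPSet) -> None:
    """Write predicted masses/lengths/inertias into the model segments.

    The lateral gyration applies to the long axis of each anatomical
    frame (x for the ulna, z for the radius, y for the humerus); the
    transverse gyration to the remaining two axes.  The girdle bones keep
    an isotropic gyration fraction of their geometric lengths.
    """
    long_axis = {"humerus": 1, "ulna": 0, "radius": 2}
    for name, seg in model.segments.items():
        seg.mass = bsip.mass[name]
        if bsip.length[name] is not None:
            seg.length = bsip.length[name]
            I = np.full(3, bsip.inertia_t[name])
            I[long_axis[name]] = bsip.inertia_l[name]
            seg.inertia_diag = I
        else:
            if name == "clavicle":
                seg.length = float(np.linalg.norm(
                    seg.landmark("AC").position
                    - model.thorax_landmark("SC").position))
            else:  # scapula
                seg.length = float(np.linalg.norm(
                    seg.landmark("AA").position
                    - seg.landmark("AI").position))
            seg.inertia_diag = np.full(
                3, seg.mass * (_GIRDLE_GYRATION * seg.length) ** 2)


def scale_subject(model: GenericModel, anthro: SubjectAnthropometry
                  ) -> Tuple[GenericModel, ScalingReport]:
    """Full subject scaling: morphology (S), ribcage ellipsoids (dilation),
    BSIP, optional glenoid adaptation, and PCSA; returns the scaled model
    and a report of every factor applied."""
    sm = scaling_matrix(anthro, model)
    d_ts, d_ai, e_ts, e_ai = dilate_ellipsoids(model, sm)
    m = scale_morphology(model, sm)
    m.ts_ellipsoid = e_ts
    m.ai_ellipsoid = e_ai

    bsip = scale_bsip(anthro)
    _apply_bsip(m, bsip)
    hand_ratio = anthro.weight / model.anthropometry_generic.weight
    m.hand_mass = model.hand_mass * hand_ratio
    m.hand_inertia = model.hand_inertia * hand_ratio

    targets = (anthro.glenoid_inclination, anthro.glenoid_version)
    if targets[0] is not None or targets[1] is not None:
        cur_gi, cur_gv = glenoid_angles(m)
        t_gi = targets[0] if targets[0] is not None else cur_gi
        t_gv = targets[1] if targets[1] is not None else cur_gv
        m = adapt_glenoid(m, t_gi, t_gv)

    r_gen = m.r_m_generic
    if r_gen is None:
        r_gen = muscle_percentage(generic_anthropometry(model))
    m, factors = scale_pcsa(m, anthro)
    r_sub = muscle_percentage(anthro)

    # the scaled model becomes its own reference for any further scaling
    m.anthropometry_generic.gender = anthro.gender
    m.anthropometry_generic.height = anthro.height
    m.anthropometry_generic.weight = anthro.weight
    m.anthropometry_generic.shoulder_width = anthro.shoulder_width
    m.r_m_generic = r_sub
    m._built = False
    m.build()

    report = ScalingReport(sm.diag, bsip, d_ts, d_ai, r_sub, r_gen,
                           factors, targets, m.hand_mass)
    return m, report
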