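"""Domain types, model schema reader/writer, and structural validation.

The model describes a right-side upper limb as a serial chain

    thorax -> clavicle -> scapula -> humerus -> ulna -> radius

actuated by three ball-and-socket joints (sternoclavicular,
acromioclavicular, glenohumeral; nine generalized coordinates) and two
non-perpendicular elbow hinges (flexion/extension ``q10``,
pronation/supination ``q11``), for eleven generalized coordinates in total.
Two holonomic constraints confine the scapular landmarks TS (trigonum
spinae) and AI (angulus inferior) to ribcage ellipsoids, leaving nine
degrees of freedom.

Geometry convention
-------------------
Every geometric entity (bony landmark, muscle attachment, via point,
wrapping-object center) is stored as its position **in the thorax frame at
the reference pose**, together with the token of the bone segment it is
rigidly attached to (``frame`` field; ``"thorax"`` for fixed points).
Bone-frame local coordinates, anatomical segment frames, and the fixed
alignment rotations between consecutive segments are derived once at model
build time and cached.  This keeps save/load round-trips stable to float
round-off and turns
anisotropic morphological scaling into a single linear map on the stored
positions.

Internally all quantities are SI (m, kg, s, N, rad).  Schema files on disk
use centimetres for lengths and degrees for angles and are converted at the
boundary.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

SEGMENT_NAMES = ("clavicle", "scapula", "humerus", "ulna", "radius")
#: depth of each body in the chain; thorax is the inertial root at depth 0
SEGMENT_DEPTH = {"thorax": 0, "clavicle": 1, "scapula": 2, "humerus": 3,
                 "ulna": 4, "radius": 5}
N_COORDS = 11
N_MUSCLES_EXPECTED = 42
N_ELBOW_MUSCLES_EXPECTED = 14

GRAVITY = 9.81  # m/s^2, acting along -z of the thorax frame

#: the fourteen elbow-spanning muscle groups of the model
ELBOW_MUSCLES = (
    "triceps_long", "triceps_medial", "triceps_lateral",
    "biceps_short", "biceps_long",
    "brachialis", "brachioradialis", "supinator", "pronator_teres",
    "flexor_carpi_radialis", "flexor_carpi_ulnaris",
    "extensor_carpi_radialis_longus", "extensor_carpi_radialis_brevis",
    "extensor_carpi_ulnaris",
)


def _as_vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name}: expected 3 components, got {v.size}")
    return v.copy()


def _feq(a, b) -> bool:
    """Float-field equality used by the model types: exact up to the
    double rounding a unit-converted save/load cycle can introduce."""
    return bool(np.allclose(np.asarray(a, float), np.asarray(b, float),
                            rtol=1e-12, atol=1e-15))


def is_rotation(R: np.ndarray, tol: float = 1e-10) -> bool:
    """True if ``R`` is orthonormal with determinant +1 (within ``tol``)."""
    R = np.asarray(R, float)
    if R.shape != (3, 3):
        return False
    return (np.max(np.abs(R.T @ R - np.eye(3))) < tol
            and abs(np.linalg.det(R) - 1.0) < tol)


@dataclass
class Landmark:
    """A named point rigidly attached to a bone segment.

    ``position`` is expressed in the thorax frame at the reference pose;
    ``frame`` names the segment the point moves with.
    """
    name: str
    position: np.ndarray
    frame: str = "thorax"

    def __post_init__(self):
        self.position = _as_vec3(self.position, f"landmark {self.name}")

    def __eq__(self, other):
        return (isinstance(other, Landmark) and self.name == other.name
                and self.frame == other.frame
                and _feq(self.position, other.position))


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in the thorax frame: (p-c)^T E (p-c) = 1."""
    center: np.ndarray
    axes: np.ndarray  # semi-axes (a, b, c), metres

    def __post_init__(self):
        self.center = _as_vec3(self.center, "ellipsoid center")
        self.axes = _as_vec3(self.axes, "ellipsoid axes")

    @property
    def quadric(self) -> np.ndarray:
        return np.diag(1.0 / self.axes ** 2)

    def residual(self, p: np.ndarray) -> float:
        """Implicit-surface value Phi = (p-c)^T E (p-c) - 1 (0 on surface)."""
        d = np.asarray(p, float) - self.center
        return float(d @ self.quadric @ d - 1.0)

    def __eq__(self, other):
        return (isinstance(other, Ellipsoid)
                and _feq(self.center, other.center)
                and _feq(self.axes, other.axes))


@dataclass
class WrappingObject:
    """Analytic wrapping surface (sphere or cylinder) for the obstacle-set
    muscle-path algorithm.

    ``center``/``axis`` follow the thorax-frame-at-reference convention and
    are transformed with ``attached_segment`` at run time.  ``wrap_side``
    fixes the tangent branch (sign of the circulation in the obstacle frame)
    so the path never flips between frames.
    """
    name: str
    kind: str  # "sphere" | "cylinder"
    center: np.ndarray
    radius: float
    attached_segment: str = "thorax"
    axis: Optional[np.ndarray] = None  # cylinder only, unit vector
    wrap_side: str = "right"  # "right" | "left"

    def __post_init__(self):
        self.center = _as_vec3(self.center, f"wrap {self.name} center")
        if self.axis is not None:
            self.axis = _as_vec3(self.axis, f"wrap {self.name} axis")
            n = np.linalg.norm(self.axis)
            if n > 0:
                self.axis = self.axis / n

    def __eq__(self, other):
        if not isinstance(other, WrappingObject):
            return False
        ax_eq = ((self.axis is None and other.axis is None)
                 or (self.axis is not None and other.axis is not None
                     and np.allclose(self.axis, other.axis, atol=1e-12)))
        return (self.name == other.name and self.kind == other.kind
                and _feq(self.center, other.center)
                and _feq(self.radius, other.radius)
                and self.attached_segment == other.attached_segment
                and self.wrap_side == other.wrap_side and ax_eq)


@dataclass
class Muscle:
    """One muscle group, represented by ``n_strings`` massless elastic
    strings threaded origin -> via points -> insertion, wrapping over the
    obstacles named in ``wraps``.

    ``wraps`` is an ordered list of ``(wrap_object_name, gap_index)`` pairs:
    the obstacle acts on the path gap between fixed points ``gap_index`` and
    ``gap_index + 1`` (0 = origin).  At most one obstacle per gap.
    """
    name: str
    origin: Landmark
    insertion: Landmark
    via_points: List[Landmark] = field(default_factory=list)
    wraps: List[Tuple[str, int]] = field(default_factory=list)
    n_strings: int = 1
    pcsa: float = 1.0  # cm^2 for the whole group

    @property
    def fixed_points(self) -> List[Landmark]:
        return [self.origin, *self.via_points, self.insertion]

    def spanned_coordinates(self) -> List[int]:
        """Indices of the generalized coordinates this muscle spans,
        derived from the chain depths of its origin and insertion segments.

        Joint j (1..5) connects segment depth j-1 to depth j and owns the
        coordinate slice: SC q0:3, AC q3:6, GH q6:9, elbow flexion q9,
        pronation q10.
        """
        d0 = SEGMENT_DEPTH[self.origin.frame]
        d1 = SEGMENT_DEPTH[self.insertion.frame]
        lo, hi = min(d0, d1), max(d0, d1)
        slices = {1: [0, 1, 2], 2: [3, 4, 5], 3: [6, 7, 8], 4: [9], 5: [10]}
        out: List[int] = []
        for j in range(lo + 1, hi + 1):
            out.extend(slices[j])
        return out

    def __eq__(self, other):
        return (isinstance(other, Muscle) and self.name == other.name
                and self.origin == other.origin
                and self.insertion == other.insertion
                and self.via_points == other.via_points
                and self.wraps == [tuple(w) for w in other.wraps]
                and self.n_strings == other.n_strings
                and _feq(self.pcsa, other.pcsa))


@dataclass
class GlenoidSpec:
    """Glenoid fossa description: four rim points, center, and orientation
    angles measured in the scapula frame (inclination in the x_s-z_s plane,
    version in the x_s-y_s plane)."""
    IG: Landmark
    SG: Landmark
    PG: Landmark
    AG: Landmark
    GC: Landmark
    inclination: float = 7.0  # deg
    version: float = 0.0  # deg
    cone_half_angle: Optional[float] = None  # deg; None -> derived from rim

    def rim(self) -> List[Landmark]:
        return [self.IG, self.SG, self.PG, self.AG]

    def __eq__(self, other):
        return (isinstance(other, GlenoidSpec)
                and all(getattr(self, k) == getattr(other, k)
                        for k in ("IG", "SG", "PG", "AG", "GC"))
                and _feq(self.inclination, other.inclination)
                and _feq(self.version, other.version)
                and self.cone_half_angle == other.cone_half_angle)


@dataclass
class BoneSegment:
    """Rigid bone segment with its inertial properties and landmarks.

    ``inertia_diag`` is diagonal in the anatomical bone-fixed frame;
    ``com_ref`` is the center of mass in the thorax frame at reference.
    """
    name: str
    mass: float
    inertia_diag: np.ndarray  # kg m^2
    com_ref: np.ndarray  # m, thorax frame at reference
    length: float  # m
    landmarks: List[Landmark] = field(default_factory=list)

    def __post_init__(self):
        self.inertia_diag = _as_vec3(self.inertia_diag,
                                     f"{self.name} inertia")
        self.com_ref = _as_vec3(self.com_ref, f"{self.name} com")

    def landmark(self, name: str) -> Landmark:
        for lm in self.landmarks:
            if lm.name == name:
                return lm
        raise KeyError(f"segment {self.name}: no landmark {name!r}")

    @property
    def landmarks_local(self):  # filled by GenericModel.build()
        return getattr(self, "_landmarks_local", None)

    def __eq__(self, other):
        return (isinstance(other, BoneSegment) and self.name == other.name
                and _feq(self.mass, other.mass)
                and _feq(self.inertia_diag, other.inertia_diag)
                and _feq(self.com_ref, other.com_ref)
                and _feq(self.length, other.length)
                and self.landmarks == other.landmarks)


@dataclass
class Anthropometry:
    """Anthropometry of the generic model's subject."""
    gender: str = "male"
    height: float = 1.86  # m
    weight: float = 85.5  # kg
    shoulder_width: float = 0.38  # m, AI-to-AI across both shoulders


@dataclass
class GenericModel:
    """Full anatomical/mechanical description of the shoulder-elbow model."""
    segments: Dict[str, BoneSegment]
    thorax_landmarks: List[Landmark]
    base_ellipsoid: Ellipsoid
    ts_ellipsoid: Ellipsoid
    ai_ellipsoid: Ellipsoid
    muscles: List[Muscle]
    wrap_objects: List[WrappingObject]
    glenoid: GlenoidSpec
    anthropometry_generic: Anthropometry
    hand_mass: float = 0.513  # kg, default 0.6% of 85.5 kg body mass
    hand_inertia: np.ndarray = field(
        default_factory=lambda: np.array([5e-4, 5e-4, 5e-4]))
    reference_pose: np.ndarray = field(
        default_factory=lambda: np.zeros(N_COORDS))
    #: intrinsic Euler sequences for the SC, AC and GH ball joints
    euler_sequences: Dict[str, str] = field(
        default_factory=lambda: {"sc": "zyx", "ac": "zyx", "gh": "yxy"})
    #: physiological coordinate ranges, radians
    q10_range: Tuple[float, float] = (0.0, math.radians(150.0))
    q11_range: Tuple[float, float] = (-math.pi / 2, math.pi / 2)
    #: elbow posture held during generated abduction motions (rad)
    carrying_posture: Tuple[float, float] = (math.radians(15.0), 0.0)
    #: body muscle percentage of the generic subject (Eq. 17 at generic BMI)
    r_m_generic: Optional[float] = None

    # ---- derived, filled by build() ----------------------------------
    def __post_init__(self):
        self.hand_inertia = _as_vec3(self.hand_inertia, "hand inertia")
        self.reference_pose = np.asarray(self.reference_pose,
                                         float).reshape(N_COORDS)
        self._built = False

    def thorax_landmark(self, name: str) -> Landmark:
        for lm in self.thorax_landmarks:
            if lm.name == name:
                return lm
        raise KeyError(f"no thorax landmark {name!r}")

    def wrap_object(self, name: str) -> WrappingObject:
        for w in self.wrap_objects:
            if w.name == name:
                return w
        raise KeyError(f"no wrapping object {name!r}")

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle {name!r}")

    def point_ref(self, name: str, segment: str) -> np.ndarray:
        """Reference thorax-frame position of a named landmark."""
        if segment == "thorax":
            return self.thorax_landmark(name).position
        return self.segments[segment].landmark(name).position

    def build(self) -> "GenericModel":
        """Derive anatomical frames, local coordinates and alignment
        rotations from the stored reference geometry (idempotent)."""
        from . import kinematics as K  # deferred: avoids import cycle
        K.build_model_frames(self)
        self._built = True
        return self

    @property
    def alignment_rotations(self) -> Tuple[np.ndarray, np.ndarray]:
        """The fixed humerus->ulna and ulna->radius alignment rotations."""
        if not self._built:
            self.build()
        return self._align["hu"], self._align["ur"]

    def copy(self) -> "GenericModel":
        return copy.deepcopy(self)

    def __eq__(self, other):
        if not isinstance(other, GenericModel):
            return False
        return (self.segments == other.segments
                and self.thorax_landmarks == other.thorax_landmarks
                and self.base_ellipsoid == other.base_ellipsoid
                and self.ts_ellipsoid == other.ts_ellipsoid
                and self.ai_ellipsoid == other.ai_ellipsoid
                and self.muscles == other.muscles
                and self.wrap_objects == other.wrap_objects
                and self.glenoid == other.glenoid
                and _feq(self.hand_mass, other.hand_mass)
                and _feq(self.hand_inertia, other.hand_inertia)
                and _feq(self.reference_pose, other.reference_pose))


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Collected structural violations/warnings; empty report == valid."""
    violations: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def __bool__(self):  # truthy when clean
        return not self.violations

    def add(self, msg: str):
        self.violations.append(msg)

    def warn(self, msg: str):
        self.warnings.append(msg)


def validate_model(model: GenericModel) -> ValidationReport:
    """Check every structural invariant of the model.

    Violations are returned as data, never raised, so a partially broken
    model file can be diagnosed in one pass.
    """
    rep = ValidationReport()

    for name in SEGMENT_NAMES:
        if name not in model.segments:
            rep.add(f"missing segment {name!r}")
    if len(model.segments) != 5:
        rep.add(f"expected exactly 5 segments, found {len(model.segments)}")

    for seg in model.segments.values():
        if not seg.mass > 0:
            rep.add(f"segment {seg.name}: mass must be > 0 (got {seg.mass})")
        I = seg.inertia_diag
        if np.any(I < 0):
            rep.add(f"segment {seg.name}: negative inertia component")
        for i in range(3):
            if I[i] > I[(i + 1) % 3] + I[(i + 2) % 3] + 1e-12:
                rep.add(f"segment {seg.name}: inertia triangle inequality "
                        f"violated on axis {i}")
        if not np.all(np.isfinite(seg.com_ref)):
            rep.add(f"segment {seg.name}: non-finite center of mass")
        seen = set()
        for lm in seg.landmarks:
            if lm.name in seen:
                rep.add(f"segment {seg.name}: duplicate landmark {lm.name}")
            seen.add(lm.name)
            if not np.all(np.isfinite(lm.position)):
                rep.add(f"landmark {lm.name}: non-finite coordinates")

    for ell, tag in ((model.base_ellipsoid, "base"),
                     (model.ts_ellipsoid, "TS"), (model.ai_ellipsoid, "AI")):
        if np.any(ell.axes <= 0):
            rep.add(f"{tag} ellipsoid: semi-axes must be positive")

    wrap_names = {w.name for w in model.wrap_objects}
    for w in model.wrap_objects:
        if w.kind not in ("sphere", "cylinder"):
            rep.add(f"wrap {w.name}: unknown kind {w.kind!r}")
        if not w.radius > 0:
            rep.add(f"wrap {w.name}: radius must be > 0")
        if w.kind == "cylinder":
            if w.axis is None:
                rep.add(f"wrap {w.name}: cylinder needs an axis")
            elif abs(np.linalg.norm(w.axis) - 1.0) > 1e-9:
                rep.add(f"wrap {w.name}: axis must be unit length")
        if w.attached_segment not in SEGMENT_DEPTH:
            rep.add(f"wrap {w.name}: unknown segment {w.attached_segment!r}")

    if len(model.muscles) != N_MUSCLES_EXPECTED:
        rep.warn(f"expected {N_MUSCLES_EXPECTED} muscle groups, "
                 f"found {len(model.muscles)}")
    seen_m = set()
    for m in model.muscles:
        if m.name in seen_m:
            rep.add(f"duplicate muscle name {m.name!r}")
        seen_m.add(m.name)
        if not m.pcsa > 0:
            rep.add(f"muscle {m.name}: pcsa must be > 0 (got {m.pcsa})")
        if not 1 <= m.n_strings <= 20:
            rep.add(f"muscle {m.name}: n_strings must be in 1..20")
        for wname, gap in m.wraps:
            if wname not in wrap_names:
                rep.add(f"muscle {m.name}: unresolved wrap {wname!r}")
            if not 0 <= gap < len(m.fixed_points) - 1:
                rep.add(f"muscle {m.name}: wrap gap index {gap} out of range")
        for lm in m.fixed_points:
            if lm.frame not in SEGMENT_DEPTH:
                rep.add(f"muscle {m.name}: point {lm.name} on unknown "
                        f"segment {lm.frame!r}")

    g = model.glenoid
    for lm in (*g.rim(), g.GC):
        if not np.all(np.isfinite(lm.position)):
            rep.add(f"glenoid point {lm.name}: non-finite coordinates")
    if g.cone_half_angle is not None and not 0 < g.cone_half_angle < 90:
        rep.add("glenoid cone_half_angle must lie in (0, 90) degrees")

    a = model.anthropometry_generic
    if not 1.2 <= a.height <= 2.3:
        rep.add(f"generic height {a.height} m outside [1.2, 2.3]")
    if not 30 <= a.weight <= 200:
        rep.add(f"generic weight {a.weight} kg outside [30, 200]")

    # reference pose must satisfy both ribcage constraints
    try:
        model.build()
        from . import kinematics as K
        phi_ts, phi_ai = K.ribcage_residuals(model.reference_pose, model)
        if abs(phi_ts) > 1e-8:
            rep.add(f"reference pose off the TS ellipsoid: Phi_TS={phi_ts:g}")
        if abs(phi_ai) > 1e-8:
            rep.add(f"reference pose off the AI ellipsoid: Phi_AI={phi_ai:g}")
        R_hu, R_ur = model.alignment_rotations
        for R, tag in ((R_hu, "humerus-ulna"), (R_ur, "ulna-radius")):
            if not is_rotation(R):
                rep.add(f"{tag} alignment rotation not orthonormal")
    except Exception as exc:  # degenerate geometry
        rep.add(f"model frames could not be built: {exc}")

    return rep


# ----------------------------------------------------------------------
# schema i/o  (YAML; cm and deg on disk, SI in memory)
# ----------------------------------------------------------------------

_CM = 100.0  # m -> cm


def _lm_out(lm: Landmark) -> dict:
    return {"name": lm.name, "frame": lm.frame,
            "position_cm": [float(x) * _CM for x in lm.position]}


def _lm_in(d: dict) -> Landmark:
    return Landmark(d["name"], np.asarray(d["position_cm"], float) / _CM,
                    d.get("frame", "thorax"))


def save_model(model: GenericModel, path) -> None:
    """Write the model to a YAML schema file (lengths in cm, angles deg)."""
    doc = {
        "format": "shoulderelbow-model/1",
        "anthropometry": {
            "gender": model.anthropometry_generic.gender,
            "height_cm": model.anthropometry_generic.height * _CM,
            "weight_kg": model.anthropometry_generic.weight,
            "shoulder_width_cm":
                model.anthropometry_generic.shoulder_width * _CM,
        },
        "hand": {"mass_kg": model.hand_mass,
                 "inertia_kgm2": [float(x) for x in model.hand_inertia]},
        "reference_pose_deg":
            [math.degrees(v) for v in model.reference_pose],
        "euler_sequences": dict(model.euler_sequences),
        "q10_range_deg": [math.degrees(v) for v in model.q10_range],
        "q11_range_deg": [math.degrees(v) for v in model.q11_range],
        "carrying_posture_deg":
            [math.degrees(v) for v in model.carrying_posture],
        "r_m_generic": model.r_m_generic,
        "thorax_landmarks": [_lm_out(lm) for lm in model.thorax_landmarks],
        "segments": [
            {"name": s.name, "mass_kg": s.mass,
             "inertia_kgm2": [float(x) for x in s.inertia_diag],
             "com_cm": [float(x) * _CM for x in s.com_ref],
             "length_cm": s.length * _CM,
             "landmarks": [_lm_out(lm) for lm in s.landmarks]}
            for s in (model.segments[n] for n in SEGMENT_NAMES)
        ],
        "ellipsoids": {
            k: {"center_cm": [float(x) * _CM for x in e.center],
                "axes_cm": [float(x) * _CM for x in e.axes]}
            for k, e in (("base", model.base_ellipsoid),
                         ("ts", model.ts_ellipsoid),
                         ("ai", model.ai_ellipsoid))
        },
        "wrap_objects": [
            {"name": w.name, "kind": w.kind,
             "center_cm": [float(x) * _CM for x in w.center],
             "radius_cm": w.radius * _CM,
             "attached_segment": w.attached_segment,
             "axis": None if w.axis is None else [float(x) for x in w.axis],
             "wrap_side": w.wrap_side}
            for w in model.wrap_objects
        ],
        "muscles": [
            {"name": m.name, "pcsa_cm2": m.pcsa, "n_strings": m.n_strings,
             "origin": _lm_out(m.origin), "insertion": _lm_out(m.insertion),
             "via_points": [_lm_out(v) for v in m.via_points],
             "wraps": [[w, int(g)] for w, g in m.wraps]}
            for m in model.muscles
        ],
        "glenoid": {
            **{k: _lm_out(getattr(model.glenoid, k))
               for k in ("IG", "SG", "PG", "AG", "GC")},
            "inclination_deg": model.glenoid.inclination,
            "version_deg": model.glenoid.version,
            "cone_half_angle_deg": model.glenoid.cone_half_angle,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> GenericModel:
    """Read a model schema file, convert to SI, validate, and build frames.

    Raises ``ValueError`` naming the offending field on schema violations.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise ValueError(f"{path}: not a shoulderelbow model schema")

    try:
        anth = doc["anthropometry"]
        model = GenericModel(
            segments={
                s["name"]: BoneSegment(
                    s["name"], float(s["mass_kg"]),
                    np.asarray(s["inertia_kgm2"], float),
                    np.asarray(s["com_cm"], float) / _CM,
                    float(s["length_cm"]) / _CM,
                    [_lm_in(d) for d in s.get("landmarks", [])])
                for s in doc["segments"]},
            thorax_landmarks=[_lm_in(d) for d in doc["thorax_landmarks"]],
            base_ellipsoid=_ell_in(doc["ellipsoids"]["base"]),
            ts_ellipsoid=_ell_in(doc["ellipsoids"]["ts"]),
            ai_ellipsoid=_ell_in(doc["ellipsoids"]["ai"]),
            muscles=[
                Muscle(m["name"], _lm_in(m["origin"]), _lm_in(m["insertion"]),
                       [_lm_in(v) for v in m.get("via_points", [])],
                       [(w, int(g)) for w, g in m.get("wraps", [])],
                       int(m.get("n_strings", 1)), float(m["pcsa_cm2"]))
                for m in doc["muscles"]],
            wrap_objects=[
                WrappingObject(
                    w["name"], w["kind"],
                    np.asarray(w["center_cm"], float) / _CM,
                    float(w["radius_cm"]) / _CM,
                    w.get("attached_segment", "thorax"),
                    None if w.get("axis") is None
                    else np.asarray(w["axis"], float),
                    w.get("wrap_side", "right"))
                for w in doc.get("wrap_objects", [])],
            glenoid=GlenoidSpec(
                **{k: _lm_in(doc["glenoid"][k])
                   for k in ("IG", "SG", "PG", "AG", "GC")},
                inclination=float(doc["glenoid"]["inclination_deg"]),
                version=float(doc["glenoid"]["version_deg"]),
                cone_half_angle=doc["glenoid"].get("cone_half_angle_deg")),
            anthropometry_generic=Anthropometry(
                anth["gender"], float(anth["height_cm"]) / _CM,
                float(anth["weight_kg"]),
                float(anth["shoulder_width_cm"]) / _CM),
            hand_mass=float(doc["hand"]["mass_kg"]),
            hand_inertia=np.asarray(doc["hand"]["inertia_kgm2"], float),
            reference_pose=np.radians(doc["reference_pose_deg"]),
            euler_sequences=dict(doc.get(
                "euler_sequences", {"sc": "zyx", "ac": "zyx", "gh": "yxy"})),
            q10_range=tuple(np.radians(doc["q10_range_deg"])),
            q11_range=tuple(np.radians(doc["q11_range_deg"])),
            carrying_posture=tuple(np.radians(doc["carrying_posture_deg"])),
            r_m_generic=doc.get("r_m_generic"),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: schema violation near {exc!r}") from exc

    rep = validate_model(model)
    if rep.violations:
        raise ValueError(f"{path}: invalid model: " + "; ".join(
            rep.violations[:5]))
    return model.build()


def _ell_in(d: dict) -> Ellipsoid:
    return Ellipsoid(np.asarray(d["center_cm"], float) / _CM,
                     np.asarray(d["axes_cm"], float) / _CM)
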