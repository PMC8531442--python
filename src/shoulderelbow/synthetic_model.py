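"""Deterministic generator of an anatomically plausible right-side
shoulder-elbow model, plus synthetic marker-motion export.

The generator replaces image-derived geometry with landmark coordinates
proportioned from standard anthropometric conventions for an adult male of
the generic stature (1.86 m, 85.5 kg).  The coordinates are fixtures: they
produce physiologically sensible moment arms, feasible load sharing and a
realistic abduction response, but make no claim of fidelity to any specific
subject.  Everything is constructed so the model's structural invariants
hold exactly:

* the two ribcage ellipsoids are dilations of the base ellipsoid passing
  exactly through the reference TS and AI landmarks;
* the glenoid rim is constructed *from* the requested inclination/version
  angles, so measuring them back returns the requested values exactly;
* HU is the midpoint of the epicondyles; the ulna/radius centers of mass
  sit at the midpoints of their proximal-to-styloid chords.

A fixed seed perturbs only soft-tissue detail (muscle attachment offsets
and non-rotator-cuff PCSAs, a few millimetres / percent) so that model
invariants stay exact for every seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .model_core import (Anthropometry, BoneSegment, Ellipsoid, GenericModel,
                         GlenoidSpec, Landmark, Muscle, WrappingObject)
from . import kinematics as K
from . import scaling as SC

#: landmark names exported as synthetic videogrammetry markers, per segment
MARKER_SETS = {
    "clavicle": ("AC", "CLM", "CLA"),
    "scapula": ("AA", "TS", "AI", "SN"),
    "humerus": ("EL", "EM", "DT"),
    "ulna": ("US", "OL", "UM"),
    "radius": ("RS", "RH", "RM"),
}

#: default rotator-cuff PCSAs [cm^2]; a 50% reduction lands on the
#: degenerated-cuff scenario values used in the parameter study
RC_PCSA = {"supraspinatus": 20.84, "infraspinatus": 33.32,
           "subscapularis": 35.68, "teres_minor": 6.80}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic anatomy.  Defaults reproduce the generic
    subject (male, 1.86 m, 85.5 kg, glenoid inclination 7 deg)."""
    seed: int = 0
    stature: float = 1.86  # m
    mass: float = 85.5  # kg
    gender: str = "male"
    glenoid_inclination: float = 7.0  # deg
    glenoid_version: float = -5.0  # deg
    n_muscles: int = 42
    marker_noise_sd: float = 0.0  # m, default for exports


# ----------------------------------------------------------------------
# skeleton (thorax frame: x right, y anterior, z up; metres at 1.86 m)
# ----------------------------------------------------------------------

_THORAX_LM = {
    "IJ": (0.000, 0.000, 0.000),
    "SC": (0.020, 0.010, -0.005),
    "C7": (0.000, -0.090, 0.030),
    "T8": (0.000, -0.110, -0.200),
    "PX": (0.000, 0.020, -0.170),
}

_CLAVICLE_LM = {
    "AC": (0.170, -0.015, 0.035),
    "CLM": (0.095, 0.020, 0.015),
    "CLA": (0.130, 0.010, 0.028),
}

_SCAPULA_LM = {
    "AA": (0.185, -0.055, 0.030),
    "SN": (0.150, -0.060, 0.005),
    "TS": (0.075, -0.105, 0.005),
    "AI": (0.095, -0.100, -0.120),
    "HH": (0.180, -0.035, -0.010),  # humeral head / GH rotation center
    "CP": (0.145, 0.010, 0.010),    # coracoid process
}

_HUMERUS_LM = {
    "EL": (0.215, -0.015, -0.315),
    "EM": (0.165, -0.025, -0.315),
    "DT": (0.198, -0.025, -0.130),  # deltoid tuberosity
}

_ULNA_LM = {
    "OL": (0.190, -0.048, -0.310),  # olecranon
    "US": (0.205, 0.000, -0.585),
    "UM": (0.197, -0.020, -0.450),
}

_RADIUS_LM = {
    "RH": (0.218, -0.015, -0.340),  # radial head
    "RS": (0.235, 0.005, -0.580),
    "RM": (0.225, -0.005, -0.460),
}

_BASE_ELLIPSOID = {"center": (0.0, -0.045, -0.140),
                   "axes": (0.120, 0.075, 0.210)}

_GLENOID_RADII = (0.016, 0.012)  # superior-inferior, antero-posterior [m]
_HEAD_RADIUS = 0.028  # humeral head wrapping sphere [m]


# ----------------------------------------------------------------------
# muscle table
# ----------------------------------------------------------------------
# (name, pcsa_cm2, origin(seg, xyz), insertion(seg, xyz),
#  [vias...], [(wrap, gap)...])

def _muscle_table() -> list:
    T, C, S, H, U, R = ("thorax", "clavicle", "scapula", "humerus",
                        "ulna", "radius")
    return [
        # ---- rotator cuff ------------------------------------------
        ("supraspinatus", RC_PCSA["supraspinatus"],
         (S, (0.090, -0.090, 0.012)), (H, (0.210, -0.036, -0.012)),
         [], [("humeral_head", 0)]),
        ("infraspinatus", RC_PCSA["infraspinatus"],
         (S, (0.100, -0.100, -0.050)), (H, (0.208, -0.048, -0.003)),
         [], [("humeral_head", 0)]),
        ("subscapularis", RC_PCSA["subscapularis"],
         (S, (0.100, -0.088, -0.040)), (H, (0.184, -0.004, -0.005)),
         [], [("humeral_head", 0)]),
        ("teres_minor", RC_PCSA["teres_minor"],
         (S, (0.105, -0.090, -0.090)), (H, (0.200, -0.040, -0.020)), [], []),
        # ---- deltoid ------------------------------------------------
        ("deltoid_anterior", 36.0,
         (C, (0.180, -0.012, 0.025)), (H, (0.192, -0.020, -0.135)),
         [], [("humeral_head", 0)]),
        ("deltoid_middle", 54.0,
         (S, (0.210, -0.030, 0.010)), (H, (0.198, -0.025, -0.130)),
         [], [("humeral_head", 0)]),
        ("deltoid_posterior", 36.0,
         (S, (0.165, -0.068, 0.022)), (H, (0.196, -0.032, -0.132)),
         [], [("humeral_head", 0)]),
        # ---- scapula/clavicle stabilizers ---------------------------
        ("trapezius_clavicular", 24.0,
         (T, (0.000, -0.080, 0.060)), (C, (0.150, -0.005, 0.035)), [], []),
        ("trapezius_acromial", 24.0,
         (T, (0.000, -0.090, 0.030)), (S, (0.183, -0.057, 0.030)), [], []),
        ("trapezius_middle", 18.0,
         (T, (0.000, -0.105, -0.060)), (S, (0.120, -0.085, 0.012)), [], []),
        ("trapezius_lower", 18.0,
         (T, (0.000, -0.110, -0.200)), (S, (0.082, -0.100, 0.003)), [], []),
        ("serratus_anterior_superior", 18.0,
         (T, (0.130, -0.010, -0.020)), (S, (0.078, -0.100, 0.010)), [], []),
        ("serratus_anterior_middle", 18.0,
         (T, (0.135, -0.020, -0.070)), (S, (0.080, -0.100, -0.040)), [], []),
        ("serratus_anterior_inferior", 15.0,
         (T, (0.110, -0.070, -0.175)), (S, (0.093, -0.100, -0.112)), [], []),
        ("serratus_anterior_lower", 15.0,
         (T, (0.102, -0.080, -0.205)), (S, (0.095, -0.100, -0.120)), [], []),
        ("rhomboid_minor", 9.0,
         (T, (0.000, -0.100, 0.010)), (S, (0.077, -0.103, 0.000)), [], []),
        ("rhomboid_major", 15.0,
         (T, (0.000, -0.110, -0.030)), (S, (0.085, -0.100, -0.060)), [], []),
        ("levator_scapulae", 12.0,
         (T, (0.020, -0.060, 0.080)), (S, (0.075, -0.095, 0.020)), [], []),
        ("pectoralis_minor", 15.0,
         (T, (0.080, 0.050, -0.080)), (S, (0.145, 0.010, 0.010)), [], []),
        ("subclavius", 6.0,
         (T, (0.050, 0.030, -0.020)), (C, (0.100, 0.005, 0.005)), [], []),
        # ---- thorax -> humerus prime movers -------------------------
        ("pectoralis_major_clavicular", 30.0,
         (C, (0.050, 0.015, 0.000)), (H, (0.185, 0.000, -0.060)), [], []),
        ("pectoralis_major_sternal", 36.0,
         (T, (0.010, 0.020, -0.060)), (H, (0.185, 0.000, -0.055)), [], []),
        ("pectoralis_major_abdominal", 18.0,
         (T, (0.020, 0.020, -0.140)), (H, (0.185, 0.000, -0.050)), [], []),
        ("latissimus_dorsi_thoracic", 24.0,
         (T, (0.000, -0.115, -0.140)), (H, (0.175, -0.005, -0.070)), [], []),
        ("latissimus_dorsi_lumbar", 21.0,
         (T, (0.000, -0.110, -0.220)), (H, (0.175, -0.005, -0.065)), [], []),
        ("latissimus_dorsi_iliac", 15.0,
         (T, (0.020, -0.100, -0.280)), (H, (0.175, -0.005, -0.060)), [], []),
        ("teres_major", 36.0,
         (S, (0.095, -0.095, -0.115)), (H, (0.175, -0.010, -0.100)),
         [], []),
        ("coracobrachialis", 12.0,
         (S, (0.145, 0.010, 0.010)), (H, (0.180, -0.010, -0.130)), [], []),
        # ---- elbow group (14) ---------------------------------------
        ("triceps_long", 36.0,
         (S, (0.155, -0.050, -0.025)), (U, (0.190, -0.048, -0.310)),
         [(H, (0.188, -0.040, -0.150))], [("elbow_extensor", 1)]),
        ("triceps_medial", 24.0,
         (H, (0.183, -0.038, -0.170)), (U, (0.189, -0.048, -0.308)),
         [], [("elbow_extensor", 0)]),
        ("triceps_lateral", 24.0,
         (H, (0.196, -0.035, -0.140)), (U, (0.191, -0.047, -0.309)),
         [], [("elbow_extensor", 0)]),
        ("biceps_short", 9.3,
         (S, (0.145, 0.010, 0.010)), (R, (0.212, -0.002, -0.362)),
         [(H, (0.190, 0.012, -0.295))], []),
        ("biceps_long", 13.5,
         (S, (0.153, -0.042, 0.008)), (R, (0.210, -0.005, -0.360)),
         [(H, (0.190, 0.005, -0.025)), (H, (0.192, 0.010, -0.295))],
         [("humeral_head", 0)]),
        ("brachialis", 21.0,
         (H, (0.185, 0.005, -0.180)), (U, (0.190, -0.002, -0.345)),
         [], []),
        ("brachioradialis", 5.4,
         (H, (0.210, -0.005, -0.280)), (R, (0.235, 0.005, -0.565)), [], []),
        ("supinator", 6.9,
         (U, (0.200, -0.030, -0.335)), (R, (0.215, 0.008, -0.352)), [], []),
        ("pronator_teres", 13.2,
         (H, (0.168, -0.012, -0.318)), (R, (0.228, 0.002, -0.430)), [], []),
        ("flexor_carpi_radialis", 6.0,
         (H, (0.170, -0.008, -0.322)), (R, (0.228, 0.012, -0.550)), [], []),
        ("flexor_carpi_ulnaris", 9.0,
         (H, (0.167, -0.015, -0.322)), (U, (0.205, 0.008, -0.575)), [], []),
        ("extensor_carpi_radialis_longus", 6.6,
         (H, (0.212, -0.010, -0.295)), (R, (0.235, -0.003, -0.570)),
         [], []),
        ("extensor_carpi_radialis_brevis", 7.5,
         (H, (0.214, -0.020, -0.310)), (R, (0.233, -0.008, -0.565)),
         [], []),
        ("extensor_carpi_ulnaris", 7.8,
         (H, (0.213, -0.025, -0.312)), (U, (0.207, -0.015, -0.578)),
         [], []),
    ]


# ----------------------------------------------------------------------
# generator
# ----------------------------------------------------------------------

def generate_generic_model(params: Optional[GeneratorParams] = None
                           ) -> GenericModel:
    """Build a complete, validated synthetic shoulder-elbow model.

    Deterministic for a fixed seed; two calls with equal parameters return
    field-wise identical models.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(p.seed)
    k = p.stature / 1.86  # isotropic stature factor for the fixture

    def pos(xyz):
        return np.asarray(xyz, float) * k

    thorax_lms = [Landmark(n, pos(v), "thorax")
                  for n, v in _THORAX_LM.items()]

    seg_lms: Dict[str, Dict[str, np.ndarray]] = {
        "clavicle": {n: pos(v) for n, v in _CLAVICLE_LM.items()},
        "scapula": {n: pos(v) for n, v in _SCAPULA_LM.items()},
        "humerus": {n: pos(v) for n, v in _HUMERUS_LM.items()},
        "ulna": {n: pos(v) for n, v in _ULNA_LM.items()},
        "radius": {n: pos(v) for n, v in _RADIUS_LM.items()},
    }
    # HU is by definition the epicondyle midpoint
    seg_lms["humerus"]["HU"] = 0.5 * (seg_lms["humerus"]["EL"]
                                      + seg_lms["humerus"]["EM"])

    anthro = SC.SubjectAnthropometry(
        p.gender, p.stature, p.mass,
        float(2.0 * seg_lms["scapula"]["AA"][0]))
    bsip = SC.scale_bsip(anthro)

    # centers of mass: girdle bones at chord midpoints/centroid, arm bones
    # at half the proximal-to-distal chord
    HH = seg_lms["scapula"]["HH"]
    HU = seg_lms["humerus"]["HU"]
    com = {
        "clavicle": 0.5 * (pos(_THORAX_LM["SC"]) + seg_lms["clavicle"]["AC"]),
        "scapula": (seg_lms["scapula"]["AA"] + seg_lms["scapula"]["TS"]
                    + seg_lms["scapula"]["AI"]) / 3.0,
        "humerus": HH + 0.437 * (HU - HH),
        "ulna": 0.5 * (HU + seg_lms["ulna"]["US"]),
        "radius": 0.5 * (seg_lms["humerus"]["EL"] + seg_lms["radius"]["RS"]),
    }

    segments = {}
    for name in ("clavicle", "scapula", "humerus", "ulna", "radius"):
        segments[name] = BoneSegment(
            name, 1.0, np.array([1e-3, 1e-3, 1e-3]), com[name], 0.25,
            [Landmark(n, v, name) for n, v in seg_lms[name].items()])

    # ---- ribcage ellipsoids ----------------------------------------
    base = Ellipsoid(pos(_BASE_ELLIPSOID["center"]),
                     np.asarray(_BASE_ELLIPSOID["axes"], float) * k)

    # ---- glenoid, constructed from the requested angles exactly ----
    f_s = K.build_scapula_frame(seg_lms["scapula"]["SN"],
                                seg_lms["scapula"]["AI"],
                                seg_lms["scapula"]["TS"])
    xs, ys, zs = f_s.rotation.T
    GC = HH - (0.023 * k) * xs
    a_gi = math.radians(p.glenoid_inclination)
    a_gv = math.radians(p.glenoid_version)
    u_si = math.cos(a_gi) * zs + math.sin(a_gi) * xs
    u_pa = math.cos(a_gv) * ys + math.sin(a_gv) * xs
    r_si, r_pa = (_GLENOID_RADII[0] * k, _GLENOID_RADII[1] * k)
    glenoid = GlenoidSpec(
        IG=Landmark("IG", GC - r_si * u_si, "scapula"),
        SG=Landmark("SG", GC + r_si * u_si, "scapula"),
        PG=Landmark("PG", GC - r_pa * u_pa, "scapula"),
        AG=Landmark("AG", GC + r_pa * u_pa, "scapula"),
        GC=Landmark("GC", GC, "scapula"),
        inclination=p.glenoid_inclination, version=p.glenoid_version)

    # ---- wrapping objects ------------------------------------------
    elbow_axis = seg_lms["humerus"]["EL"] - seg_lms["humerus"]["EM"]
    elbow_axis = elbow_axis / np.linalg.norm(elbow_axis)
    wraps = [
        WrappingObject("humeral_head", "sphere", HH.copy(),
                       _HEAD_RADIUS * k, "humerus", None, "right"),
        WrappingObject("elbow_extensor", "cylinder",
                       HU + np.array([0.0, -0.004, 0.0]) * k,
                       0.022 * k, "humerus", elbow_axis, "right"),
    ]

    # ---- muscles ----------------------------------------------------
    muscles = []
    for (name, pcsa, orig, ins, vias, wlist) in \
            _muscle_table()[:p.n_muscles]:
        def point(segpos, tag):
            seg, xyz = segpos
            q = pos(xyz)
            # wrap-adjacent attachments stay exact so tangent clearances
            # survive every seed
            if p.seed != 0 and not wlist:
                q = q + rng.normal(0.0, 0.001, 3) * k
            return Landmark(tag, q, seg)

        if name in RC_PCSA:
            pcsa_val = float(pcsa)  # study-condition values, never jittered
        else:
            pcsa_val = float(pcsa * (1.0 + rng.normal(0.0, 0.03))
                             if p.seed != 0 else pcsa)
            pcsa_val = max(pcsa_val, 0.5)
        muscles.append(Muscle(
            name,
            origin=point(orig, f"{name}_o"),
            insertion=point(ins, f"{name}_i"),
            via_points=[point(v, f"{name}_v{i}")
                        for i, v in enumerate(vias)],
            wraps=[(w, g) for w, g in wlist],
            n_strings=1, pcsa=pcsa_val))

    model = GenericModel(
        segments=segments,
        thorax_landmarks=thorax_lms,
        base_ellipsoid=base,
        ts_ellipsoid=base,  # placeholder, replaced by exact dilation below
        ai_ellipsoid=base,
        muscles=muscles,
        wrap_objects=wraps,
        glenoid=glenoid,
        anthropometry_generic=Anthropometry(
            p.gender, p.stature, p.mass, anthro.shoulder_width),
        hand_mass=0.006 * p.mass,
        hand_inertia=np.array([6e-4, 6e-4, 3e-4]) * (p.mass / 85.5) * k**2,
    )
    _apply_generic_bsip(model, bsip)

    # exact ribcage ellipsoids through the reference TS/AI
    identity = SC.ScalingMatrix(np.eye(3))
    d_ts, d_ai, e_ts, e_ai = SC.dilate_ellipsoids(model, identity)
    model.ts_ellipsoid = e_ts
    model.ai_ellipsoid = e_ai
    model.r_m_generic = SC.muscle_percentage(anthro)
    return model.build()


def _apply_generic_bsip(model: GenericModel, bsip: SC.BSIPSet) -> None:
    SC._apply_bsip(model, bsip)


# ----------------------------------------------------------------------
# synthetic videogrammetry export
# ----------------------------------------------------------------------

def export_marker_motion(model: GenericModel, traj: K.JointTrajectory,
                         noise_sd: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Thorax-frame landmark trajectories for the marker sets of every
    moving segment, with optional isotropic Gaussian noise [m].

    Returns a wide table (``time_s`` + ``<LANDMARK>_x/_y/_z`` columns in
    metres) that round-trips through :func:`kinematics.fit_landmarks`.
    """
    rng = np.random.default_rng(seed)
    cols = ["time_s"]
    for seg, names in MARKER_SETS.items():
        for n in names:
            cols.extend([f"{n}_x", f"{n}_y", f"{n}_z"])
    rows = []
    for i in range(len(traj)):
        st = K.ChainState(model, traj.q[i])
        row = [traj.times[i]]
        for seg, names in MARKER_SETS.items():
            for n in names:
                pnt = st.landmark(n, seg)
                if noise_sd > 0:
                    pnt = pnt + rng.normal(0.0, noise_sd, 3)
                row.extend(pnt.tolist())
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
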