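"""Packaged generic lower-limb + three-segment-foot template.

One right lower limb: pelvis (six ground DoFs), femur (three-DoF hip),
shank (one-DoF knee), and a three-segment foot — hindfoot, forefoot
(metatarsals) and toes — giving seventeen DoFs in total: 6 pelvis + 3 hip +
1 knee + 3 ankle + 3 hindfoot/forefoot + 1 forefoot/toes.

The muscle set comprises 54 muscle paths describing 39 distinct muscles
(multi-path muscles carry a ``~k`` suffix per path), 16 of which cross the
ankle or the internal joints of the foot.  Seven ligament records (six
crossing the ankle plus the plantar fascia) are carried but always inactive.

All numeric values — segment dimensions, inertial properties, muscle path
coordinates and maximum isometric forces — are documented,
literature-plausible placeholders sized for a juvenile lower limb
(≈1.45 m stature); they are configuration, not code, and can be replaced
wholesale via the JSON model schema.

Coordinates are metres in segment-local frames (X anterior, Y up, Z lateral,
right side); each segment's origin sits at its proximal joint centre.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "default_template_config",
    "default_landmark_groups",
    "default_landmarks",
    "MRI_FOOT_MARKERS",
    "default_perturbation_structures",
    "SEGMENT_MASS_FRACTIONS",
]

# Anthropometric layout (m) for the reference pose (standing, all q = 0).
PELVIS_HEIGHT = 0.87        # pelvis origin above ground
HIP_IN_PELVIS = (0.0, -0.07, 0.09)
FEMUR_LENGTH = 0.38         # hip centre -> knee centre
SHANK_LENGTH = 0.35         # knee centre -> ankle centre
MIDFOOT_IN_HINDFOOT = (0.05, -0.035, 0.0)
MTP_IN_FOREFOOT = (0.055, -0.015, 0.0)

# Segment mass fractions of whole-body mass (Dempster-style, foot split
# 60/30/10 across hindfoot/forefoot/toes).
SEGMENT_MASS_FRACTIONS = {
    "pelvis": 0.142,
    "femur": 0.100,
    "shank": 0.0465,
    "hindfoot": 0.0145 * 0.6,
    "forefoot": 0.0145 * 0.3,
    "toes": 0.0145 * 0.1,
}

_TEMPLATE_MASS_KG = 50.0

# The six gait markers replicated with radio-opaque markers in the MRI scan:
# lateral/medial malleolus, 5th metatarsal head, between 2nd and 3rd
# metatarsal heads, 1st metatarsal head, base of the hallux.
MRI_FOOT_MARKERS = ("RLML", "RMML", "RD5M", "RD23M", "RD1M", "RHLX")


def _rod_inertia(mass, length, radius):
    """Solid-rod inertia about the COM, long axis = Y."""
    ixx = izz = mass * (3 * radius**2 + length**2) / 12.0
    iyy = mass * radius**2 / 2.0
    return np.diag([ixx, iyy, izz]).tolist()


def _segments():
    m = {k: f * _TEMPLATE_MASS_KG for k, f in SEGMENT_MASS_FRACTIONS.items()}
    return [
        {"name": "pelvis", "mass": m["pelvis"], "com": [0.0, -0.02, 0.0],
         "inertia": _rod_inertia(m["pelvis"], 0.15, 0.10)},
        {"name": "femur", "mass": m["femur"], "com": [0.0, -0.17, 0.0],
         "inertia": _rod_inertia(m["femur"], FEMUR_LENGTH, 0.04)},
        {"name": "shank", "mass": m["shank"], "com": [0.0, -0.15, 0.0],
         "inertia": _rod_inertia(m["shank"], SHANK_LENGTH, 0.03)},
        {"name": "hindfoot", "mass": m["hindfoot"], "com": [-0.01, -0.04, 0.0],
         "inertia": _rod_inertia(m["hindfoot"], 0.08, 0.03)},
        {"name": "forefoot", "mass": m["forefoot"], "com": [0.03, -0.02, 0.0],
         "inertia": _rod_inertia(m["forefoot"], 0.06, 0.02)},
        {"name": "toes", "mass": m["toes"], "com": [0.02, -0.005, 0.0],
         "inertia": _rod_inertia(m["toes"], 0.03, 0.01)},
    ]


def _joints():
    rot = lambda n, ax, **kw: {"name": n, "kind": "rotation", "axis": ax, **kw}
    tra = lambda n, ax, **kw: {"name": n, "kind": "translation", "axis": ax, **kw}
    return [
        {
            "name": "ground_pelvis", "parent": "ground", "child": "pelvis",
            "parent_frame": {"t": [0.0, PELVIS_HEIGHT, 0.0]},
            "dofs": [
                tra("pelvis_tx", "x"), tra("pelvis_ty", "y"), tra("pelvis_tz", "z"),
                rot("pelvis_tilt", "z"), rot("pelvis_list", "x"), rot("pelvis_rot", "y"),
            ],
        },
        {
            "name": "hip", "parent": "pelvis", "child": "femur",
            "parent_frame": {"t": list(HIP_IN_PELVIS)},
            "dofs": [
                rot("hip_flexion", "z"), rot("hip_adduction", "x"),
                rot("hip_rotation", "y"),
            ],
        },
        {
            "name": "knee", "parent": "femur", "child": "shank",
            "parent_frame": {"t": [0.0, -FEMUR_LENGTH, 0.0]},
            "dofs": [rot("knee_flexion", "z")],
        },
        {
            "name": "ankle", "parent": "shank", "child": "hindfoot",
            "parent_frame": {"t": [0.0, -SHANK_LENGTH, 0.0]},
            "dofs": [
                rot("ankle_flexion", "z"), rot("ankle_inversion", "x"),
                rot("ankle_rotation", "y"),
            ],
        },
        {
            "name": "midfoot", "parent": "hindfoot", "child": "forefoot",
            "parent_frame": {"t": list(MIDFOOT_IN_HINDFOOT)},
            "dofs": [
                rot("midfoot_flexion", "z"), rot("midfoot_inversion", "x"),
                rot("midfoot_rotation", "y"),
            ],
        },
        {
            "name": "mtp", "parent": "forefoot", "child": "toes",
            "parent_frame": {"t": list(MTP_IN_FOREFOOT)},
            "dofs": [rot("mtp_flexion", "z")],
        },
    ]


# Shared Achilles insertion on the calcaneus (soleus + both gastrocnemii):
# slightly lateral of the sagittal midline of the hindfoot.
ACHILLES_INSERTION = (-0.045, -0.035, 0.002)


def _muscles():
    """(name, fmax N, crosses_ankle, [(segment, xyz), ...])"""
    P, F, S, H, FF, T = "pelvis", "femur", "shank", "hindfoot", "forefoot", "toes"
    defs = [
        # --- hip / thigh ---------------------------------------------------
        ("glut_max~1", 720, 0, [(P, (-0.10, 0.02, 0.04)), (F, (-0.03, -0.06, 0.03))]),
        ("glut_max~2", 720, 0, [(P, (-0.11, -0.01, 0.05)), (F, (-0.03, -0.10, 0.02))]),
        ("glut_max~3", 660, 0, [(P, (-0.11, -0.04, 0.05)), (F, (-0.02, -0.14, 0.015))]),
        ("glut_med~1", 480, 0, [(P, (0.055, 0.015, 0.10)), (F, (-0.035, -0.034, 0.060))]),
        ("glut_med~2", 480, 0, [(P, (-0.05, 0.01, 0.095)), (F, (-0.012, -0.040, 0.070))]),
        ("glut_med~3", 420, 0, [(P, (-0.07, 0.00, 0.085)), (F, (-0.015, -0.045, 0.065))]),
        ("glut_min~1", 180, 0, [(P, (0.045, 0.00, 0.095)), (F, (-0.025, -0.032, 0.060))]),
        ("glut_min~2", 180, 0, [(P, (-0.04, -0.01, 0.090)), (F, (-0.005, -0.035, 0.068))]),
        ("glut_min~3", 180, 0, [(P, (-0.06, -0.02, 0.085)), (F, (-0.010, -0.040, 0.066))]),
        ("iliacus~1", 540, 0, [(P, (0.01, -0.01, 0.06)), (P, (0.035, -0.075, 0.075)),
                               (F, (-0.015, -0.050, 0.045))]),
        ("iliacus~2", 420, 0, [(P, (0.02, 0.00, 0.055)), (P, (0.035, -0.073, 0.072)),
                               (F, (-0.013, -0.048, 0.043))]),
        ("psoas~1", 480, 0, [(P, (0.02, 0.08, 0.03)), (P, (0.036, -0.074, 0.070)),
                             (F, (-0.016, -0.052, 0.042))]),
        ("psoas~2", 360, 0, [(P, (0.015, 0.06, 0.028)), (P, (0.036, -0.076, 0.068)),
                             (F, (-0.014, -0.054, 0.040))]),
        ("tfl~1", 200, 0, [(P, (0.06, 0.01, 0.10)), (F, (0.02, -0.10, 0.06))]),
        ("tfl~2", 160, 0, [(P, (0.055, 0.005, 0.10)), (F, (0.015, -0.14, 0.058))]),
        ("sartorius", 120, 0, [(P, (0.075, 0.005, 0.095)), (F, (0.01, -0.25, -0.045)),
                               (S, (0.010, -0.040, -0.040))]),
        ("gracilis", 150, 0, [(P, (0.03, -0.08, 0.02)), (S, (0.005, -0.045, -0.040))]),
        ("piriformis", 240, 0, [(P, (-0.09, -0.02, 0.02)), (F, (-0.010, -0.030, 0.065))]),
        ("pectineus~1", 180, 0, [(P, (0.02, -0.06, 0.04)), (F, (-0.010, -0.080, 0.010))]),
        ("pectineus~2", 150, 0, [(P, (0.025, -0.058, 0.045)), (F, (-0.008, -0.085, 0.012))]),
        ("quad_fem", 180, 0, [(P, (-0.06, -0.08, 0.03)), (F, (-0.020, -0.040, 0.055))]),
        ("gem", 120, 0, [(P, (-0.08, -0.05, 0.03)), (F, (-0.012, -0.028, 0.062))]),
        ("add_long~1", 360, 0, [(P, (0.025, -0.075, 0.025)), (F, (0.005, -0.200, -0.005))]),
        ("add_long~2", 300, 0, [(P, (0.028, -0.073, 0.028)), (F, (0.005, -0.220, -0.006))]),
        ("add_brev~1", 240, 0, [(P, (0.01, -0.08, 0.02)), (F, (0.000, -0.120, 0.000))]),
        ("add_brev~2", 210, 0, [(P, (0.012, -0.078, 0.022)), (F, (0.000, -0.140, -0.002))]),
        ("add_mag~1", 300, 0, [(P, (-0.02, -0.095, 0.015)), (F, (0.000, -0.140, -0.010))]),
        ("add_mag~2", 300, 0, [(P, (-0.025, -0.095, 0.018)), (F, (-0.005, -0.250, -0.015))]),
        ("add_mag~3", 300, 0, [(P, (-0.03, -0.093, 0.02)), (F, (0.000, -0.370, -0.030))]),
        ("rect_fem", 660, 0, [(P, (0.06, -0.03, 0.085)), (F, (0.040, -0.360, 0.000)),
                              (S, (0.035, -0.060, 0.000))]),
        ("vas_lat", 1080, 0, [(F, (0.02, -0.12, 0.04)), (F, (0.040, -0.360, 0.010)),
                              (S, (0.035, -0.060, 0.005))]),
        ("vas_med", 780, 0, [(F, (0.015, -0.18, -0.02)), (F, (0.040, -0.360, -0.010)),
                             (S, (0.035, -0.060, -0.005))]),
        ("vas_int", 780, 0, [(F, (0.025, -0.15, 0.01)), (F, (0.040, -0.360, 0.000)),
                             (S, (0.035, -0.060, 0.000))]),
        ("semimem~1", 500, 0, [(P, (-0.07, -0.09, 0.02)), (S, (-0.020, -0.030, -0.030))]),
        ("semimem~2", 400, 0, [(P, (-0.072, -0.088, 0.022)), (S, (-0.018, -0.035, -0.028))]),
        ("semiten", 240, 0, [(P, (-0.072, -0.092, 0.025)), (S, (-0.010, -0.050, -0.035))]),
        ("bifemlh", 540, 0, [(P, (-0.068, -0.088, 0.03)), (S, (-0.020, -0.025, 0.035))]),
        ("bifemsh", 300, 0, [(F, (-0.01, -0.22, 0.03)), (S, (-0.020, -0.025, 0.035))]),
        # --- crossing the ankle / internal foot joints ----------------------
        ("soleus", 2100, 1, [(S, (-0.015, -0.10, 0.005)), (H, ACHILLES_INSERTION)]),
        ("med_gas", 900, 1, [(F, (-0.012, -0.36, -0.022)), (S, (-0.025, -0.12, -0.010)),
                             (H, ACHILLES_INSERTION)]),
        ("lat_gas", 420, 1, [(F, (-0.012, -0.36, 0.025)), (S, (-0.025, -0.12, 0.012)),
                             (H, ACHILLES_INSERTION)]),
        ("tib_ant", 540, 1, [(S, (0.018, -0.10, 0.012)), (S, (0.033, -0.335, -0.006)),
                             (FF, (0.008, -0.018, -0.028))]),
        ("tib_post", 900, 1, [(S, (-0.012, -0.12, 0.003)), (S, (-0.016, -0.345, -0.027)),
                              (H, (-0.002, -0.028, -0.030)), (FF, (0.002, -0.022, -0.030))]),
        ("per_long", 410, 1, [(S, (-0.004, -0.13, 0.022)), (S, (-0.020, -0.345, 0.030)),
                              (H, (-0.004, -0.035, 0.032)), (FF, (-0.005, -0.032, 0.022)),
                              (FF, (0.012, -0.033, -0.022))]),
        ("per_brev", 210, 1, [(S, (-0.004, -0.20, 0.024)), (S, (-0.018, -0.345, 0.028)),
                              (FF, (0.002, -0.028, 0.033))]),
        ("per_tert", 60, 1, [(S, (0.012, -0.24, 0.018)), (S, (0.030, -0.335, 0.018)),
                             (FF, (0.008, -0.012, 0.030))]),
        ("flex_hal_long", 720, 1, [(S, (-0.014, -0.18, 0.010)), (S, (-0.018, -0.348, -0.020)),
                                   (H, (0.000, -0.032, -0.018)), (FF, (0.048, -0.034, -0.020)),
                                   (T, (0.028, -0.006, -0.020))]),
        ("flex_dig_long", 360, 1, [(S, (-0.010, -0.16, -0.002)), (S, (-0.015, -0.346, -0.024)),
                                   (H, (0.000, -0.030, -0.008)), (FF, (0.048, -0.033, 0.006)),
                                   (T, (0.028, -0.006, 0.008))]),
        ("ext_hal_long", 240, 1, [(S, (0.014, -0.16, 0.006)), (S, (0.032, -0.333, -0.004)),
                                  (FF, (0.050, -0.008, -0.018)), (T, (0.030, 0.004, -0.018))]),
        ("ext_dig_long", 300, 1, [(S, (0.013, -0.13, 0.016)), (S, (0.033, -0.333, 0.010)),
                                  (FF, (0.050, -0.006, 0.010)), (T, (0.030, 0.004, 0.010))]),
        ("flex_dig_brev", 360, 1, [(H, (-0.035, -0.060, 0.005)), (FF, (0.045, -0.036, 0.006)),
                                   (T, (0.022, -0.008, 0.008))]),
        ("flex_hal_brev", 300, 1, [(FF, (0.020, -0.030, -0.022)), (FF, (0.048, -0.034, -0.020)),
                                   (T, (0.020, -0.008, -0.020))]),
        ("ext_dig_brev", 180, 1, [(H, (-0.010, -0.045, 0.025)), (FF, (0.048, -0.010, 0.012)),
                                  (T, (0.024, 0.003, 0.010))]),
        ("abd_hal", 240, 1, [(H, (-0.040, -0.060, -0.015)), (FF, (0.045, -0.034, -0.024)),
                             (T, (0.020, -0.006, -0.024))]),
    ]
    return [
        {"name": n, "fmax": float(f), "crosses_ankle": bool(c),
         "points": [[s, list(map(float, p))] for s, p in pts]}
        for n, f, c, pts in defs
    ]


def _ligaments():
    S, H, FF, T = "shank", "hindfoot", "forefoot", "toes"
    defs = [
        ("lig_atfl", [(S, (-0.008, -0.345, 0.030)), (H, (0.012, -0.012, 0.026))]),
        ("lig_ptfl", [(S, (-0.018, -0.345, 0.030)), (H, (-0.015, -0.010, 0.024))]),
        ("lig_cfl", [(S, (-0.010, -0.347, 0.032)), (H, (-0.010, -0.040, 0.028))]),
        ("lig_deltoid_ant", [(S, (-0.002, -0.344, -0.030)), (H, (0.012, -0.015, -0.024))]),
        ("lig_deltoid_post", [(S, (-0.012, -0.344, -0.030)), (H, (-0.012, -0.018, -0.022))]),
        ("lig_tib_nav", [(S, (0.000, -0.342, -0.028)), (FF, (0.004, -0.020, -0.026))]),
        ("lig_plantar_fascia", [(H, (-0.048, -0.064, 0.000)), (FF, (0.050, -0.036, 0.000)),
                                (T, (0.012, -0.010, 0.000))]),
    ]
    return [{"name": n, "points": [[s, list(map(float, p))] for s, p in pts]}
            for n, pts in defs]


def _markers():
    P, F, S, H, FF, T = "pelvis", "femur", "shank", "hindfoot", "forefoot", "toes"
    # LASI/LPSI/LGT ride on the pelvis: the left limb is not modelled, but
    # the pelvis scaling distances need both sides.
    m = {
        "RASI": (P, (0.08, 0.01, 0.11)), "LASI": (P, (0.08, 0.01, -0.11)),
        "RPSI": (P, (-0.09, 0.02, 0.04)), "LPSI": (P, (-0.09, 0.02, -0.04)),
        "LGT": (P, (-0.01, -0.105, -0.165)),
        "RGT": (F, (-0.01, -0.035, 0.075)),
        "RTHI": (F, (0.02, -0.20, 0.05)),
        "RLFE": (F, (0.0, -0.38, 0.05)), "RMFE": (F, (0.0, -0.38, -0.045)),
        "RTIB": (S, (0.015, -0.12, 0.045)), "RSHN": (S, (0.005, -0.22, 0.040)),
        "RLML": (S, (-0.005, -0.345, 0.035)), "RMML": (S, (-0.005, -0.345, -0.032)),
        "RHEE": (H, (-0.055, -0.055, 0.0)), "RPCA": (H, (-0.050, -0.020, 0.012)),
        "RLCA": (H, (-0.025, -0.050, 0.030)),
        "RP1M": (FF, (0.010, -0.020, -0.025)),
        "RD1M": (FF, (0.055, -0.028, -0.028)),
        "RD5M": (FF, (0.045, -0.025, 0.035)),
        "RD23M": (FF, (0.052, -0.020, 0.005)),
        "RHLX": (T, (0.012, -0.005, -0.022)), "RTOE": (T, (0.035, -0.003, 0.0)),
    }
    return {k: [seg, list(map(float, p))] for k, (seg, p) in m.items()}


def default_template_config() -> dict:
    """Template description consumed by :func:`tarsus.model.build_template`."""
    return {
        "segments": _segments(),
        "joints": _joints(),
        "muscles": _muscles(),
        "ligaments": _ligaments(),
        "markers": _markers(),
        "meta": {
            "name": "tarsus-juvenile-lower-limb",
            "template_mass_kg": _TEMPLATE_MASS_KG,
            "mri_foot_markers": list(MRI_FOOT_MARKERS),
        },
    }


# ---------------------------------------------------------------------------
# Virtual-palpation landmark dictionaries
# ---------------------------------------------------------------------------


def default_landmark_groups() -> dict[str, list[str]]:
    """Landmark names per registration group (hindfoot 10, talus 6,
    metatarsal 15, toe 17, shank 6)."""
    lms = default_landmarks()
    groups: dict[str, list[str]] = {}
    for name, (group, _seg, _p) in lms.items():
        groups.setdefault(group, []).append(name)
    return groups


def default_landmarks() -> dict[str, tuple[str, str, tuple]]:
    """name -> (group, owning segment, local coordinates).

    Talus landmarks ride on the hindfoot segment (the talus is not an
    articulated segment of the model) but form their own registration group.
    """
    H, FF, T, S = "hindfoot", "forefoot", "toes", "shank"
    out: dict[str, tuple[str, str, tuple]] = {}

    hindfoot = {
        "CAL_TUBER_MED": (-0.050, -0.060, -0.012),
        "CAL_TUBER_LAT": (-0.048, -0.060, 0.014),
        "CAL_POST_SUP": (-0.058, -0.025, 0.000),
        "CAL_SUSTENTACULUM": (-0.012, -0.045, -0.028),
        "CAL_PERONEAL_TROCH": (-0.012, -0.048, 0.030),
        "CAL_ANT_SUP": (0.015, -0.030, 0.008),
        "CAL_CUBOID_FACET": (0.020, -0.042, 0.018),
        "CAL_MED_PROC": (-0.040, -0.063, -0.006),
        "CAL_LAT_PROC": (-0.038, -0.063, 0.010),
        "CAL_DORSAL_SULCUS": (-0.020, -0.018, 0.004),
    }
    for k, v in hindfoot.items():
        out[k] = ("hindfoot", H, v)

    talus = {
        "TAL_HEAD": (0.030, -0.012, -0.008),
        "TAL_NECK_SUP": (0.018, -0.006, 0.000),
        "TAL_DOME_MED": (0.000, 0.002, -0.014),
        "TAL_DOME_LAT": (0.000, 0.002, 0.016),
        "TAL_POST_TUBERCLE": (-0.024, -0.012, 0.002),
        "TAL_LAT_PROCESS": (-0.004, -0.018, 0.022),
    }
    for k, v in talus.items():
        out[k] = ("talus", H, v)

    # Metatarsals 1-5: base / midshaft / head each.
    z = {1: -0.026, 2: -0.012, 3: 0.002, 4: 0.017, 5: 0.031}
    for i in range(1, 6):
        out[f"MT{i}_BASE"] = ("metatarsal", FF, (0.006, -0.024, z[i]))
        out[f"MT{i}_MID"] = ("metatarsal", FF, (0.030, -0.022 - 0.001 * i, z[i]))
        out[f"MT{i}_HEAD"] = ("metatarsal", FF, (0.053, -0.027, z[i]))

    # Toes: proximal phalanx base/head per ray, distal tips, hallux IP pair.
    for i in range(1, 6):
        out[f"PP{i}_BASE"] = ("toe", T, (0.004, -0.006, z[i] + 0.004))
        out[f"PP{i}_HEAD"] = ("toe", T, (0.020, -0.007, z[i] + 0.004))
        out[f"DP{i}_TIP"] = ("toe", T, (0.036 - 0.002 * i, -0.008, z[i] + 0.004))
    out["HLX_IP_MED"] = ("toe", T, (0.027, -0.003, -0.027))
    out["HLX_IP_LAT"] = ("toe", T, (0.027, -0.003, -0.017))

    shank_distal = {
        "TIB_MED_MALL": (-0.004, -0.346, -0.033),
        "FIB_LAT_MALL": (-0.007, -0.348, 0.036),
        "TIB_ANT_CREST_DIST": (0.016, -0.300, -0.002),
        "TIB_MED_SURF_DIST": (0.002, -0.310, -0.028),
        "FIB_SHAFT_DIST": (-0.006, -0.300, 0.032),
        "TIB_POST_DIST": (-0.020, -0.305, 0.000),
    }
    for k, v in shank_distal.items():
        out[k] = ("shank", S, v)

    return out


def default_perturbation_structures() -> list[tuple[str, list[tuple[str, int]]]]:
    """The ten perturbed structures: label -> [(muscle path, point index)].

    The Achilles tendon insertion (shared by soleus and both gastrocnemii)
    moves as one structure; for each remaining muscle crossing the ankle the
    perturbed point is the one immediately distal to the joint.
    """
    return [
        ("achilles_I", [("soleus", 1), ("med_gas", 2), ("lat_gas", 2)]),
        ("tib_ant_I", [("tib_ant", 2)]),
        ("tib_post_via1", [("tib_post", 2)]),
        ("per_long_via1", [("per_long", 2)]),
        ("per_tert_I", [("per_tert", 2)]),
        ("per_brev_I", [("per_brev", 2)]),
        ("flex_hal_long_via1", [("flex_hal_long", 2)]),
        ("flex_dig_long_via1", [("flex_dig_long", 2)]),
        ("ext_hal_long_via1", [("ext_hal_long", 2)]),
        ("ext_dig_long_via1", [("ext_dig_long", 2)]),
    ]
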