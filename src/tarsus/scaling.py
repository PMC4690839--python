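"""Generic-to-patient scaling and the marker/MRI registration chain.

The pipeline deforms the generic template onto a patient: the proximal
segments (pelvis, femur, shank) are scaled from static-trial marker
distances; the foot is made patient-specific by per-segment registration of
the generic muscle points onto virtually palpated bone landmarks, with the
ankle joint centre and flexion axis taken from a cylinder fitted to the
talar dome.  Every stage logs its transform and residual (mm) into the
assembled model's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import template as tpl
from .gait_io import GaitTrial
from .geometry import (
    AnatomicalFrame,
    Cylinder,
    DegenerateGeometryError,
    LandmarkSet,
    RigidTransform,
    ankle_frame_cga,
    ankle_frame_mr,
    fit_cylinder,
    frame_difference,
    horn_register,
    rotation_about_axis,
)
from .model import Model, ModelError, PatientMeta, forward_kinematics

__all__ = [
    "ScaleFactors",
    "StaticTrialSummary",
    "PatientInputs",
    "PipelineStageError",
    "average_static_trial",
    "compute_scale_factors",
    "apply_scaling",
    "set_patient_mass",
    "register_foot_to_mri",
    "optimize_femur_rotation",
    "assemble_patient_model",
    "apply_ankle_frame",
    "reference_marker_positions",
    "reference_landmark_positions",
]


class PipelineStageError(RuntimeError):
    """Failure in a named stage of the patient-model assembly."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ScaleFactors:
    """Patient/generic ratios: pelvis (depth, height, width), femur and shank lengths."""

    pelvis: tuple[float, float, float]
    femur: float
    shank: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in (*self.pelvis, self.femur, self.shank)):
            raise ModelError("scale factors must be positive")

    @staticmethod
    def unity() -> "ScaleFactors":
        return ScaleFactors((1.0, 1.0, 1.0), 1.0, 1.0)


@dataclass
class StaticTrialSummary:
    """Time-averaged marker positions of a static standing trial."""

    positions: dict[str, np.ndarray]
    duration_s: float
    n_frames: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def landmark_set(self) -> LandmarkSet:
        return LandmarkSet({k: v.copy() for k, v in self.positions.items()},
                           source="static")


def average_static_trial(trial: GaitTrial, required: list[str] | None = None,
                         min_visible_fraction: float = 0.5) -> StaticTrialSummary:
    """Per-marker time average over the frames where the marker is visible.

    Markers visible in fewer than ``min_visible_fraction`` of frames are an
    error (when listed in ``required``, which defaults to every label).
    """
    ms = trial.markers
    required = list(ms.labels) if required is None else required
    missing = [r for r in required if r not in ms.labels]
    if missing:
        raise ModelError(f"required markers absent from static trial: {missing}")
    out: dict[str, np.ndarray] = {}
    bad: list[str] = []
    for j, lab in enumerate(ms.labels):
        vis = ms.visible[:, j]
        if lab in required and vis.mean() < min_visible_fraction:
            bad.append(lab)
            continue
        if np.any(vis):
            out[lab] = ms.data[vis, j, :].mean(axis=0)
    if bad:
        raise ModelError(
            f"markers visible in fewer than {min_visible_fraction:.0%} of static "
            f"frames: {bad}"
        )
    return StaticTrialSummary(out, (ms.n_frames - 1) / ms.rate, ms.n_frames)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def reference_marker_positions(model: Model) -> dict[str, np.ndarray]:
    """World marker positions in the reference pose (all coordinates zero)."""
    poses = forward_kinematics(model, model.default_state())
    return {n: poses[seg].apply(p) for n, (seg, p) in model.markers.items()}


def reference_landmark_positions(model: Model,
                                 landmarks: dict | None = None) -> LandmarkSet:
    """World positions of the palpation landmark dictionary in the reference pose."""
    landmarks = landmarks if landmarks is not None else tpl.default_landmarks()
    poses = forward_kinematics(model, model.default_state())
    pts, segs = {}, {}
    for name, (_group, seg, local) in landmarks.items():
        pts[name] = poses[seg].apply(np.asarray(local, dtype=float))
        segs[name] = seg
    return LandmarkSet(pts, segs, source="generic")


def _dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def _pelvis_dimensions(p) -> tuple[float, float, float]:
    mid_asis = 0.5 * (p["RASI"] + p["LASI"])
    mid_psis = 0.5 * (p["RPSI"] + p["LPSI"])
    depth = _dist(mid_asis, mid_psis)
    mean_all = 0.25 * (p["RASI"] + p["LASI"] + p["RPSI"] + p["LPSI"])
    mid_gt = 0.5 * (p["RGT"] + p["LGT"])
    height = _dist(mean_all, mid_gt)
    width = _dist(0.5 * (p["RASI"] + p["RPSI"]), 0.5 * (p["LASI"] + p["LPSI"]))
    return depth, height, width


def compute_scale_factors(generic: dict[str, np.ndarray],
                          patient: StaticTrialSummary | dict) -> ScaleFactors:
    """Patient/generic scale ratios from anthropometric marker distances.

    Pelvis: depth = mid-ASIS to mid-PSIS; height = mean ASIS/PSIS point to
    mid greater trochanters; width = mid right ASIS/PSIS to mid left
    ASIS/PSIS.  Femur: greater trochanter to mid femoral epicondyles.
    Shank: mid epicondyles to mid malleoli.
    """
    pat = patient.positions if isinstance(patient, StaticTrialSummary) else patient
    pat = {k: np.asarray(v, dtype=float) for k, v in pat.items()}
    generic = {k: np.asarray(v, dtype=float) for k, v in generic.items()}
    needed = ["RASI", "LASI", "RPSI", "LPSI", "RGT", "LGT", "RLFE", "RMFE",
              "RLML", "RMML"]
    for src, tag in ((generic, "generic"), (pat, "patient")):
        missing = [n for n in needed if n not in src]
        if missing:
            raise ModelError(f"missing {tag} markers for scaling: {missing}")
    gd, gh, gw = _pelvis_dimensions(generic)
    pd, ph, pw = _pelvis_dimensions(pat)
    g_epi = 0.5 * (np.asarray(generic["RLFE"]) + np.asarray(generic["RMFE"]))
    p_epi = 0.5 * (np.asarray(pat["RLFE"]) + np.asarray(pat["RMFE"]))
    g_mal = 0.5 * (np.asarray(generic["RLML"]) + np.asarray(generic["RMML"]))
    p_mal = 0.5 * (np.asarray(pat["RLML"]) + np.asarray(pat["RMML"]))
    g_femur = _dist(generic["RGT"], g_epi)
    p_femur = _dist(pat["RGT"], p_epi)
    g_shank = _dist(g_epi, g_mal)
    p_shank = _dist(p_epi, p_mal)
    for name, g in (("pelvis depth", gd), ("pelvis height", gh),
                    ("pelvis width", gw), ("femur", g_femur), ("shank", g_shank)):
        if g <= 0:
            raise ModelError(f"zero generic distance for {name}")
    return ScaleFactors((pd / gd, ph / gh, pw / gw), p_femur / g_femur,
                        p_shank / g_shank)


_SCALED_SEGMENTS = ("pelvis", "femur", "shank")


def apply_scaling(model: Model, s: ScaleFactors) -> Model:
    """Scale pelvis (anisotropically: depth->X, height->Y, width->Z), femur
    and shank (isotropically) segment-local geometry: muscle points, markers,
    COM, and the child-joint frame translations.  Returns a new model."""
    out = model.copy()
    factors = {
        "pelvis": np.array(s.pelvis),
        "femur": np.full(3, s.femur),
        "shank": np.full(3, s.shank),
    }
    for seg_name, f in factors.items():
        seg = out.segments[seg_name]
        seg.com = seg.com * f
        for m in out.muscles + out.ligaments:
            m.points = [
                (sn, p * f if sn == seg_name else p) for sn, p in m.points
            ]
        for name, (sn, p) in out.markers.items():
            if sn == seg_name:
                out.markers[name] = (sn, p * f)
        for j in out.joints:
            if j.parent_segment == seg_name:
                j.parent_frame = RigidTransform(j.parent_frame.R,
                                                j.parent_frame.t * f)
    return out


def set_patient_mass(model: Model, meta: PatientMeta) -> Model:
    """Distribute the patient's mass over segments by template proportions."""
    out = model.copy()
    out.patient_meta = meta
    for name, seg in out.segments.items():
        frac = tpl.SEGMENT_MASS_FRACTIONS.get(name)
        if frac is not None:
            old = seg.mass
            seg.mass = frac * meta.mass_kg
            if old > 0:
                seg.inertia = seg.inertia * (seg.mass / old)
    return out


# ---------------------------------------------------------------------------
# Registrations
# ---------------------------------------------------------------------------


def register_foot_to_mri(static: StaticTrialSummary,
                         mri_markers: LandmarkSet) -> tuple[RigidTransform, float]:
    """Rigid registration from the averaged static foot markers (including
    the malleoli) to the marker replicas identified in the MRI scan."""
    return horn_register(static.landmark_set(), mri_markers)


def optimize_femur_rotation(
    femur_landmarks: LandmarkSet | dict,
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    gt_marker: np.ndarray,
    gt_name: str = "RGT",
    tol: float = 1e-10,
):
    """Rotate the femur landmarks about the knee flexion axis to match the
    greater-trochanter gait marker.

    Minimises ``||R(theta) GT_palpated - GT_marker||`` by bounded scalar
    (Brent) search on [-pi, pi]; returns ``(theta, rotated_landmarks)``.
    """
    pts = dict(femur_landmarks.points if isinstance(femur_landmarks, LandmarkSet)
               else femur_landmarks)
    if gt_name not in pts:
        raise ModelError(f"missing palpated landmark {gt_name!r}")
    c = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    gt_p = np.asarray(pts[gt_name], dtype=float)
    rel = gt_p - c
    perp = rel - (rel @ d) * d
    if np.linalg.norm(perp) < 1e-9:
        raise DegenerateGeometryError(
            "palpated greater trochanter lies on the knee axis; rotation is "
            "unobservable"
        )
    target = np.asarray(gt_marker, dtype=float)

    def cost(theta):
        R = rotation_about_axis(d, theta)
        return float(np.linalg.norm(c + R @ rel - target))

    res = minimize_scalar(cost, bounds=(-np.pi, np.pi), method="bounded",
                          options={"xatol": tol})
    theta = float(res.x)
    R = rotation_about_axis(d, theta)
    rotated = {n: c + R @ (np.asarray(p, float) - c) for n, p in pts.items()}
    out = LandmarkSet(rotated,
                      dict(femur_landmarks.segments)
                      if isinstance(femur_landmarks, LandmarkSet) else {},
                      "femur-rotated")
    return theta, out


# ---------------------------------------------------------------------------
# Ankle frame installation
# ---------------------------------------------------------------------------


def _frame_to_local(frame: AnatomicalFrame, pose: RigidTransform):
    R = pose.R.T @ frame.axes
    o = pose.inverse().apply(frame.origin)
    return R, o


def apply_ankle_frame(model: Model, label: str) -> Model:
    """Install the MR or CGA ankle frame stored in ``model.meta`` as the
    ankle joint's axes and centre; returns a new model."""
    frames = model.meta.get("ankle_frames")
    if not frames or label not in frames:
        raise ModelError(f"model carries no ankle frame {label!r}")
    rec = frames[label]
    out = model.copy()
    poses = forward_kinematics(out, out.default_state())
    frame = AnatomicalFrame(np.asarray(rec["origin"]), np.asarray(rec["axes"]))
    joint = out.joint_by_child["hindfoot"]
    Rp, op = _frame_to_local(frame, poses[joint.parent_segment])
    Rc, oc = _frame_to_local(frame, poses["hindfoot"])
    joint.parent_frame = RigidTransform(Rp, op)
    joint.child_frame = RigidTransform(Rc, oc)
    out.meta["ankle_frame_label"] = label
    return out


# ---------------------------------------------------------------------------
# Full assembly
# ---------------------------------------------------------------------------


@dataclass
class PatientInputs:
    """Everything the assembly pipeline consumes for one patient."""

    bone_landmarks: LandmarkSet          # virtually palpated, MRI coords
    dome_points: np.ndarray              # talar dome sample, MRI coords
    mri_markers: LandmarkSet             # marker replicas, MRI coords
    static_trial: GaitTrial
    meta: PatientMeta
    landmark_groups: dict[str, list[str]] = field(
        default_factory=tpl.default_landmark_groups)


_GROUP_TO_SEGMENT = {"hindfoot": "hindfoot", "talus": "hindfoot",
                     "metatarsal": "forefoot", "toe": "toes", "shank": "shank"}


def assemble_patient_model(template_model: Model, inputs: PatientInputs) -> Model:
    """Run the full patient-specific assembly chain on a template model.

    Stages (in order): static-trial averaging; pelvis/femur/shank scaling;
    foot-markers-to-MRI registration; MRI-to-model registration; per-segment
    muscle-point mapping; cylinder fit to the talar dome; MR and CGA ankle
    frame construction (MR installed); shank/leg registration; femur rotation
    optimization; pelvis registration.  Each stage appends a provenance
    record (transform, residual in mm) to ``model.meta['provenance']``.
    """
    prov: list[dict] = []

    def log(stage, transform=None, residual_mm=None, **extra):
        rec = {"stage": stage}
        if transform is not None:
            rec["transform"] = np.asarray(transform.matrix()).tolist()
        if residual_mm is not None:
            rec["residual_mm"] = float(residual_mm)
        rec.update(extra)
        prov.append(rec)

    def run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    static = run("static_average", lambda: average_static_trial(
        inputs.static_trial,
        required=["RASI", "LASI", "RPSI", "LPSI", "RGT", "LGT",
                  "RLFE", "RMFE", "RLML", "RMML"]))
    log("static_average", n_frames=static.n_frames)

    def _scale():
        generic = reference_marker_positions(template_model)
        s = compute_scale_factors(generic, static)
        m = apply_scaling(template_model, s)
        return s, set_patient_mass(m, inputs.meta)

    s, model = run("scaling", _scale)
    log("scaling", pelvis=list(s.pelvis), femur=s.femur, shank=s.shank)

    refpos = reference_marker_positions(model)
    poses0 = forward_kinematics(model, model.default_state())

    # Static (lab) -> MRI over the foot marker replicas.
    foot_names = [n for n in tpl.MRI_FOOT_MARKERS if n in inputs.mri_markers]
    T_lab2mri, rms = run("foot_mri_registration", lambda: horn_register(
        static.landmark_set().subset(foot_names), inputs.mri_markers))
    log("foot_mri_registration", T_lab2mri, rms)

    # MRI -> model world over the same replicas vs their template positions.
    T_mri2model, rms = run("model_registration", lambda: horn_register(
        inputs.mri_markers, {n: refpos[n] for n in foot_names}))
    log("model_registration", T_mri2model, rms)

    # Per-segment registration of the generic muscle/via points onto the
    # patient's palpated bone landmarks (virtual palpation correspondence).
    patient_world = inputs.bone_landmarks.transformed(T_mri2model)
    generic_world = reference_landmark_positions(model)

    def _map_points():
        foot_groups = {g: ns for g, ns in inputs.landmark_groups.items()
                       if g in ("hindfoot", "talus", "metatarsal", "toe")}
        transforms, residuals = {}, {}
        for g, names in foot_groups.items():
            T, r = horn_register(generic_world.subset(names),
                                 patient_world.subset(names))
            transforms[g], residuals[g] = T, r
        seg_xf = {"hindfoot": transforms["hindfoot"],
                  "forefoot": transforms["metatarsal"],
                  "toes": transforms["toe"]}
        for m in model.muscles + model.ligaments:
            new_pts = []
            for sn, p in m.points:
                if sn in seg_xf:
                    w = poses0[sn].apply(p)
                    w = seg_xf[sn].apply(w)
                    p = poses0[sn].inverse().apply(w)
                new_pts.append((sn, p))
            m.points = new_pts
        return transforms, residuals

    xf, res = run("muscle_point_mapping", _map_points)
    for g in sorted(xf):
        log(f"muscle_point_mapping/{g}", xf[g], res[g])

    # Cylinder fit to the talar dome, in model world coordinates.
    dome_world = T_mri2model.apply(np.asarray(inputs.dome_points, float))
    cyl, cyl_rms = run("cylinder_fit", lambda: fit_cylinder(dome_world))
    log("cylinder_fit", residual_mm=cyl_rms, radius_m=cyl.radius,
        direction=cyl.direction.tolist(), centre=cyl.centre.tolist())

    def _frames():
        knee_world = forward_kinematics(model, model.default_state())[
            "shank"].t  # knee centre = shank origin
        shank_lms = {
            "knee_joint_centre": knee_world,
            "medial_malleolus": patient_world["TIB_MED_MALL"],
            "lateral_malleolus": patient_world["FIB_LAT_MALL"],
        }
        mr = ankle_frame_mr(cyl, shank_lms)
        cga = ankle_frame_cga(shank_lms)
        return mr, cga

    mr_frame, cga_frame = run("ankle_frames", _frames)
    ang, off = frame_difference(mr_frame, cga_frame)
    log("ankle_frames", angle_deg=ang, offset_mm=off)

    # Leg registration: static leg markers vs MRI malleoli + template condyles.
    def _leg():
        T_lab2model = T_mri2model.compose(T_lab2mri)
        src = {n: T_lab2model.apply(static[n])
               for n in ("RLML", "RMML", "RLFE", "RMFE") if n in static}
        tgt = {"RLML": T_mri2model.apply(inputs.mri_markers["RLML"]),
               "RMML": T_mri2model.apply(inputs.mri_markers["RMML"]),
               "RLFE": refpos["RLFE"], "RMFE": refpos["RMFE"]}
        return horn_register(src, tgt)

    T_leg, rms = run("leg_registration", _leg)
    log("leg_registration", T_leg, rms)

    # Femur rotation about the knee flexion axis to match the GT marker.
    def _femur():
        T_lab2model = T_mri2model.compose(T_lab2mri)
        knee_joint = model.joint_by_child["shank"]
        knee_world = poses0["shank"].t
        axis_world = poses0["femur"].R @ knee_joint.parent_frame.R @ np.array(
            [0.0, 0.0, 1.0])
        palpated = LandmarkSet({"RGT": refpos["RGT"]})
        theta, _ = optimize_femur_rotation(
            palpated, knee_world, axis_world, T_lab2model.apply(static["RGT"]))
        # Rotate the femur-attached geometry about the knee axis (femur-local).
        c_local = poses0["femur"].inverse().apply(knee_world)
        d_local = poses0["femur"].R.T @ axis_world
        R = rotation_about_axis(d_local, theta)
        for m in model.muscles:
            m.points = [
                ("femur", c_local + R @ (p - c_local)) if sn == "femur" else (sn, p)
                for sn, p in m.points
            ]
        for name, (sn, p) in model.markers.items():
            if sn == "femur" and name != "RGT":
                model.markers[name] = (sn, c_local + R @ (p - c_local))
        return theta

    theta = run("femur_rotation", _femur)
    log("femur_rotation", angle_rad=float(theta))

    # Pelvis registration (logged; pelvis geometry is already scaled).
    def _pelvis():
        T_lab2model = T_mri2model.compose(T_lab2mri)
        names = ["RASI", "LASI", "RPSI", "LPSI"]
        src = {n: T_lab2model.apply(static[n]) for n in names}
        tgt = {n: refpos[n] for n in names}
        return horn_register(src, tgt)

    T_pelvis, rms = run("pelvis_registration", _pelvis)
    log("pelvis_registration", T_pelvis, rms)

    model.meta["provenance"] = prov
    model.meta["ankle_frames"] = {
        "MR": {"origin": mr_frame.origin.tolist(), "axes": mr_frame.axes.tolist()},
        "CGA": {"origin": cga_frame.origin.tolist(), "axes": cga_frame.axes.tolist()},
    }
    model.meta["cylinder"] = {
        "point": cyl.point.tolist(), "direction": cyl.direction.tolist(),
        "radius": cyl.radius, "extent": list(cyl.extent),
    }
    return apply_ankle_frame(model, "MR")
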