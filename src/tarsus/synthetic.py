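"""Synthetic patients: parametric foot/shank geometry with known ground
truth, static standing trials with MRI marker replicas, and walking trials
with a double-hump ground reaction force whose centre of pressure progresses
heel-to-toe.

Every generator is seed-deterministic and returns its generating parameters
so that oracle tests can compare recovered quantities against the truth.

Default study conditions (chosen once, documented in the methods note):

* talar dome cylinder: radius 20 mm, 70 deg arc, axis internally rotated
  12 deg about the vertical relative to the malleolar line — the source of
  the MR-vs-CGA ankle frame difference;
* ground reaction force: double-hump vertical profile (1.1 / 1.2 BW humps,
  0.8 BW valley) over a 0.7 s stance;
* centre of pressure: monotone heel-to-toe path that starts posterolateral,
  dwells under the midfoot and ends under the hallux, ~30 mm medial of the
  ankle-centre line at push-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import template as tpl
from .gait_io import ForcePlateSeries, GaitTrial, MarkerTrajectorySet
from .geometry import LandmarkSet, RigidTransform, rotation_about_axis
from .model import KinematicState, Model, PatientMeta, forward_kinematics
from .scaling import PatientInputs, reference_landmark_positions, \
    reference_marker_positions

__all__ = [
    "SyntheticFootParams",
    "SyntheticGaitParams",
    "SyntheticFoot",
    "make_synthetic_foot",
    "make_static_trial",
    "make_walking_trial",
    "make_patient_inputs",
    "default_patient_meta",
]


def default_patient_meta() -> PatientMeta:
    """A juvenile patient: 50 kg, 1.45 m."""
    return PatientMeta(mass_kg=50.0, height_m=1.45)


@dataclass
class SyntheticFootParams:
    """Ground-truth talar dome cylinder and sampling/noise controls."""

    dome_radius_m: float = 0.020
    dome_arc_deg: float = 70.0
    dome_axis_tilt_deg: float = 15.0   # internal rotation about the vertical
    dome_half_length_m: float = 0.014
    dome_n_points: int = 240
    dome_noise_m: float = 0.0
    landmark_noise_m: float = 0.0
    # rigid offset taking model-world coordinates into "MRI scanner" space
    mri_offset_angle_deg: float = 25.0
    mri_offset_axis: tuple = (0.3, 1.0, 0.2)
    mri_offset_translation: tuple = (0.15, -0.05, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dome_radius_m <= 0:
            raise ValueError("dome radius must be positive")
        if not 10.0 < self.dome_arc_deg <= 160.0:
            raise ValueError("dome arc must be in (10, 160] degrees")


@dataclass
class SyntheticGaitParams:
    """Walking-trial shape: GRF humps, COP progression and noise levels."""

    stance_duration_s: float = 0.7
    pad_s: float = 0.15                  # zero-load lead-in / lead-out
    marker_rate_hz: float = 100.0
    force_rate_hz: float = 1000.0
    hump1_bw: float = 1.1
    valley_bw: float = 0.8
    hump2_bw: float = 1.2
    # COP path relative to the reference ankle centre (x anterior, z lateral)
    cop_x_knots: tuple = (-0.040, 0.050, 0.065, 0.100, 0.130)
    cop_z_knots: tuple = (0.012, 0.004, -0.004, -0.026, -0.038)
    shear_x_knots: tuple = (0.0, -0.15, 0.0, 0.16, 0.0)     # BW units
    shear_z_knots: tuple = (0.0, 0.03, 0.02, -0.05, 0.0)    # BW units
    free_moment_peak_nm: float = 2.5
    marker_noise_m: float = 0.0
    knot_jitter: float = 0.0             # fractional jitter on angle knots
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hump1_bw, self.valley_bw, self.hump2_bw) <= 0:
            raise ValueError("GRF multipliers must be positive")
        if np.any(np.diff(self.cop_x_knots) <= 0):
            raise ValueError("COP path must progress monotonically anterior")


@dataclass
class SyntheticFoot:
    """Synthetic patient geometry plus every ground-truth quantity."""

    landmarks: LandmarkSet               # palpated bone landmarks, MRI coords
    dome_points: np.ndarray              # talar dome sample, MRI coords
    mri_markers: LandmarkSet             # the six foot marker replicas, MRI
    truth: dict = field(default_factory=dict)

    @property
    def mri_transform(self) -> RigidTransform:
        return self.truth["world_to_mri"]


def _ankle_axis_direction(tilt_deg: float) -> np.ndarray:
    """Dome cylinder axis: lateral (+Z) internally rotated about vertical."""
    return rotation_about_axis(np.array([0.0, 1.0, 0.0]),
                               np.radians(tilt_deg)) @ np.array([0.0, 0.0, 1.0])


def make_synthetic_foot(model: Model, params: SyntheticFootParams | None = None,
                        segment_transforms: dict[str, RigidTransform] | None = None,
                        ) -> SyntheticFoot:
    """Generate a synthetic patient's foot geometry from a template model.

    The palpated landmarks are the template's landmark dictionary placed in
    the reference pose (optionally displaced by per-group rigid
    ``segment_transforms``, which oracle tests recover); the talar dome is
    sampled from a known cylinder centred on the ankle joint centre.  All
    outputs are expressed in a known "MRI" coordinate system.
    """
    params = params or SyntheticFootParams()
    rng = np.random.default_rng(params.seed)
    poses = forward_kinematics(model, model.default_state())
    ankle_centre = poses["hindfoot"].t

    world_lms = reference_landmark_positions(model)
    groups = tpl.default_landmark_groups()
    segment_transforms = segment_transforms or {}
    pts = {}
    for g, names in groups.items():
        T = segment_transforms.get(g, RigidTransform.identity())
        for n in names:
            p = T.apply(world_lms[n])
            if params.landmark_noise_m > 0:
                p = p + rng.normal(0.0, params.landmark_noise_m, 3)
            pts[n] = p
    landmarks_world = LandmarkSet(pts, dict(world_lms.segments), "synthetic-mri")

    # Talar dome patch sampled from the ground-truth cylinder.
    d = _ankle_axis_direction(params.dome_axis_tilt_deg)
    T_talus = segment_transforms.get("talus", RigidTransform.identity())
    up = np.array([0.0, 1.0, 0.0])
    n1 = up - (up @ d) * d
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(d, n1)
    half_arc = np.radians(params.dome_arc_deg) / 2.0
    k = int(np.sqrt(params.dome_n_points))
    psi = np.linspace(-half_arc, half_arc, k)
    s = np.linspace(-params.dome_half_length_m, params.dome_half_length_m, k)
    P, S = np.meshgrid(psi, s)
    pts_dome = (ankle_centre[None, :]
                + S.ravel()[:, None] * d[None, :]
                + params.dome_radius_m * (np.cos(P.ravel())[:, None] * n1[None, :]
                                          + np.sin(P.ravel())[:, None] * n2[None, :]))
    if params.dome_noise_m > 0:
        pts_dome = pts_dome + rng.normal(0.0, params.dome_noise_m, pts_dome.shape)
    pts_dome = T_talus.apply(pts_dome)

    # World -> MRI rigid offset (known).
    axis = np.asarray(params.mri_offset_axis, dtype=float)
    T_mri = RigidTransform(
        rotation_about_axis(axis, np.radians(params.mri_offset_angle_deg)),
        np.asarray(params.mri_offset_translation, dtype=float),
    )
    refmk = reference_marker_positions(model)
    mri_markers = LandmarkSet(
        {n: T_mri.apply(refmk[n]) for n in tpl.MRI_FOOT_MARKERS},
        source="synthetic-mri",
    )
    truth = {
        "cylinder_centre": T_talus.apply(ankle_centre),
        "cylinder_direction": T_talus.R @ d,
        "cylinder_radius": params.dome_radius_m,
        "world_to_mri": T_mri,
        "segment_transforms": dict(segment_transforms),
        "params": params,
    }
    return SyntheticFoot(landmarks_world.transformed(T_mri),
                         T_mri.apply(pts_dome),
                         mri_markers, truth)


def make_static_trial(model: Model, rate_hz: float = 100.0,
                      duration_s: float = 1.0, noise_m: float = 0.0,
                      seed: int = 0) -> GaitTrial:
    """Static standing trial: markers at the reference pose (+ noise)."""
    rng = np.random.default_rng(seed)
    refmk = reference_marker_positions(model)
    labels = list(refmk)
    n = max(2, int(round(duration_s * rate_hz)))
    base = np.array([refmk[k] for k in labels])
    data = np.tile(base[None, :, :], (n, 1, 1))
    if noise_m > 0:
        data = data + rng.normal(0.0, noise_m, data.shape)
    return GaitTrial(MarkerTrajectorySet(rate_hz, labels, data), None, {},
                     "static")


# Joint-angle knot tables (degrees) at stance fractions 0/0.25/0.5/0.75/1.
_ANGLE_KNOTS_DEG = {
    "ankle_flexion": (0.0, -5.0, 5.0, 8.0, -15.0),
    "knee_flexion": (-5.0, -15.0, -8.0, -12.0, -30.0),   # negative = flexion
    "hip_flexion": (20.0, 12.0, 2.0, -5.0, -10.0),
    "mtp_flexion": (0.0, 0.0, 0.0, 6.0, 20.0),
}
_KNOT_TAU = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


def _grf_vertical_shape(params: SyntheticGaitParams):
    tau = np.array([0.0, 0.08, 0.25, 0.5, 0.75, 0.92, 1.0])
    val = np.array([0.0, 0.55, params.hump1_bw, params.valley_bw,
                    params.hump2_bw, 0.55, 0.0])
    return PchipInterpolator(tau, val)


def make_walking_trial(model: Model, params: SyntheticGaitParams | None = None,
                       ) -> tuple[GaitTrial, dict]:
    """Synthetic walking stance: smooth gait-like joint angles drive the
    model; markers come from forward kinematics; the force plate sees a
    double-hump vertical GRF with a heel-to-toe COP.

    The pelvis translation is solved per frame so the ankle joint centre
    stays put (a planted stance foot); the COP path is expressed relative to
    that fixed ankle position.  Returns ``(trial, truth)`` where ``truth``
    holds the generating coordinates and load curves.
    """
    params = params or SyntheticGaitParams()
    rng = np.random.default_rng(params.seed)
    if model.patient_meta is None:
        raise ValueError("model needs patient meta (body weight) for GRF")
    bw = model.patient_meta.body_weight_n

    rate = params.marker_rate_hz
    n_pad = int(round(params.pad_s * rate))
    n_stance = int(round(params.stance_duration_s * rate)) + 1
    n_frames = n_stance + 2 * n_pad
    t = np.arange(n_frames) / rate
    t_fs = n_pad / rate
    t_fo = (n_pad + n_stance - 1) / rate

    # stance fraction per frame (clamped into the pads)
    frac = np.clip((t - t_fs) / (t_fo - t_fs), 0.0, 1.0)

    splines = {}
    for name, knots in _ANGLE_KNOTS_DEG.items():
        k = np.asarray(knots, dtype=float)
        if params.knot_jitter > 0:
            k = k + rng.normal(0.0, params.knot_jitter, k.shape) * np.maximum(
                np.abs(k), 1.0)
        splines[name] = PchipInterpolator(_KNOT_TAU, np.radians(k))

    poses_ref = forward_kinematics(model, model.default_state())
    ankle_ref = poses_ref["hindfoot"].t

    qs = np.tile(model.default_state().q, (n_frames, 1))
    tx, ty, tz = (model.dof_index(n) for n in ("pelvis_tx", "pelvis_ty",
                                               "pelvis_tz"))
    for i in range(n_frames):
        for name, sp in splines.items():
            if name in model.dof_names and not model.dof(name).locked:
                qs[i, model.dof_index(name)] = float(sp(frac[i]))
        poses = forward_kinematics(model, KinematicState(qs[i]))
        drift = poses["hindfoot"].t - ankle_ref
        qs[i, [tx, ty, tz]] -= drift

    labels = sorted(model.markers)
    data = np.zeros((n_frames, len(labels), 3))
    for i in range(n_frames):
        poses = forward_kinematics(model, KinematicState(qs[i]))
        for j, lab in enumerate(labels):
            seg, p = model.markers[lab]
            data[i, j] = poses[seg].apply(p)
    if params.marker_noise_m > 0:
        data = data + rng.normal(0.0, params.marker_noise_m, data.shape)
    markers = MarkerTrajectorySet(rate, labels, data)

    # Force plate at its own rate.
    fr = params.force_rate_hz
    tf = np.arange(0.0, t[-1] + 0.5 / fr, 1.0 / fr)
    tf = tf[tf <= t[-1] + 1e-12]
    ffrac = np.clip((tf - t_fs) / (t_fo - t_fs), 0.0, 1.0)
    in_stance = (tf >= t_fs - 1e-12) & (tf <= t_fo + 1e-12)
    fy = _grf_vertical_shape(params)(ffrac) * bw * in_stance
    fx = PchipInterpolator(_KNOT_TAU, np.asarray(params.shear_x_knots))(
        ffrac) * bw * in_stance
    fz = PchipInterpolator(_KNOT_TAU, np.asarray(params.shear_z_knots))(
        ffrac) * bw * in_stance
    force = np.column_stack([fx, fy, fz])
    cop_x = PchipInterpolator(_KNOT_TAU, np.asarray(params.cop_x_knots))(ffrac)
    cop_z = PchipInterpolator(_KNOT_TAU, np.asarray(params.cop_z_knots))(ffrac)
    cop = np.column_stack([ankle_ref[0] + cop_x,
                           np.zeros_like(cop_x),
                           ankle_ref[2] + cop_z])
    cop[fy < 20.0] = 0.0  # COP undefined off-plate
    fm_y = params.free_moment_peak_nm * np.sin(np.pi * ffrac) * in_stance
    free_moment = np.column_stack([np.zeros_like(fm_y), fm_y,
                                   np.zeros_like(fm_y)])
    grf = ForcePlateSeries(fr, force, cop, free_moment)

    trial = GaitTrial(markers, grf,
                      {"foot_strike": t_fs, "foot_off": t_fo}, "walking")
    truth = {
        "qs": qs, "times": t, "stance_fraction": frac,
        "foot_strike": t_fs, "foot_off": t_fo,
        "cop_x_rel_ankle": cop_x, "cop_z_rel_ankle": cop_z,
        "ankle_centre": ankle_ref, "grf_vertical": fy,
        "params": params,
    }
    return trial, truth


def make_patient_inputs(template_model: Model,
                        foot_params: SyntheticFootParams | None = None,
                        meta: PatientMeta | None = None,
                        segment_transforms=None,
                        static_noise_m: float = 0.0,
                        seed: int = 0):
    """Bundle a full synthetic patient for :func:`assemble_patient_model`.

    Returns ``(PatientInputs, SyntheticFoot)``.
    """
    foot = make_synthetic_foot(template_model, foot_params, segment_transforms)
    static = make_static_trial(template_model, noise_m=static_noise_m, seed=seed)
    inputs = PatientInputs(
        bone_landmarks=foot.landmarks,
        dome_points=foot.dome_points,
        mri_markers=foot.mri_markers,
        static_trial=static,
        meta=meta or default_patient_meta(),
    )
    return inputs, foot
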