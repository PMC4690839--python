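"""Rigid-body model data structures, template building and forward kinematics.

The model is a tree of segments connected by joints rooted at the pelvis
(which floats on six ground DoFs).  Each joint carries an ordered list of
rotational/translational DoFs about axes expressed in the joint frame; the
joint frame orientation relative to the parent segment is stored in
``parent_frame`` (and mirrored in ``child_frame`` so the zero state is the
reference pose).  Muscles are via-point polylines attached to segments;
muscle forces are ideal force generators ``a * fmax``.

Units: metres, kilograms, newtons, radians.  Segment frames are right-handed
with X anterior, Y up, Z lateral (right side) in the reference pose.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import GeometryError, RigidTransform, rotation_about_axis

__all__ = [
    "ModelError",
    "Segment",
    "Joint",
    "Dof",
    "MusclePathDef",
    "LigamentRecord",
    "PatientMeta",
    "KinematicState",
    "Model",
    "build_template",
    "forward_kinematics",
    "world_muscle_path",
    "polynomial_coupling",
]

GRAVITY = 9.81  # m/s^2


class ModelError(ValueError):
    """Invalid model definition or state."""


_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


@dataclass
class Segment:
    """Rigid segment: mass properties plus an optional surface mesh reference."""

    name: str
    mass: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    mesh_ref: str | None = None

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass < 0:
            raise ModelError(f"segment {self.name!r}: mass must be >= 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ModelError(f"segment {self.name!r}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) < -1e-12):
            raise ModelError(f"segment {self.name!r}: inertia must be PSD")


@dataclass
class Dof:
    """One joint degree of freedom."""

    name: str
    kind: str  # "rotation" | "translation"
    axis: str  # "x" | "y" | "z" (in the joint frame)
    locked: bool = False
    lock_value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("rotation", "translation"):
            raise ModelError(f"dof {self.name!r}: unknown kind {self.kind!r}")
        if self.axis not in _AXES:
            raise ModelError(f"dof {self.name!r}: unknown axis {self.axis!r}")


@dataclass
class Joint:
    """Joint connecting ``parent_segment`` to ``child_segment``.

    ``parent_frame`` is the pose of the joint frame in the parent segment's
    frame; ``child_frame`` the pose of the joint frame in the child segment's
    frame (so the zero state reproduces the reference pose exactly).
    ``coupling`` optionally maps the value of the first DoF to extra
    translations/rotations applied in the joint frame (Walker-style derived
    knee motion); it returns a dict with optional keys ``"translation"``
    (3-vector) and ``"rotation"`` (3x3 matrix).
    """

    name: str
    parent_segment: str
    child_segment: str
    parent_frame: RigidTransform
    child_frame: RigidTransform = field(default_factory=RigidTransform.identity)
    dofs: list[Dof] = field(default_factory=list)
    coupling: Callable[[float], dict] | None = None


@dataclass
class MusclePathDef:
    """Polyline muscle path: ordered (segment, local point) pairs.

    First point is the origin, last the insertion.  ``fmax`` is the maximum
    isometric force of the path (N); ``crosses_ankle`` flags paths crossing
    the ankle or the internal joints of the foot.
    """

    name: str
    points: list[tuple[str, np.ndarray]]
    fmax: float
    crosses_ankle: bool = False

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ModelError(f"muscle {self.name!r}: needs >= 2 path points")
        self.points = [(s, np.asarray(p, dtype=float).reshape(3)) for s, p in self.points]
        if self.fmax <= 0:
            raise ModelError(f"muscle {self.name!r}: fmax must be positive")

    @property
    def muscle_name(self) -> str:
        """Distinct muscle this path belongs to (path suffix ``~k`` stripped)."""
        return self.name.split("~")[0]


@dataclass
class LigamentRecord:
    """Ligament polyline carried for completeness; never active in simulation."""

    name: str
    points: list[tuple[str, np.ndarray]]
    active: bool = False

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ModelError(f"ligament {self.name!r}: needs >= 2 path points")
        self.points = [(s, np.asarray(p, dtype=float).reshape(3)) for s, p in self.points]
        if self.active:
            raise ModelError(f"ligament {self.name!r}: must be inactive in simulation")


@dataclass
class PatientMeta:
    """Patient anthropometrics; ``body_weight_n = mass * g``."""

    mass_kg: float
    height_m: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0 or self.height_m <= 0:
            raise ModelError("patient mass and height must be positive")

    @property
    def body_weight_n(self) -> float:
        return self.mass_kg * GRAVITY


@dataclass
class KinematicState:
    """Generalized coordinates ``q`` (rad / m) with optional derivatives."""

    q: np.ndarray
    qdot: np.ndarray | None = None
    qddot: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(-1)
        for attr in ("qdot", "qddot"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float).reshape(-1))


class Model:
    """Musculoskeletal model: segment tree, joints, muscles, markers.

    Use :func:`build_template` (or the scaling/registration pipeline) to
    construct instances; the constructor validates the topology.
    """

    def __init__(
        self,
        segments: list[Segment],
        joints: list[Joint],
        muscles: list[MusclePathDef] | None = None,
        ligaments: list[LigamentRecord] | None = None,
        markers: dict[str, tuple[str, np.ndarray]] | None = None,
        patient_meta: PatientMeta | None = None,
        meta: dict | None = None,
    ):
        self.segments = {s.name: s for s in segments}
        if len(self.segments) != len(segments):
            raise ModelError("duplicate segment names")
        self.muscles = list(muscles or [])
        self.ligaments = list(ligaments or [])
        self.markers = {
            n: (seg, np.asarray(p, dtype=float).reshape(3))
            for n, (seg, p) in (markers or {}).items()
        }
        self.patient_meta = patient_meta
        self.meta = dict(meta or {})
        self._validate_joints(joints)
        self._validate_attachments()
        self._index_dofs()

    # -- validation ---------------------------------------------------------

    def _validate_joints(self, joints: list[Joint]) -> None:
        names = [j.name for j in joints]
        if len(set(names)) != len(names):
            raise ModelError("duplicate joint names")
        children = {}
        for j in joints:
            if j.child_segment not in self.segments:
                raise ModelError(
                    f"joint {j.name!r}: unknown child segment {j.child_segment!r}"
                )
            if j.parent_segment != "ground" and j.parent_segment not in self.segments:
                raise ModelError(
                    f"joint {j.name!r}: unknown parent segment {j.parent_segment!r}"
                )
            if j.child_segment in children:
                raise ModelError(
                    f"segment {j.child_segment!r} has two parent joints "
                    "(joint graph must be a tree)"
                )
            children[j.child_segment] = j
        # every segment must be reachable from ground
        order: list[Joint] = []
        placed = {"ground"}
        pending = list(joints)
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent_segment in placed:
                    order.append(j)
                    placed.add(j.child_segment)
                    pending.remove(j)
                    progressed = True
            if not progressed:
                bad = [j.name for j in pending]
                raise ModelError(f"joint graph is not a tree rooted at ground: {bad}")
        missing = set(self.segments) - placed
        if missing:
            raise ModelError(f"segments not connected to ground: {sorted(missing)}")
        self.joints = order
        self.joint_by_child = {j.child_segment: j for j in order}

    def _validate_attachments(self) -> None:
        for m in self.muscles:
            for seg, _ in m.points:
                if seg not in self.segments:
                    raise ModelError(
                        f"muscle {m.name!r} references unknown segment {seg!r}"
                    )
        if len({m.name for m in self.muscles}) != len(self.muscles):
            raise ModelError("duplicate muscle path names")
        for lig in self.ligaments:
            for seg, _ in lig.points:
                if seg not in self.segments:
                    raise ModelError(
                        f"ligament {lig.name!r} references unknown segment {seg!r}"
                    )
        for name, (seg, _) in self.markers.items():
            if seg not in self.segments:
                raise ModelError(f"marker {name!r} references unknown segment {seg!r}")

    def _index_dofs(self) -> None:
        self.dof_names: list[str] = []
        self._dof_owner: list[tuple[Joint, int]] = []
        for j in self.joints:
            for k, d in enumerate(j.dofs):
                if d.name in self.dof_names:
                    raise ModelError(f"duplicate dof name {d.name!r}")
                self.dof_names.append(d.name)
                self._dof_owner.append((j, k))
        self.n_dofs = len(self.dof_names)

    # -- convenience --------------------------------------------------------

    def dof_index(self, name: str) -> int:
        try:
            return self.dof_names.index(name)
        except ValueError:
            raise ModelError(f"unknown dof {name!r}") from None

    def dof(self, name: str) -> Dof:
        j, k = self._dof_owner[self.dof_index(name)]
        return j.dofs[k]

    @property
    def locked_dofs(self) -> list[str]:
        return [n for n in self.dof_names if self.dof(n).locked]

    @property
    def unlocked_dofs(self) -> list[str]:
        return [n for n in self.dof_names if not self.dof(n).locked]

    def lock(self, dof_name: str, value: float = 0.0) -> None:
        d = self.dof(dof_name)
        d.locked, d.lock_value = True, float(value)

    def unlock(self, dof_name: str) -> None:
        self.dof(dof_name).locked = False

    def muscle(self, name: str) -> MusclePathDef:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ModelError(f"unknown muscle {name!r}")

    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def distinct_muscle_names(self) -> list[str]:
        seen: list[str] = []
        for m in self.muscles:
            if m.muscle_name not in seen:
                seen.append(m.muscle_name)
        return seen

    def subtree(self, segment: str) -> list[str]:
        """Segment plus all segments distal of it."""
        out = [segment]
        for j in self.joints:
            if j.parent_segment in out:
                out.append(j.child_segment)
        return out

    def default_state(self) -> KinematicState:
        q = np.zeros(self.n_dofs)
        for i, n in enumerate(self.dof_names):
            d = self.dof(n)
            if d.locked:
                q[i] = d.lock_value
        return KinematicState(q)

    def state_from_dict(self, values: dict[str, float]) -> KinematicState:
        st = self.default_state()
        for n, v in values.items():
            st.q[self.dof_index(n)] = v
        return st

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        def pts(plist):
            return [[s, p.tolist()] for s, p in plist]

        return {
            "schema": "tarsus-model/1",
            "segments": [
                {
                    "name": s.name, "mass": s.mass, "com": s.com.tolist(),
                    "inertia": s.inertia.tolist(), "mesh_ref": s.mesh_ref,
                }
                for s in self.segments.values()
            ],
            "joints": [
                {
                    "name": j.name,
                    "parent": j.parent_segment,
                    "child": j.child_segment,
                    "parent_frame": j.parent_frame.matrix().tolist(),
                    "child_frame": j.child_frame.matrix().tolist(),
                    "dofs": [
                        {"name": d.name, "kind": d.kind, "axis": d.axis,
                         "locked": d.locked, "lock_value": d.lock_value}
                        for d in j.dofs
                    ],
                }
                for j in self.joints
            ],
            "muscles": [
                {"name": m.name, "fmax": m.fmax, "crosses_ankle": m.crosses_ankle,
                 "points": pts(m.points)}
                for m in self.muscles
            ],
            "ligaments": [
                {"name": g.name, "active": g.active, "points": pts(g.points)}
                for g in self.ligaments
            ],
            "markers": {n: [seg, p.tolist()] for n, (seg, p) in self.markers.items()},
            "patient_meta": (
                {"mass_kg": self.patient_meta.mass_kg,
                 "height_m": self.patient_meta.height_m}
                if self.patient_meta else None
            ),
            "meta": _jsonable(self.meta),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @staticmethod
    def from_json_dict(d: dict) -> "Model":
        if d.get("schema") != "tarsus-model/1":
            raise ModelError(f"unsupported model schema: {d.get('schema')!r}")
        segments = [
            Segment(s["name"], s["mass"], s["com"], s["inertia"], s.get("mesh_ref"))
            for s in d["segments"]
        ]
        joints = [
            Joint(
                j["name"], j["parent"], j["child"],
                RigidTransform.from_matrix(np.asarray(j["parent_frame"])),
                RigidTransform.from_matrix(np.asarray(j["child_frame"])),
                [Dof(x["name"], x["kind"], x["axis"], x["locked"], x["lock_value"])
                 for x in j["dofs"]],
            )
            for j in d["joints"]
        ]
        muscles = [
            MusclePathDef(m["name"], [(s, np.asarray(p)) for s, p in m["points"]],
                          m["fmax"], m["crosses_ankle"])
            for m in d["muscles"]
        ]
        ligaments = [
            LigamentRecord(g["name"], [(s, np.asarray(p)) for s, p in g["points"]],
                           g["active"])
            for g in d["ligaments"]
        ]
        markers = {n: (seg, np.asarray(p)) for n, (seg, p) in d["markers"].items()}
        pm = d.get("patient_meta")
        meta = d.get("meta") or {}
        return Model(segments, joints, muscles, ligaments, markers,
                     PatientMeta(**pm) if pm else None, meta)

    @staticmethod
    def load(path) -> "Model":
        with open(path) as fh:
            return Model.from_json_dict(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def build_template(config: dict) -> Model:
    """Build and validate a model from a template description.

    ``config`` lists segments, joints (with DoFs), muscle paths with fmax,
    ligaments and markers; see :func:`tarsus.template.default_template_config`
    for the packaged lower-limb + three-segment-foot template.
    """
    segments = [
        Segment(s["name"], s.get("mass", 0.0), s.get("com", np.zeros(3)),
                s.get("inertia", np.zeros((3, 3))), s.get("mesh_ref"))
        for s in config["segments"]
    ]
    joints = []
    for j in config["joints"]:
        pf = j.get("parent_frame", {})
        cf = j.get("child_frame", {})
        joints.append(
            Joint(
                j["name"], j["parent"], j["child"],
                RigidTransform(np.asarray(pf.get("R", np.eye(3))),
                               np.asarray(pf.get("t", np.zeros(3)))),
                RigidTransform(np.asarray(cf.get("R", np.eye(3))),
                               np.asarray(cf.get("t", np.zeros(3)))),
                [Dof(d["name"], d["kind"], d["axis"], d.get("locked", False),
                     d.get("lock_value", 0.0)) for d in j.get("dofs", [])],
                j.get("coupling"),
            )
        )
    muscles = [
        MusclePathDef(m["name"], [(s, np.asarray(p)) for s, p in m["points"]],
                      m["fmax"], m.get("crosses_ankle", False))
        for m in config.get("muscles", [])
    ]
    ligaments = [
        LigamentRecord(g["name"], [(s, np.asarray(p)) for s, p in g["points"]])
        for g in config.get("ligaments", [])
    ]
    markers = {
        n: (seg, np.asarray(p)) for n, (seg, p) in config.get("markers", {}).items()
    }
    pm = config.get("patient_meta")
    return Model(segments, joints, muscles, ligaments, markers,
                 PatientMeta(**pm) if pm else None, config.get("meta"))


def polynomial_coupling(translation_coeffs=None, rotation_coeffs=None):
    """Walker-style knee coupling hook: polynomials in the primary coordinate.

    ``translation_coeffs`` maps axis ("x"|"y"|"z") -> polynomial coefficients
    (highest power first, metres) for derived translations; ``rotation_coeffs``
    likewise for derived rotations (radians).  Coefficients are supplied by
    the user; default template uses no coupling.
    """
    tc = translation_coeffs or {}
    rc = rotation_coeffs or {}

    def fn(q0: float) -> dict:
        t = np.zeros(3)
        for ax, coeffs in tc.items():
            t += _AXES[ax] * float(np.polyval(coeffs, q0))
        R = np.eye(3)
        for ax, coeffs in rc.items():
            R = R @ rotation_about_axis(_AXES[ax], float(np.polyval(coeffs, q0)))
        return {"translation": t, "rotation": R}

    return fn


# ---------------------------------------------------------------------------
# Forward kinematics and muscle paths
# ---------------------------------------------------------------------------


def forward_kinematics(model: Model, state: KinematicState) -> dict[str, RigidTransform]:
    """World pose of every segment for generalized coordinates ``state.q``.

    Locked DoFs take their current ``q`` entry (which the default state sets
    to the lock value).  Joint couplings are applied after the explicit DoFs.
    """
    q = state.q
    if q.shape[0] != model.n_dofs:
        raise ModelError(
            f"state length {q.shape[0]} does not match model DoF count {model.n_dofs}"
        )
    poses: dict[str, RigidTransform] = {"ground": RigidTransform.identity()}
    idx = 0
    for j in model.joints:
        parent = poses[j.parent_segment]
        X = parent.compose(j.parent_frame)
        for d in j.dofs:
            v = q[idx]
            idx += 1
            if d.kind == "rotation":
                X = X.compose(RigidTransform(rotation_about_axis(_AXES[d.axis], v),
                                             np.zeros(3)))
            else:
                X = X.compose(RigidTransform(np.eye(3), _AXES[d.axis] * v))
        if j.coupling is not None and j.dofs:
            q0 = q[idx - len(j.dofs)]
            extra = j.coupling(q0)
            R = extra.get("rotation", np.eye(3))
            t = extra.get("translation", np.zeros(3))
            X = X.compose(RigidTransform(np.asarray(R), np.asarray(t)))
        poses[j.child_segment] = X.compose(j.child_frame.inverse())
    return poses


def world_marker_positions(model: Model, poses: dict[str, RigidTransform]) -> dict[str, np.ndarray]:
    return {n: poses[seg].apply(p) for n, (seg, p) in model.markers.items()}


def world_muscle_path(
    model: Model, state: KinematicState | dict[str, RigidTransform], muscle: str
) -> tuple[np.ndarray, float]:
    """Ordered world points of a muscle path and its polyline length.

    ``state`` may be a :class:`KinematicState` or a precomputed pose dict
    from :func:`forward_kinematics` (to amortise FK across muscles).
    """
    m = model.muscle(muscle)
    poses = state if isinstance(state, dict) else forward_kinematics(model, state)
    pts = np.array([poses[seg].apply(p) for seg, p in m.points])
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return pts, length
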