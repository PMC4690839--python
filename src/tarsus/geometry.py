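"""Landmark handling, rigid registration, cylinder fitting and anatomical frames.

Coordinate conventions
----------------------
All coordinates are metres in right-handed frames.  In the reference pose
X points anterior, Y up, Z lateral (right side).  Registration residuals are
reported in millimetres, which is what motion-capture practitioners expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "RigidTransform",
    "LandmarkSet",
    "Cylinder",
    "AnatomicalFrame",
    "horn_register",
    "fit_cylinder",
    "ankle_frame_mr",
    "ankle_frame_cga",
    "frame_difference",
    "map_generic_points",
]


class GeometryError(ValueError):
    """Invalid geometric input."""


class DegenerateGeometryError(GeometryError):
    """Input configuration is rank-deficient / ill-conditioned."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t``.

    ``R`` must be orthonormal with determinant +1 (no scale, no reflection).
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix is a reflection (det < 0)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return RigidTransform(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.t
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise GeometryError("rotation axis has zero length")
    a = a / n
    K = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# Landmark sets
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named 3-D points with optional segment ownership and source tag.

    ``points`` maps name -> 3-vector (m).  ``segments`` maps name -> owning
    segment (may be missing for lab-frame points), ``source`` is a free tag
    such as ``"mri"``, ``"static"`` or ``"generic"``.
    """

    points: dict[str, np.ndarray] = field(default_factory=dict)
    segments: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            v = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise GeometryError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = v
        self.points = clean

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def names(self) -> list[str]:
        return list(self.points)

    def subset(self, names) -> "LandmarkSet":
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"landmarks not present: {missing}")
        return LandmarkSet(
            {n: self.points[n].copy() for n in names},
            {n: self.segments[n] for n in names if n in self.segments},
            self.source,
        )

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            {n: T.apply(p) for n, p in self.points.items()},
            dict(self.segments),
            self.source,
        )

    def to_json_dict(self, units: str = "m") -> dict:
        scale = {"m": 1.0, "mm": 1000.0}[units]
        return {
            "units": units,
            "points": {
                n: {
                    "xyz": (self.points[n] * scale).tolist(),
                    **({"segment": self.segments[n]} if n in self.segments else {}),
                }
                for n in self.points
            },
        }

    @staticmethod
    def from_json_dict(d: dict, source: str = "") -> "LandmarkSet":
        scale = {"m": 1.0, "mm": 1e-3}[d.get("units", "m")]
        pts, segs = {}, {}
        for n, rec in d["points"].items():
            pts[n] = np.asarray(rec["xyz"], dtype=float) * scale
            if "segment" in rec:
                segs[n] = rec["segment"]
        return LandmarkSet(pts, segs, source)


# ---------------------------------------------------------------------------
# Horn absolute orientation
# ---------------------------------------------------------------------------


def horn_register(
    source: LandmarkSet | dict,
    target: LandmarkSet | dict,
) -> tuple[RigidTransform, float]:
    """Closed-form least-squares rigid registration (Horn's quaternion method).

    Finds the proper rigid transform T minimising ``sum_i ||T(s_i) - t_i||^2``
    over the landmarks common to both sets (matched by name).  No scaling, no
    reflection.

    Returns
    -------
    (transform, rms_mm)
        The transform and the root-mean-square residual in millimetres.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 common names, or the common points are (numerically)
        collinear so the rotation is not unique.
    """
    sp = source.points if isinstance(source, LandmarkSet) else source
    tp = target.points if isinstance(target, LandmarkSet) else target
    names = sorted(set(sp) & set(tp))
    if len(names) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 common landmarks for registration, got {len(names)}: {names}"
        )
    S = np.array([np.asarray(sp[n], dtype=float) for n in names])
    T = np.array([np.asarray(tp[n], dtype=float) for n in names])
    sc, tc = S.mean(axis=0), T.mean(axis=0)
    Sc, Tc = S - sc, T - tc
    M = Sc.T @ Tc  # cross-covariance
    sv = np.linalg.svd(M, compute_uv=False)
    # Collinear point sets leave the rotation about the line undetermined:
    # require rank >= 2 (planar sets are fine for absolute orientation).
    if sv[1] < 1e-10 * max(sv[0], 1e-300):
        raise DegenerateGeometryError(
            "degenerate landmark configuration (collinear points): rotation "
            "is not uniquely determined"
        )
    # Horn's symmetric 4x4 quaternion matrix.
    tr = np.trace(M)
    delta = np.array([M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]])
    N = np.empty((4, 4))
    N[0, 0] = tr
    N[0, 1:] = delta
    N[1:, 0] = delta
    N[1:, 1:] = M + M.T - tr * np.eye(3)
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # unit quaternion (w, x, y, z) of the optimal rotation
    w0, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w0), 2 * (x * z + y * w0)],
            [2 * (x * y + z * w0), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w0)],
            [2 * (x * z - y * w0), 2 * (y * z + x * w0), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = tc - R @ sc
    xform = RigidTransform(R, t)
    res = xform.apply(S) - T
    rms_mm = float(np.sqrt(np.mean(np.sum(res**2, axis=1))) * 1000.0)
    return xform, rms_mm


# ---------------------------------------------------------------------------
# Cylinder fitting (talar dome -> ankle axis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder with the finite fitted extent along its axis.

    ``point`` is a point on the axis, ``direction`` a unit vector, ``radius``
    in metres.  ``extent`` is the (min, max) of the fitted points' projections
    on the axis, measured from ``point``.
    """

    point: np.ndarray
    direction: np.ndarray
    radius: float
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("cylinder direction has zero length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)
        if self.radius <= 0:
            raise GeometryError("cylinder radius must be positive")
        if not self.extent[0] < self.extent[1]:
            raise GeometryError("cylinder extent must satisfy smin < smax")

    @property
    def centre(self) -> np.ndarray:
        """Midpoint of the fitted axial extent (the ankle joint centre)."""
        return self.point + self.direction * (0.5 * (self.extent[0] + self.extent[1]))

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis points at the two ends of the fitted extent."""
        return (
            self.point + self.direction * self.extent[0],
            self.point + self.direction * self.extent[1],
        )


def _axis_distances(points, c, d):
    rel = points - c
    along = rel @ d
    perp = rel - np.outer(along, d)
    return np.linalg.norm(perp, axis=1), along


def fit_cylinder(points: np.ndarray, max_iter: int = 200) -> tuple[Cylinder, float]:
    """Least-squares cylinder fit to a curved surface patch.

    Minimises ``sum_i (dist(p_i, axis) - r)^2`` over axis point, axis
    direction and radius, by Levenberg/trust-region nonlinear least squares.
    Initialisation tries each principal component of the cloud as the axis
    and keeps the best converged fit.

    Returns ``(cylinder, rms_mm)``.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 6 points, a (near-)coplanar cloud, or non-convergence.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if P.shape[0] < 6:
        raise DegenerateGeometryError("cylinder fit needs >= 6 points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    cov = Q.T @ Q / len(Q)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-12 * max(evals[-1], 1e-300):
        raise DegenerateGeometryError(
            "cylinder fit is ill-conditioned: point cloud is (near-)coplanar"
        )

    def residual(x):
        c = x[:3]
        alpha, beta = x[3], x[4]
        d = np.array(
            [np.cos(alpha) * np.cos(beta), np.cos(alpha) * np.sin(beta), np.sin(alpha)]
        )
        r = x[5]
        dist, _ = _axis_distances(P, c, d)
        return dist - r

    best = None
    for k in range(3):
        d0 = evecs[:, k]
        alpha = float(np.arcsin(np.clip(d0[2], -1.0, 1.0)))
        beta = float(np.arctan2(d0[1], d0[0]))
        dist0, _ = _axis_distances(P, centroid, d0)
        r0 = float(np.mean(dist0))
        if r0 <= 0:
            continue
        x0 = np.array([*centroid, alpha, beta, r0])
        sol = least_squares(
            residual, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=max_iter * 10,
        )
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise DegenerateGeometryError("cylinder fit failed to initialise")
    cost, sol = best
    if not sol.success:
        raise DegenerateGeometryError(f"cylinder fit did not converge: {sol.message}")
    c = sol.x[:3]
    alpha, beta = sol.x[3], sol.x[4]
    d = np.array(
        [np.cos(alpha) * np.cos(beta), np.cos(alpha) * np.sin(beta), np.sin(alpha)]
    )
    r = abs(float(sol.x[5]))
    _, along = _axis_distances(P, c, d)
    smin, smax = float(along.min()), float(along.max())
    if not smin < smax:
        raise DegenerateGeometryError("degenerate axial extent in cylinder fit")
    # Gauge-fix the axis point to the projection of the cloud centroid.
    s_mid = float(np.mean(along))
    c = c + d * s_mid
    cyl = Cylinder(c, d, r, (smin - s_mid, smax - s_mid))
    return cyl, cost * 1000.0


# ---------------------------------------------------------------------------
# Anatomical frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed frame: columns of ``axes`` = (anterior, vertical, transverse)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(A) < 0:
            raise GeometryError("frame is left-handed")

    @property
    def anterior(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def vertical(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def transverse(self) -> np.ndarray:
        return self.axes[:, 2]

    def transformed(self, T: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(T.apply(self.origin), T.R @ self.axes)


def _orthonormal_frame(vertical_raw, transverse_raw, origin) -> AnatomicalFrame:
    y = vertical_raw / np.linalg.norm(vertical_raw)
    x = np.cross(y, transverse_raw)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError(
            "vertical and transverse directions are parallel"
        )
    x = x / nx
    z = np.cross(x, y)
    return AnatomicalFrame(origin, np.column_stack([x, y, z]))


def ankle_frame_cga(landmarks: LandmarkSet | dict,
                    names=("medial_malleolus", "lateral_malleolus", "knee_joint_centre"),
                    ) -> AnatomicalFrame:
    """Shank (ankle parent) frame from gait-analysis landmarks.

    Built from palpable landmarks the way multi-segment foot protocols define
    the shank: vertical axis from the inter-malleolar midpoint to the knee
    joint centre; anterior axis perpendicular to the plane of the vertical
    axis and the medial-to-lateral malleolar vector; transverse axis mutually
    perpendicular.  Origin at the inter-malleolar midpoint.
    """
    pts = landmarks.points if isinstance(landmarks, LandmarkSet) else landmarks
    med, lat, knee = names
    for n in (med, lat, knee):
        if n not in pts:
            raise GeometryError(f"missing landmark {n!r} for CGA ankle frame")
    mm = np.asarray(pts[med], dtype=float)
    lm = np.asarray(pts[lat], dtype=float)
    kjc = np.asarray(pts[knee], dtype=float)
    ml = lm - mm
    if np.linalg.norm(ml) < 1e-9:
        raise DegenerateGeometryError("malleoli are coincident")
    origin = 0.5 * (mm + lm)
    vert = kjc - origin
    if np.linalg.norm(np.cross(vert, ml)) < 1e-12:
        raise DegenerateGeometryError("knee joint centre lies on the malleolar line")
    return _orthonormal_frame(vert, ml, origin)


def ankle_frame_mr(cyl: Cylinder, shank_landmarks: LandmarkSet | dict,
                   knee_name: str = "knee_joint_centre",
                   medial_name: str = "medial_malleolus",
                   lateral_name: str = "lateral_malleolus") -> AnatomicalFrame:
    """Ankle parent frame from the cylinder fitted to the talar dome.

    The joint centre is the midpoint of the fitted axial extent; the
    flexion (transverse) axis is the cylinder direction, with the lateral and
    medial ends of the cylinder axis standing in for the malleoli; the
    vertical axis points towards the knee joint centre, orthogonalised
    against the cylinder axis.
    """
    pts = (shank_landmarks.points if isinstance(shank_landmarks, LandmarkSet)
           else shank_landmarks)
    if knee_name not in pts:
        raise GeometryError(f"missing landmark {knee_name!r} for MR ankle frame")
    if abs(cyl.extent[1] - cyl.extent[0]) < 1e-12:
        raise DegenerateGeometryError("cylinder has degenerate axial extent")
    d = cyl.direction.copy()
    # Orient the axis medial -> lateral when the malleoli are available.
    if medial_name in pts and lateral_name in pts:
        ml = np.asarray(pts[lateral_name], float) - np.asarray(pts[medial_name], float)
        if float(d @ ml) < 0:
            d = -d
    origin = cyl.centre
    vert = np.asarray(pts[knee_name], dtype=float) - origin
    if np.linalg.norm(np.cross(vert, d)) < 1e-12:
        raise DegenerateGeometryError("knee joint centre lies on the cylinder axis")
    # The cylinder direction IS the flexion axis: keep it exact and
    # orthogonalise the vertical (towards-knee) direction against it.
    z = d
    x = np.cross(vert, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return AnatomicalFrame(origin, np.column_stack([x, y, z]))


def frame_difference(a: AnatomicalFrame, b: AnatomicalFrame) -> tuple[float, float]:
    """Relative rotation angle (degrees) and origin offset (mm) between frames."""
    R = a.axes.T @ b.axes
    angle = float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))
    offset_mm = float(np.linalg.norm(a.origin - b.origin) * 1000.0)
    return angle, offset_mm


# ---------------------------------------------------------------------------
# Generic -> patient point mapping (virtual palpation correspondence)
# ---------------------------------------------------------------------------


def map_generic_points(
    generic_landmarks: LandmarkSet,
    patient_landmarks: LandmarkSet,
    groups: dict[str, list[str]],
    generic_points: dict[str, np.ndarray],
    point_groups: dict[str, str],
):
    """Map generic model points onto patient geometry by per-group Horn fits.

    Parameters
    ----------
    groups
        Map group name (e.g. ``"hindfoot"``) -> landmark names used for that
        group's registration.
    generic_points, point_groups
        Points to map (name -> 3-vector) and the group each belongs to.

    Returns
    -------
    (mapped_points, transforms, residuals_mm)
        ``transforms`` and ``residuals_mm`` are keyed by group name.
    """
    transforms: dict[str, RigidTransform] = {}
    residuals: dict[str, float] = {}
    for group, names in groups.items():
        T, rms = horn_register(
            generic_landmarks.subset(names), patient_landmarks.subset(names)
        )
        transforms[group] = T
        residuals[group] = rms
    mapped = {}
    for name, p in generic_points.items():
        group = point_groups[name]
        if group not in transforms:
            raise KeyError(f"point {name!r} belongs to unknown group {group!r}")
        mapped[name] = transforms[group].apply(np.asarray(p, dtype=float))
    return mapped, transforms, residuals
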