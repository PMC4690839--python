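"""Simulation core: inverse kinematics, load assignment, quasi-static inverse
dynamics, tendon-excursion moment arms, static optimization and ankle joint
reaction analysis.

Conventions
-----------
* Generalized forces returned by :func:`inverse_dynamics` are the net moments
  the internal structures (muscles, reserves) must produce, i.e. minus the
  generalized force of the external loads and segment weights.
* Moment arms follow the tendon-excursion definition ``R = -dL/dq``: a
  plantarflexor, which lengthens with dorsiflexion, has a negative
  dorsiflexion moment arm.
* Muscles are ideal force generators: ``force = a * fmax`` with activation
  ``a`` in [0, 1].
* The ankle joint reaction force is the bone-on-bone contact force on the
  foot free body: minus the sum of external load, gravity and ankle-crossing
  muscle forces acting on the foot segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, linprog, minimize

from .gait_io import GaitTrial, JointLoadSeries, detect_stance
from .model import (
    GRAVITY,
    KinematicState,
    Model,
    ModelError,
    forward_kinematics,
    world_muscle_path,
)

__all__ = [
    "RunConfig",
    "InfeasibleError",
    "GeneralizedForces",
    "MuscleState",
    "ExternalLoadAssignment",
    "PipelineResult",
    "inverse_kinematics",
    "assign_grf",
    "inverse_dynamics",
    "moment_arms",
    "static_optimization",
    "joint_reaction",
    "run_pipeline",
    "TrialSimulation",
    "default_free_dofs",
    "DEFAULT_LOCKED_DOFS",
]

_GRAV_VEC = np.array([0.0, -GRAVITY, 0.0])

# The fore/hindfoot (midfoot) coordinates and the internal/external ankle
# rotation are locked during simulation: their moments are assumed to be
# carried by the bony and ligamentous constraints of the foot and are not
# required to reach static equilibrium.
DEFAULT_LOCKED_DOFS = ("ankle_rotation", "midfoot_flexion", "midfoot_inversion",
                       "midfoot_rotation")


class InfeasibleError(ModelError):
    """Static optimization cannot satisfy the moment constraints."""

    def __init__(self, dofs: list[str], frame: int | None = None):
        self.dofs = list(dofs)
        self.frame = frame
        where = f" at frame {frame}" if frame is not None else ""
        super().__init__(
            "static optimization infeasible without reserve actuators"
            f"{where}; violated DoF(s): {', '.join(self.dofs)}"
        )


@dataclass
class RunConfig:
    """Pipeline configuration mirroring the CLI flags."""

    mode: str = "1SEG"            # GRF assignment: 1SEG | 2SEG
    axes: str = "MR"              # ankle frame: MR | CGA
    reserves: str = "auto"        # off | on | auto (on only if needed)
    stance_threshold_n: float = 20.0
    locked_dofs: tuple = DEFAULT_LOCKED_DOFS
    free_dofs: tuple | None = None  # None -> default constraint set
    ik_weights: dict | None = None
    quasi_static: bool = True
    reserve_weight: float = 1000.0
    reserve_tau0: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("1SEG", "2SEG"):
            raise ModelError(f"unknown GRF mode {self.mode!r}")
        if self.axes not in ("MR", "CGA"):
            raise ModelError(f"unknown axes choice {self.axes!r}")
        if self.reserves not in ("off", "on", "auto"):
            raise ModelError(f"unknown reserves mode {self.reserves!r}")


def default_free_dofs(model: Model, mode: str) -> list[str]:
    """Constrained DoF set for static optimization: hip (3) + knee + ankle
    flexion + ankle inversion/eversion, plus MTP flexion when the toes can be
    loaded (2SEG).  Pelvis residual DoFs are never constrained."""
    names = ["hip_flexion", "hip_adduction", "hip_rotation", "knee_flexion",
             "ankle_flexion", "ankle_inversion"]
    if mode == "2SEG":
        names.append("mtp_flexion")
    return [n for n in names if n in model.dof_names]


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------


def inverse_kinematics(model: Model, markers, weights: dict | None = None,
                       frames=None):
    """Least-squares marker tracking over the unlocked coordinates.

    Per frame, minimises ``sum_i w_i ||model_marker_i(q) - measured_i||^2``
    with the previous frame's solution as the initial guess (zero pose for
    the first frame).  Returns ``(q_series, residual_rms_m)``.
    """
    free = [model.dof_index(n) for n in model.unlocked_dofs]
    if not free:
        raise ModelError("no unlocked coordinates to solve")
    base = model.default_state().q
    frames = range(markers.n_frames) if frames is None else frames
    weights = weights or {}

    tracked = [(j, lab) for j, lab in enumerate(markers.labels)
               if lab in model.markers]

    qs = np.tile(base, (markers.n_frames, 1))
    rms = np.full(markers.n_frames, np.nan)
    x_prev = base[free].copy()
    for f in frames:
        vis = [(j, lab) for j, lab in tracked if markers.visible[f, j]]
        if len(vis) < 3:
            raise ModelError(
                f"frame {f}: only {len(vis)} visible tracked markers (need >= 3)"
            )
        meas = np.array([markers.data[f, j] for j, _ in vis])
        w = np.sqrt([weights.get(lab, 1.0) for _, lab in vis])
        attach = [model.markers[lab] for _, lab in vis]

        def resid(x):
            q = base.copy()
            q[free] = x
            poses = forward_kinematics(model, KinematicState(q))
            pred = np.array([poses[seg].apply(p) for seg, p in attach])
            return ((pred - meas) * w[:, None]).ravel()

        sol = least_squares(resid, x_prev, method="lm", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=2000)
        if not sol.success:
            warnings.warn(f"IK did not converge at frame {f}; carrying previous "
                          "solution", stacklevel=2)
            x = x_prev
        else:
            x = sol.x
        qs[f, free] = x
        r = resid(x).reshape(-1, 3)
        rms[f] = float(np.sqrt(np.mean(np.sum(r**2, axis=1))))
        x_prev = x
    return qs, rms


# ---------------------------------------------------------------------------
# External load assignment (1SEG / 2SEG)
# ---------------------------------------------------------------------------


@dataclass
class ExternalLoadAssignment:
    """Per-frame GRF application: target segment + wrench (lab/ground frame)."""

    frames: np.ndarray              # marker-frame indices (stance)
    segment: list[str]              # target per frame: hindfoot | toes
    force: np.ndarray               # (n, 3) N
    cop: np.ndarray                 # (n, 3) m
    free_moment: np.ndarray         # (n, 3) N m
    switch_frame: int | None = None  # first frame assigned to the toes


def assign_grf(trial: GaitTrial, model: Model, qs: np.ndarray, mode: str,
               stance_idx: np.ndarray) -> ExternalLoadAssignment:
    """Assign the measured plate wrench to a foot segment per stance frame.

    1SEG: hindfoot throughout.  2SEG: hindfoot until the centre of pressure
    first passes the metatarsophalangeal flexion axis along the foot's
    anterior direction, toes from that frame on (latched: no switching back).
    """
    grf = trial.grf
    if grf is None:
        raise ModelError("trial has no force-plate data")
    n = len(stance_idx)
    force = np.empty((n, 3))
    cop = np.empty((n, 3))
    fm = np.empty((n, 3))
    segment = []
    switch: int | None = None
    mtp_joint = model.joint_by_child.get("toes")
    for k, f in enumerate(stance_idx):
        force[k] = grf.force[f]
        cop[k] = grf.cop[f]
        fm[k] = grf.free_moment[f]
        if force[k, 1] < grf.threshold:
            # unloaded edge of the stance window: zero wrench (latched target)
            force[k] = 0.0
            fm[k] = 0.0
            cop[k] = 0.0
            segment.append("toes" if switch is not None else "hindfoot")
            continue
        if not np.all(np.isfinite(cop[k])):
            raise ModelError(f"COP undefined during stance at frame {f}")
        target = "hindfoot"
        if mode == "2SEG" and mtp_joint is not None:
            if switch is not None:
                target = "toes"
            else:
                poses = forward_kinematics(model, KinematicState(qs[f]))
                X = poses[mtp_joint.parent_segment].compose(mtp_joint.parent_frame)
                anterior = poses["hindfoot"].R @ np.array([1.0, 0.0, 0.0])
                d = float((cop[k] - X.t) @ anterior)
                if d > 0.0:
                    target = "toes"
                    switch = k
        segment.append(target)
    return ExternalLoadAssignment(np.asarray(stance_idx), segment, force, cop,
                                  fm, switch)


# ---------------------------------------------------------------------------
# Inverse dynamics (quasi-static Newton-Euler, virtual-work form)
# ---------------------------------------------------------------------------


@dataclass
class GeneralizedForces:
    """Required internal generalized forces per frame (N m / N)."""

    frames: np.ndarray
    dof_names: list[str]
    tau: np.ndarray  # (n_frames, n_dofs)

    def column(self, dof: str) -> np.ndarray:
        return self.tau[:, self.dof_names.index(dof)]


def _dof_axes_world(model: Model, poses) -> list[tuple[str, np.ndarray, np.ndarray, str]]:
    """Per DoF: (kind, world axis, world point on axis, child segment)."""
    from .geometry import RigidTransform, rotation_about_axis

    out = []
    ax = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
          "z": np.array([0, 0, 1.0])}
    for j in model.joints:
        X = poses[j.parent_segment].compose(j.parent_frame)
        # recover dof values from child pose is unnecessary: accumulate via q
        for d in j.dofs:
            out.append((d.kind, X.R @ ax[d.axis], X.t.copy(), j.child_segment, d.name))
            # advance X by this dof's current value
            v = d._current  # set by caller
            if d.kind == "rotation":
                X = X.compose(RigidTransform(rotation_about_axis(ax[d.axis], v),
                                             np.zeros(3)))
            else:
                X = X.compose(RigidTransform(np.eye(3), ax[d.axis] * v))
    return out


def _generalized_external(model: Model, q: np.ndarray, poses, wrenches):
    """Generalized force of external wrenches + gravity, all DoFs.

    ``wrenches``: list of (segment, force 3-vec, point 3-vec, moment 3-vec).
    Gravity on every segment is added automatically.
    """
    loads = list(wrenches)
    for name, seg in model.segments.items():
        if seg.mass > 0:
            loads.append((name, seg.mass * _GRAV_VEC, poses[name].apply(seg.com),
                          np.zeros(3)))
    # annotate current dof values for axis propagation
    i = 0
    for j in model.joints:
        for d in j.dofs:
            d._current = q[i]
            i += 1
    axes = _dof_axes_world(model, poses)
    g = np.zeros(model.n_dofs)
    subtree_cache = {}
    for idx, (kind, n, p, child, _name) in enumerate(axes):
        if child not in subtree_cache:
            subtree_cache[child] = set(model.subtree(child))
        sub = subtree_cache[child]
        acc = 0.0
        for seg, force, point, moment in loads:
            if seg not in sub:
                continue
            if kind == "rotation":
                acc += float(n @ (np.cross(point - p, force) + moment))
            else:
                acc += float(n @ force)
        g[idx] = acc
    return g


def inverse_dynamics(model: Model, qs: np.ndarray, loads: ExternalLoadAssignment,
                     mode: str = "quasi_static", rate: float | None = None,
                     lowpass_hz: float | None = None) -> GeneralizedForces:
    """Net required generalized forces over the stance frames.

    Quasi-static mode (default) balances the external wrench and segment
    weights only; ``full`` adds inertial terms from numerically
    differentiated kinematics (central differences, optional low-pass).
    """
    n = len(loads.frames)
    tau = np.zeros((n, model.n_dofs))
    accel = None
    if mode == "full":
        if rate is None:
            raise ModelError("full inverse dynamics needs the frame rate")
        accel = _com_accelerations(model, qs, loads.frames, rate, lowpass_hz)
    for k, f in enumerate(loads.frames):
        q = qs[f]
        poses = forward_kinematics(model, KinematicState(q))
        wrenches = [(loads.segment[k], loads.force[k], loads.cop[k],
                     loads.free_moment[k])]
        if accel is not None:
            for s_i, name in enumerate(model.segments):
                seg = model.segments[name]
                if seg.mass > 0:
                    wrenches.append((name, -seg.mass * accel[k, s_i],
                                     poses[name].apply(seg.com), np.zeros(3)))
        g = _generalized_external(model, q, poses, wrenches)
        tau[k] = -g
    return GeneralizedForces(loads.frames, list(model.dof_names), tau)


def _com_accelerations(model, qs, frames, rate, lowpass_hz):
    """Central-difference COM accelerations (frames, segments, 3)."""
    seg_names = list(model.segments)
    pos = np.zeros((len(frames), len(seg_names), 3))
    for k, f in enumerate(frames):
        poses = forward_kinematics(model, KinematicState(qs[f]))
        for s_i, name in enumerate(seg_names):
            pos[k, s_i] = poses[name].apply(model.segments[name].com)
    if lowpass_hz is not None and len(frames) > 6:
        from scipy.signal import butter, filtfilt
        b, a = butter(2, lowpass_hz / (rate / 2.0))
        pos = filtfilt(b, a, pos, axis=0, method="gust")
    acc = np.zeros_like(pos)
    if len(frames) >= 3:
        acc[1:-1] = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) * rate**2
        acc[0], acc[-1] = acc[1], acc[-2]
    return acc


# ---------------------------------------------------------------------------
# Moment arms (tendon excursion)
# ---------------------------------------------------------------------------


def _fd_pose_pairs(model: Model, q: np.ndarray, dof_names, delta: float):
    pairs = []
    for name in dof_names:
        i = model.dof_index(name)
        qp, qm = q.copy(), q.copy()
        qp[i] += delta
        qm[i] -= delta
        pairs.append((forward_kinematics(model, KinematicState(qp)),
                      forward_kinematics(model, KinematicState(qm))))
    return pairs


def _arms_from_pairs(model: Model, pairs, delta: float,
                     muscle_names=None) -> np.ndarray:
    names = muscle_names if muscle_names is not None else model.muscle_names()
    R = np.zeros((len(names), len(pairs)))
    for j, (pp, pm) in enumerate(pairs):
        for i, mn in enumerate(names):
            _, lp = world_muscle_path(model, pp, mn)
            _, lm = world_muscle_path(model, pm, mn)
            R[i, j] = -(lp - lm) / (2.0 * delta)
    return R


def moment_arms(model: Model, state: KinematicState, dof_names=None,
                delta: float = 1e-5) -> np.ndarray:
    """Moment-arm matrix (muscles x DoFs, metres) by central finite
    differences of path length: ``R[i, j] = -dL_i/dq_j``."""
    dof_names = dof_names if dof_names is not None else model.dof_names
    pairs = _fd_pose_pairs(model, state.q, dof_names, delta)
    return _arms_from_pairs(model, pairs, delta)


# ---------------------------------------------------------------------------
# Static optimization
# ---------------------------------------------------------------------------


@dataclass
class MuscleState:
    """Activations, forces and (optional) reserve moments per frame."""

    muscle_names: list[str]
    dof_names: list[str]
    a: np.ndarray                   # (frames, muscles) in [0, 1]
    force: np.ndarray               # (frames, muscles) N
    reserve: np.ndarray             # (frames, dofs) N m (zero when unused)
    used_reserves: bool = False


def _active_set_qp(A, b, w, lb, ub, active0=None, max_iter=200):
    """min x' diag(w) x  s.t.  A x = b,  lb <= x <= ub.

    Primal active-set method for a strictly convex diagonal objective with a
    handful of equality constraints: the equality-constrained subproblem has
    the closed form x = -diag(1/2w) A' lam with
    (A diag(1/2w) A') lam = -b, so every iteration is a small dense solve.
    Returns None if it fails to converge (caller falls back to SLSQP).
    """
    D, N = A.shape
    inv2w = 1.0 / (2.0 * w)
    active: dict[int, float] = dict(active0 or {})
    for _ in range(max_iter):
        free = np.array([i for i in range(N) if i not in active], dtype=int)
        x = np.zeros(N)
        for i, v in active.items():
            x[i] = v
        rhs = b - A[:, list(active)] @ np.array(list(active.values())) \
            if active else b.copy()
        if free.size:
            Af = A[:, free]
            M_mat = (Af * inv2w[free]) @ Af.T
            try:
                lam = np.linalg.solve(M_mat, -rhs)
            except np.linalg.LinAlgError:
                lam, *_ = np.linalg.lstsq(M_mat, -rhs, rcond=None)
            xf = -(inv2w[free]) * (Af.T @ lam)
            x[free] = xf
            # most-violated bound among free variables joins the active set
            viol_lo = lb[free] - xf
            viol_hi = xf - ub[free]
            worst = np.concatenate([viol_lo, viol_hi])
            k = int(np.argmax(worst))
            if worst[k] > 1e-12:
                if k < len(free):
                    active[int(free[k])] = float(lb[free[k]])
                else:
                    j = free[k - len(free)]
                    active[int(j)] = float(ub[j])
                continue
        else:
            # every variable clamped: pick multipliers by least squares
            lam, *_ = np.linalg.lstsq(A.T, -2.0 * w * x, rcond=None)
            if len(b) and np.max(np.abs(A @ x - b)) > 1e-9:
                return None
        # KKT multiplier check: release wrongly-clamped variables
        grad = 2.0 * w * x + A.T @ lam
        release = None
        worst_mu = 1e-12
        for i, v in active.items():
            mu = grad[i] if v == lb[i] else -grad[i]
            # at a bound the multiplier must be >= 0
            if -mu > worst_mu:
                worst_mu = -mu
                release = i
        if release is None:
            return x
        del active[release]
    return None


def _solve_frame(A, tau, reserves, w_res, tau0, x0=None, frame=None,
                 dof_names=None):
    """One static-optimization frame: min sum a^2 (+ w*(r/tau0)^2) s.t.
    A a (+ r) = tau, 0 <= a <= 1."""
    D, M = A.shape
    # Feasibility (and infeasibility diagnosis) via L1-slack linear program.
    c = np.concatenate([np.zeros(M), np.ones(2 * D)])
    A_eq = np.hstack([A, np.eye(D), -np.eye(D)])
    bounds = [(0.0, 1.0)] * M + [(0.0, None)] * (2 * D)
    lp = linprog(c, A_eq=A_eq, b_eq=tau, bounds=bounds, method="highs")
    if lp.status != 0:
        raise ModelError(f"feasibility LP failed: {lp.message}")
    slack = lp.x[M:M + D] - lp.x[M + D:]
    infeasible = np.abs(slack) > 1e-6
    if np.any(infeasible) and not reserves:
        bad = [dof_names[i] if dof_names else str(i)
               for i in np.nonzero(infeasible)[0]]
        raise InfeasibleError(bad, frame)
    a0 = lp.x[:M]
    big = np.inf
    if reserves:
        A_full = np.hstack([A, np.eye(D)])
        w = np.concatenate([np.ones(M), np.full(D, w_res / tau0**2)])
        lb = np.concatenate([np.zeros(M), np.full(D, -big)])
        ub = np.concatenate([np.ones(M), np.full(D, big)])
        x_init = np.concatenate([a0, slack])
    else:
        A_full = A
        w = np.ones(M)
        lb, ub = np.zeros(M), np.ones(M)
        x_init = a0
    active0 = {}
    for i in range(M):
        if x_init[i] <= 1e-9:
            active0[i] = 0.0
        elif x_init[i] >= 1.0 - 1e-9:
            active0[i] = 1.0
    x = _active_set_qp(A_full, tau, w, lb, ub, active0)
    if x is None or (len(tau) and np.max(np.abs(A_full @ x - tau)) > 1e-8):
        # fall back to SLSQP from the LP point
        def obj(z):
            return float(z @ (w * z))

        def grad(z):
            return 2.0 * w * z

        cons = {"type": "eq", "fun": lambda z: A_full @ z - tau,
                "jac": lambda z: A_full}
        bnds = [(l if np.isfinite(l) else None, u if np.isfinite(u) else None)
                for l, u in zip(lb, ub)]
        res = minimize(obj, x_init, jac=grad, bounds=bnds, constraints=[cons],
                       method="SLSQP", options={"maxiter": 1000, "ftol": 1e-16})
        x = res.x
        viol = np.max(np.abs(A_full @ x - tau)) if len(tau) else 0.0
        if viol > 1e-6:
            raise ModelError(
                f"static optimization failed to satisfy constraints "
                f"(violation {viol:.2e} N m)"
            )
    a = np.clip(x[:M], 0.0, 1.0)
    r = x[M:] if reserves else np.zeros(D)
    return a, r


def static_optimization(R: np.ndarray, tau: np.ndarray, fmax: np.ndarray,
                        free_dof_names: list[str], muscle_names: list[str],
                        reserves: str = "off", w_res: float = 1000.0,
                        tau0: float = 1.0,
                        active_mask: np.ndarray | None = None) -> MuscleState:
    """Frame-by-frame muscle redundancy resolution.

    Minimises the sum of squared activations subject to moment equilibrium
    ``sum_i a_i fmax_i R[i, j] = tau_j`` on the free DoFs and ``0 <= a <= 1``.
    With ``reserves="on"`` an idealized torque actuator per free DoF enters
    the constraints and is penalised by ``w_res * (r / tau0)^2``.  With
    ``reserves="off"``, an infeasible frame raises :class:`InfeasibleError`
    naming the violated DoF(s); ``"auto"`` retries the whole solve with
    reserves enabled.

    ``R``: (frames, muscles, dofs); ``tau``: (frames, dofs).
    """
    R = np.asarray(R, dtype=float)
    tau = np.asarray(tau, dtype=float)
    fmax = np.asarray(fmax, dtype=float)
    F, M, D = R.shape
    if tau.shape != (F, D):
        raise ModelError("tau shape inconsistent with moment-arm matrix")
    if active_mask is None:
        active_mask = np.ones((F, D), dtype=bool)
    else:
        active_mask = np.asarray(active_mask, dtype=bool).reshape(F, D)

    def solve(use_reserves: bool) -> MuscleState:
        a = np.zeros((F, M))
        r = np.zeros((F, D))
        x_prev = None
        for f in range(F):
            rows = active_mask[f]
            A = (R[f] * fmax[:, None]).T[rows]
            names = [n for n, keep in zip(free_dof_names, rows) if keep]
            a[f], r_act = _solve_frame(A, tau[f][rows], use_reserves, w_res,
                                       tau0, x0=x_prev, frame=f,
                                       dof_names=names)
            r[f, rows] = r_act
            x_prev = None  # active set may change between frames
        return MuscleState(list(muscle_names), list(free_dof_names), a,
                           a * fmax[None, :], r, use_reserves)

    if reserves == "on":
        return solve(True)
    if reserves == "off":
        return solve(False)
    try:
        return solve(False)
    except InfeasibleError:
        return solve(True)


# ---------------------------------------------------------------------------
# Joint reaction analysis
# ---------------------------------------------------------------------------

_FOOT_SEGMENTS = ("hindfoot", "forefoot", "toes")


def _ankle_crossing_force(model: Model, poses, activations, distal: set):
    """Vector sum of ankle-crossing muscle forces acting on the foot."""
    total = np.zeros(3)
    for i, m in enumerate(model.muscles):
        f = activations[i] * m.fmax
        if f <= 0.0:
            continue
        segs = [s for s, _ in m.points]
        for k in range(len(segs) - 1):
            if segs[k] not in distal and segs[k + 1] in distal:
                p_prox = poses[segs[k]].apply(m.points[k][1])
                p_dist = poses[segs[k + 1]].apply(m.points[k + 1][1])
                d = p_prox - p_dist
                n = np.linalg.norm(d)
                if n < 1e-9:
                    raise ModelError(
                        f"muscle {m.name!r}: degenerate path direction at the "
                        "ankle crossing"
                    )
                total += f * d / n
                break
    return total


def joint_reaction(model: Model, qs: np.ndarray, muscle_state: MuscleState,
                   loads: ExternalLoadAssignment, rate: float,
                   frame_label: str = "MR") -> JointLoadSeries:
    """Ankle joint reaction force over the stance frames.

    The contact force on the foot free body is minus the sum of the external
    wrench force, the foot-segment weights and the ankle-crossing muscle
    forces; components are expressed in the current ankle joint frame and
    the resultant is normalised by body weight (%BW).
    """
    if model.patient_meta is None:
        raise ModelError("model carries no patient meta (body weight unknown)")
    bw = model.patient_meta.body_weight_n
    distal = set()
    for s in _FOOT_SEGMENTS:
        if s in model.segments:
            distal |= set(model.subtree(s))
    ankle = model.joint_by_child["hindfoot"]
    n = len(loads.frames)
    jrf = np.zeros((n, 3))
    mag = np.zeros(n)
    foot_weight = sum(model.segments[s].mass for s in distal) * _GRAV_VEC
    for k, f in enumerate(loads.frames):
        poses = forward_kinematics(model, KinematicState(qs[f]))
        f_ext = loads.force[k] if loads.segment[k] in distal else np.zeros(3)
        f_mus = _ankle_crossing_force(model, poses, muscle_state.a[k], distal)
        contact = -(f_ext + foot_weight + f_mus)
        X = poses[ankle.parent_segment].compose(ankle.parent_frame)
        jrf[k] = X.R.T @ contact
        mag[k] = np.linalg.norm(contact) / bw * 100.0
    time = loads.frames / rate
    return JointLoadSeries(time, jrf, mag, frame_label)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything one walking-trial simulation produced."""

    model: Model
    config: RunConfig
    qs: np.ndarray
    ik_rms: np.ndarray
    stance_idx: np.ndarray
    loads: ExternalLoadAssignment
    tau: GeneralizedForces
    free_dofs: list[str]
    R_free: np.ndarray
    muscle_state: MuscleState
    jrf: JointLoadSeries
    provenance: dict = field(default_factory=dict)

    @property
    def peak_jrf_bw(self) -> float:
        return float(np.max(self.jrf.magnitude_bw) / 100.0)


class TrialSimulation:
    """Cached per-trial simulation: IK and inverse dynamics are computed once;
    muscle-dependent stages (moment arms, static optimization, joint
    reaction) can be re-run cheaply for geometry-perturbed models."""

    def __init__(self, model: Model, trial: GaitTrial, config: RunConfig,
                 arm_delta: float = 1e-5):
        from .scaling import apply_ankle_frame

        if model.meta.get("ankle_frames"):
            model = apply_ankle_frame(model, config.axes)
        else:
            model = model.copy()
        for name in config.locked_dofs:
            if name in model.dof_names:
                model.lock(name, 0.0)
        self.model = model
        self.config = config
        self.trial = trial
        grf = trial.grf
        if grf is not None and abs(grf.rate - trial.markers.rate) > 1e-9:
            grf = grf.resampled(trial.markers.rate)
        self.grf = grf
        events = dict(trial.events)
        if not events and grf is not None:
            events = detect_stance(grf, config.stance_threshold_n)
        self.trial_events = events
        t = trial.markers.times
        self.stance_idx = np.nonzero(
            (t >= events["foot_strike"] - 1e-9) & (t <= events["foot_off"] + 1e-9)
        )[0]
        self.qs, self.ik_rms = inverse_kinematics(model, trial.markers,
                                                  config.ik_weights)
        trial2 = GaitTrial(trial.markers, grf, events, trial.kind)
        self.loads = assign_grf(trial2, model, self.qs, config.mode,
                                self.stance_idx)
        self.tau_all = inverse_dynamics(
            model, self.qs, self.loads,
            mode="quasi_static" if config.quasi_static else "full",
            rate=trial.markers.rate)
        self.free_dofs = (list(config.free_dofs) if config.free_dofs is not None
                          else default_free_dofs(model, config.mode))
        self.free_idx = [model.dof_index(n) for n in self.free_dofs]
        self.arm_delta = arm_delta
        # FD pose pairs are geometry-independent of the muscle points: cache.
        self._pairs = [
            _fd_pose_pairs(model, self.qs[f], self.free_dofs, arm_delta)
            for f in self.stance_idx
        ]
        self._base_poses = [
            forward_kinematics(model, KinematicState(self.qs[f]))
            for f in self.stance_idx
        ]
        self.R_free = np.stack([
            _arms_from_pairs(model, pairs, arm_delta) for pairs in self._pairs
        ])

    def solve(self, model: Model | None = None,
              R_free: np.ndarray | None = None) -> PipelineResult:
        """Static optimization + joint reaction for ``model`` (default: the
        baseline), reusing the cached kinematics and generalized forces."""
        model = self.model if model is None else model
        if R_free is None:
            if model is self.model:
                R_free = self.R_free
            else:
                R_free = np.stack([
                    _arms_from_pairs(model, pairs, self.arm_delta)
                    for pairs in self._pairs
                ])
        tau_free = self.tau_all.tau[:, self.free_idx]
        fmax = np.array([m.fmax for m in model.muscles])
        # The MTP moment is constrained only while the toes carry load.
        mask = np.ones((len(self.stance_idx), len(self.free_dofs)), dtype=bool)
        if "mtp_flexion" in self.free_dofs:
            j = self.free_dofs.index("mtp_flexion")
            loaded = np.array([s == "toes" for s in self.loads.segment])
            mask[:, j] = loaded
        ms = static_optimization(R_free, tau_free, fmax, self.free_dofs,
                                 model.muscle_names(), self.config.reserves,
                                 self.config.reserve_weight,
                                 self.config.reserve_tau0, active_mask=mask)
        jrf = joint_reaction(model, self.qs, ms, self.loads,
                             self.trial.markers.rate, self.config.axes)
        return PipelineResult(
            model, self.config, self.qs, self.ik_rms, self.stance_idx,
            self.loads, self.tau_all, self.free_dofs, R_free, ms, jrf,
            provenance={
                "events": self.trial_events,
                "used_reserves": ms.used_reserves,
                "mode": self.config.mode,
                "axes": self.config.axes,
                "mean_ik_rms_mm": float(np.nanmean(self.ik_rms) * 1000.0),
            },
        )

    def solve_perturbed(self, model: Model) -> PipelineResult:
        """Re-solve with a model whose muscle geometry (only) differs: moment
        arms are recomputed only for the muscle paths that changed."""
        # graft the muscle geometry onto the simulation's own model so the
        # joint frames / locked coordinates are bitwise those of the baseline
        graft = self.model.copy()
        for mg, mp in zip(graft.muscles, model.muscles):
            mg.points = [(s, p.copy()) for s, p in mp.points]
            mg.fmax = mp.fmax
        model = graft
        changed = []
        for i, (m0, m1) in enumerate(zip(self.model.muscles, model.muscles)):
            same = len(m0.points) == len(m1.points) and all(
                s0 == s1 and np.array_equal(p0, p1)
                for (s0, p0), (s1, p1) in zip(m0.points, m1.points)
            )
            if not same:
                changed.append(i)
        R = self.R_free.copy()
        if changed:
            names = [model.muscles[i].name for i in changed]
            for k, pairs in enumerate(self._pairs):
                R[k, changed, :] = _arms_from_pairs(model, pairs,
                                                    self.arm_delta, names)
        return self.solve(model, R)


def run_pipeline(model: Model, trial: GaitTrial,
                 config: RunConfig | None = None) -> PipelineResult:
    """IK -> GRF assignment -> inverse dynamics -> moment arms -> static
    optimization -> joint reaction, windowed to the stance phase."""
    config = config or RunConfig()
    return TrialSimulation(model, trial, config).solve()
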