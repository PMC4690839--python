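"""Inverse kinematics, load assignment, inverse dynamics, moment arms,
static optimization and joint reaction analysis."""

import numpy as np
import pytest

from tarsus.gait_io import ForcePlateSeries, GaitTrial, MarkerTrajectorySet
from tarsus.model import KinematicState, forward_kinematics
from tarsus.simulation import (DEFAULT_LOCKED_DOFS, InfeasibleError,
                               RunConfig, assign_grf, inverse_dynamics,
                               inverse_kinematics, joint_reaction,
                               moment_arms, run_pipeline, static_optimization)
from conftest import BW_N, build_planar_toy, planar_toy_trial


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------


class TestInverseKinematics:
    def test_static_pose_zero_residual(self, patient_model):
        from tarsus.synthetic import make_static_trial
        trial = make_static_trial(patient_model, duration_s=0.05)
        model = patient_model.copy()
        for n in DEFAULT_LOCKED_DOFS:
            model.lock(n)
        qs, rms = inverse_kinematics(model, trial.markers, frames=[0])
        np.testing.assert_allclose(qs[0], model.default_state().q, atol=1e-8)
        assert rms[0] < 1e-10

    def test_recovers_generating_angles_noiselessly(self, patient_model,
                                                    walking):
        trial, truth = walking
        model = patient_model.copy()
        for n in DEFAULT_LOCKED_DOFS:
            model.lock(n)
        frames = list(range(10, 90, 16))
        qs, rms = inverse_kinematics(model, trial.markers, frames=frames)
        for f in frames:
            np.testing.assert_allclose(qs[f], truth["qs"][f], atol=1e-6)

    def test_noisy_markers_bounded_angle_error(self, patient_model, walking):
        """1 mm marker noise keeps joint angles within ~1 degree (empirical
        bound for this marker set)."""
        trial, truth = walking
        rng = np.random.default_rng(17)
        noisy = MarkerTrajectorySet(
            trial.markers.rate, trial.markers.labels,
            trial.markers.data + rng.normal(0.0, 0.001,
                                            trial.markers.data.shape))
        model = patient_model.copy()
        for n in DEFAULT_LOCKED_DOFS:
            model.lock(n)
        frames = [30, 50, 70]
        qs, _ = inverse_kinematics(model, noisy, frames=frames)
        rot_idx = [model.dof_index(n) for n in
                   ("hip_flexion", "knee_flexion", "ankle_flexion")]
        for f in frames:
            err = np.abs(qs[f][rot_idx] - truth["qs"][f][rot_idx])
            assert np.all(err < np.radians(1.0))

    def test_too_few_markers_rejected(self, planar_toy):
        model, trial = planar_toy
        sparse = MarkerTrajectorySet(
            trial.markers.rate, trial.markers.labels[:2],
            trial.markers.data[:, :2, :])
        with pytest.raises(Exception, match="visible"):
            inverse_kinematics(model, sparse, frames=[0])


# ---------------------------------------------------------------------------
# GRF assignment
# ---------------------------------------------------------------------------


class TestAssignGRF:
    def test_total_wrench_equal_between_modes(self, baseline_sim,
                                              patient_model, walking):
        trial, _ = walking
        sim = baseline_sim
        grf = trial.grf.resampled(trial.markers.rate)
        t2 = GaitTrial(trial.markers, grf, trial.events, "walking")
        l1 = assign_grf(t2, sim.model, sim.qs, "1SEG", sim.stance_idx)
        l2 = assign_grf(t2, sim.model, sim.qs, "2SEG", sim.stance_idx)
        np.testing.assert_array_equal(l1.force, l2.force)
        np.testing.assert_array_equal(l1.cop, l2.cop)
        np.testing.assert_array_equal(l1.free_moment, l2.free_moment)

    def test_latched_switch_and_no_switch_back(self, baseline_sim, walking):
        trial, _ = walking
        sim = baseline_sim
        grf = trial.grf.resampled(trial.markers.rate)
        t2 = GaitTrial(trial.markers, grf, trial.events, "walking")
        loads = assign_grf(t2, sim.model, sim.qs, "2SEG", sim.stance_idx)
        assert loads.switch_frame is not None
        segs = np.array(loads.segment)
        assert np.all(segs[:loads.switch_frame] == "hindfoot")
        assert np.all(segs[loads.switch_frame:] == "toes")

    def test_cop_posterior_never_switches(self, planar_toy):
        model, _ = planar_toy
        # constant COP well behind the (absent) MTP: stays on the hindfoot
        trial = planar_toy_trial(model, cop_x=-0.05)
        qs = np.tile(model.default_state().q, (trial.markers.n_frames, 1))
        loads = assign_grf(trial, model, qs, "2SEG",
                           np.arange(trial.markers.n_frames))
        assert all(s == "hindfoot" for s in loads.segment)
        assert loads.switch_frame is None


# ---------------------------------------------------------------------------
# Inverse dynamics
# ---------------------------------------------------------------------------


class TestInverseDynamics:
    def test_planar_moment_matches_hand_free_body(self, planar_toy):
        """GRF 1.2 BW at 0.12 m anterior needs a 0.144 BW N m
        plantarflexion moment."""
        model, trial = planar_toy
        qs = np.tile(model.default_state().q, (trial.markers.n_frames, 1))
        loads = assign_grf(trial, model, qs, "1SEG",
                           np.arange(trial.markers.n_frames))
        tau = inverse_dynamics(model, qs, loads)
        expected = -0.144 * BW_N
        np.testing.assert_allclose(tau.column("ankle_flexion"), expected,
                                   rtol=1e-9)

    def test_static_standing_equilibrium(self, patient_model):
        """GRF = BW under the ankle: ankle moment ~0, vertical
        intersegmental force = BW minus the foot weight."""
        model = patient_model
        n = 3
        poses = forward_kinematics(model, model.default_state())
        ankle = poses["hindfoot"].t
        bw = model.patient_meta.body_weight_n
        force = np.tile([0.0, bw, 0.0], (n, 1))
        cop = np.tile([ankle[0], 0.0, ankle[2]], (n, 1))
        grf = ForcePlateSeries(100.0, force, cop, np.zeros((n, 3)))
        labels = sorted(model.markers)
        refm = {k: poses[s].apply(p) for k, (s, p) in model.markers.items()}
        mk = MarkerTrajectorySet(100.0, labels,
                                 np.tile(np.array([refm[k] for k in labels])[None],
                                         (n, 1, 1)))
        trial = GaitTrial(mk, grf, {"foot_strike": 0.0, "foot_off": 0.02},
                          "walking")
        qs = np.tile(model.default_state().q, (n, 1))
        loads = assign_grf(trial, model, qs, "1SEG", np.arange(n))
        tau = inverse_dynamics(model, qs, loads)
        # ankle flexion moment: only the COP y-offset lever remains (~0)
        assert abs(tau.column("ankle_flexion")[0]) < 2.0
        from tarsus.simulation import MuscleState
        ms = MuscleState(model.muscle_names(), [],
                         np.zeros((n, len(model.muscles))),
                         np.zeros((n, len(model.muscles))), np.zeros((n, 0)))
        jrf = joint_reaction(model, qs, ms, loads, 100.0)
        foot_w = sum(model.segments[s].mass for s in
                     ("hindfoot", "forefoot", "toes")) * 9.81
        assert jrf.magnitude_bw[0] / 100.0 * bw == pytest.approx(bw - foot_w,
                                                                 rel=1e-6)

    def test_quasi_static_close_to_full_on_slow_gait(self, baseline_sim,
                                                     walking):
        trial, _ = walking
        sim = baseline_sim
        tau_q = sim.tau_all.tau[:, sim.model.dof_index("ankle_flexion")]
        tau_f = inverse_dynamics(sim.model, sim.qs, sim.loads, mode="full",
                                 rate=trial.markers.rate).tau[
            :, sim.model.dof_index("ankle_flexion")]
        mask = np.abs(tau_q) > 10.0
        rel = np.abs(tau_f[mask] - tau_q[mask]) / np.abs(tau_q[mask])
        assert np.max(rel) < 0.05


# ---------------------------------------------------------------------------
# Moment arms
# ---------------------------------------------------------------------------


class TestMomentArms:
    def test_straight_path_arm_equals_perpendicular_distance(self):
        model = build_planar_toy(muscle_x=-0.04)
        R = moment_arms(model, model.default_state(), ["ankle_flexion"])
        assert R[0, 0] == pytest.approx(-0.04, abs=1e-4)

    def test_non_crossing_muscle_has_zero_arm(self, template_model):
        R = moment_arms(template_model, template_model.default_state(),
                        ["ankle_flexion"])
        i = template_model.muscle_names().index("glut_max~1")
        assert R[i, 0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_when_path_reflected_across_joint(self):
        post = build_planar_toy(muscle_x=-0.04)
        ant = build_planar_toy(muscle_x=+0.04)
        Rp = moment_arms(post, post.default_state(), ["ankle_flexion"])
        Ra = moment_arms(ant, ant.default_state(), ["ankle_flexion"])
        assert Rp[0, 0] == pytest.approx(-Ra[0, 0], abs=1e-6)
        assert Rp[0, 0] < 0  # plantarflexor: negative dorsiflexion arm


# ---------------------------------------------------------------------------
# Static optimization
# ---------------------------------------------------------------------------


class TestStaticOptimization:
    def test_zero_torque_gives_zero_activation(self):
        R = np.zeros((2, 3, 1))
        R[:, :, 0] = [0.05, -0.03, 0.02]
        tau = np.zeros((2, 1))
        ms = static_optimization(R, tau, np.array([1000.0, 800.0, 500.0]),
                                 ["dof"], ["m1", "m2", "m3"])
        np.testing.assert_allclose(ms.a, 0.0, atol=1e-9)

    def test_single_muscle_analytic_activation(self):
        R = np.full((1, 1, 1), 0.05)
        tau = np.full((1, 1), 25.0)
        ms = static_optimization(R, tau, np.array([1000.0]), ["dof"], ["m"])
        assert ms.a[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert ms.force[0, 0] == pytest.approx(500.0, abs=1e-6)

    @pytest.mark.parametrize("arms,fmax,tau_val", [
        ((0.06, 0.03), (1000.0, 1000.0), 30.0),
        ((0.05, 0.025, 0.04), (800.0, 1200.0, 600.0), 28.0),
    ])
    def test_matches_dense_grid_oracle(self, arms, fmax, tau_val):
        """Solution tracks a brute-force minimizer to 1e-3 activation."""
        arms = np.array(arms)
        fmax = np.array(fmax)
        M = len(arms)
        R = arms.reshape(1, M, 1)
        ms = static_optimization(R, np.array([[tau_val]]), fmax,
                                 ["dof"], [f"m{i}" for i in range(M)])
        # grid the first M-1 activations, solve the last from the constraint
        grids = np.meshgrid(*[np.arange(0.0, 1.0 + 1e-9, 1e-3)] * (M - 1),
                            indexing="ij")
        partial = sum(g * f * r for g, f, r in zip(grids, fmax, arms))
        last = (tau_val - partial) / (fmax[-1] * arms[-1])
        ok = (last >= 0.0) & (last <= 1.0)
        cost = sum(g**2 for g in grids) + np.where(ok, last**2, np.inf)
        idx = np.unravel_index(np.argmin(cost), cost.shape)
        best = [g[idx] for g in grids] + [last[idx]]
        np.testing.assert_allclose(ms.a[0], best, atol=1e-3)
        # objective never exceeds the oracle's
        assert ms.a[0] @ ms.a[0] <= cost[idx] + 1e-6

    def test_constraints_satisfied_to_tolerance(self, baseline_sim):
        sim = baseline_sim
        res = sim.solve()
        fmax = np.array([m.fmax for m in sim.model.muscles])
        for k in range(len(res.stance_idx)):
            A = (res.R_free[k] * fmax[:, None]).T
            tau = res.tau.tau[k, sim.free_idx]
            viol = np.abs(A @ res.muscle_state.a[k] - tau)
            assert np.max(viol) < 1e-6
        assert np.all(res.muscle_state.a >= -1e-12)
        assert np.all(res.muscle_state.a <= 1.0 + 1e-12)

    def test_infeasibility_names_dof(self):
        # one weak dorsiflexor cannot produce a plantarflexion moment
        R = np.full((1, 1, 1), +0.03)
        tau = np.array([[-20.0]])
        with pytest.raises(InfeasibleError, match="ankle_flexion"):
            static_optimization(R, tau, np.array([100.0]),
                                ["ankle_flexion"], ["m"], reserves="off")

    def test_reserves_make_it_feasible(self):
        R = np.full((1, 1, 1), +0.03)
        tau = np.array([[-20.0]])
        ms = static_optimization(R, tau, np.array([100.0]),
                                 ["ankle_flexion"], ["m"], reserves="on")
        assert ms.used_reserves
        assert ms.reserve[0, 0] == pytest.approx(-20.0, rel=0.05)


# ---------------------------------------------------------------------------
# Joint reaction
# ---------------------------------------------------------------------------


class TestJointReaction:
    def test_planar_pushoff_matches_hand_vector_sum(self, planar_toy):
        """Achilles 3.6 BW from a 0.04 m arm and 1.2 BW GRF at 0.12 m
        anterior combine to a ~4.8 BW joint reaction."""
        model, trial = planar_toy
        cfg = RunConfig(reserves="off", free_dofs=("ankle_flexion",))
        res = run_pipeline(model, trial, cfg)
        f_musc = res.muscle_state.force[0, 0]
        assert f_musc == pytest.approx(0.144 * BW_N / 0.04, rel=1e-6)
        assert f_musc / BW_N == pytest.approx(3.6, rel=1e-6)
        assert res.peak_jrf_bw == pytest.approx(4.8, rel=1e-6)

    def test_magnitude_invariant_to_frame_relabel(self, planar_toy):
        """Rotating the ankle frame axes (same forces, reference pose)
        changes the reported components but not the resultant magnitude."""
        from tarsus.geometry import RigidTransform, rotation_about_axis
        from tarsus.simulation import MuscleState
        model, trial = planar_toy
        n = trial.markers.n_frames
        qs = np.tile(model.default_state().q, (n, 1))
        loads = assign_grf(trial, model, qs, "1SEG", np.arange(n))
        ms = MuscleState(["achilles"], [], np.full((n, 1), 0.3),
                         np.full((n, 1), 0.3 * 5000.0), np.zeros((n, 0)))
        jrf0 = joint_reaction(model, qs, ms, loads, trial.markers.rate)
        rot = model.copy()
        Rf = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.radians(20))
        joint = rot.joint_by_child["hindfoot"]
        joint.parent_frame = RigidTransform(Rf, joint.parent_frame.t)
        joint.child_frame = RigidTransform(Rf, joint.child_frame.t)
        jrf1 = joint_reaction(rot, qs, ms, loads, trial.markers.rate)
        np.testing.assert_allclose(jrf1.magnitude_bw, jrf0.magnitude_bw,
                                   atol=1e-9)
        assert not np.allclose(jrf1.jrf, jrf0.jrf)

    def test_foot_free_body_force_balance(self, baseline_sim):
        """Muscle + intersegmental + external + weight forces on the foot
        sum to zero in quasi-static mode (by construction, checked)."""
        sim = baseline_sim
        res = sim.solve()
        from tarsus.simulation import _ankle_crossing_force
        distal = set(sim.model.subtree("hindfoot"))
        foot_w = sum(sim.model.segments[s].mass for s in distal) * \
            np.array([0.0, -9.81, 0.0])
        for k in (0, len(res.stance_idx) // 2, len(res.stance_idx) - 1):
            poses = forward_kinematics(
                sim.model, KinematicState(sim.qs[res.stance_idx[k]]))
            f_mus = _ankle_crossing_force(sim.model, poses,
                                          res.muscle_state.a[k], distal)
            ankle_joint = sim.model.joint_by_child["hindfoot"]
            X = poses[ankle_joint.parent_segment].compose(
                ankle_joint.parent_frame)
            contact = X.R @ res.jrf.jrf[k]
            resid = contact + res.loads.force[k] + foot_w + f_mus
            assert np.linalg.norm(resid) < 1e-6

    def test_jrf_scales_linearly_with_grf_in_planar_toy(self):
        model = build_planar_toy()
        res1 = run_pipeline(model, planar_toy_trial(model, grf_bw=1.2),
                            RunConfig(reserves="off",
                                      free_dofs=("ankle_flexion",)))
        res2 = run_pipeline(model, planar_toy_trial(model, grf_bw=2.4),
                            RunConfig(reserves="off",
                                      free_dofs=("ankle_flexion",)))
        assert res2.muscle_state.force[0, 0] == pytest.approx(
            2.0 * res1.muscle_state.force[0, 0], rel=1e-9)
        assert res2.peak_jrf_bw == pytest.approx(2.0 * res1.peak_jrf_bw,
                                                 rel=1e-9)
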