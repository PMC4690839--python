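"""Scaling rules, registration chain and full patient-model assembly."""

import numpy as np
import pytest

from tarsus.gait_io import GaitTrial, MarkerTrajectorySet
from tarsus.geometry import (DegenerateGeometryError, LandmarkSet,
                             RigidTransform, rotation_about_axis)
from tarsus.model import ModelError, forward_kinematics
from tarsus.scaling import (PipelineStageError, ScaleFactors,
                            apply_scaling, assemble_patient_model,
                            average_static_trial, compute_scale_factors,
                            optimize_femur_rotation, reference_marker_positions,
                            register_foot_to_mri)
from tarsus.synthetic import make_patient_inputs, make_static_trial


class TestAverageStaticTrial:
    def _trial(self, data, labels=("A", "B")):
        return GaitTrial(MarkerTrajectorySet(100.0, list(labels), data),
                         None, {}, "static")

    def test_constant_marker(self):
        data = np.tile([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]], (100, 1, 1))
        s = average_static_trial(self._trial(data))
        np.testing.assert_allclose(s["A"], [1.0, 2.0, 3.0])

    def test_alternating_marker_arithmetic_mean(self):
        data = np.zeros((10, 1, 3))
        data[1::2, 0, 2] = 2.0
        s = average_static_trial(self._trial(data, labels=("A",)))
        np.testing.assert_allclose(s["A"], [0.0, 0.0, 1.0])

    def test_sparse_marker_rejected(self):
        data = np.full((10, 1, 3), np.nan)
        data[0, 0] = [1.0, 1.0, 1.0]  # visible 10% of frames
        with pytest.raises(ModelError, match="A"):
            average_static_trial(self._trial(data, labels=("A",)))

    def test_absent_required_marker(self):
        data = np.zeros((5, 1, 3))
        with pytest.raises(ModelError, match="RASI"):
            average_static_trial(self._trial(data, labels=("A",)),
                                 required=["RASI"])


class TestComputeScaleFactors:
    def test_identity_when_distances_equal(self, template_model):
        generic = reference_marker_positions(template_model)
        s = compute_scale_factors(generic, dict(generic))
        assert s.pelvis == pytest.approx((1.0, 1.0, 1.0))
        assert s.femur == pytest.approx(1.0)
        assert s.shank == pytest.approx(1.0)

    def test_doubled_distances_give_factor_two(self, template_model):
        generic = reference_marker_positions(template_model)
        patient = {k: 2.0 * v for k, v in generic.items()}
        s = compute_scale_factors(generic, patient)
        assert s.pelvis == pytest.approx((2.0, 2.0, 2.0))
        assert s.femur == pytest.approx(2.0)
        assert s.shank == pytest.approx(2.0)

    def test_hand_computed_femur_ratio(self):
        def leg(femur_len):
            return {
                "RASI": [0.1, 0.1, 0.1], "LASI": [0.1, 0.1, -0.1],
                "RPSI": [-0.1, 0.1, 0.05], "LPSI": [-0.1, 0.1, -0.05],
                "RGT": [0, 0, 0.2], "LGT": [0, 0, -0.2],
                "RLFE": [0, -femur_len, 0.25], "RMFE": [0, -femur_len, 0.15],
                "RLML": [0, -femur_len - 0.4, 0.23],
                "RMML": [0, -femur_len - 0.4, 0.17],
            }
        s = compute_scale_factors(leg(0.432), leg(0.40))
        # GT -> mid-epicondyles: sqrt(L^2 + 0) with fixed z offset cancels in
        # the ratio only if we compare the exact distances
        g = np.linalg.norm([0.432, 0.0])
        p = np.linalg.norm([0.40, 0.0])
        assert s.femur == pytest.approx(p / g)
        assert s.femur == pytest.approx(0.9259259, abs=1e-6)

    def test_missing_marker_rejected(self, template_model):
        generic = reference_marker_positions(template_model)
        patient = dict(generic)
        del patient["RGT"]
        with pytest.raises(ModelError, match="RGT"):
            compute_scale_factors(generic, patient)


class TestApplyScaling:
    def test_unity_factors_identity(self, template_model):
        out = apply_scaling(template_model, ScaleFactors.unity())
        for m0, m1 in zip(template_model.muscles, out.muscles):
            for (s0, p0), (s1, p1) in zip(m0.points, m1.points):
                np.testing.assert_array_equal(p0, p1)
        for j0, j1 in zip(template_model.joints, out.joints):
            np.testing.assert_array_equal(j0.parent_frame.t, j1.parent_frame.t)

    def test_femur_factor_two_doubles_geometry(self, template_model):
        s = ScaleFactors((1.0, 1.0, 1.0), 2.0, 1.0)
        out = apply_scaling(template_model, s)
        knee0 = template_model.joint_by_child["shank"].parent_frame.t
        knee1 = out.joint_by_child["shank"].parent_frame.t
        np.testing.assert_allclose(knee1, 2.0 * knee0)
        for m0, m1 in zip(template_model.muscles, out.muscles):
            for (s0, p0), (s1, p1) in zip(m0.points, m1.points):
                if s0 == "femur":
                    np.testing.assert_allclose(p1, 2.0 * p0)
                else:
                    np.testing.assert_array_equal(p1, p0)

    def test_pelvis_anisotropic_height_only(self, template_model):
        s = ScaleFactors((1.0, 2.0, 1.0), 1.0, 1.0)
        out = apply_scaling(template_model, s)
        for name in ("RASI", "LPSI"):
            seg0, p0 = template_model.markers[name]
            seg1, p1 = out.markers[name]
            np.testing.assert_allclose(p1, p0 * np.array([1.0, 2.0, 1.0]))

    def test_invalid_factors_rejected(self):
        with pytest.raises(ModelError):
            ScaleFactors((1.0, -1.0, 1.0), 1.0, 1.0)


class TestFootToMRIRegistration:
    def test_identity(self, template_model):
        static = average_static_trial(make_static_trial(template_model))
        ref = reference_marker_positions(template_model)
        from tarsus.template import MRI_FOOT_MARKERS
        mri = LandmarkSet({n: ref[n] for n in MRI_FOOT_MARKERS})
        T, rms = register_foot_to_mri(static, mri)
        np.testing.assert_allclose(T.R, np.eye(3), atol=1e-9)
        assert rms < 1e-6

    def test_known_offset_recovered(self, template_model):
        static = average_static_trial(make_static_trial(template_model))
        ref = reference_marker_positions(template_model)
        from tarsus.template import MRI_FOOT_MARKERS
        T_true = RigidTransform(
            rotation_about_axis(np.array([0.2, 1.0, 0.1]), 0.4),
            np.array([0.1, -0.2, 0.3]))
        mri = LandmarkSet({n: T_true.apply(ref[n]) for n in MRI_FOOT_MARKERS})
        T, rms = register_foot_to_mri(static, mri)
        np.testing.assert_allclose(T.R, T_true.R, atol=1e-9)
        np.testing.assert_allclose(T.t, T_true.t, atol=1e-9)

    def test_two_common_markers_rejected(self, template_model):
        static = average_static_trial(make_static_trial(template_model))
        ref = reference_marker_positions(template_model)
        mri = LandmarkSet({n: ref[n] for n in ("RLML", "RMML")})
        with pytest.raises(DegenerateGeometryError):
            register_foot_to_mri(static, mri)


class TestFemurRotation:
    AXIS_P = np.array([0.0, 0.42, 0.09])
    AXIS_D = np.array([0.0, 0.0, 1.0])

    def test_zero_when_coincident(self):
        lms = LandmarkSet({"RGT": np.array([-0.01, 0.765, 0.165])})
        theta, _ = optimize_femur_rotation(lms, self.AXIS_P, self.AXIS_D,
                                           lms["RGT"])
        assert abs(theta) < 1e-6

    def test_recovers_known_rotation_vs_grid_oracle(self):
        gt = np.array([-0.01, 0.765, 0.165])
        lms = LandmarkSet({"RGT": gt})
        true_theta = np.radians(15.0)
        R = rotation_about_axis(self.AXIS_D, true_theta)
        target = self.AXIS_P + R @ (gt - self.AXIS_P)
        theta, rotated = optimize_femur_rotation(lms, self.AXIS_P, self.AXIS_D,
                                                 target)
        assert abs(theta - true_theta) < 1e-6
        np.testing.assert_allclose(rotated["RGT"], target, atol=1e-9)

        # independent dense grid search at 1e-4 rad resolution
        grid = np.arange(-np.pi, np.pi, 1e-4)
        rel = gt - self.AXIS_P
        d = self.AXIS_D
        par = (rel @ d) * d
        perp = rel - par
        e2 = np.cross(d, perp)
        pts = (self.AXIS_P + par + np.cos(grid)[:, None] * perp
               + np.sin(grid)[:, None] * e2)
        best = grid[np.argmin(np.linalg.norm(pts - target, axis=1))]
        assert abs(theta - best) <= 1e-4

    def test_gt_on_axis_rejected(self):
        lms = LandmarkSet({"RGT": self.AXIS_P + 0.1 * self.AXIS_D})
        with pytest.raises(DegenerateGeometryError):
            optimize_femur_rotation(lms, self.AXIS_P, self.AXIS_D,
                                    np.array([1.0, 0.0, 0.0]))


class TestAssembly:
    def test_identity_round_trip(self, template_model, patient_model):
        """Undeformed synthetic patient: geometry equals the template."""
        for m0, m1 in zip(template_model.muscles, patient_model.muscles):
            for (s0, p0), (s1, p1) in zip(m0.points, m1.points):
                assert s0 == s1
                np.testing.assert_allclose(p1, p0, atol=1e-9)
        for rec in patient_model.meta["provenance"]:
            if "residual_mm" in rec:
                assert rec["residual_mm"] < 1e-6

    def test_per_segment_transforms_recovered(self, template_model):
        from tarsus.synthetic import SyntheticFootParams
        rng = np.random.default_rng(5)
        # small independent rigid motions of the forefoot and toe groups
        xf = {
            "metatarsal": RigidTransform(
                rotation_about_axis(rng.normal(size=3), 0.02),
                rng.uniform(-0.003, 0.003, 3)),
            "toe": RigidTransform(
                rotation_about_axis(rng.normal(size=3), -0.015),
                rng.uniform(-0.003, 0.003, 3)),
        }
        inputs, foot = make_patient_inputs(
            template_model, foot_params=SyntheticFootParams(),
            segment_transforms=xf)
        model = assemble_patient_model(template_model, inputs)
        prov = {r["stage"]: r for r in model.meta["provenance"]}
        for group, T in xf.items():
            rec = prov[f"muscle_point_mapping/{group}"]
            np.testing.assert_allclose(np.asarray(rec["transform"]),
                                       T.matrix(), atol=1e-8)
            assert rec["residual_mm"] < 1e-6

    def test_missing_mri_marker_is_stage_labelled(self, template_model):
        inputs, _ = make_patient_inputs(template_model)
        inputs.mri_markers = LandmarkSet(
            {k: v for k, v in list(inputs.mri_markers.points.items())[:2]})
        with pytest.raises(PipelineStageError) as err:
            assemble_patient_model(template_model, inputs)
        assert err.value.stage in ("foot_mri_registration",
                                   "model_registration")

    def test_no_reflections_and_residuals_logged(self, patient_model):
        for rec in patient_model.meta["provenance"]:
            if "transform" in rec:
                R = np.asarray(rec["transform"])[:3, :3]
                assert np.linalg.det(R) > 0.999
            if "residual_mm" in rec:
                assert rec["residual_mm"] >= 0.0

    def test_reference_pose_preserved_after_frame_install(self, patient_model):
        poses = forward_kinematics(patient_model,
                                   patient_model.default_state())
        np.testing.assert_allclose(poses["hindfoot"].t, [0.0, 0.07, 0.09],
                                   atol=1e-9)
        np.testing.assert_allclose(poses["hindfoot"].R, np.eye(3), atol=1e-9)
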