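"""Shared fixtures: the packaged template, a default synthetic patient and
its walking trial, and a small planar single-muscle toy for free-body
oracle checks.  Expensive pipeline objects are session-scoped."""

import numpy as np
import pytest

from tarsus.gait_io import ForcePlateSeries, GaitTrial, MarkerTrajectorySet
from tarsus.geometry import RigidTransform
from tarsus.model import (Dof, Joint, Model, MusclePathDef, PatientMeta,
                          Segment, build_template, forward_kinematics)
from tarsus.scaling import assemble_patient_model
from tarsus.simulation import RunConfig, TrialSimulation
from tarsus.synthetic import make_patient_inputs, make_walking_trial
from tarsus.template import default_template_config


@pytest.fixture(scope="session")
def template_model() -> Model:
    return build_template(default_template_config())


@pytest.fixture(scope="session")
def patient_model(template_model) -> Model:
    inputs, _foot = make_patient_inputs(template_model)
    return assemble_patient_model(template_model, inputs)


@pytest.fixture(scope="session")
def walking(patient_model):
    """Default walking trial plus its generating ground truth."""
    return make_walking_trial(patient_model)


@pytest.fixture(scope="session")
def baseline_sim(patient_model, walking):
    """Cached MR-axes 1SEG simulation of the default trial."""
    trial, _ = walking
    return TrialSimulation(patient_model, trial,
                           RunConfig(mode="1SEG", axes="MR", reserves="off"))


BW_N = 50.0 * 9.81


def build_planar_toy(muscle_x: float = -0.04, fmax: float = 5000.0) -> Model:
    """Fixed shank + one-DoF ankle + a single vertical Achilles-like muscle
    whose plantarflexion moment arm is exactly ``|muscle_x|``."""
    segs = [Segment("shank", 0.0), Segment("hindfoot", 0.0)]
    joints = [
        Joint("weld", "ground", "shank",
              RigidTransform(np.eye(3), [0.0, 0.42, 0.0])),
        Joint("ankle", "shank", "hindfoot",
              RigidTransform(np.eye(3), [0.0, -0.35, 0.0]),
              dofs=[Dof("ankle_flexion", "rotation", "z")]),
    ]
    muscles = [MusclePathDef(
        "achilles",
        [("shank", [muscle_x, -0.10, 0.0]), ("hindfoot", [muscle_x, -0.03, 0.0])],
        fmax)]
    markers = {
        "S1": ("shank", [0.05, -0.10, 0.0]),
        "S2": ("shank", [0.0, -0.20, 0.05]),
        "S3": ("shank", [-0.05, -0.15, 0.0]),
        "H1": ("hindfoot", [0.05, -0.05, 0.0]),
        "H2": ("hindfoot", [-0.05, -0.05, 0.03]),
        "H3": ("hindfoot", [0.10, -0.06, -0.02]),
    }
    return Model(segs, joints, muscles, [], markers, PatientMeta(50.0, 1.45))


def planar_toy_trial(model: Model, grf_bw: float = 1.2, cop_x: float = 0.12,
                     n: int = 25, rate: float = 50.0) -> GaitTrial:
    """Static markers + constant vertical GRF at ``cop_x`` anterior."""
    poses = forward_kinematics(model, model.default_state())
    refm = {k: poses[s].apply(np.asarray(p)) for k, (s, p) in model.markers.items()}
    labels = sorted(refm)
    data = np.tile(np.array([refm[k] for k in labels])[None], (n, 1, 1))
    markers = MarkerTrajectorySet(rate, labels, data)
    force = np.tile([0.0, grf_bw * BW_N, 0.0], (n, 1))
    cop = np.tile([cop_x, 0.0, 0.0], (n, 1))
    grf = ForcePlateSeries(rate, force, cop, np.zeros((n, 3)))
    return GaitTrial(markers, grf,
                     {"foot_strike": 0.0, "foot_off": (n - 1) / rate},
                     "walking")


@pytest.fixture()
def planar_toy():
    model = build_planar_toy()
    return model, planar_toy_trial(model)
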