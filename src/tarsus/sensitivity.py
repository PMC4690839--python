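"""Sensitivity protocols: muscle-point perturbation tables, foot-segmentation
(1SEG vs 2SEG) and ankle-axes (MR vs CGA) experiments.

The muscle-point protocol perturbs each point adjacent to the ankle joint by
a fixed distance (default 5 mm) along each axis of the hindfoot coordinate
frame, one perturbation at a time, re-solves the load-sharing problem and
reports the signed percentage change in the resultant ankle joint reaction
force over stance: the mean across stance then across trials, and the
largest-magnitude change across stance then averaged across trials.  Stance
is resampled to 101 points (0-100%) before averaging across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_io import GaitTrial
from .model import Model, ModelError, forward_kinematics
from .simulation import InfeasibleError, RunConfig, TrialSimulation
from .template import default_perturbation_structures

__all__ = [
    "PerturbationSpec",
    "SensitivityCell",
    "perturb_model",
    "default_specs",
    "sensitivity_table",
    "segment_assumption_experiment",
    "axes_experiment",
    "REPORT_THRESHOLD_PCT",
]

# muscles enter the report when any |mean % change| reaches this value
REPORT_THRESHOLD_PCT = 0.5

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PerturbationSpec:
    """Displace one muscle path point along a hindfoot-frame axis."""

    muscle: str
    point_index: int
    axis: str            # hindfoot-frame axis: x | y | z
    magnitude_m: float   # signed displacement

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ModelError(f"unknown axis {self.axis!r}")
        if abs(self.magnitude_m) > 0.02:
            raise ModelError("perturbation magnitude exceeds the 20 mm sanity bound")


@dataclass(frozen=True)
class SensitivityCell:
    """Signed % change in JRF magnitude: stance mean and stance extreme,
    each averaged across trials."""

    mean_pct: float
    max_pct: float


def perturb_model(model: Model, spec: PerturbationSpec) -> Model:
    """Copy of ``model`` with one path point displaced by ``magnitude_m``
    along the chosen hindfoot-frame axis (expressed back in the owning
    segment's frame); everything else is bitwise identical."""
    out = model.copy()
    m = out.muscle(spec.muscle)
    if not 0 <= spec.point_index < len(m.points):
        raise ModelError(
            f"muscle {spec.muscle!r} has no point index {spec.point_index}"
        )
    poses = forward_kinematics(out, out.default_state())
    axis_world = poses["hindfoot"].R @ np.eye(3)[:, _AXES[spec.axis]]
    seg, p = m.points[spec.point_index]
    delta_local = poses[seg].R.T @ (axis_world * spec.magnitude_m)
    m.points[spec.point_index] = (seg, p + delta_local)
    return out


def default_specs(magnitude_m: float = 0.005):
    """The packaged protocol: ten structures x three axes x both signs.

    Returns a list of ``(label, axis, sign, [PerturbationSpec, ...])``; the
    Achilles insertion structure carries one spec per muscle path sharing
    the insertion point.
    """
    out = []
    for label, points in default_perturbation_structures():
        for axis in ("x", "y", "z"):
            for sign in (1.0, -1.0):
                specs = [PerturbationSpec(mn, pi, axis, sign * magnitude_m)
                         for mn, pi in points]
                out.append((label, axis, sign, specs))
    return out


def _resample_stance(values: np.ndarray, n: int = 101) -> np.ndarray:
    x = np.linspace(0.0, 1.0, len(values))
    return np.interp(np.linspace(0.0, 1.0, n), x, values)


def _signed_extreme(v: np.ndarray) -> float:
    return float(v[np.argmax(np.abs(v))])


def sensitivity_table(model: Model, trials: list[GaitTrial],
                      config: RunConfig | None = None,
                      structures=None, magnitude_m: float = 0.005,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Muscle-point sensitivity tables over one or more walking trials.

    Returns ``(mean_table, max_table, info)``: DataFrames indexed by
    structure with one column per (axis, sign), holding the signed % change
    of the resultant ankle JRF (perturbed minus original).  ``info`` carries
    the 0.5% report filter result and any failed cells.
    """
    config = config or RunConfig()
    cases = (structures if structures is not None
             else default_specs(magnitude_m))
    sims = [TrialSimulation(model, tr, config) for tr in trials]
    baselines = [s.solve() for s in sims]
    base_mag = [_resample_stance(b.jrf.magnitude_bw) for b in baselines]
    if any(np.any(m <= 0) for m in base_mag):
        raise ModelError("baseline JRF magnitude vanishes; % change undefined")

    labels = sorted({c[0] for c in cases},
                    key=[c[0] for c in cases].index)
    cols = [f"{axis}{'+' if sign > 0 else '-'}"
            for axis in ("x", "y", "z") for sign in (1.0, -1.0)]
    mean_tbl = pd.DataFrame(np.nan, index=labels, columns=cols)
    max_tbl = pd.DataFrame(np.nan, index=labels, columns=cols)
    failures: dict[str, str] = {}
    reserve_cells: list[str] = []

    for label, axis, sign, specs in cases:
        col = f"{axis}{'+' if sign > 0 else '-'}"
        pert = model
        for sp in specs:
            pert = perturb_model(pert, sp)
        means, extremes = [], []
        used_res = False
        try:
            for sim, bm in zip(sims, base_mag):
                res = sim.solve_perturbed(pert)
                pm = _resample_stance(res.jrf.magnitude_bw)
                pct = 100.0 * (pm - bm) / bm
                means.append(float(np.mean(pct)))
                extremes.append(_signed_extreme(pct))
                used_res |= res.muscle_state.used_reserves
        except InfeasibleError as exc:
            failures[f"{label}/{col}"] = str(exc)
            continue
        if used_res:
            reserve_cells.append(f"{label}/{col}")
        mean_tbl.loc[label, col] = float(np.mean(means))
        max_tbl.loc[label, col] = float(np.mean(extremes))

    included = mean_tbl.index[
        (mean_tbl.abs() >= REPORT_THRESHOLD_PCT).any(axis=1)
    ].tolist()
    info = {
        "included": included,
        "threshold_pct": REPORT_THRESHOLD_PCT,
        "failures": failures,
        "reserve_cells": reserve_cells,
        "magnitude_m": magnitude_m,
        "n_trials": len(trials),
    }
    return mean_tbl, max_tbl, info


def segment_assumption_experiment(model: Model, trials: list[GaitTrial],
                                  config: RunConfig | None = None):
    """2SEG minus 1SEG ankle JRF difference over normalised stance.

    Returns a dict with the 101-point mean difference (%BW), both mean
    magnitude curves, the per-trial COP switch frames, and the
    peak-difference / peak-JRF summary ratio.
    """
    config = config or RunConfig()
    curves = {}
    switches = []
    for mode in ("1SEG", "2SEG"):
        cfg = RunConfig(**{**config.__dict__, "mode": mode})
        mags = []
        for tr in trials:
            res = TrialSimulation(model, tr, cfg).solve()
            mags.append(_resample_stance(res.jrf.magnitude_bw))
            if mode == "2SEG":
                switches.append(res.loads.switch_frame)
        curves[mode] = np.mean(mags, axis=0)
    diff = curves["2SEG"] - curves["1SEG"]
    peak = float(np.max(curves["1SEG"]))
    peak_diff = float(np.max(np.abs(diff)))
    return {
        "stance_pct": np.linspace(0.0, 100.0, 101),
        "difference_bw_pct": diff,
        "jrf_1seg_bw_pct": curves["1SEG"],
        "jrf_2seg_bw_pct": curves["2SEG"],
        "switch_frames": switches,
        "peak_difference_bw": peak_diff / 100.0,
        "peak_jrf_bw": peak / 100.0,
        "difference_pct_of_peak": 100.0 * peak_diff / peak,
    }


def axes_experiment(model: Model, trials: list[GaitTrial],
                    config: RunConfig | None = None):
    """MR-axes vs CGA-axes ankle JRF difference over normalised stance.

    Each frame definition is run with reserves off first; a run that is
    infeasible without reserves is re-run with reserves enabled and flagged
    in the report.  Also reports the MR/CGA frame difference (angle, origin
    offset).
    """
    from .geometry import AnatomicalFrame, frame_difference

    config = config or RunConfig()
    curves = {}
    used_reserves = {}
    for axes in ("MR", "CGA"):
        cfg_off = RunConfig(**{**config.__dict__, "axes": axes,
                               "reserves": "off"})
        mags = []
        flagged = False
        for tr in trials:
            sim = TrialSimulation(model, tr, cfg_off)
            try:
                res = sim.solve()
            except InfeasibleError:
                cfg_on = RunConfig(**{**config.__dict__, "axes": axes,
                                      "reserves": "on"})
                res = TrialSimulation(model, tr, cfg_on).solve()
                flagged = True
            mags.append(_resample_stance(res.jrf.magnitude_bw))
        curves[axes] = np.mean(mags, axis=0)
        used_reserves[axes] = flagged
    out = {
        "stance_pct": np.linspace(0.0, 100.0, 101),
        "difference_bw_pct": curves["CGA"] - curves["MR"],
        "jrf_mr_bw_pct": curves["MR"],
        "jrf_cga_bw_pct": curves["CGA"],
        "used_reserves": used_reserves,
    }
    frames = model.meta.get("ankle_frames")
    if frames:
        fa = AnatomicalFrame(np.asarray(frames["MR"]["origin"]),
                             np.asarray(frames["MR"]["axes"]))
        fb = AnatomicalFrame(np.asarray(frames["CGA"]["origin"]),
                             np.asarray(frames["CGA"]["axes"]))
        ang, off = frame_difference(fa, fb)
        out["frame_angle_deg"] = ang
        out["frame_offset_mm"] = off
    return out
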