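"""Readers/writers for marker trajectories and force-plate data, trial assembly.

Interchange dialects are the plain-text motion-capture formats: TRC for
marker trajectories, MOT/STO for force-plate and result time series.  All
in-memory quantities are SI (metres, newtons, seconds); marker files in mm
are converted on read.  Readers reject malformed files rather than silently
reinterpreting them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaitIOError",
    "MarkerTrajectorySet",
    "ForcePlateSeries",
    "GaitTrial",
    "JointLoadSeries",
    "read_trc",
    "write_trc",
    "read_grf_mot",
    "write_grf_mot",
    "write_sto",
    "read_sto",
    "detect_stance",
    "DEFAULT_CONTACT_THRESHOLD_N",
]

DEFAULT_CONTACT_THRESHOLD_N = 20.0  # conventional force-plate noise floor


class GaitIOError(ValueError):
    """Malformed gait data file or inconsistent trial."""


@dataclass
class MarkerTrajectorySet:
    """Marker trajectories: ``data`` is (frames, markers, 3) in metres.

    ``visible`` masks valid samples; missing samples are NaN in ``data``.
    """

    rate: float
    labels: list[str]
    data: np.ndarray
    visible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise GaitIOError("marker rate must be positive")
        if self.data.ndim != 3 or self.data.shape[1] != len(self.labels) \
                or self.data.shape[2] != 3:
            raise GaitIOError(
                f"marker data shape {self.data.shape} inconsistent with "
                f"{len(self.labels)} labels"
            )
        if self.visible is None:
            self.visible = np.all(np.isfinite(self.data), axis=2)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker {label!r}") from None

    def marker(self, label: str) -> np.ndarray:
        return self.data[:, self.index(label), :]

    def frame_dict(self, i: int) -> dict[str, np.ndarray]:
        """Visible markers of frame ``i`` as name -> 3-vector."""
        return {
            lab: self.data[i, j]
            for j, lab in enumerate(self.labels)
            if self.visible[i, j]
        }


@dataclass
class ForcePlateSeries:
    """Ground reaction data in the model ground frame (Y up), SI units.

    ``cop`` rows are NaN wherever the vertical force is below the contact
    threshold (centre of pressure is undefined without contact).
    """

    rate: float
    force: np.ndarray
    cop: np.ndarray
    free_moment: np.ndarray
    threshold: float = DEFAULT_CONTACT_THRESHOLD_N

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).reshape(-1, 3)
        self.cop = np.asarray(self.cop, dtype=float).reshape(-1, 3)
        self.free_moment = np.asarray(self.free_moment, dtype=float).reshape(-1, 3)
        if self.rate <= 0:
            raise GaitIOError("force rate must be positive")
        n = len(self.force)
        if len(self.cop) != n or len(self.free_moment) != n:
            raise GaitIOError("force/cop/free-moment lengths differ")
        off = self.force[:, 1] < self.threshold
        if np.any(off & np.all(np.isfinite(self.cop), axis=1) &
                  np.any(self.cop != 0.0, axis=1)):
            warnings.warn(
                "COP defined while vertical force below contact threshold; masking",
                stacklevel=2,
            )
        self.cop = self.cop.copy()
        self.cop[off] = np.nan

    @property
    def n_frames(self) -> int:
        return len(self.force)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def resampled(self, rate: float) -> "ForcePlateSeries":
        """Linear-interpolation resample onto a uniform grid at ``rate`` Hz."""
        if rate <= 0:
            raise GaitIOError("target rate must be positive")
        t_old = self.times
        t_new = np.arange(0.0, t_old[-1] + 0.5 / rate, 1.0 / rate)
        t_new = t_new[t_new <= t_old[-1] + 1e-12]

        def interp(arr):
            return np.column_stack(
                [np.interp(t_new, t_old, arr[:, k]) for k in range(3)]
            )

        force = interp(self.force)
        cop = interp(np.nan_to_num(self.cop, nan=0.0))
        with_nan = ~np.all(np.isfinite(self.cop), axis=1)
        cop_bad = np.interp(t_new, t_old, with_nan.astype(float)) > 0.0
        cop[cop_bad] = np.nan
        fm = interp(self.free_moment)
        return ForcePlateSeries(rate, force, cop, fm, self.threshold)


@dataclass
class GaitTrial:
    """A static or walking trial: markers + (for walking) force-plate data."""

    markers: MarkerTrajectorySet
    grf: ForcePlateSeries | None = None
    events: dict[str, float] = field(default_factory=dict)
    kind: str = "walking"

    def __post_init__(self) -> None:
        if self.kind not in ("static", "walking"):
            raise GaitIOError(f"unknown trial kind {self.kind!r}")
        dur = (self.markers.n_frames - 1) / self.markers.rate
        for name, t in self.events.items():
            if not 0.0 <= t <= dur + 1e-9:
                raise GaitIOError(f"event {name!r} at {t} s outside trial [0, {dur}] s")
        if self.kind == "walking" and self.events:
            fs = self.events.get("foot_strike")
            fo = self.events.get("foot_off")
            if fs is not None and fo is not None and not fs < fo:
                raise GaitIOError("stance window [foot_strike, foot_off] is empty")

    @property
    def stance_window(self) -> tuple[float, float] | None:
        if "foot_strike" in self.events and "foot_off" in self.events:
            return self.events["foot_strike"], self.events["foot_off"]
        return None

    def stance_frames(self) -> np.ndarray:
        """Marker-frame indices inside the stance window."""
        w = self.stance_window
        if w is None:
            return np.arange(self.markers.n_frames)
        t = self.markers.times
        return np.nonzero((t >= w[0] - 1e-9) & (t <= w[1] + 1e-9))[0]


@dataclass
class JointLoadSeries:
    """Ankle joint reaction force time series.

    ``jrf`` holds the force components (N) expressed in the chosen ankle
    frame; ``magnitude_bw`` the resultant as a percentage of body weight.
    """

    time: np.ndarray
    jrf: np.ndarray
    magnitude_bw: np.ndarray
    frame_label: str = "MR"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        self.jrf = np.asarray(self.jrf, dtype=float).reshape(-1, 3)
        self.magnitude_bw = np.asarray(self.magnitude_bw, dtype=float).reshape(-1)
        if not (len(self.time) == len(self.jrf) == len(self.magnitude_bw)):
            raise GaitIOError("joint load series lengths differ")
        if np.any(self.magnitude_bw < -1e-9):
            raise GaitIOError("JRF magnitude cannot be negative")


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

_UNIT_TO_M = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


def read_trc(path) -> MarkerTrajectorySet:
    """Read a TRC marker-trajectory file (units converted to metres)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise GaitIOError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        n_frames = int(hdr["NumFrames"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise GaitIOError(f"{path}: malformed TRC header: {exc}") from exc
    if units not in _UNIT_TO_M:
        raise GaitIOError(f"{path}: unknown TRC unit token {units!r}")
    scale = _UNIT_TO_M[units]
    labels = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(labels) != n_markers:
        raise GaitIOError(
            f"{path}: header NumMarkers={n_markers} but {len(labels)} labels"
        )
    data = np.full((n_frames, n_markers, 3), np.nan)
    rows = [ln for ln in lines[5:] if ln.strip()]
    if len(rows) != n_frames:
        raise GaitIOError(f"{path}: header NumFrames={n_frames} but {len(rows)} rows")
    for i, ln in enumerate(rows):
        cells = ln.split("\t")
        expected = 2 + 3 * n_markers
        if len(cells) < expected:
            cells = cells + [""] * (expected - len(cells))
        for j in range(n_markers):
            tri = cells[2 + 3 * j: 5 + 3 * j]
            if all(c.strip() for c in tri):
                data[i, j] = [float(c) for c in tri]
    return MarkerTrajectorySet(rate, labels, data * scale)


def write_trc(mset: MarkerTrajectorySet, path, units: str = "mm") -> None:
    scale = 1.0 / _UNIT_TO_M[units]
    n_frames, n_markers = mset.n_frames, len(mset.labels)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{mset.rate:.6f}\t{mset.rate:.6f}\t{n_frames}\t{n_markers}\t"
                 f"{units}\t{mset.rate:.6f}\t1\t{n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(mset.labels) + "\t\t\n")
        comps = "\t".join(
            f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(n_markers)
        )
        fh.write("\t\t" + comps + "\n")
        for i in range(n_frames):
            cells = [str(i + 1), f"{i / mset.rate:.8f}"]
            for j in range(n_markers):
                if mset.visible[i, j]:
                    cells.extend(f"{v * scale:.10f}" for v in mset.data[i, j])
                else:
                    cells.extend(["", "", ""])
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# MOT / STO
# ---------------------------------------------------------------------------


def _read_sto_table(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise GeneratorExit  # unreachable; placate linters
    cols = lines[end + 1].split("\t")
    cols = [c.strip() for c in cols if c.strip()]
    rows = [ln.split("\t") for ln in lines[end + 2:] if ln.strip()]
    data = np.array([[float(c) for c in r[: len(cols)]] for r in rows])
    if data.shape[1] != len(cols):
        raise GaitIOError(f"{path}: column count mismatch")
    return cols, data


def read_sto(path) -> tuple[list[str], np.ndarray]:
    """Read a MOT/STO table: (column names, data array incl. time column)."""
    try:
        return _read_sto_table(path)
    except (StopIteration, GeneratorExit):
        raise GaitIOError(f"{path}: missing 'endheader' line") from None
    except ValueError as exc:
        raise GaitIOError(f"{path}: malformed numeric data: {exc}") from exc


def write_sto(columns: list[str], data: np.ndarray, path, name: str = "tarsus") -> None:
    """Write a MOT/STO table; first column must be time (s)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(columns):
        raise GaitIOError("data shape inconsistent with column names")
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={data.shape[0]}\n"
                 f"nColumns={data.shape[1]}\ninDegrees=no\nendheader\n")
        fh.write("\t".join(columns) + "\n")
        for row in data:
            fh.write("\t".join(f"{v:.10f}" for v in row) + "\n")


_GRF_TRIPLETS = {
    "force": ("ground_force_vx", "ground_force_vy", "ground_force_vz"),
    "cop": ("ground_force_px", "ground_force_py", "ground_force_pz"),
    "moment": ("ground_torque_x", "ground_torque_y", "ground_torque_z"),
}


def read_grf_mot(path, threshold: float = DEFAULT_CONTACT_THRESHOLD_N,
                 resample_to: float | None = None) -> ForcePlateSeries:
    """Read force-plate data from a MOT/STO file.

    Requires the ``ground_force_v*`` / ``ground_force_p*`` /
    ``ground_torque_*`` column triplets plus ``time``.  Optionally resamples
    (linear) onto ``resample_to`` Hz, e.g. the marker rate.
    """
    cols, data = read_sto(path)
    if "time" not in cols:
        raise GaitIOError(f"{path}: missing time column")
    t = data[:, cols.index("time")]
    if len(t) < 2:
        raise GaitIOError(f"{path}: need >= 2 samples")
    rate = 1.0 / np.mean(np.diff(t))
    triplets = {}
    for key, names in _GRF_TRIPLETS.items():
        try:
            idx = [cols.index(n) for n in names]
        except ValueError:
            raise GaitIOError(f"{path}: missing column triplet {names}") from None
        triplets[key] = data[:, idx]
    series = ForcePlateSeries(rate, triplets["force"], triplets["cop"],
                              triplets["moment"], threshold)
    if resample_to is not None:
        series = series.resampled(resample_to)
    return series


def write_grf_mot(series: ForcePlateSeries, path, name: str = "tarsus-grf") -> None:
    cols = ["time"]
    for names in _GRF_TRIPLETS.values():
        cols.extend(names)
    data = np.column_stack([
        series.times, series.force, np.nan_to_num(series.cop, nan=0.0),
        series.free_moment,
    ])
    write_sto(cols, data, path, name)


# ---------------------------------------------------------------------------
# Stance detection
# ---------------------------------------------------------------------------


def detect_stance(grf: ForcePlateSeries,
                  threshold: float = DEFAULT_CONTACT_THRESHOLD_N) -> dict[str, float]:
    """Foot-strike/foot-off from the vertical force channel.

    Finds the longest contiguous run of samples above ``threshold`` (brief
    supra-threshold noise spikes are therefore ignored) and returns its
    edges as event times.
    """
    fy = grf.force[:, 1]
    above = fy > threshold
    if not np.any(above):
        raise GaitIOError("no samples above the contact threshold")
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(fy) - 1)
    runs = list(zip(starts, ends))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    return {"foot_strike": s / grf.rate, "foot_off": e / grf.rate}
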