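"""Trial kinematics: motion-table I/O, filtering, phase segmentation, time normalization.

A jump-shot trial is represented by the vertical center-of-mass (COM)
trajectory plus sagittal-plane angular velocities of the bilateral hip,
knee and ankle (flexion/dorsiflexion positive, deg/s).  The movement is
split into a Loading phase (initial static position down to the COM
minimum) and a Jump phase (COM minimum up to the COM maximum), and each
phase is resampled onto a uniform 0-100% grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

JOINTS = ("hip", "knee", "ankle")
SIDES = ("L", "R")

#: Shooting-distance conditions (perpendicular distance from the baseline, m).
CONDITIONS = ("P1", "P2", "P3", "P4")
CONDITION_DISTANCES_M = {"P1": 4.6, "P2": 5.8, "P3": 7.0, "P4": 8.325}


class Phase(str, Enum):
    LOADING = "Loading"
    JUMP = "Jump"


class MotionFormatError(ValueError):
    """Raised for malformed motion tables (empty, non-monotone time, ...)."""


class MissingColumnError(KeyError):
    """Raised when a mapped column is absent from a motion table."""


class SegmentationError(ValueError):
    """Raised when the COM trajectory has no loading dip / jump rise."""


@dataclass
class TrialKinematics:
    """One shot trial: time base, COM height and six joint angular velocities."""

    subject_id: str
    condition: str
    trial_index: int
    time: np.ndarray                       # s, strictly increasing, uniform step
    com_vertical: np.ndarray               # m
    joint_velocity: dict[tuple[str, str], np.ndarray]  # (joint, side) -> deg/s
    sample_rate: float                     # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.com_vertical = np.asarray(self.com_vertical, dtype=float)
        n = self.time.size
        if n < 3:
            raise MotionFormatError("trial must contain at least 3 samples")
        if not np.all(np.diff(self.time) > 0):
            raise MotionFormatError("time must be strictly increasing")
        if self.com_vertical.size != n:
            raise MotionFormatError("COM series length differs from time base")
        for key, v in self.joint_velocity.items():
            v = np.asarray(v, dtype=float)
            if v.size != n:
                raise MotionFormatError(f"velocity series {key} length differs from time base")
            self.joint_velocity[key] = v
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open sample window [start, end) of one movement phase."""

    phase: Phase
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 2:
            raise SegmentationError(
                f"{self.phase.value} window [{self.start}, {self.end}) shorter than 2 samples"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FilterConfig:
    """Zero-phase low-pass Butterworth settings.

    ``order`` is the *net* order after the forward-backward pass: a net
    4th-order zero-phase filter is designed as 2nd order and applied twice.
    """

    cutoff_hz: float = 8.0
    order: int = 4
    enabled: bool = True


@dataclass
class NormalizeConfig:
    n_points: int = 101  # 0..100% inclusive


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "time": "time",
    "com_vertical": "com_y",
    **{
        f"{joint}_{side}": f"{joint}_angle_{side.lower()}_vel"
        for joint in JOINTS
        for side in SIDES
    },
}


def read_motion_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    subject_id: str = "unknown",
    condition: str = "P1",
    trial_index: int = 1,
) -> TrialKinematics:
    """Read an OpenSim-style storage/motion table into a :class:`TrialKinematics`.

    The dialect is a whitespace/tab-delimited numeric table whose first column
    is time, optionally preceded by free-form header lines terminated by a
    line reading ``endheader``.  ``column_map`` maps the logical names
    ``time``, ``com_vertical`` and ``{joint}_{side}`` (e.g. ``knee_R``) to the
    column names found in the file; unmapped columns are ignored.
    """
    path = Path(path)
    column_map = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)

    lines = path.read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            start = i + 1
            break
    body = [ln for ln in lines[start:] if ln.strip()]
    if len(body) < 2:
        raise MotionFormatError(f"{path}: no data rows found")
    names = body[0].split()
    try:
        df = pd.DataFrame(
            [[float(x) for x in ln.split()] for ln in body[1:]], columns=names
        )
    except ValueError as exc:
        raise MotionFormatError(f"{path}: non-numeric data row ({exc})") from exc
    if df.empty:
        raise MotionFormatError(f"{path}: empty table")

    def col(logical: str) -> np.ndarray:
        name = column_map[logical]
        if name not in df.columns:
            raise MissingColumnError(
                f"{path}: mapped column {name!r} (for {logical!r}) not in table"
            )
        return df[name].to_numpy(dtype=float)

    time = col("time")
    if not np.all(np.diff(time) > 0):
        raise MotionFormatError(f"{path}: time column is not strictly increasing")
    dt = np.diff(time)
    sample_rate = 1.0 / float(np.mean(dt))
    velocities = {
        (joint, side): col(f"{joint}_{side}") for joint in JOINTS for side in SIDES
    }
    return TrialKinematics(
        subject_id=subject_id,
        condition=condition,
        trial_index=trial_index,
        time=time,
        com_vertical=col("com_vertical"),
        joint_velocity=velocities,
        sample_rate=sample_rate,
    )


def butterworth_zero_phase(
    series: np.ndarray, sample_rate: float, cutoff: float = 8.0, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``order`` is the net order: the underlying design uses ``order // 2``
    poles and the forward-backward pass doubles it, giving zero phase lag.
    """
    series = np.asarray(series, dtype=float)
    nyquist = sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    if order < 2 or order % 2:
        raise ValueError("net filter order must be an even integer >= 2")
    b, a = butter(order // 2, cutoff / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if series.size <= padlen:
        raise ValueError(
            f"series of length {series.size} too short for filtering (needs > {padlen})"
        )
    return filtfilt(b, a, series)


def filter_trial(trial: TrialKinematics, config: FilterConfig | None = None) -> TrialKinematics:
    """Return a copy of ``trial`` with COM and all velocities low-pass filtered."""
    config = config or FilterConfig()
    if not config.enabled:
        return trial

    def f(x: np.ndarray) -> np.ndarray:
        return butterworth_zero_phase(x, trial.sample_rate, config.cutoff_hz, config.order)

    return TrialKinematics(
        subject_id=trial.subject_id,
        condition=trial.condition,
        trial_index=trial.trial_index,
        time=trial.time.copy(),
        com_vertical=f(trial.com_vertical),
        joint_velocity={k: f(v) for k, v in trial.joint_velocity.items()},
        sample_rate=trial.sample_rate,
    )


def segment_phases(
    com_vertical: np.ndarray, *, motion_start: int = 0
) -> tuple[PhaseWindow, PhaseWindow]:
    """Split a COM height series into Loading and Jump windows.

    Loading runs from ``motion_start`` (default: the first sample) to the COM
    global minimum; Jump runs from the minimum to the maximum of the
    post-minimum segment.  Ties in either extremum resolve to the earliest
    index.
    """
    com = np.asarray(com_vertical, dtype=float)
    if com.size < 4:
        raise SegmentationError("COM series too short to segment")
    seg = com[motion_start:]
    i_min = motion_start + int(np.argmin(seg))
    if i_min <= motion_start or i_min >= com.size - 1:
        raise SegmentationError("COM minimum is not interior: no loading dip found")
    i_max = i_min + int(np.argmax(com[i_min:]))
    if i_max <= i_min:
        raise SegmentationError("COM maximum does not follow the minimum")
    loading = PhaseWindow(Phase.LOADING, motion_start, i_min)
    jump = PhaseWindow(Phase.JUMP, i_min, i_max)
    return loading, jump


def detect_motion_onset(
    com_vertical: np.ndarray, sample_rate: float, threshold: float = 0.02
) -> int:
    """First sample where |COM vertical velocity| exceeds ``threshold`` (m/s).

    Optional helper for trials with a long static hold; segmentation defaults
    to starting at sample 0.
    """
    com = np.asarray(com_vertical, dtype=float)
    vel = np.gradient(com) * sample_rate
    above = np.nonzero(np.abs(vel) > threshold)[0]
    return int(above[0]) if above.size else 0


def time_normalize(window_values: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Resample a phase window onto a uniform 0-100% grid by linear interpolation.

    Endpoints are preserved exactly; the input is assumed uniformly sampled
    within the window.
    """
    values = np.asarray(window_values, dtype=float)
    if values.size < 2:
        raise ValueError("phase window must contain at least 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    src = np.linspace(0.0, 100.0, values.size)
    dst = np.linspace(0.0, 100.0, n_points)
    return np.interp(dst, src, values)


@dataclass
class NormalizedPhaseSeries:
    """Angular velocities of one phase resampled onto the percent grid.

    ``zero_mask`` flags grid points whose interpolation support includes a
    sample with exactly zero measured (pre-filter) velocity for that joint:
    the direction of such samples carries no information.
    """

    phase: Phase
    percent: np.ndarray
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    zero_mask: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def normalize_phases(
    trial: TrialKinematics,
    windows: tuple[PhaseWindow, PhaseWindow],
    config: NormalizeConfig | None = None,
    raw_trial: TrialKinematics | None = None,
) -> list[NormalizedPhaseSeries]:
    """Time-normalize every joint velocity series within each phase window.

    When ``raw_trial`` (the unfiltered kinematics) is given, grid points
    interpolating from samples whose raw velocity is exactly zero are
    flagged in ``zero_mask``, so downstream coupling-angle means can exclude
    motionless samples whose post-filter direction is pure numerical
    ringing.
    """
    config = config or NormalizeConfig()
    out = []
    for w in windows:
        percent = np.linspace(0.0, 100.0, config.n_points)
        values = {
            key: time_normalize(v[w.start : w.end], config.n_points)
            for key, v in trial.joint_velocity.items()
        }
        zero_mask = {}
        for key, v in trial.joint_velocity.items():
            raw = raw_trial.joint_velocity[key] if raw_trial is not None else v
            indicator = (raw[w.start : w.end] == 0.0).astype(float)
            zero_mask[key] = time_normalize(indicator, config.n_points) > 0.0
        out.append(
            NormalizedPhaseSeries(
                phase=w.phase, percent=percent, values=values, zero_mask=zero_mask
            )
        )
    return out
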