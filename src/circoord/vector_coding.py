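"""Vector coding of paired joint angular velocities.

The coupling angle γ(t) is the polar direction of the point
(ω_distal, ω_proximal) in the velocity-velocity plane: the distal joint's
angular velocity on the abscissa and the proximal joint's on the ordinate,
wrapped to [0°, 360°).  γ near an abscissa axis (0°/180°) means the motion
is dominated by the distal joint, near an ordinate axis (90°/270°) by the
proximal joint; the first and third quadrant halves are in-phase (both
joints rotating in the same direction), the others anti-phase.

Per-trial mean coupling angles are circular means (mean sine and cosine),
the dependent variable of the downstream circular mixed-effects model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .kinematics import (
    FilterConfig,
    NormalizeConfig,
    Phase,
    TrialKinematics,
    filter_trial,
    normalize_phases,
    segment_phases,
)


class CoordinationPattern(str, Enum):
    IN_PHASE_DISTAL = "InPhaseDistal"
    IN_PHASE_PROXIMAL = "InPhaseProximal"
    ANTI_PHASE_DISTAL = "AntiPhaseDistal"
    ANTI_PHASE_PROXIMAL = "AntiPhaseProximal"


@dataclass(frozen=True)
class Coupling:
    """A proximal-distal joint pair on one side, e.g. Hip-Knee right."""

    proximal: str
    distal: str
    side: str

    _ORDER = ("hip", "knee", "ankle")

    def __post_init__(self) -> None:
        if self.proximal not in self._ORDER or self.distal not in self._ORDER:
            raise ValueError(f"unknown joint in coupling {self.proximal}-{self.distal}")
        if self._ORDER.index(self.proximal) >= self._ORDER.index(self.distal):
            raise ValueError(
                f"proximal joint {self.proximal!r} must be above distal {self.distal!r}"
            )
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def label(self) -> str:
        return f"{self.side}_{self.proximal.capitalize()}-{self.distal.capitalize()}"


#: The six study couplings: {Hip-Knee, Hip-Ankle, Knee-Ankle} x {L, R}.
STUDY_COUPLINGS: tuple[Coupling, ...] = tuple(
    Coupling(p, d, s)
    for s in ("R", "L")
    for (p, d) in (("hip", "knee"), ("hip", "ankle"), ("knee", "ankle"))
)


def coupling_angle(
    omega_proximal: np.ndarray, omega_distal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling angle γ ∈ [0°, 360°) of paired angular velocities.

    Returns ``(gamma_deg, undefined_mask)``; γ is the full-quadrant
    arctangent of proximal over distal velocity, undefined (masked) where
    both velocities are zero.  Scalar inputs return scalar-shaped arrays.
    """
    wy = np.asarray(omega_proximal, dtype=float)
    wx = np.asarray(omega_distal, dtype=float)
    if not (np.all(np.isfinite(wy)) and np.all(np.isfinite(wx))):
        raise ValueError("angular velocities must be finite")
    gamma = np.degrees(np.arctan2(wy, wx)) % 360.0
    undefined = (wx == 0.0) & (wy == 0.0)
    gamma = np.where(undefined, np.nan, gamma)
    return gamma, undefined


# Half-open 45-degree bins on [0, 360): a total, non-overlapping partition.
# The printed bin table of the source methodology leaves 45/135/225/315
# unassigned and double-assigns 90/270; [lo, hi) is adopted uniformly.
_PATTERN_BY_OCTANT = (
    CoordinationPattern.IN_PHASE_DISTAL,      # [0, 45)
    CoordinationPattern.IN_PHASE_PROXIMAL,    # [45, 90)
    CoordinationPattern.ANTI_PHASE_DISTAL,    # [90, 135)
    CoordinationPattern.ANTI_PHASE_PROXIMAL,  # [135, 180)
)


def classify_pattern(gamma: float) -> CoordinationPattern:
    """Map a coupling angle to one of the four coordination patterns.

    Bins are half-open 45° sectors: [0,45)∪[180,225) in-phase distal,
    [45,90)∪[225,270) in-phase proximal, [90,135)∪[270,315) anti-phase
    distal, [135,180)∪[315,360) anti-phase proximal — except that the pure
    proximal axes 90° and 270° (distal joint motionless) belong to in-phase
    proximal dominancy, keeping every axis classified by the joint that is
    actually moving.
    """
    g = float(gamma)
    if not (0.0 <= g < 360.0):
        raise ValueError(f"gamma {g} outside [0, 360); wrap before classifying")
    if g in (90.0, 270.0):
        return CoordinationPattern.IN_PHASE_PROXIMAL
    return _PATTERN_BY_OCTANT[int(g // 45.0) % 4]


def dominancy_percent(gamma: float) -> tuple[float, float]:
    """Distal/proximal dominancy percentages of a coupling angle.

    Linear in angular distance from the nearest distal axis (0°/180°):
    100% distal on those axes, 100% proximal on 90°/270°, 50/50 on the
    quadrant diagonals.  The two percentages always sum to 100.
    """
    g = float(gamma)
    if not (0.0 <= g < 360.0):
        raise ValueError(f"gamma {g} outside [0, 360)")
    theta = g % 180.0
    dist_to_distal_axis = min(theta, 180.0 - theta)  # in [0, 90]
    distal = 100.0 * (1.0 - dist_to_distal_axis / 90.0)
    return distal, 100.0 - distal


def pattern_frequencies(
    gamma: np.ndarray, mask: np.ndarray | None = None
) -> dict[CoordinationPattern, float]:
    """Fraction of defined samples falling in each coordination pattern."""
    gamma = np.asarray(gamma, dtype=float)
    defined = ~np.asarray(mask, bool) if mask is not None else ~np.isnan(gamma)
    g = gamma[defined]
    if g.size == 0:
        return {p: np.nan for p in CoordinationPattern}
    octant = (g // 45.0).astype(int) % 4
    octant[(g == 90.0) | (g == 270.0)] = 1  # pure proximal axes
    return {
        p: float(np.mean(octant == i)) for i, p in enumerate(_PATTERN_BY_OCTANT)
    }


class UndefinedMeanError(ValueError):
    """Circular mean has zero resultant (e.g. antipodal angles) or no samples."""


def mean_angle_from_components(x_bar: float, y_bar: float) -> float:
    """Mean direction in [0°, 360°) from mean cosine and sine, by quadrant cases.

    Piecewise mapping of the principal arctangent: atan(ȳ/x̄) in the first
    quadrant, +180° when x̄ < 0, +360° in the fourth quadrant, 90°/270° on
    the ordinate axis; undefined (raises) when x̄ = ȳ = 0.
    """
    if x_bar == 0.0 and y_bar == 0.0:
        raise UndefinedMeanError("zero resultant: mean direction undefined")
    if x_bar == 0.0:
        return 90.0 if y_bar > 0 else 270.0
    base = float(np.degrees(np.arctan(y_bar / x_bar)))
    if x_bar < 0:
        return (base + 180.0) % 360.0
    if y_bar < 0:
        return (base + 360.0) % 360.0
    return base % 360.0


def circular_mean(
    gammas: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Circular mean direction and resultant length of angles in degrees.

    The mean is the direction of the average (cos γ, sin γ) vector, mapped
    to [0°, 360°); the resultant length R ∈ [0, 1] measures concentration.
    Masked (undefined) samples are excluded.  Raises
    :class:`UndefinedMeanError` when no samples remain or the resultant is
    numerically zero (no mean direction exists).
    """
    g = np.asarray(gammas, dtype=float)
    if mask is not None:
        g = g[~np.asarray(mask, dtype=bool)]
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise UndefinedMeanError("no defined coupling-angle samples")
    rad = np.radians(g)
    x_bar = float(np.mean(np.cos(rad)))
    y_bar = float(np.mean(np.sin(rad)))
    resultant = float(np.hypot(x_bar, y_bar))
    if resultant < 1e-12:
        raise UndefinedMeanError("zero resultant: mean direction undefined")
    return mean_angle_from_components(x_bar, y_bar), resultant


@dataclass(frozen=True)
class MeanAngleObservation:
    """One (subject, condition, phase, coupling, trial) mean coupling angle."""

    subject_id: str
    condition: str
    phase: Phase
    coupling: Coupling
    trial_index: int
    mean_angle_deg: float
    resultant_length: float

    @property
    def mean_angle_rad(self) -> float:
        return float(np.radians(self.mean_angle_deg))


def trial_coupling_series(
    velocities: dict[tuple[str, str], np.ndarray],
    coupling: Coupling,
    zero_mask: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling-angle series for one coupling from per-joint velocity series.

    ``zero_mask`` optionally flags per-joint grid points with no measured
    motion (see :func:`circoord.kinematics.normalize_phases`); a sample is
    undefined when both joints are flagged, in addition to the exact
    both-zero case.
    """
    wy = velocities[(coupling.proximal, coupling.side)]
    wx = velocities[(coupling.distal, coupling.side)]
    gamma, undefined = coupling_angle(wy, wx)
    if zero_mask is not None:
        motionless = (
            zero_mask[(coupling.proximal, coupling.side)]
            & zero_mask[(coupling.distal, coupling.side)]
        )
        undefined = undefined | motionless
        gamma = np.where(motionless, np.nan, gamma)
    return gamma, undefined


def trial_mean_angles(
    trial: TrialKinematics,
    filter_config: FilterConfig | None = None,
    normalize_config: NormalizeConfig | None = None,
    couplings: tuple[Coupling, ...] = STUDY_COUPLINGS,
) -> list[MeanAngleObservation]:
    """Full per-trial pipeline: filter, segment, normalize, vector-code, average.

    Emits one observation per coupling × phase (12 per trial for the six
    study couplings).
    """
    filtered = filter_trial(trial, filter_config)
    windows = segment_phases(filtered.com_vertical)
    phases = normalize_phases(filtered, windows, normalize_config, raw_trial=trial)
    out: list[MeanAngleObservation] = []
    for phase_series in phases:
        for coupling in couplings:
            gamma, mask = trial_coupling_series(
                phase_series.values, coupling, phase_series.zero_mask
            )
            mean_deg, resultant = circular_mean(gamma, mask)
            out.append(
                MeanAngleObservation(
                    subject_id=trial.subject_id,
                    condition=trial.condition,
                    phase=phase_series.phase,
                    coupling=coupling,
                    trial_index=trial.trial_index,
                    mean_angle_deg=mean_deg,
                    resultant_length=resultant,
                )
            )
    return out


def observations_to_frame(observations: list[MeanAngleObservation]) -> pd.DataFrame:
    """Tabulate observations: the CSV contract consumed by the model module."""
    return pd.DataFrame(
        {
            "subject": [o.subject_id for o in observations],
            "condition": [o.condition for o in observations],
            "phase": [o.phase.value for o in observations],
            "coupling": [o.coupling.label for o in observations],
            "side": [o.coupling.side for o in observations],
            "trial": [o.trial_index for o in observations],
            "mean_deg": [o.mean_angle_deg for o in observations],
            "mean_rad": [o.mean_angle_rad for o in observations],
            "resultant_length": [o.resultant_length for o in observations],
        }
    )


def condition_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per coupling × condition × phase circular mean and circular SD of trial means.

    The dispersion column is the circular standard deviation
    ``sqrt(-2 ln R)`` in degrees across trial means, computed over subjects
    and trials.
    """
    rows = []
    for (coupling, condition, phase), grp in frame.groupby(
        ["coupling", "condition", "phase"], sort=True
    ):
        mean_deg, resultant = circular_mean(grp["mean_deg"].to_numpy())
        circ_sd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(resultant)))))
        rows.append(
            {
                "coupling": coupling,
                "condition": condition,
                "phase": phase,
                "n": len(grp),
                "circular_mean_deg": mean_deg,
                "circular_sd_deg": circ_sd,
            }
        )
    return pd.DataFrame(rows)
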