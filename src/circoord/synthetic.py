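"""Synthetic jump-shot kinematics and mean-angle tables with known ground truth.

Two generative levels are provided:

* :func:`generate_trial` builds full trial kinematics — a dip-then-rise COM
  trajectory and six joint angular-velocity curves whose pointwise coupling
  angles equal prescribed per-cell targets — so the whole filtering /
  segmentation / vector-coding pipeline can be tested against analytic
  truth.
* :func:`generate_angle_table` draws mean-angle observations directly from
  the projected-normal mixed model, the generative twin of the inference
  module, for parameter-recovery and calibration studies.

Within a phase the three joint velocities of one side are a smooth positive
envelope times a fixed direction vector (hip, knee, ankle), which makes
every coupling angle constant over the phase.  Because the three couplings
share three joints, only the Hip-Knee and Knee-Ankle targets are free; the
Hip-Ankle angle is implied by the geometry and an explicitly supplied
inconsistent value raises :class:`ScenarioError`.  The envelope is zero in
a short buffer on both sides of the Loading/Jump boundary and the COM
curvature is matched across the boundary, so the low-pass filter neither
moves the segmentation indices nor mixes the two phases' velocity
directions into each other's windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import CONDITIONS, JOINTS, SIDES, Phase, TrialKinematics
from .vector_coding import MeanAngleObservation  # noqa: F401  (re-export convenience)


class ScenarioError(ValueError):
    """Raised for inconsistent or degenerate scenario parameters."""


# Per-cell target coupling angles (deg) for the generator defaults,
# matching the study's reported per-cell circular means; Hip-Ankle is
# implied by the Hip-Knee / Knee-Ankle geometry.
_DEFAULT_TARGETS: dict[tuple[str, str, str], dict[str, float]] = {}
_HK_LOADING = {"R": (23.46, 22.72, 22.35, 22.10), "L": (23.39, 23.07, 23.13, 23.42)}
_KA_LOADING = {"R": (70.02, 68.97, 69.66, 65.78), "L": (65.01, 66.49, 66.63, 66.20)}
_HK_JUMP = {"R": (214.73, 209.70, 207.84, 202.16), "L": (208.65, 204.40, 202.58, 200.48)}
_KA_JUMP = {"R": (232.41, 232.86, 234.10, 235.02), "L": (238.59, 234.07, 233.25, 235.61)}
for _i, _cond in enumerate(CONDITIONS):
    for _side in SIDES:
        _DEFAULT_TARGETS[(_cond, Phase.LOADING.value, _side)] = {
            "hip_knee": _HK_LOADING[_side][_i],
            "knee_ankle": _KA_LOADING[_side][_i],
        }
        _DEFAULT_TARGETS[(_cond, Phase.JUMP.value, _side)] = {
            "hip_knee": _HK_JUMP[_side][_i],
            "knee_ankle": _KA_JUMP[_side][_i],
        }


def joint_direction(
    hip_knee_deg: float,
    knee_ankle_deg: float,
    hip_ankle_deg: float | None = None,
    tol: float = 0.5,
) -> np.ndarray:
    """Unit (hip, knee, ankle) velocity direction realising two coupling targets.

    The Knee-Ankle target fixes (knee, ankle) up to positive scale and the
    Hip-Knee target then fixes hip.  Raises :class:`ScenarioError` when no
    positive-scale solution exists or when an explicit Hip-Ankle target
    disagrees with the implied one by more than ``tol`` degrees.
    """
    g_ka = np.radians(knee_ankle_deg)
    g_hk = np.radians(hip_knee_deg)
    knee, ankle = np.sin(g_ka), np.cos(g_ka)
    cos_hk, sin_hk = np.cos(g_hk), np.sin(g_hk)
    if abs(knee) < 1e-12:
        if abs(cos_hk) > 1e-12:
            raise ScenarioError(
                "knee velocity is zero under the Knee-Ankle target but the "
                "Hip-Knee target requires a nonzero knee component"
            )
        hip = float(np.sign(sin_hk))
    else:
        if np.sign(knee) != np.sign(cos_hk):
            raise ScenarioError(
                f"targets Hip-Knee={hip_knee_deg}°, Knee-Ankle={knee_ankle_deg}° "
                "admit no common joint velocity direction (sign conflict)"
            )
        hip = float(knee / cos_hk * sin_hk)
    vec = np.array([hip, knee, ankle])
    implied_ha = float(np.degrees(np.arctan2(hip, ankle)) % 360.0)
    if hip_ankle_deg is not None:
        d = abs((implied_ha - hip_ankle_deg + 180.0) % 360.0 - 180.0)
        if d > tol:
            raise ScenarioError(
                f"explicit Hip-Ankle target {hip_ankle_deg}° inconsistent with "
                f"implied {implied_ha:.2f}° (|Δ| = {d:.2f}° > {tol}°)"
            )
    return vec / np.linalg.norm(vec)


@dataclass
class KinematicScenario:
    """Study-shaped synthetic kinematics: 14 subjects × 4 distances × 4 trials.

    ``cell_targets`` maps (condition, phase, side) to target coupling angles
    in degrees with keys ``hip_knee``, ``knee_ankle`` and optionally
    ``hip_ankle``.  ``subject_spread_deg`` is the SD of a per-subject
    angular offset added to every target; ``noise_rms`` is additive white
    noise on the velocity series (deg/s), applied before filtering.
    """

    n_subjects: int = 14
    trials_per_condition: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    sample_rate: float = 60.0
    static_duration: float = 0.10   # brief quiet stance before the dip
    loading_duration: float = 0.45
    jump_duration: float = 0.65
    landing_duration: float = 0.15
    boundary_buffer: float = 0.05   # zero-velocity reversal zone each side of the COM minimum, s
    com_standing: float = 0.95      # m
    com_dip: float = 0.30           # m descent during loading
    loading_amplitude: float = 300.0  # deg/s envelope peak
    jump_amplitude: float = 420.0
    cell_targets: dict[tuple[str, str, str], dict[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    subject_spread_deg: float = 3.0
    noise_rms: float = 8.0          # deg/s
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (
            self.static_duration,
            self.loading_duration,
            self.jump_duration,
            self.landing_duration,
        ):
            if d <= 0:
                raise ScenarioError("all durations must be positive")
        for key, targets in self.cell_targets.items():
            for name, v in targets.items():
                if not (0.0 <= v < 360.0):
                    raise ScenarioError(f"target {name}={v} for cell {key} outside [0, 360)")

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def subject_offset(self, subject_index: int) -> float:
        """Reproducible per-subject angular offset (deg), N(0, spread²)."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 7919, subject_index])
        )
        return float(rng.normal(0.0, self.subject_spread_deg))


def _envelope(n: int, active_start: int, active_end: int) -> np.ndarray:
    """sin² bump over [active_start, active_end), zero elsewhere."""
    e = np.zeros(n)
    span = active_end - active_start
    if span < 2:
        raise ScenarioError("active envelope span too short")
    tau = np.arange(span) / span
    e[active_start:active_end] = np.sin(np.pi * tau) ** 2
    return e


def generate_trial(
    scenario: KinematicScenario,
    subject_index: int,
    condition: str,
    trial_index: int,
) -> TrialKinematics:
    """Generate one synthetic trial with analytically known phase structure.

    The COM minimum falls exactly at the end of the loading segment and the
    maximum at the end of the jump segment; the rise and landing curvatures
    are matched to the descent at those junctions so zero-phase filtering
    preserves both extremum indices.
    """
    if condition not in scenario.conditions:
        raise ScenarioError(f"unknown condition {condition!r}")
    fs = scenario.sample_rate
    n_s = round(scenario.static_duration * fs)
    n_l = round(scenario.loading_duration * fs)
    n_j = round(scenario.jump_duration * fs)
    n_land = round(scenario.landing_duration * fs)
    n_buf = round(scenario.boundary_buffer * fs)
    if n_land >= n_j:
        raise ScenarioError("landing must be shorter than the jump rise")
    i_min = n_s + n_l
    i_max = i_min + n_j
    n = i_max + n_land + 1
    t = np.arange(n) / fs

    dip = scenario.com_dip
    # apex chosen so descent and rise curvatures match at the COM minimum
    rise = dip * (n_j / n_l) ** 2
    y = np.empty(n)
    y[: n_s + 1] = scenario.com_standing
    j = np.arange(1, n_l + 1)
    y[n_s + 1 : i_min + 1] = scenario.com_standing - dip / 2 * (1 - np.cos(np.pi * j / n_l))
    j = np.arange(1, n_j + 1)
    y_min = scenario.com_standing - dip
    y[i_min + 1 : i_max + 1] = y_min + rise / 2 * (1 - np.cos(np.pi * j / n_j))
    j = np.arange(1, n - i_max)
    y_max = y_min + rise
    y[i_max + 1 :] = y_max - rise / 2 * (1 - np.cos(np.pi * j / n_j))

    offset = scenario.subject_offset(subject_index)
    cond_idx = scenario.conditions.index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, subject_index, cond_idx, trial_index])
    )

    env = {
        Phase.LOADING: scenario.loading_amplitude
        * _envelope(n, n_s, i_min - n_buf),
        Phase.JUMP: scenario.jump_amplitude
        * _envelope(n, i_min + n_buf, i_max),
    }
    velocity: dict[tuple[str, str], np.ndarray] = {
        (joint, side): np.zeros(n) for joint in JOINTS for side in SIDES
    }
    for side in SIDES:
        for phase in (Phase.LOADING, Phase.JUMP):
            targets = scenario.cell_targets[(condition, phase.value, side)]
            vec = joint_direction(
                (targets["hip_knee"] + offset) % 360.0,
                (targets["knee_ankle"] + offset) % 360.0,
                (targets["hip_ankle"] + offset) % 360.0
                if "hip_ankle" in targets
                else None,
            )
            for joint, comp in zip(JOINTS, vec):
                velocity[(joint, side)] += env[phase] * comp
    if scenario.noise_rms > 0:
        for key in velocity:
            velocity[key] = velocity[key] + rng.normal(0.0, scenario.noise_rms, n)

    return TrialKinematics(
        subject_id=scenario.subject_ids()[subject_index],
        condition=condition,
        trial_index=trial_index,
        time=t,
        com_vertical=y,
        joint_velocity=velocity,
        sample_rate=fs,
    )


def generate_dataset(scenario: KinematicScenario) -> list[TrialKinematics]:
    """All trials of the scenario: subjects × conditions × trials."""
    return [
        generate_trial(scenario, s, c, k)
        for s in range(scenario.n_subjects)
        for c in scenario.conditions
        for k in range(1, scenario.trials_per_condition + 1)
    ]


# ---------------------------------------------------------------------------
# angle-level generator (generative twin of the circular mixed model)


@dataclass
class AngleScenario:
    """Mean-angle observations drawn from the projected-normal mixed model.

    ``cell_angles_deg`` maps (condition, phase) to the population-level mean
    angle; ``latent_norm`` is the length of the latent bivariate mean (the
    concentration: the angular SD is ≈ 1/latent_norm radians); the subject
    intercept is bivariate normal on the latent components with SD chosen so
    the induced angular spread is ``subject_spread_deg``.
    """

    cell_angles_deg: dict[tuple[str, str], float]
    n_subjects: int = 14
    trials_per_cell: int = 4
    latent_norm: float = 15.0
    subject_spread_deg: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        expected = {(c, p.value) for c in CONDITIONS for p in (Phase.LOADING, Phase.JUMP)}
        if set(self.cell_angles_deg) != expected:
            raise ScenarioError("cell_angles_deg must cover all 8 Condition × Phase cells")
        if self.latent_norm <= 0:
            raise ScenarioError("latent mean norm must be positive (angle undefined at 0)")


def uniform_angle_scenario(angle_deg: float = 40.0, seed: int = 0, **kw) -> AngleScenario:
    """All-cells-equal scenario: the null model for calibration studies."""
    cells = {
        (c, p.value): angle_deg for c in CONDITIONS for p in (Phase.LOADING, Phase.JUMP)
    }
    return AngleScenario(cell_angles_deg=cells, seed=seed, **kw)


def effect_angle_scenario(
    base_deg: float = 30.0,
    condition_effects: tuple[float, float, float, float] = (0.0, 6.0, 12.0, 20.0),
    phase_effect: float = 15.0,
    interaction_effects: tuple[float, float, float, float] = (0.0, -6.0, -9.0, -12.0),
    seed: int = 0,
    **kw,
) -> AngleScenario:
    """Scenario with known condition, phase and interaction effects (degrees).

    Loading cell c = base + condition_effects[c]; Jump cell c adds the phase
    effect and the interaction term, so the generating interaction contrast
    of condition c against P1 equals ``interaction_effects[c]``.
    """
    cells = {}
    for i, c in enumerate(CONDITIONS):
        loading = (base_deg + condition_effects[i]) % 360.0
        jump = (loading + phase_effect + interaction_effects[i]) % 360.0
        cells[(c, Phase.LOADING.value)] = loading
        cells[(c, Phase.JUMP.value)] = jump
    return AngleScenario(cell_angles_deg=cells, seed=seed, **kw)


def generate_angle_table(scenario: AngleScenario) -> pd.DataFrame:
    """Draw a mean-angle observation table from the scenario.

    Output follows the vector-coding CSV contract (columns ``subject``,
    ``condition``, ``phase``, ``trial``, ``mean_deg``, ``mean_rad``) and can
    be fed directly to the model module.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 104729]))
    sd_lat = scenario.latent_norm * np.tan(np.radians(scenario.subject_spread_deg))
    subjects = [f"S{i + 1:02d}" for i in range(scenario.n_subjects)]
    b = rng.normal(0.0, sd_lat, size=(scenario.n_subjects, 2))
    rows = []
    for si, subj in enumerate(subjects):
        for (cond, phase), angle in sorted(scenario.cell_angles_deg.items()):
            mu = scenario.latent_norm * np.array(
                [np.cos(np.radians(angle)), np.sin(np.radians(angle))]
            )
            for trial in range(1, scenario.trials_per_cell + 1):
                latent = mu + b[si] + rng.standard_normal(2)
                theta = float(np.arctan2(latent[1], latent[0]) % (2 * np.pi))
                rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "phase": phase,
                        "coupling": "synthetic",
                        "side": "R",
                        "trial": trial,
                        "mean_deg": float(np.degrees(theta)),
                        "mean_rad": theta,
                        "resultant_length": 1.0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motion-table writer (inverse of kinematics.read_motion_table)


def write_motion_table(trial: TrialKinematics, path: str | Path) -> Path:
    """Write a trial in the OpenSim-style storage dialect.

    ``read_motion_table(write_motion_table(x))`` reproduces the trial to
    numeric precision.
    """
    path = Path(path)
    cols = ["time", "com_y"] + [
        f"{joint}_angle_{side.lower()}_vel" for joint in JOINTS for side in SIDES
    ]
    data = np.column_stack(
        [trial.time, trial.com_vertical]
        + [trial.joint_velocity[(joint, side)] for joint in JOINTS for side in SIDES]
    )
    with path.open("w") as fh:
        fh.write(f"{path.stem}\nversion=1\n")
        fh.write(f"nRows={data.shape[0]}\nnColumns={data.shape[1]}\n")
        fh.write("inDegrees=yes\nendheader\n")
        fh.write("\t".join(cols) + "\n")
        for row in data:
            fh.write("\t".join(f"{v:.10f}" for v in row) + "\n")
    return path
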