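"""Bayesian projected-normal circular mixed-effects model.

The mean coupling angle θ of a trial is modelled as the direction of a
latent bivariate normal vector with identity covariance,

    y = r (cos θ, sin θ),     y ~ N2(μ, I2),
    μ = (xᵀβ_I + u_I[subject],  xᵀβ_II + u_II[subject]),

where x is the fixed-effects design row of the trial's shooting-distance
condition and movement phase (full factorial, reference cell P1/Loading,
8 columns per component) and u_I, u_II are subject random intercepts on
the two latent components.  Integrating the latent length r out of the
bivariate normal yields the projected normal distribution on the circle.

Sampling follows the standard data-augmentation Gibbs scheme for this
model: conditional on the latent lengths r the model is a pair of
independent Gaussian linear mixed models with unit residual variance
(conjugate updates for coefficients, random intercepts and their
variance), and conditional on everything else each rᵢ has density
∝ r·exp(−(r−tᵢ)²/2) on r>0 with tᵢ = uᵢᵀμᵢ, sampled by a slice step with
an exact inverse-CDF draw from the ∝ r segment.

Inference on effects works on the per-draw population-level marginal
predicted angle of each design cell (fixed effects only): contrasts are
shortest circular differences of cell angles, summarised by the circular
mean of per-draw differences and the 95% highest-posterior-density (HPD)
interval; an effect is flagged when the HPD excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinematics import CONDITIONS, Phase
from .vector_coding import mean_angle_from_components

DESIGN_COLUMNS = (
    "intercept",
    "P2",
    "P3",
    "P4",
    "Jump",
    "P2:Jump",
    "P3:Jump",
    "P4:Jump",
)


class DesignError(ValueError):
    """Raised when the observation table cannot support the factorial design."""


@dataclass
class ModelSpec:
    """Fixed Condition(4) × Phase(2) design with a subject random intercept.

    ``prior_sd`` is the standard deviation of the zero-mean normal prior on
    every fixed-effect coefficient (diffuse by default); the random-intercept
    variance on each latent component gets an inverse-gamma(a, b) prior.
    ``design='intercept_only'`` drops all condition/phase terms (a single
    mean direction), mainly for validation against numerical posteriors.
    """

    prior_sd: float = 100.0
    random_intercept: bool = True
    ig_shape: float = 0.1
    ig_scale: float = 0.1
    design: str = "full_factorial"

    def __post_init__(self) -> None:
        if self.design not in ("full_factorial", "intercept_only"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class SamplerConfig:
    """MCMC run lengths.  ``iterations`` counts post-burn-in sweeps per chain."""

    n_chains: int = 4
    iterations: int = 35_000
    burn_in: int = 13_000
    thin: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.iterations, self.burn_in, self.thin) < 1:
            raise ValueError("all sampler settings must be positive")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin


def reduced_sampler(seed: int = 0) -> SamplerConfig:
    """A short sampler (4 chains × 2,000 retained draws) for simulations."""
    return SamplerConfig(n_chains=4, iterations=2_000, burn_in=500, thin=1, seed=seed)


def cell_design_row(condition: str, phase: Phase | str) -> np.ndarray:
    """Fixed-effects design row of one Condition × Phase cell."""
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    phase = Phase(phase)
    x = np.zeros(len(DESIGN_COLUMNS))
    x[0] = 1.0
    if condition != "P1":
        x[CONDITIONS.index(condition)] = 1.0
    if phase is Phase.JUMP:
        x[4] = 1.0
        if condition != "P1":
            x[4 + CONDITIONS.index(condition)] = 1.0
    return x


@dataclass
class PosteriorDraws:
    """Retained MCMC draws and convergence diagnostics of one model fit.

    Coefficient arrays are shaped (chains, draws, 8) for the cosine (I) and
    sine (II) latent components; random intercepts (chains, draws, subjects).
    """

    beta_cos: np.ndarray
    beta_sin: np.ndarray
    subj_cos: np.ndarray | None
    subj_sin: np.ndarray | None
    sigma2: np.ndarray | None          # (chains, draws, 2) random-intercept variances
    subjects: tuple[str, ...]
    sampler: SamplerConfig
    design: str = "full_factorial"
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta_cos.shape[0] * self.beta_cos.shape[1]

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, arr.shape[-1])

    def marginal_predicted_angles(self, condition: str, phase: Phase | str) -> np.ndarray:
        """Per-draw population-level predicted angle (degrees in [0, 360))
        for one design cell, excluding subject random effects."""
        if self.design == "intercept_only":
            x = np.ones(1)
        else:
            x = cell_design_row(condition, phase)
        mu1 = self._flat(self.beta_cos) @ x
        mu2 = self._flat(self.beta_sin) @ x
        return np.degrees(np.arctan2(mu2, mu1)) % 360.0

    def cell_angle_draws(self) -> dict[tuple[str, str], np.ndarray]:
        """All eight cells' per-draw marginal predicted angles, degrees."""
        return {
            (c, p.value): self.marginal_predicted_angles(c, p)
            for c in CONDITIONS
            for p in (Phase.LOADING, Phase.JUMP)
        }


def _compute_diagnostics(arrays: dict[str, np.ndarray]) -> dict:
    """Max split-R̂ and min bulk ESS across all scalar parameters via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=arrays)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(np.nanmax(v.values) for v in rhat.data_vars.values()))
    ess_min = float(min(np.nanmin(v.values) for v in ess.data_vars.values()))
    return {
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "converged": bool(rhat_max < 1.01),
        "ess_floor": 400,
        "ess_sufficient": bool(ess_min >= 400),
    }


def _gibbs_chain(
    rng: np.random.Generator,
    theta: np.ndarray,
    X: np.ndarray,
    subj_idx: np.ndarray | None,
    n_subjects: int,
    spec: ModelSpec,
    n_sweeps: int,
    burn_in: int,
    thin: int,
) -> tuple[np.ndarray, ...]:
    n, p = X.shape
    u1, u2 = np.cos(theta), np.sin(theta)
    XtX = X.T @ X
    chol = cho_factor(XtX + np.eye(p) / spec.prior_sd**2, lower=True)
    L_lower = np.linalg.cholesky(XtX + np.eye(p) / spec.prior_sd**2)

    r = np.ones(n)
    beta = np.column_stack(
        [np.linalg.lstsq(X, u1, rcond=None)[0], np.linalg.lstsq(X, u2, rcond=None)[0]]
    )  # (p, 2)
    use_ranef = subj_idx is not None and n_subjects > 0
    b = np.zeros((n_subjects, 2))
    sigma2 = np.ones(2)
    if use_ranef:
        counts = np.bincount(subj_idx, minlength=n_subjects).astype(float)

    keep = (n_sweeps - burn_in) // thin
    out_beta = np.empty((keep, p, 2))
    out_b = np.empty((keep, n_subjects, 2)) if use_ranef else None
    out_s2 = np.empty((keep, 2)) if use_ranef else None

    k = 0
    for sweep in range(n_sweeps):
        Xb = X @ beta  # (n, 2)
        if use_ranef:
            mu1 = Xb[:, 0] + b[subj_idx, 0]
            mu2 = Xb[:, 1] + b[subj_idx, 1]
        else:
            mu1, mu2 = Xb[:, 0], Xb[:, 1]

        # latent lengths: slice step, then exact draw from density ∝ r on the slice
        t = u1 * mu1 + u2 * mu2
        h = np.sqrt((r - t) ** 2 - 2.0 * np.log(rng.uniform(size=n)))
        lo = np.maximum(0.0, t - h)
        hi = t + h
        r = np.sqrt(lo**2 + rng.uniform(size=n) * (hi**2 - lo**2))

        y = np.column_stack([r * u1, r * u2])

        # fixed effects: conjugate normal update per component
        resid = y - b[subj_idx] if use_ranef else y
        mean = cho_solve(chol, X.T @ resid)  # (p, 2)
        beta = mean + np.linalg.solve(L_lower.T, rng.standard_normal((p, 2)))

        if use_ranef:
            # subject intercepts and their variances, per component
            res2 = y - X @ beta
            for c in range(2):
                s = np.bincount(subj_idx, weights=res2[:, c], minlength=n_subjects)
                prec = counts + 1.0 / sigma2[c]
                b[:, c] = s / prec + rng.standard_normal(n_subjects) / np.sqrt(prec)
                shape = spec.ig_shape + n_subjects / 2.0
                scale = spec.ig_scale + 0.5 * float(b[:, c] @ b[:, c])
                sigma2[c] = scale / rng.gamma(shape)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and k < keep:
            out_beta[k] = beta
            if use_ranef:
                out_b[k] = b
                out_s2[k] = sigma2
            k += 1
    return out_beta, out_b, out_s2


def _prepare_design(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, tuple[str, ...]]:
    required = {"mean_rad"}
    if spec.design == "full_factorial":
        required |= {"condition", "phase"}
    if spec.random_intercept:
        required |= {"subject"}
    missing = required - set(frame.columns)
    if missing:
        raise DesignError(f"observation table missing columns: {sorted(missing)}")
    if spec.design == "full_factorial":
        cells = frame.groupby(["condition", "phase"]).size()
        expected = [(c, p.value) for c in CONDITIONS for p in (Phase.LOADING, Phase.JUMP)]
        empty = [cell for cell in expected if cell not in cells.index]
        if empty:
            raise DesignError(f"empty design cells: {empty}")
        X = np.stack(
            [cell_design_row(c, p) for c, p in zip(frame["condition"], frame["phase"])]
        )
    else:
        X = np.ones((len(frame), 1))
    if spec.random_intercept:
        subjects = tuple(sorted(frame["subject"].astype(str).unique()))
        if len(subjects) < 2:
            raise DesignError("need at least 2 subjects for a random intercept")
        subj_idx = (
            frame["subject"]
            .astype(str)
            .map({s: i for i, s in enumerate(subjects)})
            .to_numpy(dtype=int)
        )
    else:
        subjects, subj_idx = (), None
    theta = frame["mean_rad"].to_numpy(dtype=float)
    return theta, X, subj_idx, subjects


def fit(
    frame: pd.DataFrame,
    spec: ModelSpec | None = None,
    sampler: SamplerConfig | None = None,
    *,
    compute_diagnostics: bool = True,
) -> PosteriorDraws:
    """Fit the circular mixed-effects model to a mean-angle observation table.

    ``frame`` follows the vector-coding CSV contract (one coupling at a
    time): columns ``subject``, ``condition``, ``phase``, ``mean_rad``.
    The fit is deterministic for a fixed seed, sampler config and input.
    Non-convergence (any R̂ ≥ 1.01) is flagged in ``diagnostics``, not
    raised.
    """
    spec = spec or ModelSpec()
    sampler = sampler or SamplerConfig()
    theta, X, subj_idx, subjects = _prepare_design(frame, spec)

    n_sweeps = sampler.burn_in + sampler.iterations
    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.n_chains)
    betas, bs, s2s = [], [], []
    for ss in seeds:
        ob, obb, os2 = _gibbs_chain(
            np.random.default_rng(ss),
            theta,
            X,
            subj_idx,
            len(subjects),
            spec,
            n_sweeps,
            sampler.burn_in,
            sampler.thin,
        )
        betas.append(ob)
        bs.append(obb)
        s2s.append(os2)
    beta = np.stack(betas)  # (chains, draws, p, 2)
    use_ranef = subj_idx is not None
    draws = PosteriorDraws(
        beta_cos=beta[..., 0],
        beta_sin=beta[..., 1],
        subj_cos=np.stack(bs)[..., 0] if use_ranef else None,
        subj_sin=np.stack(bs)[..., 1] if use_ranef else None,
        sigma2=np.stack(s2s) if use_ranef else None,
        subjects=subjects,
        sampler=sampler,
        design=spec.design,
    )
    if compute_diagnostics:
        arrays = {"beta_cos": draws.beta_cos, "beta_sin": draws.beta_sin}
        if use_ranef:
            arrays["sigma2"] = draws.sigma2
        draws.diagnostics = _compute_diagnostics(arrays)
    return draws


# ---------------------------------------------------------------------------
# contrasts


def circular_difference(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Shortest signed circular difference a − b, in degrees in (−180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    d = np.where(d == -180.0, 180.0, d)
    return float(d) if d.ndim == 0 else d


def wrap_to_pm180(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees to (−180, 180]."""
    return circular_difference(x, 0.0)


@dataclass(frozen=True)
class ContrastResult:
    """A summarised posterior contrast between design cells (degrees)."""

    label: str
    mean_difference_deg: float
    hpd_low: float
    hpd_high: float
    excludes_zero: bool
    contrast_class: str
    n_draws: int
    n_degenerate: int = 0


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass·n)`` of the sorted samples.

    Differences are treated on the linear (−180, 180] scale; a warning is
    emitted when >1% of the samples lie within 10° of ±180, where the
    linear representation is unreliable.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HPD interval, got {n}")
    if np.mean(np.abs(s) > 170.0) > 0.01:
        warnings.warn(
            "more than 1% of difference draws lie within 10° of ±180; "
            "the linear HPD interval may wrap",
            RuntimeWarning,
        )
    k = int(np.ceil(mass * n))
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def _summarise(
    diffs: np.ndarray, label: str, contrast_class: str, mass: float, n_degenerate: int = 0
) -> ContrastResult:
    rad = np.radians(diffs)
    mean_deg = wrap_to_pm180(
        mean_angle_from_components(float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad))))
    )
    low, high = hpd_interval(diffs, mass)
    return ContrastResult(
        label=label,
        mean_difference_deg=float(mean_deg),
        hpd_low=low,
        hpd_high=high,
        excludes_zero=not (low <= 0.0 <= high),
        contrast_class=contrast_class,
        n_draws=int(diffs.size),
        n_degenerate=n_degenerate,
    )


def interaction_contrasts(
    draws: PosteriorDraws,
    baseline_condition: str = "P1",
    baseline_phase: Phase | str = Phase.LOADING,
    hpd_mass: float = 0.95,
) -> list[ContrastResult]:
    """Condition × phase interaction contrasts against a baseline condition.

    Per draw, the phase difference (Jump − Loading) of each non-baseline
    condition is compared with the baseline condition's phase difference;
    positive values mean the phase difference grew relative to baseline.
    """
    if baseline_condition not in CONDITIONS:
        raise KeyError(f"unknown baseline condition {baseline_condition!r}")
    Phase(baseline_phase)  # validation; Loading is the reference by construction
    cells = draws.cell_angle_draws()
    d_base = circular_difference(
        cells[(baseline_condition, Phase.JUMP.value)],
        cells[(baseline_condition, Phase.LOADING.value)],
    )
    out = []
    for c in CONDITIONS[CONDITIONS.index(baseline_condition) + 1 :]:
        d_c = circular_difference(
            cells[(c, Phase.JUMP.value)], cells[(c, Phase.LOADING.value)]
        )
        diffs = wrap_to_pm180(d_c - d_base)
        out.append(
            _summarise(diffs, f"{baseline_condition} vs. {c}", "interaction", hpd_mass)
        )
    return out


def simple_main_effects(
    draws: PosteriorDraws,
    phase: Phase | str,
    baseline_condition: str = "P1",
    hpd_mass: float = 0.95,
) -> list[ContrastResult]:
    """Condition contrasts within one phase against a baseline condition."""
    phase = Phase(phase)
    if baseline_condition not in CONDITIONS:
        raise KeyError(f"unknown baseline condition {baseline_condition!r}")
    cells = draws.cell_angle_draws()
    base = cells[(baseline_condition, phase.value)]
    out = []
    for c in CONDITIONS[CONDITIONS.index(baseline_condition) + 1 :]:
        diffs = circular_difference(cells[(c, phase.value)], base)
        out.append(
            _summarise(
                diffs,
                f"{baseline_condition} vs. {c} ({phase.value})",
                "simple_main",
                hpd_mass,
            )
        )
    return out


def _per_draw_circular_mean(angle_arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw circular mean of several cell-angle arrays (degrees).

    Returns (mean_deg, degenerate_mask); draws whose resultant is
    numerically zero (antipodal cells) are flagged degenerate.
    """
    rads = np.radians(np.stack(angle_arrays))
    x = np.mean(np.cos(rads), axis=0)
    y = np.mean(np.sin(rads), axis=0)
    degenerate = np.hypot(x, y) < 1e-9
    mean = np.degrees(np.arctan2(y, x)) % 360.0
    return mean, degenerate


def main_effects(draws: PosteriorDraws, hpd_mass: float = 0.95) -> list[ContrastResult]:
    """Condition and phase main effects from phase-/condition-averaged cells.

    Condition main effects: per draw, the Loading and Jump predictions are
    circularly averaged within each condition before pairwise circular
    differences between conditions.  The phase main effect circularly
    averages across conditions within each phase before the Jump − Loading
    difference.  Draws with a degenerate (zero-resultant) circular mean are
    excluded, with the count reported.
    """
    cells = draws.cell_angle_draws()
    cond_mean, cond_degen = {}, {}
    for c in CONDITIONS:
        m, d = _per_draw_circular_mean(
            [cells[(c, Phase.LOADING.value)], cells[(c, Phase.JUMP.value)]]
        )
        cond_mean[c], cond_degen[c] = m, d
    out = []
    for i, a in enumerate(CONDITIONS):
        for b in CONDITIONS[i + 1 :]:
            ok = ~(cond_degen[a] | cond_degen[b])
            diffs = circular_difference(cond_mean[b][ok], cond_mean[a][ok])
            out.append(
                _summarise(
                    diffs,
                    f"{a} vs. {b}",
                    "condition_main",
                    hpd_mass,
                    n_degenerate=int((~ok).sum()),
                )
            )
    phase_mean, phase_degen = {}, {}
    for p in (Phase.LOADING, Phase.JUMP):
        m, d = _per_draw_circular_mean([cells[(c, p.value)] for c in CONDITIONS])
        phase_mean[p], phase_degen[p] = m, d
    ok = ~(phase_degen[Phase.LOADING] | phase_degen[Phase.JUMP])
    diffs = circular_difference(phase_mean[Phase.JUMP][ok], phase_mean[Phase.LOADING][ok])
    out.append(
        _summarise(
            diffs,
            "Jump vs. Loading",
            "phase_main",
            hpd_mass,
            n_degenerate=int((~ok).sum()),
        )
    )
    return out


def choose_branch(interactions: list[ContrastResult]) -> str:
    """Follow-up branch for one coupling: ``simple_main`` when any
    interaction contrast excludes zero, else ``main``."""
    if not interactions:
        raise ValueError("no interaction contrasts supplied")
    return (
        "simple_main" if any(c.excludes_zero for c in interactions) else "main"
    )


def analyze_coupling(
    draws: PosteriorDraws,
    baselines: Sequence[str] = ("P1", "P2", "P3"),
    hpd_mass: float = 0.95,
) -> dict:
    """Full inference record for one coupling's fitted model.

    Interaction contrasts are computed against each baseline in
    ``baselines``; the follow-up branch is decided on the primary
    (first) baseline's contrasts — the sequential-baseline interaction
    analyses are reported but do not drive the branch — and then either
    simple main effects per phase (all baselines) or overall condition and
    phase main effects are emitted.
    """
    primary = interaction_contrasts(
        draws, baseline_condition=baselines[0], hpd_mass=hpd_mass
    )
    secondary = [
        c
        for b in baselines[1:]
        for c in interaction_contrasts(draws, baseline_condition=b, hpd_mass=hpd_mass)
    ]
    interactions = primary + secondary
    branch = choose_branch(primary)
    record: dict = {
        "interactions": interactions,
        "branch": branch,
        "diagnostics": draws.diagnostics,
    }
    if branch == "simple_main":
        record["simple_main_effects"] = {
            p.value: [
                c
                for b in baselines
                for c in simple_main_effects(
                    draws, p, baseline_condition=b, hpd_mass=hpd_mass
                )
            ]
            for p in (Phase.LOADING, Phase.JUMP)
        }
    else:
        record["main_effects"] = main_effects(draws, hpd_mass=hpd_mass)
    return record


def contrasts_to_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """Contrast table in the report shape: label, difference, HPD, evidence."""
    return pd.DataFrame(
        {
            "comparison": [c.label for c in contrasts],
            "class": [c.contrast_class for c in contrasts],
            "mean_difference_deg": [c.mean_difference_deg for c in contrasts],
            "hpd_low_deg": [c.hpd_low for c in contrasts],
            "hpd_high_deg": [c.hpd_high for c in contrasts],
            "excludes_zero": [c.excludes_zero for c in contrasts],
            "n_degenerate_draws": [c.n_degenerate for c in contrasts],
        }
    )
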