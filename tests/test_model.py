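"""Circular mixed-effects model: contrasts, HPD intervals, sampler behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circoord.kinematics import CONDITIONS, Phase
from circoord.model import (
    ContrastResult,
    DesignError,
    ModelSpec,
    PosteriorDraws,
    SamplerConfig,
    cell_design_row,
    choose_branch,
    circular_difference,
    fit,
    hpd_interval,
    interaction_contrasts,
    main_effects,
    simple_main_effects,
    wrap_to_pm180,
)
from circoord.synthetic import uniform_angle_scenario, generate_angle_table

CELLS = [(c, p) for c in CONDITIONS for p in (Phase.LOADING, Phase.JUMP)]


def draws_from_cells(cell_angles_deg: dict, n_draws: int = 200) -> PosteriorDraws:
    """Construct posterior draws whose marginal cell angles are prescribed.

    ``cell_angles_deg`` maps (condition, Phase) to a scalar or an
    (n_draws,) array of angles; the fixed-effect coefficients are solved
    from the 8×8 cell design system with latent norm 10.
    """
    X = np.stack([cell_design_row(c, p) for c, p in CELLS])  # (8, 8), invertible
    ang = np.stack(
        [np.broadcast_to(np.asarray(cell_angles_deg[(c, p)], float), (n_draws,))
         for c, p in CELLS]
    )  # (8, n_draws)
    rad = np.radians(ang)
    beta_cos = np.linalg.solve(X, 10.0 * np.cos(rad)).T  # (n_draws, 8)
    beta_sin = np.linalg.solve(X, 10.0 * np.sin(rad)).T
    cfg = SamplerConfig(n_chains=1, iterations=n_draws, burn_in=1, thin=1, seed=0)
    return PosteriorDraws(
        beta_cos=beta_cos[None],
        beta_sin=beta_sin[None],
        subj_cos=None,
        subj_sin=None,
        sigma2=None,
        subjects=(),
        sampler=cfg,
    )


class TestCircularDifference:
    @pytest.mark.parametrize(
        "a,b,expected", [(10, 350, 20), (350, 10, -20), (180, 0, 180), (0, 0, 0)]
    )
    def test_wraparound_examples(self, a, b, expected):
        assert circular_difference(a, b) == pytest.approx(expected)

    @given(st.floats(0, 360), st.floats(0, 360))
    def test_bounded_and_antisymmetric(self, a, b):
        d_ab = circular_difference(a, b)
        d_ba = circular_difference(b, a)
        assert abs(d_ab) <= 180.0
        if abs(d_ab) < 180.0 - 1e-9:  # antisymmetry away from the boundary
            assert d_ab == pytest.approx(-d_ba, abs=1e-9)

    @given(st.floats(-1000, 1000))
    def test_wrap_range(self, x):
        w = wrap_to_pm180(x)
        assert -180.0 < w <= 180.0


class TestHpdInterval:
    def test_identical_samples_zero_width(self):
        low, high = hpd_interval(np.full(500, 3.3))
        assert (low, high) == (3.3, 3.3)

    def test_uniform_width_matches_order_statistics(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(-1, 1, 20_000)
        low, high = hpd_interval(s, 0.95)
        assert high - low == pytest.approx(1.9, abs=0.02)

    def test_normal_matches_closed_form(self):
        rng = np.random.default_rng(8)
        sigma = 5.0
        s = rng.normal(0, sigma, 50_000)
        low, high = hpd_interval(s, 0.95)
        assert low == pytest.approx(-1.96 * sigma, abs=0.15)
        assert high == pytest.approx(1.96 * sigma, abs=0.15)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            hpd_interval(np.zeros(99))

    def test_wraparound_warning_near_180(self):
        rng = np.random.default_rng(9)
        s = wrap_to_pm180(rng.normal(180.0, 5.0, 1000))
        with pytest.warns(RuntimeWarning, match="±180"):
            hpd_interval(s)


class TestDesign:
    def test_cell_design_rows(self):
        assert cell_design_row("P1", Phase.LOADING).tolist() == [1, 0, 0, 0, 0, 0, 0, 0]
        assert cell_design_row("P4", Phase.JUMP).tolist() == [1, 0, 0, 1, 1, 0, 0, 1]
        with pytest.raises(KeyError):
            cell_design_row("P9", Phase.JUMP)

    def test_empty_cell_rejected(self):
        frame = generate_angle_table(uniform_angle_scenario(seed=1, n_subjects=3))
        frame = frame[frame["condition"] != "P4"]
        with pytest.raises(DesignError, match="empty design cells"):
            fit(frame)

    def test_single_subject_rejected(self):
        frame = generate_angle_table(uniform_angle_scenario(seed=1, n_subjects=1))
        with pytest.raises(DesignError, match="2 subjects"):
            fit(frame)


class TestMarginalPredictedAngles:
    def test_equal_components_give_45(self):
        beta = np.zeros((1, 5, 8))
        beta[..., 0] = 1.0
        draws = PosteriorDraws(
            beta_cos=beta, beta_sin=beta.copy(), subj_cos=None, subj_sin=None,
            sigma2=None, subjects=(),
            sampler=SamplerConfig(n_chains=1, iterations=5, burn_in=1, thin=1, seed=0),
        )
        assert np.allclose(draws.marginal_predicted_angles("P1", "Loading"), 45.0)

    def test_zero_sine_component_gives_0(self):
        beta = np.zeros((1, 5, 8))
        beta[..., 0] = 2.0
        draws = PosteriorDraws(
            beta_cos=beta, beta_sin=np.zeros_like(beta), subj_cos=None,
            subj_sin=None, sigma2=None, subjects=(),
            sampler=SamplerConfig(n_chains=1, iterations=5, burn_in=1, thin=1, seed=0),
        )
        assert np.allclose(draws.marginal_predicted_angles("P2", "Jump"), 0.0)

    def test_unknown_cell_rejected(self):
        draws = draws_from_cells({cell: 10.0 for cell in CELLS}, n_draws=2)
        with pytest.raises(KeyError):
            draws.marginal_predicted_angles("P7", "Loading")


class TestContrasts:
    def test_null_cells_give_exact_zero_everywhere(self):
        draws = draws_from_cells({cell: 40.0 for cell in CELLS})
        for contrast in (
            interaction_contrasts(draws)
            + simple_main_effects(draws, Phase.LOADING)
            + main_effects(draws)
        ):
            assert contrast.mean_difference_deg == pytest.approx(0.0, abs=1e-9)
            assert not contrast.excludes_zero
            assert contrast.hpd_low <= 0.0 <= contrast.hpd_high

    def test_constructed_interaction_recovered_exactly(self):
        cells = {cell: 30.0 for cell in CELLS}
        for c in CONDITIONS:
            cells[(c, Phase.JUMP)] = 50.0
        cells[("P4", Phase.JUMP)] = 40.0  # interaction of −10° at P4
        draws = draws_from_cells(cells)
        by_label = {c.label: c for c in interaction_contrasts(draws)}
        assert by_label["P1 vs. P4"].mean_difference_deg == pytest.approx(-10.0, abs=1e-9)
        assert by_label["P1 vs. P4"].excludes_zero
        assert by_label["P1 vs. P2"].mean_difference_deg == pytest.approx(0.0, abs=1e-9)

    def test_phase_main_effect_of_constant_cells(self):
        cells = {}
        for c in CONDITIONS:
            cells[(c, Phase.LOADING)] = 10.0
            cells[(c, Phase.JUMP)] = 30.0
        results = main_effects(draws_from_cells(cells))
        phase = [r for r in results if r.contrast_class == "phase_main"][0]
        assert phase.mean_difference_deg == pytest.approx(20.0, abs=1e-9)
        conditions = [r for r in results if r.contrast_class == "condition_main"]
        assert len(conditions) == 6
        assert all(abs(r.mean_difference_deg) < 1e-9 for r in conditions)

    def test_sequential_baseline_identity(self):
        rng = np.random.default_rng(5)
        cells = {cell: rng.uniform(0, 360) for cell in CELLS}
        draws = draws_from_cells(cells)
        p1 = {c.label: c.mean_difference_deg
              for c in simple_main_effects(draws, Phase.JUMP, "P1")}
        p2 = {c.label: c.mean_difference_deg
              for c in simple_main_effects(draws, Phase.JUMP, "P2")}
        expected = wrap_to_pm180(p1["P1 vs. P3 (Jump)"] - p1["P1 vs. P2 (Jump)"])
        assert p2["P2 vs. P3 (Jump)"] == pytest.approx(expected, abs=1e-9)

    def test_antipodal_cells_flagged_degenerate(self):
        n = 300
        jump = np.concatenate([np.full(n // 2, 190.0), np.full(n // 2, 20.0)])
        cells = {cell: np.full(n, 10.0) for cell in CELLS}
        for c in CONDITIONS:
            cells[(c, Phase.JUMP)] = jump
        results = main_effects(draws_from_cells(cells, n_draws=n))
        conditions = [r for r in results if r.contrast_class == "condition_main"]
        assert all(r.n_degenerate == n // 2 for r in conditions)
        assert all(np.isfinite(r.mean_difference_deg) for r in conditions)

    def test_unknown_baseline_rejected(self):
        draws = draws_from_cells({cell: 10.0 for cell in CELLS}, n_draws=2)
        with pytest.raises(KeyError):
            interaction_contrasts(draws, baseline_condition="P5")


class TestDecisionTree:
    def _contrast(self, excludes: bool) -> ContrastResult:
        return ContrastResult(
            label="x", mean_difference_deg=1.0, hpd_low=0.5 if excludes else -1.0,
            hpd_high=2.0, excludes_zero=excludes, contrast_class="interaction",
            n_draws=100,
        )

    def test_any_exclusion_takes_simple_effects_branch(self):
        assert choose_branch([self._contrast(False), self._contrast(True)]) == "simple_main"

    def test_no_exclusion_takes_main_effects_branch(self):
        assert choose_branch([self._contrast(False), self._contrast(False)]) == "main"

    def test_empty_contrast_list_rejected(self):
        with pytest.raises(ValueError):
            choose_branch([])


class TestFit:
    def test_deterministic_under_fixed_seed(self):
        frame = generate_angle_table(
            uniform_angle_scenario(seed=2, n_subjects=4, trials_per_cell=1)
        )
        cfg = SamplerConfig(n_chains=2, iterations=150, burn_in=50, thin=1, seed=42)
        a = fit(frame, sampler=cfg, compute_diagnostics=False)
        b = fit(frame, sampler=cfg, compute_diagnostics=False)
        assert np.array_equal(a.beta_cos, b.beta_cos)
        assert np.array_equal(a.beta_sin, b.beta_sin)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_different_seed_changes_draws(self):
        frame = generate_angle_table(
            uniform_angle_scenario(seed=2, n_subjects=4, trials_per_cell=1)
        )
        a = fit(frame, sampler=SamplerConfig(2, 150, 50, 1, seed=1),
                compute_diagnostics=False)
        b = fit(frame, sampler=SamplerConfig(2, 150, 50, 1, seed=2),
                compute_diagnostics=False)
        assert not np.array_equal(a.beta_cos, b.beta_cos)

    def test_concentrated_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(3)
        angles = np.radians(45.0 + rng.normal(0, 1.0, 200))
        frame = pd.DataFrame({"mean_rad": angles % (2 * np.pi)})
        spec = ModelSpec(random_intercept=False, design="intercept_only")
        draws = fit(frame, spec,
                    SamplerConfig(n_chains=2, iterations=1000, burn_in=200, thin=1, seed=0),
                    compute_diagnostics=False)
        post = np.radians(draws.marginal_predicted_angles("P1", "Loading"))
        post_mean = np.degrees(np.angle(np.mean(np.exp(1j * post))))
        sample_mean = np.degrees(np.angle(np.mean(np.exp(1j * angles))))
        assert post_mean == pytest.approx(sample_mean, abs=2.0)

    def test_diagnostics_reported(self):
        frame = generate_angle_table(
            uniform_angle_scenario(seed=4, n_subjects=4, trials_per_cell=1)
        )
        draws = fit(frame, sampler=SamplerConfig(2, 200, 50, 1, seed=0))
        assert {"rhat_max", "ess_min", "converged", "ess_sufficient"} <= set(
            draws.diagnostics
        )
        assert draws.diagnostics["rhat_max"] > 0
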