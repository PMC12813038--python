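"""Independent numerical checks of the circular model's posterior.

These routines never touch the MCMC sampler: the projected-normal density
is evaluated in closed form and the intercept-only posterior is integrated
on a dense polar grid, giving a reference distribution for the mean
direction that MCMC output can be compared against (total variation
distance on a shared binning).
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm


def projected_normal_logpdf(theta: np.ndarray, mu1: float, mu2: float) -> np.ndarray:
    """Log density of the projected normal PN2((mu1, mu2), I2) at angle theta (rad).

    With t = μᵀu(θ):  p(θ) = (2π)⁻¹ e^{−‖μ‖²/2} [1 + t √(2π) e^{t²/2} Φ(t)].
    """
    theta = np.asarray(theta, dtype=float)
    t = mu1 * np.cos(theta) + mu2 * np.sin(theta)
    norm_sq = mu1**2 + mu2**2
    # log of the bracket, stable for large |t| via log Φ
    bracket = 1.0 + t * np.sqrt(2 * np.pi) * np.exp(
        np.clip(t**2 / 2.0, None, 700.0)
    ) * norm.cdf(t)
    # for large positive t the '1 +' is negligible; use the log form there
    large = t > 25.0
    log_bracket = np.where(
        large,
        np.log(np.sqrt(2 * np.pi)) + np.log(np.maximum(t, 1e-300)) + t**2 / 2.0
        + log_ndtr(t),
        np.log(np.maximum(bracket, 1e-300)),
    )
    return -np.log(2 * np.pi) - norm_sq / 2.0 + log_bracket


def grid_posterior_direction(
    theta_obs: np.ndarray,
    prior_sd: float = 100.0,
    n_angle: int = 720,
    n_radius: int = 400,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior of the mean-direction angle of an intercept-only model,
    by dense polar-grid integration over the latent mean β ∈ R².

    Returns ``(bin_edges, probabilities)``: probabilities sum to 1 over
    ``n_angle`` equal angular bins of [0, 2π); the radial coordinate is
    integrated out (with the polar Jacobian).
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    if r_max is None:
        # generous upper bound on the latent norm given n observations
        r_max = 10.0 + 4.0 * np.sqrt(theta_obs.size)
    edges = np.linspace(0.0, 2 * np.pi, n_angle + 1)
    phi = 0.5 * (edges[:-1] + edges[1:])
    rho = np.linspace(1e-6, r_max, n_radius)
    mu1 = rho[None, :] * np.cos(phi[:, None])
    mu2 = rho[None, :] * np.sin(phi[:, None])
    log_post = np.zeros_like(mu1)
    for th in theta_obs:
        log_post += projected_normal_logpdf(np.array(th), mu1, mu2)
    log_post += -(mu1**2 + mu2**2) / (2 * prior_sd**2)  # prior (up to constant)
    log_post += np.log(rho)[None, :]                    # polar Jacobian
    log_post -= log_post.max()
    p_phi = np.trapezoid(np.exp(log_post), rho, axis=1)
    return edges, p_phi / p_phi.sum()


def bin_angles(angles_rad: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Empirical probabilities of angles (rad, wrapped to [0, 2π)) per bin."""
    wrapped = np.asarray(angles_rad, dtype=float) % (2 * np.pi)
    counts, _ = np.histogram(wrapped, bins=edges)
    return counts / counts.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two discrete distributions."""
    return float(0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum())
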