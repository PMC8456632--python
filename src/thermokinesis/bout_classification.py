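"""Forward/turn bout classification.

The one-sided (absolute) turn-angle distribution is modelled as a
mixture of a zero-mean Gaussian (narrow forward peak, width fixed a
priori) and a gamma distribution (wide turning tail, scale fixed a
priori, shape fitted). The angle at which the two weighted component
densities cross defines the forward/turn threshold; the canonical value
is 0.17 rad (~10 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AngleMixtureFit",
    "MixtureFitError",
    "DEFAULT_THRESHOLD",
    "DEFAULT_SIGMA",
    "DEFAULT_GAMMA_SCALE",
    "fit_angle_mixture",
    "classify_bout",
    "classify_bouts",
    "estimate_p_turn",
]

DEFAULT_THRESHOLD = 0.17  # rad
DEFAULT_SIGMA = 0.07  # rad, half-normal width of the forward peak
DEFAULT_GAMMA_SCALE = 0.12  # rad, gamma scale of the turning tail

FORWARD = "forward"
TURN = "turn"


class MixtureFitError(RuntimeError):
    """Raised when the Gaussian + gamma mixture cannot be fitted or the
    component densities do not cross in (0, pi)."""


@dataclass(frozen=True)
class AngleMixtureFit:
    """Fitted one-sided turn-angle mixture and its crossing threshold."""

    sigma: float  # rad, fixed
    gamma_shape: float  # fitted
    gamma_scale: float  # rad, fixed
    weight: float  # mixture weight of the gamma (turn) component
    threshold: float  # rad, where the weighted densities cross

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        fwd = stats.halfnorm.pdf(theta, scale=self.sigma)
        turn = stats.gamma.pdf(theta, self.gamma_shape, scale=self.gamma_scale)
        return (1.0 - self.weight) * fwd + self.weight * turn


def _kde_log_density(
    abs_angles: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    # fixed-bandwidth Gaussian KDE; gaussian_kde's bw is a factor of the
    # sample sd, so rescale
    sd = np.std(abs_angles, ddof=1)
    kde = stats.gaussian_kde(abs_angles, bw_method=bandwidth / sd)
    return np.log(np.clip(kde(grid), 1e-300, None))


def fit_angle_mixture(
    abs_angles,
    sigma: float = DEFAULT_SIGMA,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
    kde_bandwidth_deg: float = 0.5,
    fit_range: tuple[float, float] = (0.02, 2.0),
    n_grid: int = 200,
) -> AngleMixtureFit:
    """Fit the gamma shape and mixture weight against a KDE of |angles|.

    Weighted least squares between the model log-density and a
    fixed-bandwidth KDE (bandwidth given on the degree scale), weighting
    grid points by local data counts. The threshold is the smallest
    positive crossing of the two weighted component densities, located by
    bracketed root-finding on (0, pi).
    """
    abs_angles = np.abs(np.asarray(abs_angles, dtype=float))
    if abs_angles.size < 100:
        raise MixtureFitError(f"need >=100 angles, got {abs_angles.size}")
    bandwidth = np.deg2rad(kde_bandwidth_deg)
    lo = max(fit_range[0], 1e-4)
    hi = min(fit_range[1], float(np.max(abs_angles)))
    grid = np.linspace(lo, hi, n_grid)
    log_kde = _kde_log_density(abs_angles, grid, bandwidth)
    # weight each grid point by the number of observations in its bin
    edges = np.concatenate(
        ([grid[0] - (grid[1] - grid[0]) / 2], (grid[1:] + grid[:-1]) / 2,
         [grid[-1] + (grid[1] - grid[0]) / 2])
    )
    counts, _ = np.histogram(abs_angles, bins=edges)
    w = np.sqrt(counts.astype(float))

    fwd_pdf = stats.halfnorm.pdf(grid, scale=sigma)

    def residuals(params):
        shape, weight = params
        model = (1.0 - weight) * fwd_pdf + weight * stats.gamma.pdf(
            grid, shape, scale=gamma_scale
        )
        return w * (np.log(np.clip(model, 1e-300, None)) - log_kde)

    try:
        result = optimize.least_squares(
            residuals,
            x0=[3.0, 0.5],
            bounds=([1.01, 0.01], [60.0, 0.99]),
            xtol=1e-10,
        )
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise MixtureFitError(f"mixture optimisation failed: {exc}") from exc
    shape, weight = result.x

    def density_gap(theta):
        return weight * stats.gamma.pdf(theta, shape, scale=gamma_scale) - (
            1.0 - weight
        ) * stats.halfnorm.pdf(theta, scale=sigma)

    # bracket the smallest positive root on (0, pi)
    scan = np.linspace(1e-3, np.pi, 2000)
    gap = density_gap(scan)
    sign_change = np.flatnonzero(np.diff(np.sign(gap)) != 0)
    if sign_change.size == 0:
        raise MixtureFitError("component densities do not cross in (0, pi)")
    i = sign_change[0]
    threshold = float(optimize.brentq(density_gap, scan[i], scan[i + 1]))
    return AngleMixtureFit(
        sigma=float(sigma),
        gamma_shape=float(shape),
        gamma_scale=float(gamma_scale),
        weight=float(weight),
        threshold=threshold,
    )


def classify_bout(delta_theta: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Label one bout: |dtheta| > threshold -> turn, else forward.

    Exactly at the threshold the bout counts as forward. The sign of
    dtheta only sets left (positive) vs right (negative).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return TURN if abs(delta_theta) > threshold else FORWARD


def classify_bouts(delta_thetas, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Vectorized :func:`classify_bout` over an angle array."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    delta_thetas = np.asarray(delta_thetas, dtype=float)
    return np.where(np.abs(delta_thetas) > threshold, TURN, FORWARD)


def estimate_p_turn(bout_classes) -> float:
    """Fraction of turn bouts over all bouts."""
    classes = np.asarray(bout_classes)
    if classes.size == 0:
        raise ValueError("cannot estimate p_turn from zero bouts")
    return float(np.mean(classes == TURN))
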