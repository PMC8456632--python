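"""Two-Markov-chain reorientation inference.

Bout reorientations are ternarized (left turn +1, forward 0, right turn
-1). Under the two-chain model — a memoryless forward/turn selector with
rate p_turn and a persistent left/right state flipping with per-bout
probability p_flip — the conditional mean of the next ternary value
obeys

    <D_{n+1} | D_n> = p_turn * (1 - 2 * p_flip) * D_n

so the slope of the conditional means against D_n measures p_flip. The
hidden left/right state is piecewise constant between turn bouts
(forward bouts are transparent); its autocorrelation decays as
exp(-2 * k_flip * t) for a symmetric telegraph process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .bout_classification import DEFAULT_THRESHOLD

__all__ = [
    "TernarySequence",
    "OrientationSignal",
    "FlipEstimates",
    "DegenerateSignalError",
    "ternarize",
    "ternarize_values",
    "estimate_p_flip",
    "reconstruct_orientation_signal",
    "acf_orientation",
    "mean_acf",
    "fit_k_flip",
]


class DegenerateSignalError(ValueError):
    """Raised for signals with no usable structure (no turns, zero variance)."""


@dataclass
class TernarySequence:
    """Ternarized reorientations with their bout onset times."""

    values: np.ndarray  # in {-1, 0, +1}
    times: np.ndarray  # s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if np.any(np.abs(self.values) > 1):
            raise ValueError("ternary values must be in {-1, 0, +1}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OrientationSignal:
    """Reconstructed left/right state sampled on a uniform time grid."""

    t_grid: np.ndarray  # s
    state: np.ndarray  # +-1 per grid point


@dataclass(frozen=True)
class FlipEstimates:
    p_flip: float
    slope: float
    k_flip_ratio: float | None = None  # p_flip / <dt>, 1/s
    k_flip_acf: float | None = None  # from telegraph ACF fit, 1/s


def ternarize(delta_thetas, threshold: float = DEFAULT_THRESHOLD, times=None) -> TernarySequence:
    """Map signed reorientation angles to {-1, 0, +1}."""
    delta_thetas = np.asarray(delta_thetas, dtype=float)
    values = np.where(
        np.abs(delta_thetas) > threshold, np.sign(delta_thetas).astype(int), 0
    )
    if times is None:
        times = np.arange(len(values), dtype=float)
    return TernarySequence(values=values, times=np.asarray(times, dtype=float))


def ternarize_values(values, times=None) -> TernarySequence:
    """Wrap already-ternary values in a :class:`TernarySequence`."""
    values = np.asarray(values, dtype=int)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return TernarySequence(values=values, times=np.asarray(times, dtype=float))


def estimate_p_flip(seq: TernarySequence, p_turn: float) -> FlipEstimates:
    """Estimate p_flip from the slope of conditional means of D_{n+1}.

    The three conditional means (for D_n in {-1, 0, +1}) are fitted by a
    count-weighted least-squares line through the origin; then
    p_flip = (1 - slope / p_turn) / 2, clamped into [0, 1].
    """
    if p_turn <= 0:
        raise ValueError("p_flip is undefined for p_turn = 0")
    values = seq.values
    if np.sum(values != 0) < 2:
        raise DegenerateSignalError("need at least 2 turn bouts")
    prev, nxt = values[:-1], values[1:]
    num = 0.0
    den = 0.0
    for level in (-1, 0, 1):
        mask = prev == level
        n = int(np.sum(mask))
        if n == 0:
            continue
        num += n * level * float(np.mean(nxt[mask]))
        den += n * level * level
    if den == 0:
        raise DegenerateSignalError("no turn bouts precede another bout")
    slope = num / den
    p_flip = (1.0 - slope / p_turn) / 2.0
    if not 0.0 <= p_flip <= 1.0:
        warnings.warn(
            f"p_flip estimate {p_flip:.3f} outside [0, 1]; clamped", stacklevel=2
        )
        p_flip = float(np.clip(p_flip, 0.0, 1.0))
    return FlipEstimates(p_flip=float(p_flip), slope=float(slope))


def reconstruct_orientation_signal(
    seq: TernarySequence,
    dt_grid: float = 0.1,
    t_start: float | None = None,
    t_end: float | None = None,
) -> OrientationSignal:
    """Sample the hidden left/right state on a uniform grid.

    The state at time t is the sign of the most recent turn bout at or
    before t; before the first turn it is back-filled from that turn.
    """
    turn_mask = seq.values != 0
    if not np.any(turn_mask):
        raise DegenerateSignalError("cannot reconstruct state without turn bouts")
    turn_times = seq.times[turn_mask]
    turn_signs = seq.values[turn_mask]
    t0 = seq.times[0] if t_start is None else t_start
    t1 = seq.times[-1] if t_end is None else t_end
    t_grid = np.arange(t0, t1 + dt_grid / 2, dt_grid)
    idx = np.searchsorted(turn_times, t_grid, side="right") - 1
    state = turn_signs[np.clip(idx, 0, None)]  # idx=-1 -> back-fill first sign
    return OrientationSignal(t_grid=t_grid, state=state.astype(int))


def _sample_acf(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased sample ACF of a mean-removed 1-D signal, R(0) = 1."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    var = np.mean(x * x)
    if var == 0:
        raise DegenerateSignalError("constant signal has undefined ACF")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: n_lags + 1] / n
    return acov / acov[0]


def acf_orientation(signal: OrientationSignal, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """ACF of the mean-removed state signal; returns (lags_s, acf)."""
    dt = float(signal.t_grid[1] - signal.t_grid[0])
    duration = float(signal.t_grid[-1] - signal.t_grid[0])
    if max_lag >= duration:
        raise ValueError("max_lag must be below the signal duration")
    n_lags = int(round(max_lag / dt))
    acf = _sample_acf(signal.state.astype(float), n_lags)
    return np.arange(n_lags + 1) * dt, acf


def mean_acf(acfs: list[np.ndarray]) -> np.ndarray:
    """Equal-weight average of per-trajectory ACFs, truncated to the
    shortest one."""
    if not acfs:
        raise ValueError("no ACFs to average")
    n = min(len(a) for a in acfs)
    return np.mean([a[:n] for a in acfs], axis=0)


def fit_k_flip(
    lags: np.ndarray, acf: np.ndarray, fit_window: float | None = None
) -> tuple[float, tuple[float, float]]:
    """Fit R(t) = exp(-2 k t) to a mean ACF; returns (k, 95% CI)."""
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    if fit_window is not None:
        keep = lags <= fit_window
        lags, acf = lags[keep], acf[keep]
    if not np.any(acf[1:] > 0):
        raise RuntimeError("ACF is non-positive over the fit window")

    def model(t, k):
        return np.exp(-2.0 * k * t)

    popt, pcov = optimize.curve_fit(model, lags, acf, p0=[0.2], bounds=(0, np.inf))
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    return k, (k - 1.96 * se, k + 1.96 * se)
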