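"""Distribution estimates, batch averaging, bootstrap CIs, MSD/MSR."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BatchDistribution",
    "MsdCurve",
    "kde_pdf",
    "batch_average",
    "bootstrap_ci",
    "propagate_ratio_error",
    "msd_msr",
    "kruskal_wallis",
    "sample_acf",
]


@dataclass
class BatchDistribution:
    grid: np.ndarray
    mean_pdf: np.ndarray
    sem_pdf: np.ndarray
    n_batches: int


@dataclass
class MsdCurve:
    lag: np.ndarray  # s
    msd: np.ndarray  # mm^2
    msd_sem: np.ndarray
    msr: np.ndarray | None = None  # rad^2
    msr_sem: np.ndarray | None = None


def kde_pdf(
    values, bandwidth: float, grid: np.ndarray | None = None, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE at a fixed absolute bandwidth.

    The default grid covers [min - 3h, max + 3h]. Note scipy's
    ``gaussian_kde`` takes a bandwidth *factor*, so we rescale by the
    sample sd; degenerate samples fall back to an explicit kernel sum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("kde_pdf requires at least one value")
    if grid is None:
        grid = np.linspace(values.min() - 3 * bandwidth, values.max() + 3 * bandwidth, n_grid)
    sd = np.std(values, ddof=1) if values.size > 1 else 0.0
    if sd > 0:
        kde = stats.gaussian_kde(values, bw_method=bandwidth / sd)
        pdf = kde(grid)
    else:
        pdf = stats.norm.pdf(grid, loc=values[0], scale=bandwidth)
    return grid, pdf


def batch_average(pdfs: Sequence[np.ndarray], grid: np.ndarray) -> BatchDistribution:
    """Pointwise mean and s.e.m. of per-batch pdfs on a common grid."""
    if len(pdfs) < 2:
        raise ValueError("need at least 2 batches")
    arr = np.asarray(pdfs, dtype=float)
    if arr.shape[1] != len(grid):
        raise ValueError("pdfs do not share the given grid")
    return BatchDistribution(
        grid=np.asarray(grid, dtype=float),
        mean_pdf=arr.mean(axis=0),
        sem_pdf=arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]),
        n_batches=arr.shape[0],
    )


def bootstrap_ci(
    values,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI (default 95%, 1000 resamples)."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = np.array([statistic(values[row]) for row in idx])
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def propagate_ratio_error(a: float, sa: float, b: float, sb: float) -> float:
    """First-order standard error of the ratio a/b."""
    r = a / b
    return abs(r) * np.sqrt((sa / a) ** 2 + (sb / b) ** 2)


def _ta_msd(series: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time-averaged mean squared increment at integer lags.

    ``series`` is (n, d); squared Euclidean increment averaged over all
    start points.
    """
    out = np.empty(len(lags))
    for j, k in enumerate(lags):
        diff = series[k:] - series[:-k]
        out[j] = float(np.mean(np.sum(diff * diff, axis=-1)))
    return out


def msd_msr(
    paths: Sequence[dict],
    dt: float | None = None,
    max_lag: float | None = None,
) -> MsdCurve:
    """Ensemble-averaged time-averaged MSD (and MSR when headings given).

    Each path is a dict with keys ``t``, ``x``, ``y`` and optionally
    ``theta`` (cumulative, unwrapped heading). Paths are resampled on a
    uniform clock (default: the median sampling interval across paths);
    the maximum lag defaults to half the shortest path duration.
    """
    if not paths:
        raise ValueError("no paths given")
    durations = [float(p["t"][-1] - p["t"][0]) for p in paths]
    if dt is None:
        dt = float(np.median([np.median(np.diff(p["t"])) for p in paths]))
    if max_lag is None:
        max_lag = min(durations) / 2
    n_lags = max(int(max_lag / dt), 1)
    lags = np.arange(1, n_lags + 1)

    msds, msrs = [], []
    for p in paths:
        t0 = float(p["t"][0])
        grid = t0 + np.arange(int(np.floor((p["t"][-1] - t0) / dt)) + 1) * dt
        if len(grid) <= n_lags:
            continue
        xy = np.column_stack(
            [np.interp(grid, p["t"], p["x"]), np.interp(grid, p["t"], p["y"])]
        )
        msds.append(_ta_msd(xy, lags))
        if "theta" in p and p["theta"] is not None:
            th = np.interp(grid, p["t"], p["theta"])[:, None]
            msrs.append(_ta_msd(th, lags))
    if not msds:
        raise ValueError("all paths shorter than the lag range")
    msds = np.asarray(msds)
    lag_s = np.concatenate(([0.0], lags * dt))
    msd = np.concatenate(([0.0], msds.mean(axis=0)))
    msd_sem = np.concatenate(([0.0], msds.std(axis=0, ddof=1) / np.sqrt(len(msds))))
    curve = MsdCurve(lag=lag_s, msd=msd, msd_sem=msd_sem)
    if msrs:
        msrs = np.asarray(msrs)
        curve.msr = np.concatenate(([0.0], msrs.mean(axis=0)))
        curve.msr_sem = np.concatenate(
            ([0.0], msrs.std(axis=0, ddof=1) / np.sqrt(len(msrs)))
        )
    return curve


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, str]:
    """Kruskal–Wallis H test across groups; returns (H, p, star label)."""
    h, p = stats.kruskal(*groups)
    if p < 0.001:
        label = "***"
    elif p < 0.01:
        label = "**"
    elif p < 0.05:
        label = "*"
    else:
        label = "ns"
    return float(h), float(p), label


def sample_acf(x: np.ndarray, n_lags: int, axis: int = -1) -> np.ndarray:
    """Biased sample autocorrelation of mean-removed series, R(0) = 1.

    Computed with FFTs; supports batches of series along ``axis``.
    """
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, -1)
    x = x - x.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft, axis=-1)
    acov = np.fft.irfft(f * np.conj(f), axis=-1)[..., : n_lags + 1] / n
    denom = acov[..., :1]
    if np.any(denom == 0):
        raise ValueError("constant series has undefined ACF")
    return np.moveaxis(acov / denom, -1, axis)
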