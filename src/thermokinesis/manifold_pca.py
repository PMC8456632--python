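"""Per-trajectory feature matrices and the common 2-PC behavioral space.

Each trajectory contributes five summary parameters (mean interbout
interval, turn probability, flip rate, mean turn amplitude, mean
displacement). PCA runs per temperature, on the pooled block-standardized
matrix, or on the 5-temperatures x 5-parameters mean matrix; the number
of retained components follows the Guttman–Kaiser criterion (eigenvalue
above 1 on standardized data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "PcaSpace",
    "build_feature_matrix",
    "correlation_matrix",
    "pca",
    "project",
    "variance_partition",
]

FEATURE_COLUMNS = ("mean_ibi", "p_turn", "k_flip", "mean_abs_turn_angle", "mean_disp")


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_trajectories, 5)
    temperatures: np.ndarray  # label per row
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.temperatures = np.asarray(self.temperatures)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError(f"feature matrix must have {len(self.columns)} columns")
        if len(self.temperatures) != len(self.values):
            raise ValueError("one temperature label per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing entries")

    def subset(self, temperature) -> "FeatureMatrix":
        mask = self.temperatures == temperature
        return FeatureMatrix(self.values[mask], self.temperatures[mask], self.columns)


@dataclass
class PcaSpace:
    loadings: np.ndarray  # (5, n_components), orthonormal columns
    explained_variance: np.ndarray  # fractions, sums to 1
    means: np.ndarray
    sds: np.ndarray
    n_retained: int


def build_feature_matrix(trajectories) -> FeatureMatrix:
    """Assemble the trajectories x 5 matrix with temperature labels.

    Accepts a DataFrame with the feature columns plus ``temperature``, or
    an iterable of objects with ``summary`` dicts and
    ``temperature_label`` (as produced by the bout pipeline).
    """
    if isinstance(trajectories, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in trajectories.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        values = trajectories[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        temps = trajectories["temperature"].to_numpy()
    else:
        rows, temps_list = [], []
        for k, traj in enumerate(trajectories):
            row = [traj.summary.get(c, np.nan) for c in FEATURE_COLUMNS]
            if not np.all(np.isfinite(row)):
                raise ValueError(f"trajectory {k} is missing summary values")
            rows.append(row)
            temps_list.append(traj.temperature_label)
        if not rows:
            raise ValueError("no trajectories given")
        values = np.asarray(rows, dtype=float)
        temps = np.asarray(temps_list)
    if len(values) == 0:
        raise ValueError("no trajectories given")
    return FeatureMatrix(values=values, temperatures=temps)


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns (symmetric, unit diagonal)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if np.any(np.std(values, axis=0) == 0):
        raise ValueError("constant column has undefined correlation")
    return np.corrcoef(values, rowvar=False)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _standardize(values: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=ddof)
    if np.any(sds == 0):
        raise ValueError("constant column cannot be standardized")
    return (values - means) / sds, means, sds


def pca(matrix: FeatureMatrix, mode: str = "pooled", kaiser: bool = True) -> PcaSpace:
    """SVD-based PCA in one of three modes.

    - ``per_temperature``: caller passes a single-temperature matrix.
    - ``pooled``: each temperature block standardized independently, then
      concatenated.
    - ``inter_temperature``: PCA of the 5 x 5 per-temperature mean matrix,
      standardized across temperatures.
    """
    if mode in ("per_temperature", "pooled", "inter_temperature"):
        if mode == "pooled":
            blocks = []
            for temp in np.unique(matrix.temperatures):
                block = matrix.values[matrix.temperatures == temp]
                blocks.append(_standardize(block)[0])
            data = np.vstack(blocks)
            means = np.zeros(matrix.values.shape[1])
            sds = np.ones(matrix.values.shape[1])
        elif mode == "inter_temperature":
            temps = np.unique(matrix.temperatures)
            mean_matrix = np.vstack(
                [matrix.values[matrix.temperatures == t].mean(axis=0) for t in temps]
            )
            data, means, sds = _standardize(mean_matrix)
        else:
            data, means, sds = _standardize(matrix.values)
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")

    if data.shape[0] <= data.shape[1] and mode != "inter_temperature":
        warnings.warn("fewer rows than features; components are rank-limited")

    centered = data - data.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / max(data.shape[0] - 1, 1)
    total = eigenvalues.sum()
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if rank < len(s):
        warnings.warn(f"rank-deficient input; keeping {rank} components")
    loadings = _fix_signs(vt.T[:, :rank])
    explained = eigenvalues[:rank] / total
    n_retained = int(np.sum(eigenvalues[:rank] > 1.0)) if kaiser else min(2, rank)
    n_retained = max(n_retained, 1)
    return PcaSpace(
        loadings=loadings,
        explained_variance=explained,
        means=means,
        sds=sds,
        n_retained=n_retained,
    )


def project(
    values: np.ndarray,
    space: PcaSpace,
    pooled_sds: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """Project rows into the retained-PC space.

    Rows are scaled by the pooled standard deviations (no centering, so
    different temperatures stay comparable) and multiplied by the
    retained loadings.
    """
    values = np.asarray(values, dtype=float)
    pooled_sds = np.asarray(pooled_sds, dtype=float)
    if values.shape[1] != space.loadings.shape[0]:
        raise ValueError("dimension mismatch between data and loadings")
    return (values / pooled_sds) @ space.loadings[:, :n_components]


def variance_partition(projections_per_fish: Sequence[np.ndarray]) -> dict:
    """Intra-individual variance fraction per PC.

    ``projections_per_fish`` holds one (n_trajectories, n_pcs) array per
    fish. Intra = mean over fish of the per-fish projection variance;
    overall = variance of the pooled projections.
    """
    if len(projections_per_fish) < 2:
        raise ValueError("need at least 2 fish")
    for p in projections_per_fish:
        if len(p) < 2:
            raise ValueError("each fish needs at least 2 trajectories")
    intra = np.mean([np.var(p, axis=0, ddof=1) for p in projections_per_fish], axis=0)
    pooled = np.vstack(projections_per_fish)
    overall = np.var(pooled, axis=0, ddof=1)
    fractions = intra / overall
    return {f"intra_fraction_pc{j + 1}": float(fractions[j]) for j in range(pooled.shape[1])}
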