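"""LIBSHUFF comparison of two sequence libraries.

For libraries X and Y drawn from a pooled distance matrix, the homologous
coverage C_X(D) is the fraction of X-sequences having another X-sequence
within distance D, and the heterologous coverage C_XY(D) is the fraction
of X-sequences having a Y-sequence within D. The test statistic

    dC_XY = sum over the distance grid of (C_X(D) - C_XY(D))^2 * step

is large when Y fails to "cover" X, i.e. when the libraries sample
different communities. Significance comes from permuting library labels
over the pooled set with library sizes fixed; both reciprocal directions
are tested, with an experiment-wise correction for the two comparisons.

The grid runs from 0 to the maximum observed pooled distance in steps of
0.01 by default. The statistic multiplies by the grid step; because the
same discretization is used for observed and permuted statistics, the
p-values are invariant to this choice (it is recorded in the result).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import LibshuffError
from .io import DistanceMatrix


def _coverage_from_minima(minima: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Coverage curve: fraction of minima <= D for each grid point D."""
    return (minima[:, None] <= grid[None, :] + 1e-12).mean(axis=0)


def homologous_coverage(dmatrix_x: DistanceMatrix, D: float) -> float:
    """C_X(D): fraction of X-sequences with another X-sequence within D."""
    n = len(dmatrix_x)
    if n == 0:
        raise LibshuffError("empty library")
    if n == 1:
        return 0.0
    v = dmatrix_x.values.copy()
    np.fill_diagonal(v, np.inf)
    minima = v.min(axis=1)
    return float(np.mean(minima <= D + 1e-12))


def heterologous_coverage(dmatrix_xy: np.ndarray, D: float) -> float:
    """C_XY(D): fraction of X (rows) with a Y-sequence (columns) within D."""
    xy = np.asarray(dmatrix_xy, dtype=float)
    if xy.size == 0:
        raise LibshuffError("empty cross-library matrix")
    minima = xy.min(axis=1)
    return float(np.mean(minima <= D + 1e-12))


def _minima(values: np.ndarray, in_x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sequence nearest-neighbor distances within and across libraries.

    Returns (min_same_x, min_cross_x, min_same_y, min_cross_y) where the
    "same" minima exclude self.
    """
    v = values.copy()
    np.fill_diagonal(v, np.inf)
    x_idx = np.flatnonzero(in_x)
    y_idx = np.flatnonzero(~in_x)
    min_same_x = v[np.ix_(x_idx, x_idx)].min(axis=1)
    min_cross_x = values[np.ix_(x_idx, y_idx)].min(axis=1)
    min_same_y = v[np.ix_(y_idx, y_idx)].min(axis=1)
    min_cross_y = values[np.ix_(y_idx, x_idx)].min(axis=1)
    return min_same_x, min_cross_x, min_same_y, min_cross_y


def _delta_c_values(values: np.ndarray, in_x: np.ndarray, grid: np.ndarray, step: float) -> tuple[float, float]:
    msx, mcx, msy, mcy = _minima(values, in_x)
    cx = _coverage_from_minima(msx, grid)
    cxy = _coverage_from_minima(mcx, grid)
    cy = _coverage_from_minima(msy, grid)
    cyx = _coverage_from_minima(mcy, grid)
    d_xy = float(np.sum((cx - cxy) ** 2) * step)
    d_yx = float(np.sum((cy - cyx) ** 2) * step)
    return d_xy, d_yx


def _grid(values: np.ndarray, step: float, d_max: float | None) -> np.ndarray:
    if d_max is None:
        d_max = float(values.max())
    n_steps = int(np.ceil(d_max / step)) + 1
    return np.arange(n_steps + 1) * step  # 0, step, ..., >= d_max


def delta_c(
    dmatrix_pooled: DistanceMatrix,
    labels_x: Sequence[str],
    labels_y: Sequence[str],
    step: float = 0.01,
    d_max: float | None = None,
) -> tuple[float, float]:
    """Both reciprocal Cramer-von-Mises-type statistics (dC_XY, dC_YX)."""
    if step <= 0:
        raise LibshuffError("grid step must be positive")
    sx, sy = set(labels_x), set(labels_y)
    if sx & sy or (sx | sy) != set(dmatrix_pooled.labels):
        raise LibshuffError("labels_x and labels_y must partition the matrix")
    if len(sx) < 2 or len(sy) < 2:
        raise LibshuffError("each library needs at least 2 sequences")
    in_x = np.array([l in sx for l in dmatrix_pooled.labels])
    grid = _grid(dmatrix_pooled.values, step, d_max)
    return _delta_c_values(dmatrix_pooled.values, in_x, grid, step)


@dataclass(frozen=True)
class LibshuffResult:
    delta_c_xy: float
    delta_c_yx: float
    p_xy: float
    p_yx: float
    n_permutations: int
    seed: int
    alpha: float
    pairwise_alpha: float
    significant: bool
    step: float
    d_max: float
    library_x: str
    library_y: str
    statistic: str = "sum (C_X - C_XY)^2 * step over grid 0..d_max"


def libshuff_test(
    dmatrix_pooled: DistanceMatrix,
    labels: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    step: float = 0.01,
    d_max: float | None = None,
) -> LibshuffResult:
    """Two-library LIBSHUFF permutation test.

    ``labels`` maps each matrix label to one of exactly two library names.
    p-values use the add-one estimator (1 + #{permuted >= observed}) /
    (1 + n_permutations); the per-comparison threshold is the
    experiment-wise correction 1 - (1 - alpha)^(1/2) for the two
    reciprocal tests.
    """
    if n_permutations < 1:
        raise LibshuffError("need at least one permutation")
    libs = sorted(set(labels.values()))
    if len(libs) != 2:
        raise LibshuffError(f"need exactly 2 libraries, got {libs}")
    lib_x, lib_y = libs
    labels_x = [l for l in dmatrix_pooled.labels if labels[l] == lib_x]
    labels_y = [l for l in dmatrix_pooled.labels if labels[l] == lib_y]
    if len(labels_x) < 2 or len(labels_y) < 2:
        raise LibshuffError("each library needs at least 2 sequences")

    values = dmatrix_pooled.values
    if np.isnan(values).any():
        raise LibshuffError("distance matrix contains NaN")
    in_x = np.array([labels[l] == lib_x for l in dmatrix_pooled.labels])
    grid = _grid(values, step, d_max)
    obs_xy, obs_yx = _delta_c_values(values, in_x, grid, step)

    rng = np.random.default_rng(seed)
    n = len(in_x)
    n_x = int(in_x.sum())
    ge_xy = ge_yx = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_x, replace=False)] = True
        p_xy_stat, p_yx_stat = _delta_c_values(values, perm, grid, step)
        ge_xy += p_xy_stat >= obs_xy - 1e-15
        ge_yx += p_yx_stat >= obs_yx - 1e-15
    p_xy = (1 + ge_xy) / (1 + n_permutations)
    p_yx = (1 + ge_yx) / (1 + n_permutations)
    pairwise_alpha = 1.0 - (1.0 - alpha) ** 0.5
    return LibshuffResult(
        delta_c_xy=obs_xy,
        delta_c_yx=obs_yx,
        p_xy=p_xy,
        p_yx=p_yx,
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
        pairwise_alpha=pairwise_alpha,
        significant=min(p_xy, p_yx) < pairwise_alpha,
        step=step,
        d_max=float(grid[-1]),
        library_x=lib_x,
        library_y=lib_y,
    )
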