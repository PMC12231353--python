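"""Design of experiments over the discrete screw-angle grid.

The design space is 7 screws x 2 tilt axes, each axis restricted to a small
symmetric grid of angles: {-10, -5, 0, 5, 10}° for training designs and
{-10, 0, 10}° for the reduced full factorial, giving (5x5)^7 and 9^7 possible
configurations respectively.  Training designs are Latin Hypercube draws in
the 14-dimensional unit cube snapped to grid levels by equal-probability
binning; the full factorial is enumerated lexicographically in memory-bounded
batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .geometry import ANGLE_COLUMNS

__all__ = [
    "DesignGrid",
    "TRAINING_GRID",
    "FULLFACT_GRID",
    "count_configs",
    "lhs_design",
    "random_design",
    "split_dataset",
    "full_factorial",
    "design_frame",
]


@dataclass(frozen=True)
class DesignGrid:
    """Allowed angle levels per tilt axis, shared by all screws and axes."""

    levels_deg: tuple[float, ...]
    axes_per_screw: int = 2
    n_screws: int = 7

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels_deg)
        if list(levels) != sorted(set(levels)):
            raise ValueError("levels must be sorted and unique")
        if 0.0 not in levels:
            raise ValueError("levels must contain 0")
        if any(-v not in levels for v in levels):
            raise ValueError("levels must be symmetric about 0")
        object.__setattr__(self, "levels_deg", levels)

    @property
    def n_axes(self) -> int:
        return self.axes_per_screw * self.n_screws

    @property
    def n_levels(self) -> int:
        return len(self.levels_deg)


TRAINING_GRID = DesignGrid((-10.0, -5.0, 0.0, 5.0, 10.0))
FULLFACT_GRID = DesignGrid((-10.0, 0.0, 10.0))


def count_configs(grid: DesignGrid) -> int:
    """Exact number of configurations, as an arbitrary-precision integer."""
    return (grid.n_levels**grid.axes_per_screw) ** grid.n_screws


def design_frame(angles: np.ndarray) -> pd.DataFrame:
    """Wrap an (N, 14) angle array as a design table with standard columns."""
    angles = np.asarray(angles)
    if angles.ndim != 2 or angles.shape[1] != len(ANGLE_COLUMNS):
        raise ValueError("expected an (N, 14) angle array")
    return pd.DataFrame(angles, columns=list(ANGLE_COLUMNS))


def _snap(u: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Equal-probability binning of unit-cube coordinates to grid levels."""
    L = len(levels)
    idx = np.minimum((u * L).astype(int), L - 1)
    return levels[idx]


def lhs_design(
    n: int,
    grid: DesignGrid = TRAINING_GRID,
    seed: int | None = None,
    max_attempts_factor: int = 100,
) -> pd.DataFrame:
    """Latin Hypercube design snapped to the grid, deduplicated.

    Draws an n-point LHS in [0, 1)^14, maps each coordinate to its
    equal-probability level bin, and replaces exact duplicate rows with fresh
    LHS draws until n unique rows are collected (capped at
    ``max_attempts_factor * n`` total draws).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > count_configs(grid):
        raise ValueError("n exceeds the number of distinct configurations")
    levels = np.asarray(grid.levels_deg)
    sampler = qmc.LatinHypercube(d=grid.n_axes, seed=seed)
    rows = _snap(sampler.random(n), levels)
    seen: set[tuple] = set()
    unique: list[np.ndarray] = []
    drawn = n
    while True:
        for r in rows:
            key = tuple(r)
            if key not in seen:
                seen.add(key)
                unique.append(r)
                if len(unique) == n:
                    return design_frame(np.asarray(unique))
        deficit = n - len(unique)
        if drawn + deficit > max_attempts_factor * n:
            raise RuntimeError(
                f"could not collect {n} unique rows within {max_attempts_factor * n} draws"
            )
        rows = _snap(sampler.random(deficit), levels)
        drawn += deficit


def random_design(
    n: int, grid: DesignGrid = FULLFACT_GRID, seed: int | None = None
) -> pd.DataFrame:
    """Testing design on the reduced grid (same snapped-LHS machinery)."""
    return lhs_design(n, grid=grid, seed=seed)


def split_dataset(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random 80/10/10 partition into (train, validation, test).

    Validation and test sizes are round(n * fraction); the remainder goes to
    the training part.  The three parts are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(table)
    if n == 0:
        raise ValueError("table is empty")
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    n_train = n - n_val - n_test
    if n >= 10:
        for size, frac in ((n_train, fractions[0]), (n_val, fractions[1]), (n_test, fractions[2])):
            if frac > 0 and size == 0:
                raise ValueError("a split with positive fraction came out empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )
    return tuple(table.iloc[np.sort(p)].reset_index(drop=True) for p in parts)


def full_factorial(
    grid: DesignGrid = FULLFACT_GRID, batch_size: int = 100_000
) -> Iterator[np.ndarray]:
    """Stream every configuration exactly once, lexicographically.

    Yields (batch, 14) float arrays ordered lexicographically over
    (s6_dp, s6_ap, ..., s12_ap) with the lowest level first; memory use is
    bounded by ``batch_size``.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    levels = np.asarray(grid.levels_deg)
    total = count_configs(grid)
    shape = (grid.n_levels,) * grid.n_axes
    start = 0
    while start < total:
        stop = min(start + batch_size, total)
        lin = np.arange(start, stop, dtype=np.int64)
        idx = np.stack(np.unravel_index(lin, shape), axis=1)
        yield levels[idx]
        start = stop
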