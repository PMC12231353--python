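"""Reported statistics: regression quality, classification tables, Welch
t-tests, full-factorial heatmaps of per-screw strain variation, and
strain-range comparisons across designs.

The heatmap machinery streams over a full-factorial prediction set with
bounded memory: for every screw and every tip state it keeps exact
count/sum/sum-of-squares accumulators of the chosen output over the
non-colliding configurations sharing that state, from which the percent
variation from the neutral state and a Welch two-sample p-value against the
neutral group are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import DesignGrid
from .geometry import SCREW_IDS

__all__ = [
    "RegressionMetrics",
    "HeatmapCell",
    "regression_metrics",
    "classification_table",
    "welch_ttest",
    "welch_ttest_from_stats",
    "HeatmapAccumulator",
    "heatmap_variation",
    "strain_range_comparison",
    "plot_heatmap",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """R-squared, regression slope, RMSE (microstrain and % of range)."""

    r2: float
    slope: float
    rmse_ustrain: float
    rmse_pct: float


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """Prediction-quality metrics against observed values.

    ``r2`` is 1 - SS_res/SS_tot with residuals y_pred - y_true; ``slope`` is
    the OLS slope of y_pred regressed on y_true (with intercept);
    ``rmse_pct`` normalizes the RMSE by the observed range of y_true.
    """
    yt = np.asarray(y_true, dtype=float).reshape(-1)
    yp = np.asarray(y_pred, dtype=float).reshape(-1)
    if yt.shape != yp.shape or yt.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    res = yp - yt
    ss_res = float(res @ res)
    slope = float(np.cov(yt, yp, ddof=1)[0, 1] / np.var(yt, ddof=1))
    rmse = float(np.sqrt(np.mean(res**2)))
    rng = float(yt.max() - yt.min())
    return RegressionMetrics(1.0 - ss_res / ss_tot, slope, rmse, 100.0 * rmse / rng)


def classification_table(y_true, y_pred) -> tuple[float, float]:
    """(percent correct, percent error) of binary predictions."""
    yt = np.asarray(y_true).astype(int).reshape(-1)
    yp = np.asarray(y_pred).astype(int).reshape(-1)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("need equal-length non-empty binary vectors")
    pct_true = 100.0 * float(np.mean(yt == yp))
    return pct_true, 100.0 - pct_true


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns (t, Satterthwaite df, p).
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_ttest_from_stats(
    mean1: float, var1: float, n1: int, mean2: float, var2: float, n2: int
) -> tuple[float, float, float]:
    """Welch test from summary statistics (sample variances, ddof=1)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if var1 == 0 and var2 == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    res = sps.ttest_ind_from_stats(
        mean1, np.sqrt(var1), n1, mean2, np.sqrt(var2), n2, equal_var=False
    )
    sa, sb = var1 / n1, var2 / n2
    df = (sa + sb) ** 2 / (sa**2 / (n1 - 1) + sb**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# streamed heatmaps


@dataclass(frozen=True)
class HeatmapCell:
    """Per-screw, per-tip-state summary of a full-factorial exploration."""

    screw_id: int
    dp_deg: float
    ap_deg: float
    pct_variation: float
    p_value: float
    significant: bool
    n: int
    valid: bool = True


class HeatmapAccumulator:
    """Streaming per-(screw, tip-state) accumulators over prediction batches.

    Feed (angles, values, keep) batches; for every screw k and state (dp, ap)
    the accumulator tracks count, sum and sum of squares of ``values`` over
    kept rows in which screw k sits in that state.  One pass therefore yields
    the heatmaps of all seven screws at once.
    """

    def __init__(self, grid: DesignGrid):
        self.grid = grid
        L = grid.n_levels
        self.levels = np.asarray(grid.levels_deg)
        self.n_states = L * L
        self.n_screws = grid.n_screws
        self.count = np.zeros((self.n_screws, self.n_states), dtype=np.int64)
        self.total = np.zeros((self.n_screws, self.n_states))
        self.total_sq = np.zeros((self.n_screws, self.n_states))

    def update(self, angles: np.ndarray, values: np.ndarray, keep: np.ndarray) -> None:
        angles = np.asarray(angles, dtype=float)
        values = np.asarray(values, dtype=float).reshape(-1)
        keep = np.asarray(keep, dtype=bool).reshape(-1)
        if not np.any(keep):
            return
        A = angles[keep]
        v = values[keep]
        if A.shape[1] != 2 * self.n_screws:
            raise ValueError("angle batch width does not match the grid")
        L = self.grid.n_levels
        idx = np.searchsorted(self.levels, A)
        state = idx[:, 0::2] * L + idx[:, 1::2]  # (n, n_screws)
        for k in range(self.n_screws):
            s = state[:, k]
            self.count[k] += np.bincount(s, minlength=self.n_states)
            self.total[k] += np.bincount(s, weights=v, minlength=self.n_states)
            self.total_sq[k] += np.bincount(s, weights=v * v, minlength=self.n_states)

    def _group_stats(self, k: int, s: int) -> tuple[int, float, float]:
        n = int(self.count[k, s])
        if n == 0:
            return 0, np.nan, np.nan
        mean = self.total[k, s] / n
        var = (self.total_sq[k, s] - n * mean**2) / (n - 1) if n > 1 else 0.0
        return n, float(mean), float(max(var, 0.0))

    def cells(self, screw_id: int, alpha: float = 0.001) -> list[HeatmapCell]:
        """HeatmapCells of one screw: % variation from neutral + Welch p.

        ``screw_id`` is a plate screw id (6..12) on the standard seven-screw
        grid, or a 0-based screw index on reduced grids.
        """
        k = SCREW_IDS.index(screw_id) if self.n_screws == 7 else int(screw_id)
        L = self.grid.n_levels
        zero = int(np.searchsorted(self.levels, 0.0))
        s0 = zero * L + zero
        n0, m0, v0 = self._group_stats(k, s0)
        out: list[HeatmapCell] = []
        for di, dp in enumerate(self.levels):
            for ai, ap in enumerate(self.levels):
                s = di * L + ai
                n, m, v = self._group_stats(k, s)
                if s == s0:
                    out.append(HeatmapCell(screw_id, dp, ap, 0.0, 1.0, False, n))
                    continue
                if n == 0 or n0 == 0:
                    out.append(
                        HeatmapCell(screw_id, dp, ap, np.nan, np.nan, False, n, valid=False)
                    )
                    continue
                pct = 100.0 * (m - m0) / m0
                if n < 2 or n0 < 2 or (v == 0 and v0 == 0):
                    p = np.nan
                else:
                    _, _, p = welch_ttest_from_stats(m, v, n, m0, v0, n0)
                out.append(
                    HeatmapCell(screw_id, dp, ap, pct, p, bool(p < alpha), n)
                )
        return out

    def frame(self, alpha: float = 0.001) -> pd.DataFrame:
        """All screws' cells as a tidy table."""
        ids = SCREW_IDS if self.n_screws == 7 else range(self.n_screws)
        rows = [vars(c) for sid in ids for c in self.cells(sid, alpha=alpha)]
        return pd.DataFrame(rows)


def heatmap_variation(
    prediction_stream: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray]],
    screw_id: int,
    grid: DesignGrid,
    alpha: float = 0.001,
) -> list[HeatmapCell]:
    """One-screw heatmap from a stream of (angles, values, keep) batches.

    ``keep`` marks the non-colliding configurations to include.  For a
    multi-screw analysis prefer building one :class:`HeatmapAccumulator` and
    asking it for each screw's cells, which needs a single pass.
    """
    acc = HeatmapAccumulator(grid)
    for angles, values, keep in prediction_stream:
        acc.update(angles, values, keep)
    return acc.cells(screw_id, alpha=alpha)


# ---------------------------------------------------------------------------
# strain-range comparison (training sets vs full factorial)


def strain_range_comparison(
    tables: Mapping[str, pd.DataFrame],
    output_key: str,
    reference: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-design summary of an output plus Welch tests vs a reference design.

    For each named table: min, max, range and quartiles of ``output_key``;
    plus the two-sided Welch p-value against the reference table (the
    reference row reports p = 1).
    """
    if len(tables) < 2:
        raise ValueError("need at least two named tables")
    if reference not in tables:
        raise ValueError(f"reference table {reference!r} not given")
    for name, tab in tables.items():
        if output_key not in tab.columns:
            raise KeyError(f"table {name!r} lacks column {output_key!r}")
    ref = tables[reference][output_key].to_numpy(dtype=float)
    rows = []
    for name, tab in tables.items():
        v = tab[output_key].to_numpy(dtype=float)
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        if name == reference:
            p = 1.0
        else:
            _, _, p = welch_ttest(v, ref)
        rows.append(
            {
                "design": name,
                "n": v.size,
                "min": v.min(),
                "q1": q1,
                "median": q2,
                "q3": q3,
                "max": v.max(),
                "range": v.max() - v.min(),
                "p_vs_reference": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def plot_heatmap(cells: Sequence[HeatmapCell], path: str, title: str = "") -> None:
    """Render one screw's cells as a dp x ap heatmap PNG (stars mark
    significance at the alpha used to build the cells)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dps = sorted({c.dp_deg for c in cells})
    aps = sorted({c.ap_deg for c in cells})
    M = np.full((len(dps), len(aps)), np.nan)
    for c in cells:
        M[dps.index(c.dp_deg), aps.index(c.ap_deg)] = c.pct_variation
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(M, origin="lower", cmap="RdBu_r", aspect="auto")
    for c in cells:
        if c.significant:
            ax.text(
                aps.index(c.ap_deg), dps.index(c.dp_deg), "*", ha="center", va="center"
            )
    ax.set_xticks(range(len(aps)), [f"{a:g}" for a in aps])
    ax.set_yticks(range(len(dps)), [f"{d:g}" for d in dps])
    ax.set_xlabel("anterior(+)/posterior(-) tilt [deg]")
    ax.set_ylabel("proximal(+)/distal(-) tilt [deg]")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% strain variation vs neutral")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
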