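"""LOESS smoothing of per-feature RMS against mean log2 expression.

Classical locally-weighted polynomial regression: at each evaluation point
the ``ceil(span * n)`` nearest neighbours on the x-axis are fit with a
degree-1 or degree-2 polynomial under tricube weights
``w = (1 - (d / d_max)^3)^3`` and the local fit is evaluated at the point.
One curve per variance source, all on a common expression grid, makes the
sources directly comparable pointwise — the central readout of the
platform comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NCompareError
from .anova import anova_sources

#: Plot colors per variance source, matching the comparison figures' legend
#: (biology blue, prep/prep+scanner red, other technical sources green,
#: residual black).
SOURCE_COLORS = {
    "B": "tab:blue",
    "P": "tab:red",
    "PS": "tab:red",
    "S": "tab:green",
    "Cart": "tab:green",
    "T": "tab:green",
    "residual": "black",
}


@dataclass
class TrendCurve:
    """A smoothed RMS-vs-expression curve for one variance source."""

    source: str
    grid_x: np.ndarray
    smoothed_y: np.ndarray
    span: float
    degree: int

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.smoothed_y = np.asarray(self.smoothed_y, dtype=float)
        if len(self.grid_x) != len(self.smoothed_y):
            raise NCompareError("grid_x and smoothed_y lengths differ")
        if len(self.grid_x) > 1 and not (np.diff(self.grid_x) > 0).all():
            raise NCompareError("grid_x must be strictly increasing")
        if not np.isfinite(self.smoothed_y).all():
            raise NCompareError(f"curve {self.source!r}: non-finite smoothed values")


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, k: int, degree: int) -> float:
    d = np.abs(x - x0)
    window = np.argpartition(d, k - 1)[:k]
    xw, yw, dw = x[window], y[window], d[window]
    dmax = dw.max()
    if dmax == 0:
        return float(yw.mean())
    w = (1.0 - (dw / dmax) ** 3) ** 3
    if (w > 0).sum() <= degree:  # boundary guard: too few carrying points
        w = np.ones_like(w)
    sw = np.sqrt(w)
    X = np.vander(xw - x0, N=degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
    return float(beta[0])


def loess_fit(x, y, span: float = 0.75, degree: int = 2,
              grid=None, source: str = "y") -> TrendCurve:
    """Smooth ``y`` against ``x`` and evaluate on ``grid``.

    ``span`` is the fraction of points in each local window (0 < span <= 1);
    ``degree`` the local polynomial degree (1 or 2).  ``grid`` defaults to
    the sorted unique x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NCompareError("x and y must be equal-length 1-d arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise NCompareError("non-finite values in LOESS input")
    if not 0 < span <= 1:
        raise NCompareError(f"span must be in (0, 1], got {span}")
    if degree not in (1, 2):
        raise NCompareError(f"degree must be 1 or 2, got {degree}")
    n = len(x)
    required = max(10, math.ceil(degree * 3 / span))
    if n < required:
        raise NCompareError(f"LOESS needs >= {required} points for span={span}, "
                            f"degree={degree}; got {n}")
    k = max(degree + 1, math.ceil(span * n))
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    smoothed = np.array([_local_fit(x, y, g, k, degree) for g in grid])
    return TrendCurve(source=source, grid_x=grid, smoothed_y=smoothed,
                      span=span, degree=degree)


def default_grid(mean_expression, n_points: int = 100,
                 trim_fraction: float = 0.98) -> np.ndarray:
    """Equispaced grid over the central ``trim_fraction`` of expression.

    Trimming the extreme tails avoids boundary windows supported by a
    handful of features; conclusions are drawn over the well-populated
    medium-high range anyway.
    """
    me = np.asarray(mean_expression, dtype=float)
    lo_q = (1.0 - trim_fraction) / 2.0
    lo, hi = np.quantile(me, [lo_q, 1.0 - lo_q])
    return np.linspace(lo, hi, n_points)


def curves_for_model(anova_table: pd.DataFrame, span: float = 0.75, degree: int = 2,
                     grid_points: int = 100, trim_fraction: float = 0.98) -> list[TrendCurve]:
    """One LOESS curve per variance source of a decomposition table.

    All curves share a common grid over the central part of the
    mean-expression range, so their values are comparable pointwise.
    """
    if len(anova_table) == 0:
        raise NCompareError("empty decomposition table")
    x = anova_table["mean_expression"].to_numpy()
    grid = default_grid(x, grid_points, trim_fraction)
    curves = []
    for source in anova_sources(anova_table):
        y = anova_table[f"rms_{source}"].to_numpy()
        curves.append(loess_fit(x, y, span=span, degree=degree, grid=grid, source=source))
    return curves


def export_curves(curves: list[TrendCurve], out: str | Path,
                  plot: bool = True) -> dict[str, Path]:
    """Write curves as a TSV (grid + one column per source) and a plot."""
    if not curves:
        raise NCompareError("no curves to export")
    grid = curves[0].grid_x
    for c in curves[1:]:
        if len(c.grid_x) != len(grid) or not np.allclose(c.grid_x, grid):
            raise NCompareError("curves do not share a common grid")
    out = Path(out)
    table = pd.DataFrame({"mean_log2_expression": grid})
    for c in curves:
        table[c.source] = c.smoothed_y
    tsv_path = out.with_suffix(".tsv")
    table.to_csv(tsv_path, sep="\t", index=False)
    paths = {"tsv": tsv_path}
    if plot:
        png_path = out.with_suffix(".png")
        _plot_curves(curves, png_path)
        paths["plot"] = png_path
    return paths


def _plot_curves(curves: list[TrendCurve], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for c in curves:
        ax.plot(c.grid_x, c.smoothed_y, label=c.source,
                color=SOURCE_COLORS.get(c.source, None), lw=1.8)
    ax.set_xlabel("mean log2 expression")
    ax.set_ylabel("RMS (log2 units)")
    ax.legend(title="source")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
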