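"""Bivariate density analysis of indicator pairs over fruit-growing cells.

Reproduces the CP-GDH / CP-SFPO relationship machinery: trim each margin
to its [q5, q95] band, min-max scale to the unit square, smooth with an
isotropic Gaussian kernel of bandwidth 0.1 (scaled units), normalize the
surface by its maximum so densities land in [0, 1], and summarize with
Spearman correlation and quartile statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientSampleError


def q5q95_filter(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Keep pairs inside the marginal [q5, q95] band of both variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientSampleError("x and y must pair up")
    if x.size < 20:
        raise InsufficientSampleError("q5-q95 filtering needs at least 20 pairs")
    x_lo, x_hi = np.quantile(x, [0.05, 0.95])
    y_lo, y_hi = np.quantile(y, [0.05, 0.95])
    keep = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    return x[keep], y[keep]


@dataclass
class DensitySurface:
    """Max-normalized KDE surface on a regular grid in data units."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray  # (ny, nx), max = 1
    bandwidth: float
    integral: float  # of the unnormalized density over the plane


def _minmax_scale(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo
    if span == 0:
        return np.zeros_like(v), lo, 1.0
    return (v - lo) / span, lo, span


def kde2d(x, y, bandwidth: float = 0.1, grid_size: int = 101) -> DensitySurface:
    """2-D Gaussian KDE on min-max-scaled pairs, normalized to [0, 1].

    The bandwidth is the kernel standard deviation in scaled units, so
    "0.1" means one tenth of each variable's range. A degenerate sample
    (all pairs identical) yields a single-peak surface.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise InsufficientSampleError("kde2d needs at least 2 paired points")
    xs, x0, xspan = _minmax_scale(x)
    ys, y0, yspan = _minmax_scale(y)
    pad = 3.0 * bandwidth
    u = np.linspace(-pad, 1.0 + pad, grid_size)
    v = np.linspace(-pad, 1.0 + pad, grid_size)
    uu = u[None, :, None]  # broadcast: (1, nx, n)
    vv = v[:, None, None]
    du = (uu - xs[None, None, :]) / bandwidth
    dv = (vv - ys[None, None, :]) / bandwidth
    dens = np.exp(-0.5 * (du**2 + dv**2)).sum(axis=2) / (
        x.size * 2.0 * np.pi * bandwidth**2
    )
    step = (u[1] - u[0]) * (v[1] - v[0])
    integral = float(dens.sum() * step)
    peak = float(dens.max())
    return DensitySurface(
        x_grid=x0 + u * xspan,
        y_grid=y0 + v * yspan,
        density=dens / peak,
        bandwidth=bandwidth,
        integral=integral,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-rank ties.

    Returns NaN (the undefined flag) when either margin is constant —
    e.g. when frost probability collapses to zero everywhere.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InsufficientSampleError("spearman_rho needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def quartile_summary(values) -> tuple[float, float, float, float]:
    """(q1, q2, q3, IQR) with linear-rank interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientSampleError("quartile summary needs at least 4 values")
    q1, q2, q3 = np.quantile(v, [0.25, 0.50, 0.75], method="linear")
    return float(q1), float(q2), float(q3), float(q3 - q1)
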