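"""Minimal plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .density import DensitySurface  # noqa: E402


def plot_density_surface(surface: DensitySurface, ax=None, levels=10):
    """Filled-contour view of a normalized bivariate density surface."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(
        surface.x_grid, surface.y_grid, surface.density, levels=levels, cmap="viridis"
    )
    ax.figure.colorbar(cs, ax=ax, label="relative density")
    return ax
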