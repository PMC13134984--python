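"""Grid definitions for the synthetic study region.

Cells live on a regular lon/lat lattice (row-major order, longitude varying
fastest) so that a coarse "climate model" grid can be taken as every k-th
cell per axis and bilinear regridding between the two is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidGridError


@dataclass
class GridDefinition:
    """A set of grid cells with coordinates, elevation and land-use flags.

    ``nx``/``ny`` record the underlying lattice shape when the cells form a
    complete regular lattice (needed for coarsening and regridding); they
    are ``None`` for irregular cell collections.
    """

    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    elevation: np.ndarray
    fruit_area: np.ndarray
    region: np.ndarray
    nx: int | None = None
    ny: int | None = None

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=int)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.fruit_area = np.asarray(self.fruit_area, dtype=bool)
        self.region = np.asarray(self.region, dtype=object)
        if len(np.unique(self.cell_id)) != self.n_cells:
            raise InvalidArgumentError("cell ids must be unique")
        if np.any(np.abs(self.lat) > 90):
            raise InvalidArgumentError("latitude outside [-90, 90]")
        if np.any(self.elevation < -100):
            raise InvalidArgumentError("elevation below -100 m")

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    def is_lattice(self) -> bool:
        return self.nx is not None and self.ny is not None and self.nx * self.ny == self.n_cells

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "lon": self.lon,
                "lat": self.lat,
                "elevation": self.elevation,
                "fruit_area": self.fruit_area,
                "region": self.region,
            }
        )


def make_grid(
    n_cells: int,
    lat_range: tuple[float, float] = (40.0, 42.5),
    elev_range: tuple[float, float] = (150.0, 1500.0),
    fruit_fraction: float = 0.3,
    seed: int = 0,
    lon_range: tuple[float, float] = (-2.0, 0.5),
) -> GridDefinition:
    """Build a reproducible regular grid of ``n_cells`` cells.

    Cells sit on an approximately square lon/lat lattice spanning the given
    ranges. Elevation mixes a south-north gradient with seeded noise;
    roughly ``fruit_fraction`` of cells are flagged as fruit-growing area;
    the region label splits cells east/west at the median longitude.
    """
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    if not 0 <= fruit_fraction <= 1:
        raise InvalidArgumentError("fruit_fraction must be in [0, 1]")
    if lat_range[1] < lat_range[0] or elev_range[1] < elev_range[0]:
        raise InvalidArgumentError("empty lat_range or elev_range")
    if lon_range[1] < lon_range[0]:
        raise InvalidArgumentError("empty lon_range")

    nx = int(np.ceil(np.sqrt(n_cells)))
    ny = int(np.ceil(n_cells / nx))
    lon_axis = (
        np.linspace(lon_range[0], lon_range[1], nx)
        if nx > 1
        else np.array([np.mean(lon_range)])
    )
    lat_axis = (
        np.linspace(lat_range[0], lat_range[1], ny)
        if ny > 1
        else np.array([np.mean(lat_range)])
    )
    iy, ix = np.divmod(np.arange(n_cells), nx)
    lon = lon_axis[ix]
    lat = lat_axis[iy]

    rng = np.random.default_rng(seed)
    lat_norm = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-12)
    frac = np.clip(0.65 * lat_norm + 0.35 * rng.random(n_cells), 0.0, 1.0)
    elevation = elev_range[0] + frac * (elev_range[1] - elev_range[0])
    fruit_area = rng.random(n_cells) < fruit_fraction
    region = np.where(lon >= np.median(lon), "east", "west").astype(object)

    lattice = nx * ny == n_cells
    return GridDefinition(
        cell_id=np.arange(n_cells),
        lon=lon,
        lat=lat,
        elevation=elevation,
        fruit_area=fruit_area,
        region=region,
        nx=nx if lattice else None,
        ny=ny if lattice else None,
    )


def coarsen(grid: GridDefinition, k: int = 5) -> GridDefinition:
    """Every k-th lattice cell per axis, emulating a coarse model grid."""
    if not grid.is_lattice():
        raise InvalidGridError("coarsening requires a complete regular lattice")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    nx, ny = grid.nx, grid.ny
    ix_sel = np.arange(0, nx, k)
    iy_sel = np.arange(0, ny, k)
    if len(ix_sel) < 2 or len(iy_sel) < 2:
        raise InvalidGridError("coarse grid needs at least 2x2 nodes")
    idx = (iy_sel[:, None] * nx + ix_sel[None, :]).ravel()
    return GridDefinition(
        cell_id=grid.cell_id[idx],
        lon=grid.lon[idx],
        lat=grid.lat[idx],
        elevation=grid.elevation[idx],
        fruit_area=grid.fruit_area[idx],
        region=grid.region[idx],
        nx=len(ix_sel),
        ny=len(iy_sel),
    )
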