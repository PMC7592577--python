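"""Shared raster geometry, utilization-distribution grids and 95% regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "UDGrid", "RegionMask", "isopleth_region", "make_grid"]


class GridError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Planar raster geometry; row 0 is the southmost row, cell centres at
    origin + (index + 0.5) * cell_size."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def contains(self, x: np.ndarray, y: np.ndarray, padding: float = 0.0) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return bool(
            np.all(x >= xmin + padding)
            and np.all(x <= xmax - padding)
            and np.all(y >= ymin + padding)
            and np.all(y <= ymax - padding)
        )


def make_grid(
    x: np.ndarray,
    y: np.ndarray,
    cell_size: float,
    padding: float,
) -> GridSpec:
    """Grid covering the data bounding box with the requested padding."""
    if cell_size <= 0:
        raise ParameterError("cell_size must be positive")
    xmin = float(np.min(x)) - padding
    xmax = float(np.max(x)) + padding
    ymin = float(np.min(y)) - padding
    ymax = float(np.max(y)) + padding
    n_cols = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    n_rows = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    return GridSpec(xmin, ymin, cell_size, n_rows, n_cols)


@dataclass
class UDGrid:
    """Gridded utilization/occurrence distribution; masses sum to 1."""

    grid: GridSpec
    masses: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.grid.n_rows, self.grid.n_cols):
            raise GridError("mass array shape does not match grid")
        if np.any(self.masses < 0):
            raise GridError("cell masses must be nonnegative")
        total = self.masses.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise GridError(f"cell masses must sum to 1, got {total}")


@dataclass
class RegionMask:
    """A space-use region at a given UD level (default 95%).

    Holds a boolean raster mask on a shared grid and/or a shapely polygon;
    ``converged`` is always True except for KDE LSCV fits whose score
    minimum fell on the candidate boundary.
    """

    method: str
    level: float = 0.95
    grid: GridSpec | None = None
    mask: np.ndarray | None = field(default=None, repr=False)
    polygon: object | None = field(default=None, repr=False)
    area: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.level <= 1.0):
            raise ParameterError("level must lie in (0, 1]")
        if self.area < 0:
            raise ParameterError("area must be nonnegative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def rasterize(self, grid: GridSpec) -> "RegionMask":
        """Return a copy with a boolean mask on ``grid`` (cell-centre test).

        Polygon-backed regions (MCP) are rasterized by testing whether each
        cell centre falls inside the polygon; mask-backed regions must
        already live on the target grid.
        """
        if self.mask is not None:
            if self.grid != grid:
                raise GridError("mask-backed region lives on a different grid")
            return self
        if self.polygon is None:
            raise GridError("region has neither mask nor polygon")
        import shapely

        xc = grid.x_centers()
        yc = grid.y_centers()
        xx, yy = np.meshgrid(xc, yc)
        inside = shapely.contains_xy(self.polygon, xx.ravel(), yy.ravel())
        mask = inside.reshape(grid.n_rows, grid.n_cols)
        return RegionMask(
            method=self.method,
            level=self.level,
            grid=grid,
            mask=mask,
            polygon=self.polygon,
            area=float(mask.sum()) * grid.cell_area,
            converged=self.converged,
        )


def isopleth_region(ud: UDGrid, level: float = 0.95, method_label: str = "UD") -> RegionMask:
    """Smallest cell set whose cumulative mass reaches ``level``.

    Cells are taken in descending mass order; ties are broken by row-major
    cell index (stable sort), and the cumulative sum stops at the first
    cell where it reaches the level.
    """
    if not (0.0 < level <= 1.0):
        raise ParameterError("level must lie in (0, 1]")
    flat = ud.masses.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    # first index whose cumulative mass >= level (tolerate float round-off)
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.masses.shape)
    return RegionMask(
        method=method_label,
        level=level,
        grid=ud.grid,
        mask=mask,
        area=float(k) * ud.grid.cell_area,
    )
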