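"""Core spatial primitives: grid geometry and in-memory rasters.

All rasters in the package share one planar convention: the grid origin is
the top-left corner, x grows east and y grows north (both in metres), and a
cell ``(row, col)`` is sampled at its centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "RasterGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two rasters do not share the same grid geometry."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    The centre of cell ``(r, c)`` is located at
    ``(origin_x + (c + 0.5) * resolution, origin_y - (r + 0.5) * resolution)``.
    """

    n_rows: int
    n_cols: int
    resolution: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        """Extent along x, in metres."""
        return self.n_cols * self.resolution

    @property
    def height(self) -> float:
        """Extent along y, in metres."""
        return self.n_rows * self.resolution

    def cell_center(self, row, col):
        """World coordinates of one or many cell centres."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.resolution
        y = self.origin_y - (row + 0.5) * self.resolution
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (x, y) coordinate arrays, each of shape ``(n_rows, n_cols)``."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def index_of(self, x, y):
        """Grid indices of the cells containing world points (x, y).

        Raises :class:`ValueError` for points outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.resolution).astype(int)
        row = np.floor((self.origin_y - y) / self.resolution).astype(int)
        out = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        if np.any(out):
            raise ValueError("point(s) outside the raster extent")
        return row, col


@dataclass
class RasterGrid:
    """A 2D field of values (continuous or categorical) on a :class:`GridSpec`.

    ``nodata`` cells (NaN for float rasters, or equal to ``nodata_value``)
    are excluded from statistics by all operations in this package.
    """

    spec: GridSpec
    values: np.ndarray
    nodata_value: float | None = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        mask = np.ones(self.values.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        if self.nodata_value is not None:
            mask &= self.values != self.nodata_value
        return mask

    def like(self, values: np.ndarray, name: str = "") -> "RasterGrid":
        """New raster on the same grid with different values."""
        return RasterGrid(self.spec, values, nodata_value=None, name=name or self.name)

    def sample(self, x, y):
        """Values at world coordinates (nearest cell)."""
        row, col = self.spec.index_of(x, y)
        return self.values[row, col]


def require_same_grid(*rasters: RasterGrid) -> GridSpec:
    """Assert that all rasters share one GridSpec and return it."""
    spec = rasters[0].spec
    for r in rasters[1:]:
        if r.spec != spec:
            raise GridMismatchError(f"grid mismatch: {r.spec} != {spec}")
    return spec
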