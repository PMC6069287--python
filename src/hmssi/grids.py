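"""North-up pixel grids with an affine-style geotransform.

The pixel model is cell-centre registered, row/col 0-based, with
half-open cell intervals [left, right) x [top, bottom): a point on the
shared left/top edge of two cells belongs to the cell to the right/below
it. Rows increase southward (decreasing y), columns eastward.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import PlotOutOfBoundsError, ResolutionError

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a north-up raster grid.

    Parameters
    ----------
    rows, cols
        Grid shape.
    x0, y0
        Map coordinates of the *outer top-left corner* of pixel (0, 0).
    resolution
        Pixel size in map units (square pixels, >0).
    crs
        Coordinate reference system identifier, e.g. ``"EPSG:32649"``.
    """

    rows: int
    cols: int
    x0: float
    y0: float
    resolution: float
    crs: str = "EPSG:32649"

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.resolution > 0):
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer envelope."""
        return (
            self.x0,
            self.y0 - self.rows * self.resolution,
            self.x0 + self.cols * self.resolution,
            self.y0,
        )

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-extent test under the half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) of the containing cell.

        Half-open cells: left/top edges inclusive, right/bottom exclusive.
        Points outside the extent raise :class:`PlotOutOfBoundsError`.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.nonzero(~np.atleast_1d(inside))[0]
            raise PlotOutOfBoundsError(bad)
        col = np.floor((x - self.x0) / self.resolution).astype(int)
        row = np.floor((self.y0 - y) / self.resolution).astype(int)
        # y exactly on the top edge of the grid maps into row 0 (top inclusive);
        # the floor above would land at -0.0 -> 0 already, but a point exactly on
        # an interior horizontal edge belongs to the cell *below* per [top, bottom)
        # with y decreasing, which floor((y0 - y)/res) delivers.
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.resolution
        y = self.y0 - (row + 0.5) * self.resolution
        return x, y

    def with_resolution(self, resolution: float) -> "GridGeometry":
        """Geometry of the same envelope at a new resolution.

        The new resolution must divide or be divided by the current one by
        an integer factor so the envelope is tiled exactly.
        """
        factor = self.resolution / resolution
        if factor >= 1:
            k = round(factor)
            ok = abs(factor - k) < 1e-9
            rows, cols = self.rows * k, self.cols * k
        else:
            k = round(1 / factor)
            ok = abs(1 / factor - k) < 1e-9 and self.rows % k == 0 and self.cols % k == 0
            rows, cols = self.rows // k, self.cols // k
        if not ok:
            raise ResolutionError(
                f"cannot retile {self.resolution} m grid at {resolution} m: non-integer factor"
            )
        return replace(self, rows=rows, cols=cols, resolution=resolution)

    def almost_equals(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )
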