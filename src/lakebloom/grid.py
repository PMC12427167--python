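"""Affine grid georeferencing for axis-aligned raster grids.

The transform follows the GeoTIFF/GDAL convention: the origin ``(c, f)`` is
the outer corner of the upper-left pixel, ``a`` is the pixel width (east
positive) and ``e`` the pixel height (negative for north-up grids).  World
coordinates of a pixel ``(row, col)``::

    x = c + a * col + b * row
    y = f + d * col + e * row

Only rectilinear (``b == d == 0``) grids are supported, which covers every
product this package reads or writes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTransform", "regrid_nearest"]


@dataclass(frozen=True)
class GridTransform:
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, pixel_size: float) -> "GridTransform":
        """North-up grid with square pixels anchored at its upper-left corner."""
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        return cls(pixel_size, 0.0, west, 0.0, -pixel_size, north)

    def __post_init__(self) -> None:
        if self.b != 0.0 or self.d != 0.0:
            raise ValueError("rotated/sheared grids are not supported")
        if self.a == 0.0 or self.e == 0.0:
            raise ValueError("degenerate transform")

    @property
    def pixel_area(self) -> float:
        """Ground area of one pixel, |a*e - b*d| (m^2 in a metric CRS)."""
        return abs(self.a * self.e - self.b * self.d)

    @property
    def pixel_size(self) -> float:
        if abs(abs(self.a) - abs(self.e)) > 1e-9 * abs(self.a):
            raise ValueError("pixels are not square")
        return abs(self.a)

    def xy(self, row, col, offset: str = "center"):
        """World coordinates of pixel indices (vectorised)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        shift = 0.5 if offset == "center" else 0.0
        x = self.c + self.a * (col + shift)
        y = self.f + self.e * (row + shift)
        return x, y

    def rowcol(self, x, y):
        """Fractional pixel indices of world coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.c) / self.a
        row = (y - self.f) / self.e
        return row, col

    def cell_centers(self, shape: tuple[int, int]):
        """(xs, ys) center coordinate vectors for a (rows, cols) grid."""
        rows, cols = shape
        xs = self.c + self.a * (np.arange(cols) + 0.5)
        ys = self.f + self.e * (np.arange(rows) + 0.5)
        return xs, ys

    def almost_equals(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return all(
            abs(getattr(self, k) - getattr(other, k)) <= tol
            for k in ("a", "b", "c", "d", "e", "f")
        )


def regrid_nearest(
    values: np.ndarray,
    src_transform: GridTransform,
    dst_transform: GridTransform,
    dst_shape: tuple[int, int],
    fill: float = np.nan,
) -> np.ndarray:
    """Nearest-neighbour resampling of a single-band grid onto a target grid.

    Destination cells whose centers fall outside the source extent are set
    to ``fill``.
    """
    xs, ys = dst_transform.cell_centers(dst_shape)
    xg, yg = np.meshgrid(xs, ys)
    row, col = src_transform.rowcol(xg, yg)
    ri = np.floor(row).astype(int)
    ci = np.floor(col).astype(int)
    out = np.full(dst_shape, fill, dtype=float)
    ok = (ri >= 0) & (ri < values.shape[0]) & (ci >= 0) & (ci < values.shape[1])
    out[ok] = values[ri[ok], ci[ok]]
    return out
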