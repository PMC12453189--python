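"""Gridded covariate handling.

Rasters are square-celled grids in the package's projected (equal-area)
coordinate system.  On disk they are plain-text ESRI ASCII grids (``.asc``),
which every GIS reads and which keep fixtures human-inspectable.

The three covariates consumed by the persistence model are
habitat suitability (unitless, [0,1]), mean winter precipitation (mm,
rescaled to [0,1] before zonal averaging), and surface imperviousness
(fraction, [0,1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class DegenerateScalingError(ValueError):
    """Raised when min-max scaling is requested for constant input."""


@dataclass
class Raster:
    """A single-band grid.

    ``values`` is (nrows, ncols), row 0 at the *top* (largest y).  ``x0``/``y0``
    are the coordinates of the lower-left corner of the grid; ``cell`` the cell
    size in meters.  ``nodata`` cells are represented as NaN in memory.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    nodata: float = -9999.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: xs (ncols,), ys (nrows,), ys aligned with row order."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        # row 0 is the top row
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return xs, ys

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(np.asarray(values, dtype=float), self.x0, self.y0, self.cell, self.nodata, self.units)

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path: str | Path) -> None:
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    meta[parts[0].lower()] = float(parts[1])
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value", -9999.0)
        vals = np.where(vals == nodata, np.nan, vals)
        r = cls(vals, meta["xllcorner"], meta["yllcorner"], meta["cellsize"], nodata)
        if r.nrows != int(meta["nrows"]) or r.ncols != int(meta["ncols"]):
            raise ValueError(f"grid shape {vals.shape} disagrees with header in {path}")
        return r


def winter_precip_mean(
    monthly: Mapping[tuple[int, int], Raster],
    year_range: tuple[int, int],
    months: Iterable[int] = (12, 1, 2),
) -> Raster:
    """Per-cell mean of monthly precipitation over all winters in ``year_range``.

    A winter labeled ``y`` comprises December of ``y - 1`` and January/February
    of ``y``; ``year_range`` is inclusive on both ends.  Raises ``KeyError``
    naming the first missing (year, month) grid.
    """
    y_lo, y_hi = year_range
    stack: list[np.ndarray] = []
    ref: Raster | None = None
    for y in range(y_lo, y_hi + 1):
        for m in months:
            key = (y - 1, m) if m == 12 else (y, m)
            if key not in monthly:
                raise KeyError(f"missing monthly precipitation grid for year={key[0]} month={key[1]}")
            r = monthly[key]
            if ref is None:
                ref = r
            elif r.values.shape != ref.values.shape:
                raise ValueError("monthly grids have inconsistent shapes")
            stack.append(r.values)
    assert ref is not None
    out = ref.copy_with(np.nanmean(np.stack(stack, axis=0), axis=0))
    out.units = "mm"
    return out


def scale_01(x):
    """Min-max rescale to [0,1]: (x - min) / (max - min), NaN-aware.

    Works on a :class:`Raster` or any array-like.  Constant input (no spread)
    raises :class:`DegenerateScalingError`.
    """
    if isinstance(x, Raster):
        return x.copy_with(scale_01(x.values))
    arr = np.asarray(x, dtype=float)
    lo = np.nanmin(arr)
    hi = np.nanmax(arr)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
        raise DegenerateScalingError("input has no spread; cannot rescale to [0,1]")
    return (arr - lo) / (hi - lo)
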