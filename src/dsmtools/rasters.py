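"""Covariate rasters and plain-text grid I/O.

Environmental covariates (Depth, Slope, DFC, DF200, SST, CHL) arrive as
gridded fields.  Static variables are a single grid; dynamic variables (SST,
CHL) come as a stack of 8-day composites, each carrying its validity window.
Grids are stored as ESRI ASCII rasters (``.asc``) — a self-describing text
format — with the time window encoded in the file name as
``<name>_<start>_<end>.asc`` (ISO dates, end-exclusive... see `window`).

Lookup is nearest-cell with half-open cell intervals ``[edge, edge + Δ)`` so
a point on a cell boundary belongs unambiguously to one cell; there is no
interpolation, matching the semantics of gridded composite products.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CovariateRaster", "RasterStack", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0
_WINDOW_RE = re.compile(r"^(?P<name>.+?)_(?P<start>\d{4}-\d{2}-\d{2})_(?P<end>\d{4}-\d{2}-\d{2})$")


@dataclass
class CovariateRaster:
    """A rectangular grid of one covariate in projected metres.

    ``values`` is (nrows, ncols) with row 0 the *northernmost* row (the ESRI
    ASCII convention); ``x0, y0`` are the lower-left corner, ``cell`` the
    square cell size.  Missing cells are NaN.  ``window`` is an optional
    (start, end) date pair for 8-day composites, closed at both ends.
    """

    name: str
    x0: float
    y0: float
    cell: float
    values: np.ndarray
    window: tuple[dt.date, dt.date] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.window is not None and self.window[0] > self.window[1]:
            raise ValueError("raster window start after end")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def covers(self, date: dt.date | None) -> bool:
        if self.window is None:
            return True
        if date is None:
            return False
        return self.window[0] <= date <= self.window[1]

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell (containing-cell) lookup; NaN outside the extent.

        Cells are half-open: a point on the shared edge of two cells belongs
        to the cell whose lower edge it sits on.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell).astype(int)
        row = self.nrows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        return out


def write_ascii_grid(raster: CovariateRaster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid; the window, if any, goes into the file name."""
    path = Path(path)
    if raster.window is not None and not _WINDOW_RE.match(path.stem):
        path = path.with_name(
            f"{path.stem}_{raster.window[0].isoformat()}_{raster.window[1].isoformat()}{path.suffix}"
        )
    vals = np.where(np.isnan(raster.values), _NODATA, raster.values)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {raster.y0!r}\n"
        f"cellsize {raster.cell!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.7g")
    return path


def read_ascii_grid(path: str | Path, name: str | None = None) -> CovariateRaster:
    """Read an ESRI ASCII grid, recovering any time window from the file name."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path.name}: grid is {vals.shape}, header says "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    window = None
    stem = path.stem
    m = _WINDOW_RE.match(stem)
    if m:
        stem = m.group("name")
        window = (
            dt.date.fromisoformat(m.group("start")),
            dt.date.fromisoformat(m.group("end")),
        )
    return CovariateRaster(
        name=name or stem,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        values=vals,
        window=window,
    )


@dataclass
class RasterStack:
    """All composites of all covariates, keyed by covariate name."""

    rasters: dict[str, list[CovariateRaster]] = field(default_factory=dict)

    def add(self, raster: CovariateRaster) -> None:
        self.rasters.setdefault(raster.name, []).append(raster)

    @classmethod
    def from_dir(cls, directory: str | Path, pattern: str = "*.asc") -> "RasterStack":
        stack = cls()
        for path in sorted(Path(directory).glob(pattern)):
            stack.add(read_ascii_grid(path))
        if not stack.rasters:
            raise FileNotFoundError(f"no {pattern} rasters under {directory}")
        return stack

    @property
    def names(self) -> list[str]:
        return sorted(self.rasters)

    def select(self, name: str, date: dt.date | None):
        """The composite of ``name`` whose window contains ``date`` (or the
        static grid).  None if no composite covers the date."""
        if name not in self.rasters:
            raise KeyError(f"no raster named {name!r}; have {self.names}")
        for r in self.rasters[name]:
            if r.covers(date):
                return r
        return None
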