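"""Georeferenced grid container and ESRI ASCII grid I/O.

A :class:`Raster` is a dense 2-D array of per-cell values on a square grid
in a projected coordinate system (meters).  Row 0 is the *top* row, matching
the on-disk layout of the ESRI ASCII format that Circuitscape-style tools
consume.  NoData cells are held as ``nan`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "classify_landcover",
]

_DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band grid with square cells in projected meters.

    Parameters
    ----------
    data
        2-D float array, row 0 at the top (northernmost). NoData is ``nan``.
    cell_size
        Edge length of a cell in meters.
    xll, yll
        Projected coordinates of the lower-left corner of the grid.
    crs
        Free-text tag for the projected CRS; not interpreted.
    """

    data: np.ndarray
    cell_size: float = 100.0
    xll: float = 0.0
    yll: float = 0.0
    crs: str | None = None
    nodata_value: float = field(default=_DEFAULT_NODATA, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.n_cols * self.cell_size,
            self.yll + self.n_rows * self.cell_size,
        )

    def is_nodata(self) -> np.ndarray:
        return np.isnan(self.data)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of the center of cell (row, col)."""
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of all cell centers, shaped like ``data``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.xll + (cols + 0.5) * self.cell_size
        y = self.yll + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) whose footprint contains projected point (x, y)."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = min(int((x - self.xll) / self.cell_size), self.n_cols - 1)
        row = min(int((self.yll + self.n_rows * self.cell_size - y) / self.cell_size), self.n_rows - 1)
        return row, col

    def copy(self) -> "Raster":
        return replace(self, data=self.data.copy())


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc); NoData becomes ``nan``."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header.get("yllcorner", 0.0)
    else:  # center-registered variant
        xll = header.get("xllcenter", 0.0) - cell / 2
        yll = header.get("yllcenter", 0.0) - cell / 2
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {data.shape}, header says ({nrows}, {ncols})"
        )
    data[data == nodata] = np.nan
    return Raster(data, cell_size=cell, xll=xll, yll=yll, nodata_value=nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid; ``nan`` cells become the NoData value."""
    path = Path(path)
    data = raster.data.copy()
    nodata = raster.nodata_value
    data[np.isnan(data)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xll:.6f}\n")
        fh.write(f"yllcorner {raster.yll:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, data, fmt="%.10g")


def classify_landcover(
    landcover: Raster,
    cost_table: Mapping[int | str, float],
    default: float | None = None,
) -> Raster:
    """Translate a categorical land-cover raster into a resistance raster.

    Every land-cover class present in the grid must appear in ``cost_table``
    (keys are class codes) unless ``default`` supplies a fallback cost.  The
    canonical three-class scheme maps permeable natural cover to cost 10,
    semi-permeable cover to 100 and impermeable (largely anthropogenic)
    cover to 1000.
    """
    data = landcover.data
    out = np.full_like(data, np.nan)
    finite = ~np.isnan(data)
    classes = np.unique(data[finite])
    table = {float(k) if not isinstance(k, str) else k: v for k, v in cost_table.items()}
    unmapped = [c for c in classes if float(c) not in table]
    if unmapped and default is None:
        raise ValueError(
            "land-cover classes without a cost mapping and no default: "
            + ", ".join(f"{c:g}" for c in unmapped)
        )
    for c in classes:
        cost = table.get(float(c), default)
        if cost is not None and cost <= 0:
            raise ValueError(f"cost for class {c:g} must be positive, got {cost}")
        out[finite & (data == c)] = cost
    return replace(landcover, data=out)
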