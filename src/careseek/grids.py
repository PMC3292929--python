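"""Planar raster grids and ESRI ASCII grid I/O.

All spatial layers in a pipeline run share a single :class:`GridSpec` in a
projected planar frame (metres).  Row 0 is the northern edge, matching the
usual raster convention; cell (row, col) has its centre at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y + (n_rows - row - 0.5) * cell_size

where ``(origin_x, origin_y)`` is the lower-left (south-west) corner of the
grid.  Rasters are exchanged on disk as single-band ESRI ASCII grids, a plain
text format that round-trips values exactly (17 significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "read_raster", "write_raster", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when rasters with different grids are combined."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid in a projected planar frame.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; at least 2 each.
    cell_size : float
        Cell edge length in metres (default 1000, i.e. a 1 km grid).
    origin_x, origin_y : float
        Coordinates (metres) of the lower-left corner of the grid.
    nodata : float
        Sentinel written for missing cells on disk.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in metres."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of x and y cell-centre coordinates."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); raises for points off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        # points exactly on the top/right edge belong to the last cell
        col = np.where(
            (x == self.origin_x + self.n_cols * self.cell_size), self.n_cols - 1, col
        )
        row_from_bottom = np.where(
            (y == self.origin_y + self.n_rows * self.cell_size),
            self.n_rows - 1,
            row_from_bottom,
        )
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            xi = np.atleast_1d(x)[i]
            yi = np.atleast_1d(y)[i]
            raise ValueError(f"point ({xi}, {yi}) lies outside the grid extent {self.extent}")
        return row, col


@dataclass
class Raster:
    """A single-band raster: a 2-D value array tied to a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.grid)

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point."""
        row, col = self.grid.point_to_cell(x, y)
        return self.values[row, col]


def check_same_grid(*rasters: Raster, names: list[str] | None = None) -> GridSpec:
    """Assert all rasters share one grid; return it.

    Error messages name the offending layers so mixed-resolution inputs are
    diagnosed at the door rather than mid-pipeline.
    """
    grids = [r.grid for r in rasters]
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g != ref:
            a = names[0] if names else "layer 0"
            b = names[i] if names else f"layer {i}"
            raise GridMismatchError(
                f"grid mismatch between {a} ({ref.n_rows}x{ref.n_cols} @ {ref.cell_size} m)"
                f" and {b} ({g.n_rows}x{g.n_cols} @ {g.cell_size} m)"
            )
    return ref


def write_raster(path: str | Path, raster: Raster, *, inf_as_nodata: bool = True) -> None:
    """Write a raster as an ESRI ASCII grid.

    Non-finite values (the +inf sentinel of unreached travel-time cells, or
    NaN) are written as the grid's nodata value when ``inf_as_nodata`` is set.
    """
    path = Path(path)
    g = raster.grid
    vals = np.asarray(raster.values, dtype=float)
    if inf_as_nodata:
        vals = np.where(np.isfinite(vals), vals, g.nodata)
    lines = [
        f"ncols {g.n_cols}",
        f"nrows {g.n_rows}",
        f"xllcorner {g.origin_x!r}",
        f"yllcorner {g.origin_y!r}",
        f"cellsize {g.cell_size!r}",
        f"NODATA_value {g.nodata!r}",
    ]
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_raster(
    path: str | Path,
    *,
    nodata_as_inf: bool = False,
    dtype=float,
    expect_grid: GridSpec | None = None,
) -> Raster:
    """Read an ESRI ASCII grid.

    With ``nodata_as_inf`` nodata cells come back as +inf (used for travel
    time surfaces, whose unreached cells carry an infinity sentinel in
    memory).  ``expect_grid`` enforces grid agreement across pipeline inputs;
    a mismatch raises :class:`GridMismatchError` naming the file.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=header.get("nodata_value", -9999.0),
    )
    if expect_grid is not None and grid != expect_grid:
        raise GridMismatchError(
            f"raster {path} has grid {grid.n_rows}x{grid.n_cols} @ {grid.cell_size} m, "
            f"expected {expect_grid.n_rows}x{expect_grid.n_cols} @ {expect_grid.cell_size} m"
        )
    if nodata_as_inf:
        data = np.where(data == grid.nodata, np.inf, data)
    if dtype is not float:
        data = data.astype(dtype)
    return Raster(data, grid)
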