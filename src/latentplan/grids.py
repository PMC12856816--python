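"""Lightweight raster grids on a regular square lattice.

All spatial layers in the package (environment, tenure, species ranges,
risk maps) live on one shared grid: ``values[0, 0]`` is the north-west
cell, coordinates are planar kilometres, and the origin is the lower-left
corner of the lattice.  Grids serialize to the ESRI ASCII grid format, a
plain-text raster interchange format readable by standard GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: a 2-D array plus cell size and origin.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    cell_size : float
        Cell edge length in km.
    origin : (float, float)
        Planar (x, y) of the lower-left corner of the lattice, in km.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as 2-D arrays matching ``values``."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.nrows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid with the same georeferencing and different values."""
        return Grid(values, self.cell_size, self.origin, self.nodata)


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    vals = np.array(grid.values, dtype=float)
    vals = np.where(np.isnan(vals), grid.nodata, vals)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.1f}\n")
        for row in vals:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows)
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Grid(
        vals,
        cell_size=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=nodata,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def morans_i(values: np.ndarray) -> float:
    """Moran's I spatial autocorrelation with rook (4-neighbour) weights.

    Used as a diagnostic for the synthetic landscape generator: an
    autocorrelated field scores well above a spatially shuffled copy.
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    num = 0.0
    wsum = 0.0
    for shift_axis in (0, 1):
        a = np.take(z, range(z.shape[shift_axis] - 1), axis=shift_axis)
        b = np.take(z, range(1, z.shape[shift_axis]), axis=shift_axis)
        num += 2.0 * (a * b).sum()  # each pair counted in both directions
        wsum += 2.0 * a.size
    denom = (z**2).sum()
    n = z.size
    return (n / wsum) * (num / denom)
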