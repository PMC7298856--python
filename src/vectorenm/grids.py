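"""Regular latitude-longitude grids, layer stacks, and text raster I/O.

All rasters in this package live on a shared regular geographic grid
(WGS84 decimal degrees).  A :class:`Grid` is defined by the lower-left
corner of the raster extent, a square cell size in degrees, and the
array shape; row 0 of every array is the *northernmost* row, matching
the ESRI ASCII grid convention used for on-disk storage.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

__all__ = [
    "Grid",
    "LayerStack",
    "haversine_km",
    "read_ascii_grid",
    "write_ascii_grid",
]


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclasses.dataclass(frozen=True)
class Grid:
    """A regular geographic grid.

    Parameters
    ----------
    nrows, ncols : int
        Array shape; row 0 is the northernmost row.
    cellsize : float
        Cell edge length in decimal degrees (square cells).
    xll, yll : float
        Longitude / latitude of the lower-left corner of the extent
        (edge, not cell center).
    """

    nrows: int
    ncols: int
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell center, as 2-D arrays."""
        lon = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row = int(np.floor((self.yll + self.nrows * self.cellsize - lat) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) lies outside the grid")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat


def haversine_km(
    lon1: np.ndarray | float,
    lat1: np.ndarray | float,
    lon2: np.ndarray | float,
    lat2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Inputs in decimal degrees; broadcasts like numpy ufuncs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class LayerStack:
    """Named, co-registered raster layers with a shared validity mask.

    Layers are stored as a dict of 2-D float arrays; cells where
    ``mask`` is False are treated as no-data everywhere downstream.
    """

    def __init__(
        self,
        grid: Grid,
        layers: Mapping[str, np.ndarray],
        mask: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} has shape {arr.shape}, grid is {grid.shape}"
                )
            if name in self.layers:
                raise ValueError(f"duplicate layer name {name!r}")
            self.layers[name] = arr
        if mask is None:
            mask = np.ones(grid.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise GridMismatchError("mask shape does not match grid")
        self.mask = mask

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: Iterable[str]) -> "LayerStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return LayerStack(self.grid, {n: self.layers[n] for n in names}, self.mask)

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid-cell values as an (n_cells, n_layers) array (row-major order)."""
        m = self.mask if mask is None else (self.mask & mask)
        return np.column_stack([self.layers[n][m] for n in self.names])

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) array of layer values at the given cells."""
        return np.column_stack([self.layers[n][rows, cols] for n in self.names])

    def copy(self) -> "LayerStack":
        return LayerStack(
            self.grid,
            {n: a.copy() for n, a in self.layers.items()},
            self.mask.copy(),
        )

    def assert_same_grid(self, other: "LayerStack") -> None:
        if self.grid != other.grid:
            raise GridMismatchError("layer stacks are on different grids")

    # ------------------------------------------------------------------ I/O

    def write(self, directory: str | Path) -> None:
        """Write one ESRI ASCII grid per layer plus a manifest of names."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.names:
            arr = np.where(self.mask, self.layers[name], np.nan)
            write_ascii_grid(directory / f"{name}.asc", arr, self.grid)
        (directory / "layers.txt").write_text("\n".join(self.names) + "\n")

    @classmethod
    def read(cls, directory: str | Path) -> "LayerStack":
        directory = Path(directory)
        names = (directory / "layers.txt").read_text().split()
        layers = {}
        grid = None
        mask = None
        for name in names:
            arr, g = read_ascii_grid(directory / f"{name}.asc")
            if grid is None:
                grid, mask = g, ~np.isnan(arr)
            elif g != grid:
                raise GridMismatchError(f"layer {name!r} is on a different grid")
            else:
                mask &= ~np.isnan(arr)
            layers[name] = arr
        if grid is None:
            raise ValueError("empty layer manifest")
        for name in layers:
            layers[name] = np.nan_to_num(layers[name], nan=0.0)
        return cls(grid, layers, mask)


_NODATA = -9999.0


def write_ascii_grid(path: str | Path, arr: np.ndarray, grid: Grid) -> None:
    """Write a 2-D array as an ESRI ASCII grid (NaN -> nodata)."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise GridMismatchError("array shape does not match grid")
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xll!r}\n"
        f"yllcorner {grid.yll!r}\n"
        f"cellsize {grid.cellsize!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    body = np.where(np.isnan(arr), _NODATA, arr)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and re.match(r"^[A-Za-z_]", lines[i]):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"missing ASCII grid header keys in {path}")
    arr = np.loadtxt(lines[i:], dtype=float)
    arr = np.atleast_2d(arr)
    grid = Grid(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        cellsize=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
    )
    if arr.shape != grid.shape:
        raise ValueError(f"ASCII grid body shape {arr.shape} != header {grid.shape}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, grid
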