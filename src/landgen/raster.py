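"""Gridded climate data containers and plain-text raster I/O.

The package works on co-registered stacks of climate layers stored as
2-D float arrays with NaN marking nodata. Geographic referencing is a
simple north-up, square-cell grid in unprojected degrees (the analysis
operates at regional extents where this is adequate); cell areas are
computed with spherical cos(latitude) weighting when km² are needed.

Rasters are read and written as ESRI ASCII grids (``.asc``), a
self-describing plain-text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "RasterStack",
    "SuitabilityMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "average_gcm_stacks",
    "cell_area_km2",
]

#: mean km per degree of great-circle arc (spherical Earth, R=6371.0088 km)
KM_PER_DEGREE = 111.19492664455873


@dataclass(frozen=True)
class GridSpec:
    """North-up square-cell grid georeference.

    ``xmin``/``ymin`` are the outer corner of the lower-left cell
    (ESRI ``xllcorner``/``yllcorner``); row 0 is the northernmost row.
    """

    xmin: float
    ymin: float
    cellsize: float
    nrows: int
    ncols: int

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.xmin) / self.cellsize))
        row = int(np.floor((self.ymax - lat) / self.cellsize))
        # points exactly on the right/bottom extent edge belong to the edge cell
        if col == self.ncols and lon == self.xmax:
            col -= 1
        if row == self.nrows and lat == self.ymin:
            row -= 1
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) falls outside grid extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xmin + (col + 0.5) * self.cellsize
        lat = self.ymax - (row + 0.5) * self.cellsize
        return lon, lat

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of all cell centres."""
        lons = self.xmin + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.ymax - (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(lons, lats)


def cell_area_km2(grid: GridSpec) -> np.ndarray:
    """Per-cell area in km² using cos(latitude) weighting of a square
    degree cell; returns an (nrows, ncols) array constant along rows."""
    _, lat = grid.centers()
    side_km = grid.cellsize * KM_PER_DEGREE
    return side_km * side_km * np.cos(np.radians(lat))


@dataclass
class RasterStack:
    """Named, co-registered climate layers sharing one grid and mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where every layer has data."""
        if not self.layers:
            return np.zeros(self.grid.shape, dtype=bool)
        m = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            m &= np.isfinite(arr)
        return m

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at given cells."""
        return np.column_stack([self.layers[n][rows, cols] for n in self.names])

    def values_at_points(self, lons, lats) -> np.ndarray:
        rc = [self.grid.cell_of(lo, la) for lo, la in zip(lons, lats)]
        rows = np.array([r for r, _ in rc])
        cols = np.array([c for _, c in rc])
        return self.values_at_cells(rows, cols)

    def table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, X) over unmasked cells, X shaped (n_cells, n_layers)."""
        rows, cols = np.nonzero(self.mask)
        return rows, cols, self.values_at_cells(rows, cols)

    def subset(self, names) -> "RasterStack":
        return RasterStack(self.grid, {n: self.layers[n] for n in names})

    def copy(self) -> "RasterStack":
        return RasterStack(self.grid, {n: a.copy() for n, a in self.layers.items()})

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.grid)

    @classmethod
    def read(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        layers: dict[str, np.ndarray] = {}
        grid = None
        for path in sorted(directory.glob("*.asc")):
            arr, g = read_ascii_grid(path)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"{path.name} grid differs from other layers")
            layers[path.stem] = arr
        if grid is None:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        return cls(grid, layers)


@dataclass
class SuitabilityMap:
    """Habitat-suitability surface in [0, 1] for one climate scenario.

    ``binary`` and ``lpt`` are populated by thresholding (see
    :func:`landgen.sdm.binarize`); ``binary`` is boolean with nodata
    propagated as False.
    """

    grid: GridSpec
    values: np.ndarray
    scenario: str = "current"
    binary: np.ndarray | None = None
    lpt: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.grid.cell_of(lon, lat)
        return float(self.values[r, c])


def write_ascii_grid(path: str | Path, arr: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (NaN → nodata)."""
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xmin!r}\n"
        f"yllcorner {grid.ymin!r}\n"
        f"cellsize {grid.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata values become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if "xllcorner" in header:
        xmin, ymin = header["xllcorner"], header["yllcorner"]
    else:  # xllcenter variant
        xmin = header["xllcenter"] - header["cellsize"] / 2
        ymin = header["yllcenter"] - header["cellsize"] / 2
    grid = GridSpec(xmin, ymin, header["cellsize"], nrows, ncols)
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows},{ncols})")
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return data, grid


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def average_gcm_stacks(stacks: list[RasterStack]) -> RasterStack:
    """Per-variable, per-cell arithmetic mean across general-circulation-model
    stacks; all stacks must share layer names and grid."""
    if not stacks:
        raise ValueError("no stacks given")
    first = stacks[0]
    for s in stacks[1:]:
        if s.grid != first.grid:
            raise ValueError("stacks have differing grids")
        if set(s.names) != set(first.names):
            raise ValueError("stacks have differing layer names")
    layers = {
        n: np.mean([s.layers[n] for s in stacks], axis=0) for n in first.names
    }
    return RasterStack(first.grid, layers)
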