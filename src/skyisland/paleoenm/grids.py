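"""Gridded climate containers: raster stacks, forcing curves, occurrences.

Rasters follow the north-up convention: row 0 is the northern edge, cells
are registered on centers, coordinates are WGS84 decimal degrees.  The
nodata mask is shared by all layers of a stack and propagated through
every map operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "ClimateStack",
    "ForcingCurve",
    "OccurrenceSet",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, lower-left corner, square cell size."""

    n_rows: int
    n_cols: int
    xll: float
    yll: float
    cellsize: float

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a lon/lat point (row 0 = north)."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.n_rows - 1 - row + 0.5) * self.cellsize
        return lon, lat

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 first (northernmost)."""
        rows = np.arange(self.n_rows)
        return self.yll + (self.n_rows - 1 - rows + 0.5) * self.cellsize


@dataclass
class ClimateStack:
    """Named climate layers (raw variables or PCA axes) on a shared grid.

    ``layers`` maps variable name -> (n_rows, n_cols) float array; masked
    (nodata) cells hold NaN and are flagged in ``mask`` (True = valid).
    ``time`` is the slice age in ky BP (0 = present).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    time: float = 0.0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {shape}")
            self.layers[name] = arr
        if self.mask is None:
            valid = np.ones(shape, dtype=bool)
            for arr in self.layers.values():
                valid &= ~np.isnan(arr)
            self.mask = valid
        for name, arr in self.layers.items():
            arr[~self.mask] = np.nan

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.n_rows, self.grid.n_cols)

    def to_table(self) -> np.ndarray:
        """Valid cells as an (n_valid, n_vars) matrix (row-major cell order)."""
        cols = [self.layers[v][self.mask] for v in self.variables]
        return np.column_stack(cols)

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_vars) climate matrix at given cells."""
        return np.column_stack(
            [self.layers[v][rows, cols] for v in self.variables]
        )

    def with_layers(self, layers: dict[str, np.ndarray], time: float | None = None) -> "ClimateStack":
        return ClimateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in layers.items()},
            time=self.time if time is None else time,
            mask=self.mask.copy(),
        )


@dataclass
class ForcingCurve:
    """A univariate forcing series (benthic δ18O, per mil) on a ky BP axis."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("requested time outside the forcing domain")
        return np.interp(t, self.times, self.values)

    @classmethod
    def from_csv(cls, path) -> "ForcingCurve":
        frame = pd.read_csv(path)
        return cls(frame["time_ky"].to_numpy(), frame["d18O"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ky": self.times, "d18O": self.values}).to_csv(
            path, index=False
        )


@dataclass
class OccurrenceSet:
    """Presence-only occurrence points for one species."""

    species: str
    lon: np.ndarray
    lat: np.ndarray
    deduplicated: bool = False

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape or self.lon.ndim != 1:
            raise ValueError("lon and lat must be matching 1-D arrays")

    @property
    def n_points(self) -> int:
        return self.lon.size

    def dedup_on_grid(self, grid: GridSpec) -> "OccurrenceSet":
        """Keep at most one point per grid cell (oversampling correction)."""
        seen: dict[tuple[int, int], int] = {}
        for i in range(self.n_points):
            cell = grid.cell_of(self.lon[i], self.lat[i])
            seen.setdefault(cell, i)
        idx = sorted(seen.values())
        return OccurrenceSet(
            species=self.species,
            lon=self.lon[idx],
            lat=self.lat[idx],
            deduplicated=True,
        )

    def cells(self, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
        rc = np.array(
            [grid.cell_of(lo, la) for lo, la in zip(self.lon, self.lat)], dtype=int
        )
        return rc[:, 0], rc[:, 1]

    @classmethod
    def from_csv(cls, path, species: str | None = None) -> "OccurrenceSet":
        frame = pd.read_csv(path)
        if species is not None:
            frame = frame[frame["species"] == species]
        name = species if species is not None else str(frame["species"].iloc[0])
        return cls(name, frame["lon"].to_numpy(), frame["lat"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"species": self.species, "lon": self.lon, "lat": self.lat}
        ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# ESRI ASCII grid I/O
# ----------------------------------------------------------------------

def write_ascii_grid(
    path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0,
    fmt: str = "%.10g",
) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = north, as on disk)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("values shape does not match grid")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.xll:.10g}\n"
        f"yllcorner {grid.yll:.10g}\n"
        f"cellsize {grid.cellsize:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha() and _is_number(parts[1]):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:], ndmin=2)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"ASCII grid header missing keys: {sorted(missing)}")
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    if data.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(
            f"grid body shape {data.shape} does not match header "
            f"({grid.n_rows} x {grid.n_cols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, grid


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
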