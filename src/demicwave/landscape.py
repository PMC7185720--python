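"""Equal-area gridded model space: suitability rasters and coordinate mapping.

The simulator operates on a square grid of 10 × 10 km cells in an
equal-area projection (equal-area so that planar distances and cell
areas are meaningful continent-wide). Each cell carries a habitat
suitability in [0, 1] — in the real pipeline the output of a species
distribution model — and a boolean settleability derived by
thresholding the suitability.

Rasters are read from the ESRI ASCII grid dialect (plain text; NODATA
honored). The grid must already be projected and have square cells; the
module validates but does not reproject. Closed-form spherical forward/
inverse projections (Lambert azimuthal equal-area, Albers equal-area
conic) are provided for mapping site longitude/latitude onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from demicwave.spacetime import EARTH_RADIUS_KM

__all__ = [
    "Grid",
    "RasterFormatError",
    "LocationError",
    "load_suitability",
    "write_ascii_grid",
    "site_to_cell",
    "cell_center",
    "miami_npp",
    "laea_projection",
    "albers_projection",
]

Projection = Callable[[float, float], tuple[float, float]]


class RasterFormatError(ValueError):
    """Raster file malformed or not on a valid square-cell grid."""


class LocationError(ValueError):
    """A point falls outside the grid bounds."""


@dataclass(frozen=True)
class Grid:
    """A suitability raster with settleability mask on an equal-area plane.

    ``xll``/``yll`` are the projected coordinates (km) of the lower-left
    corner of the lower-left cell; row 0 is the top (northernmost) row,
    as in common raster layouts. ``project``/``unproject`` map
    lon/lat ↔ projected km and may be ``None`` for purely synthetic
    grids addressed by cell index.
    """

    suitability: np.ndarray  # (n_rows, n_cols), NaN for no-data
    settleable: np.ndarray  # (n_rows, n_cols) bool
    cell_km: float = 10.0
    xll: float = 0.0
    yll: float = 0.0
    threshold: float = 0.0
    project: Projection | None = field(default=None, compare=False)
    unproject: Projection | None = field(default=None, compare=False)

    @property
    def n_rows(self) -> int:
        return self.suitability.shape[0]

    @property
    def n_cols(self) -> int:
        return self.suitability.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def xy_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Projected km → (row, col) of the containing cell."""
        col = int(np.floor((x - self.xll) / self.cell_km))
        row = int(np.floor((self.yll + self.n_rows * self.cell_km - y) / self.cell_km))
        if not self.in_bounds(row, col):
            raise LocationError(f"point ({x}, {y}) km outside grid bounds")
        return row, col

    def cell_to_xy(self, row: int, col: int) -> tuple[float, float]:
        """(row, col) → projected km of the cell center."""
        x = self.xll + (col + 0.5) * self.cell_km
        y = self.yll + (self.n_rows - row - 0.5) * self.cell_km
        return x, y

    def with_projection(self, project: Projection, unproject: Projection | None = None) -> "Grid":
        return replace(self, project=project, unproject=unproject)


def load_suitability(path: str | Path, threshold: float) -> Grid:
    """Read an ESRI ASCII suitability grid and threshold it.

    Cells with suitability ≥ ``threshold`` are settleable; NODATA cells
    never are. ``cellsize`` may be in km or meters (auto-detected:
    values > 1000 are taken as meters).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing header field {key!r}")

    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    cell_km = cell / 1000.0 if cell > 1000.0 else cell
    nodata = header.get("nodata_value")

    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: bad data block: {exc}") from exc
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"{path}: data shape {values.shape} != header ({n_rows}, {n_cols})"
        )
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise RasterFormatError(f"{path}: suitability values outside [0, 1]")

    xll = header.get("xllcorner", header.get("xllcenter", 0.0))
    yll = header.get("yllcorner", header.get("yllcenter", 0.0))
    if "xllcenter" in header:
        xll -= cell / 2.0
    if "yllcenter" in header:
        yll -= cell / 2.0
    scale = 1000.0 if cell > 1000.0 else 1.0

    settleable = np.isfinite(values) & (values >= threshold)
    return Grid(
        suitability=values,
        settleable=settleable,
        cell_km=cell_km,
        xll=xll / scale,
        yll=yll / scale,
        threshold=threshold,
    )


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    cell_km: float = 10.0,
    xll: float = 0.0,
    yll: float = 0.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-d array as an ESRI ASCII grid (NaN → NODATA)."""
    arr = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        f"xllcorner {xll}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def site_to_cell(lon: float, lat: float, grid: Grid) -> tuple[int, int]:
    """Map a lon/lat site onto its containing grid cell.

    Requires the grid to carry a projection.
    """
    if grid.project is None:
        raise ValueError("grid has no projection; use Grid.with_projection")
    x, y = grid.project(lon, lat)
    return grid.xy_to_cell(x, y)


def cell_center(row: int, col: int, grid: Grid) -> tuple[float, float]:
    """Inverse of :func:`site_to_cell`: cell → lon/lat of its center."""
    x, y = grid.cell_to_xy(row, col)
    if grid.unproject is None:
        raise ValueError("grid has no inverse projection")
    return grid.unproject(x, y)


def miami_npp(temp_c: float, precip_mm: float) -> float:
    """Miami-model net primary productivity, g m⁻² yr⁻¹.

    The minimum of a temperature term ``3000 / (1 + exp(1.315 − 0.119 T))``
    and a precipitation term ``3000 (1 − exp(−0.000664 P))``; both
    saturate at 3000.
    """
    t_term = 3000.0 / (1.0 + np.exp(1.315 - 0.119 * temp_c))
    p_term = 3000.0 * (1.0 - np.exp(-0.000664 * precip_mm))
    return float(min(t_term, p_term))


def laea_projection(lon0: float, lat0: float) -> tuple[Projection, Projection]:
    """Spherical Lambert azimuthal equal-area centered at (lon0, lat0).

    Returns ``(forward, inverse)`` mapping lon/lat ↔ (x, y) in km.
    Suited to synthetic radial-expansion grids: equal-area everywhere and
    radial distances from the center match great circles to <0.2% within
    ~2000 km.
    """
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)
    R = EARTH_RADIUS_KM

    def forward(lon: float, lat: float) -> tuple[float, float]:
        lam = np.radians(lon)
        phi = np.radians(lat)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        k = np.sqrt(2.0 / denom)
        x = R * k * np.cos(phi) * np.sin(lam - lam0)
        y = R * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
        return float(x), float(y)

    def inverse(x: float, y: float) -> tuple[float, float]:
        rho = np.hypot(x, y)
        if rho == 0.0:
            return float(np.degrees(lam0)), float(np.degrees(phi0))
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * R), -1.0, 1.0))
        phi = np.arcsin(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / rho)
        lam = lam0 + np.arctan2(
            x * np.sin(c), rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)
        )
        return float(np.degrees(lam)), float(np.degrees(phi))

    return forward, inverse


def albers_projection(
    lon0: float, lat0: float, lat1: float, lat2: float
) -> tuple[Projection, Projection]:
    """Spherical Albers equal-area conic with standard parallels lat1/lat2.

    Returns ``(forward, inverse)`` in km. Provided for real-data grids;
    synthetic grids use :func:`laea_projection`.
    """
    lam0, phi0, phi1, phi2 = map(np.radians, (lon0, lat0, lat1, lat2))
    R = EARTH_RADIUS_KM
    n = (np.sin(phi1) + np.sin(phi2)) / 2.0
    C = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
    rho0 = R * np.sqrt(C - 2.0 * n * np.sin(phi0)) / n

    def forward(lon: float, lat: float) -> tuple[float, float]:
        lam = np.radians(lon)
        phi = np.radians(lat)
        theta = n * (lam - lam0)
        rho = R * np.sqrt(C - 2.0 * n * np.sin(phi)) / n
        return float(rho * np.sin(theta)), float(rho0 - rho * np.cos(theta))

    def inverse(x: float, y: float) -> tuple[float, float]:
        # with southern standard parallels n < 0 and both rho and theta
        # flip sign; fold the sign in before the arctangent
        s = 1.0 if n >= 0 else -1.0
        rho = s * np.hypot(x, rho0 - y)
        theta = np.arctan2(s * x, s * (rho0 - y))
        phi = np.arcsin(np.clip((C - (rho * n / R) ** 2) / (2.0 * n), -1.0, 1.0))
        lam = lam0 + theta / n
        return float(np.degrees(lam)), float(np.degrees(phi))

    return forward, inverse
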