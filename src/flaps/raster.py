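"""Gridded rasters: ESRI ASCII grid I/O, geotransform, probability surface.

Rasters are plain-text ESRI ASCII grids (``ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value`` header followed by rows north-to-south), the format
every desktop GIS reads and writes.  The geotransform maps pixel indices to
geographic coordinates of pixel centers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
import numpy as np

__all__ = ["GeoTransform", "ProbabilitySurface", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass(frozen=True)
class GeoTransform:
    """Affine pixel ↔ coordinate mapping for a north-up grid.

    ``x0``/``y0`` are the coordinates of the grid's upper-left corner; ``dx``
    is the pixel width (positive east) and ``dy`` the pixel height (positive
    number, applied southward).
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def pixel_center(self, row: np.ndarray, col: np.ndarray):
        """(lon, lat) of the center of pixel (row, col)."""
        lon = self.x0 + (np.asarray(col) + 0.5) * self.dx
        lat = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def to_pixel(self, lon: np.ndarray, lat: np.ndarray):
        """(row, col) of the pixel containing (lon, lat)."""
        col = np.floor((np.asarray(lon) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(lat)) / self.dy).astype(int)
        return row, col


@dataclass
class ProbabilitySurface:
    """Occurrence-probability raster plus availability state for placement.

    ``grid`` holds per-pixel farm-occurrence probabilities in [0, 1];
    ``available`` is False where the exclusion mask forbids farms (urban,
    water, public land) or a placement has since claimed the pixel;
    ``county_index`` maps each pixel to an index into ``county_fips``
    (-1 = outside every county).
    """

    grid: np.ndarray
    available: np.ndarray
    transform: GeoTransform
    county_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    county_fips: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        if self.grid.shape != self.available.shape:
            raise ValueError("grid and availability mask differ in shape")
        if np.nanmin(self.grid) < 0 or np.nanmax(self.grid) > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.county_index is None:
            self.county_index = np.zeros(self.grid.shape, dtype=np.int32)
            if not self.county_fips:
                self.county_fips = ["00000"]
        self.county_index = np.asarray(self.county_index, dtype=np.int32)
        if self.county_index.shape != self.grid.shape:
            raise ValueError("county index raster differs in shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def county_pixels(self, fips: str) -> np.ndarray:
        """Flat indices of the pixels belonging to county ``fips``."""
        try:
            ci = self.county_fips.index(fips)
        except ValueError:
            raise KeyError("county %s not on this surface" % fips)
        return np.flatnonzero(self.county_index.ravel() == ci)


def read_ascii_grid(path_or_buf) -> tuple[np.ndarray, GeoTransform]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = text.splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and len(hdr) < 6:
        key, _, val = lines[i].partition(" ")
        hdr[key.strip().lower()] = float(val)
        i += 1
    ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
    cell = hdr["cellsize"]
    nodata = hdr.get("nodata_value", NODATA)
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])), dtype=float)
    data = data.reshape(nrows, ncols)
    data[data == nodata] = np.nan
    gt = GeoTransform(
        x0=hdr["xllcorner"], y0=hdr["yllcorner"] + nrows * cell, dx=cell, dy=cell
    )
    return data, gt


def write_ascii_grid(path_or_buf, data: np.ndarray, gt: GeoTransform) -> None:
    """Write an ESRI ASCII grid (requires square pixels); NaN becomes NODATA."""
    data = np.asarray(data, dtype=float)
    if abs(gt.dx - gt.dy) > 1e-12:
        raise ValueError("ASCII grids require square pixels")
    nrows, ncols = data.shape
    hdr = (
        "ncols %d\nnrows %d\nxllcorner %.10g\nyllcorner %.10g\n"
        "cellsize %.10g\nNODATA_value %g\n"
        % (ncols, nrows, gt.x0, gt.y0 - nrows * gt.dy, gt.dx, NODATA)
    )
    out = np.where(np.isnan(data), NODATA, data)

    def _dump(fh) -> None:
        fh.write(hdr)
        np.savetxt(fh, out, fmt="%.8g")

    if hasattr(path_or_buf, "write"):
        _dump(path_or_buf)
    else:
        with open(path_or_buf, "w") as fh:
            _dump(fh)
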