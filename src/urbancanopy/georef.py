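"""Minimal north-up georeferencing and plain-text raster I/O.

Rasters are exchanged as ESRI ASCII grids (``.asc``) — a self-describing
text format with a 6-line header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by rows of values from the top row down.
Values are written with 17 significant digits so write→read round-trips are
bit-exact for float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeoref:
    """North-up square-pixel georeference.

    x0, y0 are the lower-left corner coordinates (m); cell is the pixel
    edge (m).  Row 0 is the northernmost row.
    """

    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate grids in metres for an array shape."""
        rows, cols = shape
        x = self.x0 + (np.arange(cols) + 0.5) * self.cell
        y = self.y0 + (rows - np.arange(rows) - 0.5) * self.cell
        return np.meshgrid(x, y)


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    georef: GridGeoref,
    nodata: float = NODATA,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaNs become the nodata value."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("ASCII grid requires a 2-D array")
    out = np.where(np.isnan(data), nodata, data)
    rows, cols = data.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {georef.x0!r}\n"
        f"yllcorner {georef.y0!r}\n"
        f"cellsize {georef.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeoref]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    georef = GridGeoref(header["xllcorner"], header["yllcorner"], header["cellsize"])
    return data, georef


def write_stack(
    directory: str | Path,
    stem: str,
    stack: np.ndarray,
    band_names: list[str] | tuple[str, ...],
    georef: GridGeoref,
) -> list[Path]:
    """Write a (bands, rows, cols) stack as one ASCII grid per band."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for band, name in zip(stack, band_names, strict=True):
        p = directory / f"{stem}_{name}.asc"
        write_ascii_grid(p, band, georef)
        paths.append(p)
    return paths
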