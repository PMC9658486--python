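"""Readers and writers for point clouds and height grids.

Supported formats are the two plain-text conventions used in the field:

* xyz point clouds — three whitespace-separated columns (x, y, z in m);
* ESRI-ASCII-style grids — a six-line header (ncols, nrows, xllcorner,
  yllcorner, cellsize, NODATA_value) followed by rows of elevations, the
  first file row being the northernmost.

Nodata cells become NaN on read and are ignored by all grid reductions.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .errors import DomainError
from .geometry import HeightGrid

__all__ = ["read_xyz", "write_xyz", "read_esri_ascii", "write_esri_ascii"]


def read_xyz(path) -> np.ndarray:
    """Read an xyz point cloud; returns an (n, 3) float array."""
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.shape[1] != 3:
        raise DomainError(f"expected 3 columns (x y z), got {pts.shape[1]}")
    return pts


def write_xyz(path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DomainError("points must be an (n, 3) array")
    np.savetxt(path, points, fmt="%.4f")


def read_esri_ascii(path, plot_id: str | None = None) -> HeightGrid:
    """Read an ESRI-ASCII grid into a :class:`HeightGrid` (z0 unset)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        z = np.loadtxt(fh, dtype=float, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if z.shape != (nrows, ncols):
        raise DomainError(f"grid body {z.shape} does not match header ({nrows}, {ncols})")
    z[z == header["nodata_value"]] = np.nan
    return HeightGrid(
        plot_id=plot_id or path.stem,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        z=z,
    )


def write_esri_ascii(path, grid: HeightGrid, nodata: float = -9999.0) -> None:
    z = np.where(np.isfinite(grid.z), grid.z, nodata)
    buf = io.StringIO()
    buf.write(f"ncols {grid.z.shape[1]}\n")
    buf.write(f"nrows {grid.z.shape[0]}\n")
    buf.write(f"xllcorner {grid.origin[0]:.4f}\n")
    buf.write(f"yllcorner {grid.origin[1]:.4f}\n")
    buf.write(f"cellsize {grid.cell_size:.6g}\n")
    buf.write(f"NODATA_value {nodata:.6g}\n")
    np.savetxt(buf, z, fmt="%.4f")
    Path(path).write_text(buf.getvalue())
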