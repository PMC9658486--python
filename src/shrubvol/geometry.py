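"""Field and canopy-height-model geometry.

Two kinds of inputs are reduced to the allometric predictors here:

* manual field measurements of single shrubs — total height ``H`` and two
  perpendicular canopy diameters ``C1 >= C2`` — from which canopy area is
  computed as a circle with radius equal to the mean of the two canopy
  radii, and crown volume as the cone ``A * H / 3``;
* gridded canopy height models (or raw xyz point clouds) from UAV
  photogrammetry, from which surface volume, vegetated cover area (cells
  higher than a 30 cm threshold) and mean canopy height are computed after
  referencing the surface to the bare-soil level.

All heights are in metres, areas in m^2 and volumes in m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GridStateError, SoilReferenceError

__all__ = [
    "HeightGrid",
    "canopy_area",
    "cone_volume",
    "soil_reference",
    "surface_volume",
    "cover_area",
    "mean_height",
]

#: Default vegetation cover threshold (m above soil level).
COVER_THRESHOLD_M = 0.30


def canopy_area(c1, c2):
    """Canopy area (m^2) as a circle from the mean of both canopy radii.

    ``A = pi * ((C1 + C2) / 4)^2`` with ``C1`` the largest and ``C2`` the
    perpendicular canopy diameter (m). Accepts scalars or arrays.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if np.any(c1 <= 0) or np.any(c2 <= 0):
        raise DomainError("canopy diameters must be positive")
    if np.any(c1 < c2):
        raise DomainError("C1 must be the largest canopy diameter (C1 >= C2)")
    out = np.pi * ((c1 + c2) / 4.0) ** 2
    return out.item() if out.ndim == 0 else out


def cone_volume(area, height):
    """Crown volume (m^3) of a cone with base ``area`` and apex at ``height``."""
    area = np.asarray(area, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(area <= 0) or np.any(height <= 0):
        raise DomainError("cone area and height must be positive")
    out = area * height / 3.0
    return out.item() if out.ndim == 0 else out


@dataclass
class HeightGrid:
    """A regular canopy-height raster for one plot.

    ``z`` holds surface elevations (m); NaN cells are nodata and are ignored
    by every reduction. ``z0`` is the bare-soil reference elevation; it must
    be set (directly or via :func:`soil_reference`) before volume, cover or
    mean-height queries.
    """

    plot_id: str
    origin: tuple[float, float]
    cell_size: float
    z: np.ndarray
    z0: float | None = field(default=None)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise DomainError("grid z must be a 2-D array")
        if not self.cell_size > 0:
            raise DomainError("cell_size must be positive")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.z)

    def heights(self) -> np.ndarray:
        """Canopy heights z - z0 over valid cells (1-D, unclamped)."""
        if self.z0 is None:
            raise GridStateError("soil reference z0 is not set")
        return self.z[self.valid] - self.z0


def soil_reference(grid: HeightGrid, bare_cells: np.ndarray, method: str = "mean") -> float:
    """Estimate and set the bare-soil elevation from vegetation-free cells.

    The study sites are flat, so the default is the plain mean elevation of
    the masked cells; ``method="plane"`` fits a least-squares plane instead
    and returns its value at the grid centre (for gently sloping sites).
    """
    bare_cells = np.asarray(bare_cells, dtype=bool)
    if bare_cells.shape != grid.z.shape:
        raise SoilReferenceError("bare-cell mask shape does not match the grid")
    usable = bare_cells & grid.valid
    if not usable.any():
        raise SoilReferenceError("bare-cell mask selects no valid cells")
    if method == "mean":
        z0 = float(grid.z[usable].mean())
    elif method == "plane":
        rows, cols = np.nonzero(usable)
        design = np.column_stack([np.ones(rows.size), rows, cols])
        coef, *_ = np.linalg.lstsq(design, grid.z[usable], rcond=None)
        centre = np.array([1.0, (grid.z.shape[0] - 1) / 2, (grid.z.shape[1] - 1) / 2])
        z0 = float(centre @ coef)
    else:
        raise DomainError(f"unknown soil reference method {method!r}")
    grid.z0 = z0
    return z0


def surface_volume(grid: HeightGrid) -> float:
    """Volume (m^3) between the canopy surface and the soil reference.

    Sum over valid cells of ``max(z - z0, 0) * cell_size^2``; negative
    heights (sensor noise over bare ground) are clamped to zero.
    """
    h = grid.heights()
    return float(np.clip(h, 0.0, None).sum() * grid.cell_size**2)


def cover_area(grid: HeightGrid, threshold: float = COVER_THRESHOLD_M) -> float:
    """Vegetated area (m^2): cells strictly higher than ``threshold`` above soil."""
    if threshold < 0:
        raise DomainError("cover threshold must be non-negative")
    h = grid.heights()
    return float((h > threshold).sum() * grid.cell_size**2)


def mean_height(data, z0: float | None = None) -> float:
    """Mean canopy height (m) of a grid or a 1-D point-cloud height sample.

    For a :class:`HeightGrid` the mean is taken over *all* valid cells
    (vegetated or not), without clamping negative values. For a raw array of
    z values, ``z0`` (default 0) is subtracted first.
    """
    if isinstance(data, HeightGrid):
        h = data.heights()
    else:
        arr = np.asarray(data, dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        h = arr - (0.0 if z0 is None else z0)
    if h.size == 0:
        raise DomainError("no height observations")
    return float(h.mean())
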