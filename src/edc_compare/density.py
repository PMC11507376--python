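"""Electron-density grids: MRC/CCP4 I/O, moving-average smoothing, point sampling.

The central object is :class:`DensityGrid`, a 3-D scalar field with voxel
geometry.  Conventions used throughout the package (and documented only
here):

* Grid indexing is 0-based and the ``values`` array is stored in canonical
  Cartesian order: ``values[i, j, k]`` is the cell at x-index ``i``,
  y-index ``j``, z-index ``k``, regardless of the axis order of the source
  file.
* ``origin`` is the Cartesian position (Å) of the **center** of cell
  (0, 0, 0); the center of cell (i, j, k) is therefore
  ``origin + (i, j, k) * voxel_size``.
* Map values are never rescaled on read — scores computed from a map are in
  the same arbitrary units as the deposited map.

File I/O is delegated to :mod:`gemmi`, which handles the MRC/CCP4 2014
format including the MAPC/MAPR/MAPS axis permutation; this module only
reconstructs the canonical origin from the header (ORIGIN words first,
NXSTART-style start indices as fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import MapFormatError, UsageError

__all__ = [
    "DensityGrid",
    "read_map",
    "write_map",
    "smooth_map",
    "sample_at",
    "sample_points",
]


@dataclass
class DensityGrid:
    """A 3-D scalar density field with voxel geometry.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        One finite scalar per cell, in map units, canonical x,y,z order.
    voxel_size : ndarray, shape (3,)
        Å per cell along x, y, z; all components > 0.
    origin : ndarray, shape (3,)
        Cartesian Å position of the center of cell (0, 0, 0).
    axis_permutation : tuple of int
        Mapping from file storage axes to Cartesian axes (0-based), kept
        for provenance; ``values`` is always already canonical.
    smoothed : bool
        Whether ``values`` has been moving-average filtered.
    oob_count : int
        Running tally of out-of-bounds point samples taken from this grid.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_permutation: tuple[int, int, int] = (0, 1, 2)
    smoothed: bool = False
    oob_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise MapFormatError("grid values must be a 3-D array with all dims >= 1")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise MapFormatError("voxel_size must be three positive components")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("grid contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def cell_center(self, i: int, j: int, k: int) -> np.ndarray:
        """Cartesian Å position of the center of cell (i, j, k)."""
        return self.origin + np.array([i, j, k]) * self.voxel_size

    def reset_oob_count(self) -> None:
        self.oob_count = 0


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 map into a canonical-axis-order :class:`DensityGrid`.

    The origin is taken from the header ORIGIN record (words 50-52) when any
    component is non-zero, otherwise reconstructed as start-index x
    voxel-size from the NC/NR/NSSTART words (permuted into x,y,z order).
    Values are returned untouched, in the units of the file.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path!r}: {exc}") from exc

    # Header words (1-based): 5-7 start indices along file axes,
    # 17-19 MAPC/MAPR/MAPS axis assignment, 50-52 ORIGIN (Cartesian).
    map_axes = [ccp4.header_i32(w) for w in (17, 18, 19)]
    if sorted(map_axes) != [1, 2, 3]:
        raise MapFormatError(
            f"MAPC/MAPR/MAPS must be a permutation of 1,2,3, got {map_axes}"
        )
    starts = [ccp4.header_i32(w) for w in (5, 6, 7)]
    header_origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    # file axis f holds Cartesian axis map_axes[f]-1
    axis_permutation = tuple(a - 1 for a in map_axes)

    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True, dtype=np.float64)
    cell = ccp4.grid.unit_cell
    for name, (length, n) in zip(
        "abc", [(cell.a, values.shape[0]), (cell.b, values.shape[1]), (cell.c, values.shape[2])]
    ):
        if length <= 0:
            raise MapFormatError(f"unit cell axis {name} is non-positive ({length})")
    voxel = np.array(
        [cell.a / values.shape[0], cell.b / values.shape[1], cell.c / values.shape[2]]
    )

    if np.any(header_origin != 0.0):
        origin = header_origin
    else:
        # starts are in file-axis order; permute to Cartesian order
        start_xyz = np.empty(3)
        for file_axis, cart_axis in enumerate(axis_permutation):
            start_xyz[cart_axis] = starts[file_axis]
        origin = start_xyz * voxel

    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path!r} contains non-finite values (DMIN/DMAX region)")

    return DensityGrid(
        values=values,
        voxel_size=voxel,
        origin=origin,
        axis_permutation=axis_permutation,  # type: ignore[arg-type]
    )


def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as an MRC/CCP4 2014 map (mode 2, canonical axis order).

    The origin is stored in the ORIGIN header words; values are written as
    32-bit floats (the format's precision), so a round trip preserves values
    to float32 resolution.
    """
    fgrid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.dims
    vx, vy, vz = grid.voxel_size
    fgrid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    fgrid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fgrid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def _window_sums(values: np.ndarray, half: int) -> np.ndarray:
    """Sliding-cube sums with truncation at the boundaries, via per-axis
    cumulative sums (exact up to float addition order)."""
    out = values
    for axis in range(3):
        n = out.shape[axis]
        csum = np.cumsum(out, axis=axis)
        hi = np.minimum(np.arange(n) + half, n - 1)
        lo = np.arange(n) - half - 1
        upper = np.take(csum, hi, axis=axis)
        lower = np.take(csum, np.maximum(lo, 0), axis=axis)
        shape = [1, 1, 1]
        shape[axis] = n
        lower = lower * (lo >= 0).reshape(shape)
        out = upper - lower
    return out


def _window_counts(dims: tuple[int, int, int], half: int) -> np.ndarray:
    """Number of in-bounds cells in each truncated window cube (exact)."""
    per_axis = []
    for n in dims:
        idx = np.arange(n)
        per_axis.append(np.minimum(idx + half, n - 1) - np.maximum(idx - half, 0) + 1)
    return (
        per_axis[0][:, None, None] * per_axis[1][None, :, None] * per_axis[2][None, None, :]
    ).astype(np.float64)


def smooth_map(grid: DensityGrid, window: int = 5) -> DensityGrid:
    """Moving-average smooth: each cell becomes the mean of the centered
    ``window**3`` cube, truncated to in-bounds cells at the box edges.

    Truncation (rather than zero padding) keeps constant maps constant
    everywhere, including edges.  Window 5 reproduces the 125-cell cube used
    to suppress atom-scale density fluctuations before compliance scoring.
    """
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window!r}")
    if grid.smoothed:
        raise UsageError("grid is already smoothed; smoothing twice is not the intended filter")
    half = int(window) // 2
    if half == 0:
        values = grid.values.copy()
    else:
        values = _window_sums(grid.values, half) / _window_counts(grid.dims, half)
    return DensityGrid(
        values=values,
        voxel_size=grid.voxel_size.copy(),
        origin=grid.origin.copy(),
        axis_permutation=grid.axis_permutation,
        smoothed=True,
    )


def _fractional_index(grid: DensityGrid, points: np.ndarray) -> np.ndarray:
    return (points - grid.origin) / grid.voxel_size


def sample_points(
    grid: DensityGrid, points: np.ndarray, mode: str = "nearest"
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the grid at Cartesian points.

    Returns ``(values, oob_mask)``.  Out-of-bounds points yield 0.0 and are
    flagged in the mask (and added to ``grid.oob_count``).  ``mode`` is
    ``"nearest"`` (value of the cell whose center is nearest, the default
    used for compliance scoring) or ``"trilinear"`` (interpolation between
    the 8 surrounding cell centers, for sensitivity checks).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.all(np.isfinite(points)):
        raise ValueError("point coordinates must be finite")
    frac = _fractional_index(grid, points)
    dims = np.array(grid.dims)
    if mode == "nearest":
        idx = np.rint(frac).astype(np.int64)
        oob = np.any((idx < 0) | (idx >= dims), axis=1)
        idx_clipped = np.clip(idx, 0, dims - 1)
        vals = grid.values[idx_clipped[:, 0], idx_clipped[:, 1], idx_clipped[:, 2]]
        vals = np.where(oob, 0.0, vals)
    elif mode == "trilinear":
        oob = np.any((frac < 0) | (frac > dims - 1), axis=1)
        vals = map_coordinates(grid.values, frac.T, order=1, mode="constant", cval=0.0)
        vals = np.where(oob, 0.0, vals)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    grid.oob_count += int(oob.sum())
    return vals, oob


def sample_at(grid: DensityGrid, point, mode: str = "nearest") -> float:
    """Sample a single Cartesian point; out-of-bounds returns 0.0 (tallied
    on ``grid.oob_count``)."""
    vals, _ = sample_points(grid, np.asarray(point, dtype=np.float64).reshape(1, 3), mode=mode)
    return float(vals[0])
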