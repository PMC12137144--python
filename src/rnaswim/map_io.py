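"""Density-map container and grid-level operations.

Maps live on a regular orthogonal grid. Internally, ``values[i, j, k]``
corresponds to the (x, y, z) axes in that index order; positions are
Angstroms in the model frame, with ``origin`` the position of voxel
(0, 0, 0). MRC/CCP4 files in any axis order are normalized to this
convention on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "GridStats",
    "read_density_map",
    "write_density_map",
    "map_stats",
    "interpolate_density",
    "zscore_normalize",
    "shuffle_within_mask",
]


class MapFormatError(ValueError):
    """Raised when a volume file cannot be interpreted as MRC/CCP4."""


class DegenerateMapError(ValueError):
    """Raised when an operation requires non-zero density variance."""


@dataclass
class DensityMap:
    values: np.ndarray          # 3D float array, index order (x, y, z)
    voxel_size: np.ndarray      # Angstrom per voxel along each axis
    origin: np.ndarray          # Angstrom position of voxel (0, 0, 0)
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive on all axes")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_position(self, index) -> np.ndarray:
        """Angstrom position of (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def position_to_index(self, position) -> np.ndarray:
        """Fractional voxel index of an Angstrom position."""
        return (np.asarray(position, dtype=float) - self.origin) / self.voxel_size

    def contains(self, positions) -> np.ndarray:
        """True where positions fall inside the grid bounding box."""
        f = np.atleast_2d(self.position_to_index(positions))
        upper = np.asarray(self.shape) - 1
        ok = np.all((f >= 0) & (f <= upper), axis=1)
        return ok if np.asarray(positions).ndim > 1 else bool(ok[0])

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        return DensityMap(
            self.values.copy() if values is None else values,
            self.voxel_size.copy(),
            self.origin.copy(),
            self.label,
        )


@dataclass(frozen=True)
class GridStats:
    avgD: float
    sigma: float

    @property
    def is_degenerate(self) -> bool:
        return self.sigma == 0.0

    def threshold(self, k: float) -> float:
        """Density level k standard deviations above the grid mean."""
        return self.avgD + k * self.sigma


def read_density_map(path) -> DensityMap:
    """Read an MRC/CCP4 volume, normalizing axis order and origin.

    Both the MRC2014 ORIGIN record and the older NCSTART/NRSTART/NSSTART
    start-index convention are honored; ORIGIN wins when non-zero.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 volume {path!r}: {exc}") from exc
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True).astype(np.float64)
    cell = ccp4.grid.unit_cell
    shape = np.asarray(values.shape, dtype=float)
    voxel = np.array([cell.a, cell.b, cell.c]) / shape
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0):
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    return DensityMap(values, voxel, origin, label=str(path))


def write_density_map(dmap: DensityMap, path) -> None:
    """Write as MRC mode 2 (32-bit float) with the ORIGIN record set."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    n = dmap.shape
    grid.unit_cell = gemmi.UnitCell(
        n[0] * dmap.voxel_size[0],
        n[1] * dmap.voxel_size[1],
        n[2] * dmap.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def map_stats(dmap: DensityMap) -> GridStats:
    """Mean and standard deviation over every voxel of the grid."""
    if dmap.values.size == 0:
        raise ValueError("empty grid")
    return GridStats(float(dmap.values.mean()), float(dmap.values.std()))


def interpolate_density(dmap: DensityMap, positions) -> np.ndarray | float:
    """Trilinear interpolation of the 8 voxels surrounding each position.

    Positions must lie inside the grid bounding box; out-of-bounds input
    raises rather than silently extrapolating.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    f = dmap.position_to_index(pos)
    upper = np.asarray(dmap.shape) - 1
    if np.any(f < 0) or np.any(f > upper):
        raise ValueError("position outside grid bounds")
    i0 = np.minimum(np.floor(f).astype(int), upper - 1)
    i0 = np.maximum(i0, 0)
    t = f - i0
    v = dmap.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    out = np.zeros(len(pos))
    for dx in (0, 1):
        wx = tx if dx else 1.0 - tx
        for dy in (0, 1):
            wy = ty if dy else 1.0 - ty
            for dz in (0, 1):
                wz = tz if dz else 1.0 - tz
                out += wx * wy * wz * v[ix + dx, iy + dy, iz + dz]
    return float(out[0]) if single else out


def zscore_normalize(dmap: DensityMap) -> DensityMap:
    """Rescale so the full grid has mean 0 and standard deviation 1."""
    stats = map_stats(dmap)
    if stats.sigma == 0:
        raise DegenerateMapError("constant map cannot be Z-score normalized")
    return dmap.copy(values=(dmap.values - stats.avgD) / stats.sigma)


def shuffle_within_mask(dmap: DensityMap, mask: np.ndarray, seed: int) -> DensityMap:
    """Randomly permute the values inside a boolean voxel mask.

    The multiset of masked values is conserved exactly; voxels outside
    the mask are untouched. The permutation is reproducible from seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dmap.shape:
        raise ValueError("mask shape does not match grid shape")
    if not mask.any():
        raise ValueError("empty mask")
    rng = np.random.default_rng(seed)
    out = dmap.values.copy()
    out[mask] = rng.permutation(out[mask])
    return dmap.copy(values=out)
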