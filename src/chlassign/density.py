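"""Cryo-EM density handling: MRC/CCP4 I/O, interpolation, per-site scaling.

A :class:`DensityGrid` stores map values on a canonical X,Y,Z index order
with an explicit voxel basis, so sampling by physical coordinate does not
depend on the axis order the file happened to be written in.  Non-orthogonal
cells are supported through the full fractional<->Cartesian matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .structure_io import ChlSite, MACROCYCLE_LABELS

__all__ = [
    "MapFormatError",
    "OutOfBoundsError",
    "NormalizationError",
    "DensityGrid",
    "ScaleModel",
    "load_map",
    "write_map",
    "sample_density",
    "normalize_site",
    "macrocycle_reference_stats",
]


class MapFormatError(RuntimeError):
    pass


class OutOfBoundsError(RuntimeError):
    pass


class NormalizationError(RuntimeError):
    pass


@dataclass
class DensityGrid:
    """A 3D scalar map with a voxel -> Cartesian affine transform.

    values[i, j, k] is the density at origin + basis @ (i, j, k); basis
    columns are the Cartesian step vectors per index increment (Angstrom).
    """

    values: np.ndarray  # (nx, ny, nz), canonical X,Y,Z order
    cell: tuple[float, float, float, float, float, float]
    origin: np.ndarray  # Cartesian position of voxel (0,0,0), Angstrom
    basis: np.ndarray  # (3, 3) voxel step matrix
    axis_order: tuple[int, int, int] = (0, 1, 2)  # as found in the file

    _inv_basis: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise MapFormatError("density array must be 3-dimensional")
        self.origin = np.asarray(self.origin, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if np.any(np.linalg.norm(self.basis, axis=0) <= 0):
            raise MapFormatError("voxel size must be positive")
        self._inv_basis = np.linalg.inv(self.basis)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.basis, axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_of(self, point: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a Cartesian point."""
        return self._inv_basis @ (np.asarray(point, dtype=float) - self.origin)

    def position_of(self, index: Sequence[float]) -> np.ndarray:
        return self.origin + self.basis @ np.asarray(index, dtype=float)


@dataclass
class ScaleModel:
    """How raw map values are scaled before entering the cone statistic.

    macrocycle_mean (default): divide by the mean density at the site's
    macrocycle atom centers — a per-site occupancy/contrast proxy that
    makes profiles comparable across sites, which the pooled null needs.
    zscore_local: subtract the macrocycle mean, divide by its SD (invariant
    under positive affine transforms of the map).  none: identity.
    """

    mode: str = "macrocycle_mean"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("zscore_local", "macrocycle_mean", "none"):
            raise ValueError(f"unknown scale mode {self.mode!r}")


def _grid_from_ccp4(m: gemmi.Ccp4Map) -> DensityGrid:
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)
    cellp = m.grid.unit_cell
    cell = (cellp.a, cellp.b, cellp.c, cellp.alpha, cellp.beta, cellp.gamma)
    # sampling counts along the cell axes (header words 8-10)
    mx, my, mz = (m.header_i32(8), m.header_i32(9), m.header_i32(10))
    if min(mx, my, mz) <= 0:
        raise MapFormatError("non-positive sampling in map header")
    orth = np.array(cellp.orth.mat.tolist())
    basis = orth @ np.diag([1.0 / mx, 1.0 / my, 1.0 / mz])
    # origin: MRC2014 ORIGIN words plus CCP4-style start indices (if any)
    origin_words = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    # after ReorderOnly the grid is in XYZ order, but words 5-7 remain in
    # file (column, row, section) order; map them through words 17-19
    axes = [m.header_i32(17) - 1, m.header_i32(18) - 1, m.header_i32(19) - 1]
    starts_file = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    starts_xyz = [0, 0, 0]
    for file_axis, xyz_axis in enumerate(axes):
        starts_xyz[xyz_axis] = starts_file[file_axis]
    origin = origin_words + basis @ np.asarray(starts_xyz, dtype=float)
    return DensityGrid(
        values=values,
        cell=cell,
        origin=origin,
        basis=basis,
        axis_order=tuple(axes),  # type: ignore[arg-type]
    )


def load_map(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 map (modes 0/1/2) into a canonical DensityGrid."""
    path = Path(path)
    if not path.exists():
        raise MapFormatError(f"no such file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read {path}: {exc}") from exc
    return _grid_from_ccp4(m)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a DensityGrid as an MRC/CCP4 map (mode 2, float32)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(*grid.cell)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def sample_density(grid: DensityGrid, point: np.ndarray) -> float:
    """Trilinear interpolation of the map at a Cartesian point.

    Raises OutOfBoundsError if the point falls outside the voxel-center
    bounding box (no periodic wrapping, no padding).
    """
    idx = grid.index_of(point)
    nx, ny, nz = grid.shape
    if np.any(idx < 0) or np.any(idx > np.array([nx - 1, ny - 1, nz - 1])):
        raise OutOfBoundsError(
            f"point {np.asarray(point).round(2)} outside grid (index {idx.round(2)})"
        )
    i0 = np.minimum(np.floor(idx).astype(int), [nx - 2 if nx > 1 else 0,
                                               ny - 2 if ny > 1 else 0,
                                               nz - 2 if nz > 1 else 0])
    i0 = np.maximum(i0, 0)
    f = idx - i0
    v = grid.values
    ix, iy, iz = i0
    ix1 = min(ix + 1, nx - 1)
    iy1 = min(iy + 1, ny - 1)
    iz1 = min(iz + 1, nz - 1)
    c000 = v[ix, iy, iz]
    c100 = v[ix1, iy, iz]
    c010 = v[ix, iy1, iz]
    c110 = v[ix1, iy1, iz]
    c001 = v[ix, iy, iz1]
    c101 = v[ix1, iy, iz1]
    c011 = v[ix, iy1, iz1]
    c111 = v[ix1, iy1, iz1]
    fx, fy, fz = f
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return float(c0 * (1 - fz) + c1 * fz)


def macrocycle_reference_stats(site: ChlSite, grid: DensityGrid) -> tuple[float, float]:
    """Mean and sample SD of map density at the site's macrocycle atoms."""
    labels = [lbl for lbl in MACROCYCLE_LABELS if lbl in site.atoms]
    if len(labels) < 2:
        raise NormalizationError(f"site {site.site_id}: too few macrocycle atoms")
    vals = np.array([sample_density(grid, site.atoms[lbl]) for lbl in labels])
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return mu, sd


def normalize_site(
    values: Sequence[float],
    model: ScaleModel,
    site: Optional[ChlSite] = None,
    grid: Optional[DensityGrid] = None,
) -> np.ndarray:
    """Scale raw sampled densities according to the ScaleModel.

    Reference statistics (mean/SD over the site's macrocycle atom centers)
    may be precomputed and passed via model.params ("mu", "sigma"); otherwise
    site and grid are required to derive them.
    """
    vals = np.asarray(values, dtype=float)
    if model.mode == "none":
        return vals
    if vals.size < 2 and model.mode == "zscore_local":
        raise NormalizationError("zscore_local needs >= 2 values")
    mu = model.params.get("mu")
    sigma = model.params.get("sigma")
    if mu is None or (sigma is None and model.mode == "zscore_local"):
        if site is None or grid is None:
            raise NormalizationError("site and grid required to derive reference stats")
        mu, sigma = macrocycle_reference_stats(site, grid)
    if model.mode == "zscore_local":
        if sigma == 0:
            raise NormalizationError("zero variance at macrocycle reference atoms")
        return (vals - mu) / sigma
    # macrocycle_mean
    if mu == 0:
        raise NormalizationError("zero mean macrocycle density")
    return vals / mu
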