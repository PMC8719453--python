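"""Voxel lattice geometry: coordinates, distances and face adjacency.

All downstream distance-controlled statistics (DCBC bins, boundary
enumeration) operate on a regular 3-D voxel lattice with millimetre
coordinates.  Voxels are indexed by their C-order linear index within
``grid_shape`` so that the mapping between a flat per-voxel vector and
the 3-D volume is fixed and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import InvalidArgumentError

__all__ = ["VoxelGeometry", "generate_geometry"]


@dataclass
class VoxelGeometry:
    """A set of voxels on a regular lattice with mm coordinates.

    Parameters
    ----------
    voxel_ids : (V,) int array
        C-order linear index of each voxel within ``grid_shape``.
    coords : (V, 3) float array
        Voxel-center positions in millimetres.
    grid_shape : tuple of 3 ints
        Shape of the enclosing lattice.
    spacing : tuple of 3 floats
        Millimetres per axis step.
    hemisphere : str
        ``left``, ``right`` or ``synthetic``.
    """

    voxel_ids: np.ndarray
    coords: np.ndarray
    grid_shape: tuple
    spacing: tuple
    hemisphere: str = "synthetic"

    def __post_init__(self):
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidArgumentError("coords must be (V, 3)")
        if self.voxel_ids.shape[0] != self.coords.shape[0]:
            raise InvalidArgumentError("voxel_ids and coords length mismatch")
        if len(np.unique(self.voxel_ids)) != len(self.voxel_ids):
            raise InvalidArgumentError("voxel_ids must be unique")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise InvalidArgumentError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Condensed (scipy ``pdist`` order) Euclidean distances in mm."""
        return pdist(self.coords)

    def grid_indices(self) -> np.ndarray:
        """(V, 3) integer lattice indices recovered from the linear ids."""
        return np.stack(np.unravel_index(self.voxel_ids, self.grid_shape), axis=1)

    def to_volume(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Scatter a per-voxel vector into a dense ``grid_shape`` volume."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise InvalidArgumentError(
                f"expected {self.n_voxels} per-voxel values, got {values.shape[0]}"
            )
        vol = np.full(self.grid_shape, fill, dtype=values.dtype)
        vol.reshape(-1)[self.voxel_ids] = values
        return vol

    def face_adjacent_pairs(self) -> np.ndarray:
        """(P, 2) array of voxel-array-index pairs sharing a lattice face.

        6-connectivity on the lattice; only pairs where both voxels belong
        to this geometry are returned.  Indices are positions within the
        geometry's voxel arrays, i < j.
        """
        pos = np.full(int(np.prod(self.grid_shape)), -1, dtype=np.int64)
        pos[self.voxel_ids] = np.arange(self.n_voxels)
        grid = pos.reshape(self.grid_shape)
        pairs = []
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            a = grid[tuple(lo)].reshape(-1)
            b = grid[tuple(hi)].reshape(-1)
            keep = (a >= 0) & (b >= 0)
            pairs.append(np.stack([a[keep], b[keep]], axis=1))
        out = np.concatenate(pairs, axis=0)
        out.sort(axis=1)
        return out

    def __eq__(self, other):
        if not isinstance(other, VoxelGeometry):
            return NotImplemented
        return (
            self.grid_shape == other.grid_shape
            and self.spacing == other.spacing
            and self.hemisphere == other.hemisphere
            and np.array_equal(self.voxel_ids, other.voxel_ids)
            and np.array_equal(self.coords, other.coords)
        )


def generate_geometry(grid_shape, spacing_mm, hemisphere: str = "synthetic") -> VoxelGeometry:
    """Build a full regular lattice of voxel centers.

    Parameters
    ----------
    grid_shape : 3 ints, each >= 1
    spacing_mm : positive scalar or 3 floats, mm per axis
    """
    grid_shape = tuple(int(d) for d in grid_shape)
    if len(grid_shape) != 3 or any(d < 1 for d in grid_shape):
        raise InvalidArgumentError(f"grid_shape must be 3 positive ints, got {grid_shape}")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=np.float64), (3,))
    if np.any(spacing <= 0):
        raise InvalidArgumentError(f"spacing must be positive, got {spacing_mm}")
    idx = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coords = idx * spacing
    voxel_ids = np.ravel_multi_index(idx.T, grid_shape)
    return VoxelGeometry(
        voxel_ids=voxel_ids,
        coords=coords,
        grid_shape=grid_shape,
        spacing=tuple(spacing),
        hemisphere=hemisphere,
    )
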