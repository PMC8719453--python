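"""The BoldSeries container: one subject's time x voxel matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import IncompatibleInputError, InvalidArgumentError
from .geometry import VoxelGeometry

__all__ = ["BoldSeries"]


@dataclass
class BoldSeries:
    """One subject's BOLD signal restricted to a voxel set.

    ``data`` is a T x V matrix: rows are time points, columns follow the
    voxel order of ``geometry``.  ``standardized`` records whether every
    column has been brought to zero mean / unit variance; columns that
    were constant before standardization are flagged in ``constant_mask``
    and set to zero.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    geometry: VoxelGeometry
    standardized: bool = False
    constant_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be a 2-D time x voxel matrix")
        if self.data.shape[0] < 2:
            raise InvalidArgumentError("need at least 2 time points")
        if self.data.shape[1] != self.geometry.n_voxels:
            raise IncompatibleInputError(
                f"data has {self.data.shape[1]} columns but geometry has "
                f"{self.geometry.n_voxels} voxels"
            )
        if self.standardized:
            ok = self.constant_mask if self.constant_mask is not None else np.zeros(
                self.n_voxels, dtype=bool
            )
            live = ~ok
            mu = self.data[:, live].mean(axis=0)
            sd = self.data[:, live].std(axis=0)
            if mu.size and (np.max(np.abs(mu)) > 1e-8 or np.max(np.abs(sd - 1.0)) > 1e-8):
                raise InvalidArgumentError(
                    "standardized series must have zero-mean unit-variance columns"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]
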