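"""In-memory containers shared across the pipeline.

Conventions
-----------
* Voxel data are stored in ``(z, y, x)`` axis order (slice-major, matching
  multi-page TIFF layout).
* Physical voxel spacing is carried as ``voxel_nm = (x, y, z)`` in
  nanometres, the order in which acquisition settings are usually quoted
  (in-plane pixel size first, section thickness last).
* The physical position of a voxel with index ``(k, j, i)`` is
  ``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)`` in ``(x, y, z)`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageStack", "LabelVolume"]


def _validate_grid(data: np.ndarray, voxel_nm: tuple[float, float, float]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got ndim={data.ndim}")
    if len(voxel_nm) != 3:
        raise ValueError("voxel_nm must be a (x, y, z) triple in nm")
    if any(s <= 0 for s in voxel_nm):
        raise ValueError(f"voxel spacing must be positive, got {voxel_nm}")


@dataclass
class ImageStack:
    """A 3D grayscale intensity grid with anisotropic physical spacing."""

    data: np.ndarray
    voxel_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_nm = tuple(float(s) for s in self.voxel_nm)
        _validate_grid(self.data, self.voxel_nm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.voxel_nm
        return (sz, sy, sx)

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.voxel_nm
        return sx * sy * sz

    @property
    def axial_extent_nm(self) -> float:
        """Physical depth of the stack: number of slices x section thickness."""
        return self.n_slices * self.voxel_nm[2]


@dataclass
class LabelVolume:
    """A 3D integer grid mapping each voxel to background (0) or an object id."""

    data: np.ndarray
    voxel_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_nm = tuple(float(s) for s in self.voxel_nm)
        _validate_grid(self.data, self.voxel_nm)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.voxel_nm
        return (sz, sy, sx)

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.voxel_nm
        return sx * sy * sz

    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids > 0]

    def mask(self, object_id: int) -> np.ndarray:
        return self.data == object_id
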