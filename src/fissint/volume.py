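"""In-memory container for CT-like volumes.

Axis convention throughout the package is RAS-like: array axis 0 (+x)
points toward the patient's right, axis 1 (+y) anterior, axis 2 (+z)
superior.  ``spacing`` is the physical voxel size in mm per axis, so a
voxel index ``(i, j, k)`` sits at ``origin + spacing * (i, j, k)`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in Hounsfield-like units.
    spacing : tuple of float
        Voxel size in mm along (x, y, z); strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def coords_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)
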