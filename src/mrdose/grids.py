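"""Regular 3-D voxel grids.

A :class:`Volume` is the common container for densities (g/cm^3), dose
(Gy), image intensities and structure masks.  Axes follow the patient
convention used throughout the package: ``x`` = left-right (LR),
``y`` = anterior-posterior (AP), ``z`` = cranial-caudal (CC), all in mm.
Arrays are indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A scalar field sampled on a regular 3-D grid.

    Parameters
    ----------
    values
        3-D array of voxel values (any physical quantity).
    spacing
        Voxel spacing per axis in mm; all entries strictly positive.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along ``axis``."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def center(self) -> np.ndarray:
        """Physical centre of the grid (mm)."""
        return np.array(
            [
                self.origin[a] + 0.5 * self.spacing[a] * (self.shape[a] - 1)
                for a in range(3)
            ]
        )

    def like(self, values: np.ndarray) -> "Volume":
        """A new volume with the same geometry and different values."""
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return Volume(values, self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing, self.origin)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (N, 3) to fractional voxel indices (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.array(self.origin)) / np.array(self.spacing)

    def sample(
        self, points_mm: np.ndarray, order: int = 1, cval: float = 0.0
    ) -> np.ndarray:
        """Interpolate the volume at physical points (N, 3)."""
        idx = self.world_to_index(points_mm)
        return ndimage.map_coordinates(
            self.values.astype(float), idx.T, order=order, mode="constant", cval=cval
        )

    # ---- I/O -----------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def grid_points(vol: Volume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadcastable physical coordinate arrays (X, Y, Z) for a volume."""
    x = vol.axis_coords(0)[:, None, None]
    y = vol.axis_coords(1)[None, :, None]
    z = vol.axis_coords(2)[None, None, :]
    return x, y, z
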