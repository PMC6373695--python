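"""Attenuation-coefficient voxel volumes and MetaImage I/O.

A :class:`VoxelVolume` stores linear attenuation coefficients mu [1/mm] on a
regular grid.  Indexing is 0-based ``values[ix, iy, iz]``; ``origin`` is the
world position [mm] of the *center* of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelVolume", "hu_to_mu", "read_metaimage", "write_metaimage"]


@dataclass
class VoxelVolume:
    """3D attenuation grid with physical spacing and origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Linear attenuation coefficients [1/mm], non-negative.
    spacing : tuple of float
        Voxel size (sx, sy, sz) [mm].
    origin : tuple of float
        World position [mm] of the center of voxel (0, 0, 0).  Defaults to
        centering the volume on the world origin.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.values < 0):
            raise ValueError("attenuation coefficients must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.values.shape, self.spacing)
            )
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (low corner, high corner) [mm] of the grid."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        low = o - 0.5 * s
        return low, low + n * s

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate meshgrid (X, Y, Z) of all voxel centers."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    def total_mass(self) -> float:
        """Sum of voxel values times voxel volume (attenuation 'mass')."""
        return float(self.values.sum() * self.voxel_volume_mm3)

    def same_grid(self, other: "VoxelVolume", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def hu_to_mu(hu: np.ndarray, mu_water: float = 0.02) -> np.ndarray:
    """Linear CT-number map: mu = mu_water * (1 + HU/1000), clipped at 0."""
    return np.clip(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0, None)


def write_metaimage(volume: VoxelVolume, path) -> None:
    """Write a volume as MetaImage (.mha / .mhd)."""
    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def read_metaimage(path) -> VoxelVolume:
    """Read a MetaImage volume written by :func:`write_metaimage`."""
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T.astype(np.float64)
    return VoxelVolume(values=values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))
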