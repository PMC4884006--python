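"""3D scalar volumes with isotropic voxel size, backed by NIfTI-1 files."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeImage:
    """A 3D scalar grid (activity counts or a linear-attenuation map).

    Parameters
    ----------
    data
        3D array; counts per voxel for emission volumes, cm^-1 for
        attenuation maps.
    voxel_size_mm
        Isotropic voxel spacing in millimetres.
    meta
        Free-form provenance (role, generating parameters, ...).
    """

    data: np.ndarray
    voxel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (mm) on axes centred at the grid midpoint."""
        return coordinate_grids(self.shape, self.voxel_size_mm)


def coordinate_grids(
    shape: tuple[int, int, int], voxel_size_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open mesh of voxel-centre coordinates in mm, origin at grid centre."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in shape]
    return np.ix_(*axes)


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume to a NIfTI-1 file, voxel size in the affine."""
    path = Path(path)
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume; requires isotropic voxels."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxels not supported: {zooms}")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return VolumeImage(data=data, voxel_size_mm=float(zooms[0]), meta={"path": str(path)})
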