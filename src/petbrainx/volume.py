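"""3-D PET volume container and NIfTI I/O.

The package uses a single axis convention everywhere: the array index
order is ``(x, y, z)`` with x = left-right, y = anterior-posterior and
z = inferior-superior (z increasing toward the head).  NIfTI images
whose affine encodes a different orientation are reoriented to the
closest canonical (RAS) orientation on load, which coincides with this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A 3-D image in SUV units with voxel spacing in millimetres.

    Parameters
    ----------
    data:
        3-D float array indexed ``(x, y, z)``; values are standardized
        uptake values and must be non-negative.
    voxel_mm:
        Spacing per axis in mm, all positive.
    origin_mm:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got ndim={self.data.ndim}")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine, diagonal by convention."""
        aff = np.diag(list(self.voxel_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_mm, self.origin_mm)


def save_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.voxel_mm)
    nib.save(img, str(path))


def load_volume(path) -> Volume:
    """Load a NIfTI file, reorienting to the canonical x=LR/y=AP/z=IS axes."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return Volume(data, tuple(float(z) for z in zooms), tuple(float(o) for o in origin))
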