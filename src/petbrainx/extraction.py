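"""Reslicing to 2 mm and padded cropping of the predicted brain box."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import model as model_mod
from .boxes import Box3D
from .volume import Volume


@dataclass
class ExtractionResult:
    brain_volume: Volume
    crop_box: Box3D  # on the resliced grid, after padding and clipping
    provenance: dict = field(default_factory=dict)


@dataclass
class AbsentBrain:
    """Typed outcome for scans classified as not containing the entire brain."""

    p_exist: float
    provenance: dict = field(default_factory=dict)


def reslice_isotropic(volume: Volume, target_mm: float = 2.0, order: int = 1) -> Volume:
    """Trilinear reslice onto an isotropic grid covering the original FOV.

    Values sampled outside the original extent are 0 (air).  ``order=0``
    gives nearest-neighbour resampling, used for label masks.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    factors = np.array(volume.voxel_mm) / target_mm
    new_shape = tuple(int(math.ceil(s * f)) for s, f in zip(volume.shape, factors))
    matrix = np.diag(1.0 / factors)  # output index -> input index
    data = ndimage.affine_transform(
        volume.data.astype(np.float64), matrix, output_shape=new_shape,
        order=order, mode="constant", cval=0.0,
    )
    return Volume(data.astype(np.float32), (target_mm,) * 3, volume.origin_mm)


def crop_with_padding(volume: Volume, box: Box3D, pad_voxels: int = 10) -> ExtractionResult:
    """Expand the box by ``pad_voxels`` on every face, clip to the grid, crop."""
    lo = np.maximum(np.asarray(box.min_corner) - pad_voxels, 0)
    hi = np.minimum(np.asarray(box.max_corner) + pad_voxels, volume.shape)
    if np.any(hi <= lo):
        raise ValueError(f"box {box} lies entirely outside the grid {volume.shape}")
    crop = Box3D(tuple(int(v) for v in lo), tuple(int(v) for v in hi - lo))
    data = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    origin = tuple(
        o + int(l) * v for o, l, v in zip(volume.origin_mm, lo, volume.voxel_mm)
    )
    return ExtractionResult(Volume(data, volume.voxel_mm, origin), crop)


def rescale_box(box: Box3D, from_mm, to_mm) -> Box3D:
    """Carry a voxel-index box from one grid spacing to another."""
    f = np.asarray(from_mm, dtype=float) / np.asarray(to_mm, dtype=float)
    lo = np.floor(np.asarray(box.min_corner) * f + 0.5).astype(int)
    hi = np.floor(np.asarray(box.max_corner) * f + 0.5).astype(int)
    hi = np.maximum(hi, lo + 1)
    return Box3D(tuple(lo), tuple(hi - lo))


def extract_brain(
    volume: Volume,
    model: "model_mod.DualViewModel | None" = None,
    box: Box3D | None = None,
    pad_voxels: int = 10,
    target_mm: float = 2.0,
    source_id: str = "",
    checkpoint_id: str = "",
):
    """Predict, reslice and crop: the brain-extraction front half.

    The box is predicted on the original grid (from the MIP views),
    the volume is resliced to ``target_mm`` isotropic, and the box —
    rescaled to the new grid — is cropped with ``pad_voxels`` padding.
    Returns :class:`ExtractionResult`, or :class:`AbsentBrain` when the
    model decides the scan does not contain the entire brain.  An
    explicit ``box`` (e.g. ground truth) bypasses the model.
    """
    provenance = {"source": source_id, "checkpoint": checkpoint_id}
    p_exist = 1.0
    if box is None:
        if model is None:
            raise ValueError("either a trained model or an explicit box is required")
        output, box = model_mod.predict(model, volume)
        p_exist = output.p_exist
        if box is None:
            return AbsentBrain(p_exist, provenance)
    resliced = reslice_isotropic(volume, target_mm)
    box2 = rescale_box(box, volume.voxel_mm, (target_mm,) * 3)
    result = crop_with_padding(resliced, box2, pad_voxels)
    result.provenance = dict(provenance, p_exist=p_exist)
    return result
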