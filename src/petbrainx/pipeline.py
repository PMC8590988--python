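"""End-to-end orchestration: extract -> normalize -> smooth -> t-map.

Thin glue over the per-stage modules so the CLI, the tests and the
reproduction script all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import extraction, normalization, statmap
from .extraction import AbsentBrain, ExtractionResult
from .model import DualViewModel
from .volume import Volume


@dataclass
class NormalizedScan:
    smoothed: Volume  # on the template grid, smoothed
    warped: Volume  # on the template grid, unsmoothed
    extraction: ExtractionResult
    registration: normalization.RegistrationResult


def process_scan(
    volume: Volume,
    model: DualViewModel | None,
    template: Volume,
    box=None,
    fwhm_mm: float = 10.0,
    pad_voxels: int = 10,
    target_mm: float = 2.0,
    syn_config: normalization.SyNConfig | None = None,
):
    """Run one scan through extraction, normalization and smoothing.

    Returns :class:`NormalizedScan`, or :class:`AbsentBrain` when the
    model classifies the scan as not containing the entire brain.
    """
    ext = extraction.extract_brain(volume, model=model, box=box,
                                   pad_voxels=pad_voxels, target_mm=target_mm)
    if isinstance(ext, AbsentBrain):
        return ext
    reg = normalization.spatial_normalize(ext.brain_volume, template, syn_config)
    smoothed = normalization.smooth_fwhm(reg.warped, fwhm_mm)
    return NormalizedScan(smoothed, reg.warped, ext, reg)


def warp_mask_to_template(
    mask: np.ndarray,
    source: Volume,
    scan: NormalizedScan,
    template: Volume,
    target_mm: float = 2.0,
) -> np.ndarray:
    """Carry a voxel mask from the original grid into template space.

    Replays the scan's reslice/crop and applies its fitted registration
    with nearest-neighbour interpolation.
    """
    mask_vol = Volume(mask.astype(np.float32), source.voxel_mm, source.origin_mm)
    resliced = extraction.reslice_isotropic(mask_vol, target_mm, order=0)
    crop = scan.extraction.crop_box
    lo, hi = crop.min_corner, crop.max_corner
    cropped = Volume(
        resliced.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
        resliced.voxel_mm, scan.extraction.brain_volume.origin_mm,
    )
    warped = normalization.apply_transform(scan.registration, cropped, template,
                                           nearest=True)
    return warped.data > 0.5


def analyze_subject(
    subject: Volume,
    controls_normalized: list[Volume],
    model: DualViewModel | None,
    template: Volume,
    p: float = 0.001,
    direction: str = statmap.CONTROLS_GREATER,
    fwhm_mm: float = 10.0,
    box=None,
):
    """Normalize a subject and t-map it against pre-normalized controls.

    Returns ``(NormalizedScan, TMap, ClusterReport)`` or
    :class:`AbsentBrain`.
    """
    scan = process_scan(subject, model, template, box=box, fwhm_mm=fwhm_mm)
    if isinstance(scan, AbsentBrain):
        return scan
    mask = statmap.default_mask(template)
    tmap = statmap.single_subject_tmap(scan.smoothed, controls_normalized,
                                       direction=direction, mask=mask)
    report = statmap.threshold_and_cluster(tmap, p=p)
    return scan, tmap, report
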