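"""Single-subject-versus-controls voxel-wise T mapping.

One patient scan is compared with a control group by a two-sample
pooled-variance t test at every voxel.  With a single observation in
the case group the subject contributes no variance, so at each voxel

    t = (mean_ctrl - x_subj) / (s_p * sqrt(1 + 1/n_ctrl)),
    s_p^2 = sum_i (ctrl_i - mean_ctrl)^2 / (n_ctrl - 1),
    df = 1 + n_ctrl - 2 = n_ctrl - 1.

The default direction is ``controls_greater`` (suprathreshold voxels
are hypometabolic in the subject), matching the edema signature this
pipeline screens for.  Thresholding is at an uncorrected per-voxel P
(default 0.001) with no multiple-comparison correction, and clusters
are formed under 18-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import Volume

log = logging.getLogger(__name__)

CONTROLS_GREATER = "controls_greater"
SUBJECT_GREATER = "subject_greater"
TWO_SIDED = "two_sided"

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class TMap:
    t_values: np.ndarray
    df: int
    direction: str
    mask: np.ndarray
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_zero_variance: int = 0


@dataclass
class Cluster:
    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int]


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold_t: float
    p_uncorrected: float
    label_map: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cluster_id": i + 1, "size_voxels": c.size, "peak_t": c.peak_t,
                 "x": c.peak_voxel[0], "y": c.peak_voxel[1], "z": c.peak_voxel[2]}
                for i, c in enumerate(self.clusters)
            ],
            columns=["cluster_id", "size_voxels", "peak_t", "x", "y", "z"],
        )


def default_mask(template: Volume, fraction: float = 0.2) -> np.ndarray:
    """Analysis mask: template voxels above ``fraction`` of its maximum."""
    return template.data > fraction * float(template.data.max())


def single_subject_tmap(
    subject: Volume,
    controls: list[Volume],
    direction: str = CONTROLS_GREATER,
    mask: np.ndarray | None = None,
) -> TMap:
    """Voxel-wise pooled two-sample t of one subject against controls."""
    if direction not in (CONTROLS_GREATER, SUBJECT_GREATER, TWO_SIDED):
        raise ValueError(f"unknown direction {direction!r}")
    if len(controls) < 3:
        raise ValueError(f"need at least 3 controls, got {len(controls)}")
    shapes = {c.data.shape for c in controls} | {subject.data.shape}
    if len(shapes) != 1:
        raise ValueError(f"volumes are not on a common grid: shapes {shapes}")

    ctrl = np.stack([c.data.astype(np.float64) for c in controls])
    n = ctrl.shape[0]
    mean = ctrl.mean(axis=0)
    var = ctrl.var(axis=0, ddof=1)
    denom = np.sqrt(var * (1.0 + 1.0 / n))
    diff = mean - subject.data.astype(np.float64)

    zero = denom == 0
    n_zero = int(zero.sum())
    if n_zero:
        log.info("t map: %d zero-variance voxels set to t=0", n_zero)
    t = np.zeros_like(diff)
    np.divide(diff, denom, out=t, where=~zero)
    if direction == SUBJECT_GREATER:
        t = -t

    if mask is None:
        mask = np.ones_like(t, dtype=bool)
    t[~mask] = 0.0
    return TMap(t, df=n - 1, direction=direction, mask=mask,
                voxel_mm=subject.voxel_mm, n_zero_variance=n_zero)


def threshold_and_cluster(
    tmap: TMap, p: float = 0.001, connectivity: int = 18
) -> ClusterReport:
    """Threshold at the one-sided t quantile for P < p and form clusters.

    For a ``two_sided`` map the threshold is applied to |t| at p/2 per
    tail.  Clusters are sorted by peak T, descending.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    if tmap.direction == TWO_SIDED:
        t_crit = float(stats.t.ppf(1.0 - p / 2.0, tmap.df))
        field_vals = np.abs(tmap.t_values)
    else:
        t_crit = float(stats.t.ppf(1.0 - p, tmap.df))
        field_vals = tmap.t_values
    supra = (field_vals >= t_crit) & tmap.mask
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_labels = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_labels + 1):
        idx = np.nonzero(labels == lab)
        vals = field_vals[idx]
        k = int(np.argmax(vals))
        clusters.append(Cluster(
            size=idx[0].size, peak_t=float(vals[k]),
            peak_voxel=(int(idx[0][k]), int(idx[1][k]), int(idx[2][k])),
        ))
    clusters.sort(key=lambda c: c.peak_t, reverse=True)
    return ClusterReport(clusters, threshold_t=t_crit, p_uncorrected=p,
                         label_map=labels)


def detect_lesion(report: ClusterReport, lesion_mask: np.ndarray) -> bool:
    """Hit iff any suprathreshold cluster touches the 1-voxel-dilated lesion."""
    if not report.clusters:
        return False
    dilated = ndimage.binary_dilation(
        lesion_mask.astype(bool), structure=ndimage.generate_binary_structure(3, 3)
    )
    return bool(np.any((report.label_map > 0) & dilated))
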