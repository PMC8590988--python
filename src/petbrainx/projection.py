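"""Maximum-intensity projections and the 224x224 network inputs.

Two views are produced from each volume: ``anterior`` (maximum over
the AP axis; image columns = x) and ``lateral`` (maximum over the LR
axis; image columns = y).  In both views the image row axis is the
volume z axis with the superior end at row 0, the familiar way PET
MIPs are displayed.

Preprocessing reproduces the network input recipe: zero-pad the
shorter image axis to a square (split evenly, extra pixel on the
high-index side), resize to 224x224 with bilinear interpolation, then
map SUV ``v`` to ``min(v, 30) / 30 * 255``.  Padding offsets and the
resize scale are recorded so predicted pixel coordinates can be mapped
back to voxel indices exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

ANTERIOR = "anterior"
LATERAL = "lateral"

TARGET_SIZE = 224
SUV_CLIP = 30.0


@dataclass
class MIPImage:
    """A MIP view plus the bookkeeping needed to invert preprocessing.

    ``pixels`` is (rows, cols).  ``source_shape`` is the projected
    image shape before padding; ``pad_before`` gives the zero pixels
    prepended per image axis and ``scale`` the resize factor per axis
    (both None until :func:`preprocess` runs).  ``volume_shape`` is the
    originating grid, kept so row indices can be flipped back to z.
    """

    pixels: np.ndarray
    view: str
    volume_shape: tuple[int, int, int]
    source_shape: tuple[int, int] | None = None
    pad_before: tuple[int, int] | None = None
    scale: tuple[float, float] | None = None

    @property
    def preprocessed(self) -> bool:
        return self.pad_before is not None

    def axis_extents(self) -> tuple[int, int]:
        """Voxel extents of the (row, col) image axes: (nz, nx-or-ny)."""
        nx, ny, nz = self.volume_shape
        return (nz, nx if self.view == ANTERIOR else ny)


def mip(volume, view: str) -> MIPImage:
    """Project a volume into one MIP view."""
    data = np.asarray(volume.data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={data.ndim}")
    if view == ANTERIOR:
        proj = data.max(axis=1)  # (x, z)
    elif view == LATERAL:
        proj = data.max(axis=0)  # (y, z)
    else:
        raise ValueError(f"unknown view {view!r}")
    # rows = z flipped (superior at row 0), cols = x or y
    pixels = proj.T[::-1, :].copy()
    return MIPImage(pixels, view, tuple(data.shape), source_shape=pixels.shape)


def preprocess(mip_image: MIPImage) -> MIPImage:
    """Pad to square, resize to 224x224 and scale SUV to ~[0, 255]."""
    px = np.asarray(mip_image.pixels, dtype=np.float64)
    rows, cols = px.shape
    side = max(rows, cols)
    pad = []
    for extent in (rows, cols):
        total = side - extent
        before = total // 2
        pad.append((before, total - before))
    padded = np.pad(px, pad, mode="constant")
    resized = _sk_resize(
        padded,
        (TARGET_SIZE, TARGET_SIZE),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
        mode="constant",
    )
    scaled = np.minimum(resized, SUV_CLIP) / SUV_CLIP * 255.0
    return dc_replace(
        mip_image,
        pixels=scaled.astype(np.float32),
        source_shape=(rows, cols),
        pad_before=(pad[0][0], pad[1][0]),
        scale=(TARGET_SIZE / side, TARGET_SIZE / side),
    )


def _require_bookkeeping(mip_image: MIPImage) -> None:
    if not mip_image.preprocessed:
        raise ValueError("MIP image lacks preprocessing bookkeeping (run preprocess first)")


# -- continuous pixel <-> source-image coordinate maps ----------------
#
# skimage's resize samples output pixel p at input coordinate
# (p + 0.5)/scale - 0.5, so that is the exact inverse used here.

def _px_to_src(p: np.ndarray, pad: float, scale: float) -> np.ndarray:
    return (np.asarray(p, dtype=float) + 0.5) / scale - 0.5 - pad


def _src_to_px(s: np.ndarray, pad: float, scale: float) -> np.ndarray:
    return (np.asarray(s, dtype=float) + pad + 0.5) * scale - 0.5


def pixel_to_voxel(mip_image: MIPImage, point2d) -> tuple[int, int]:
    """Map a preprocessed-image pixel (row, col) to voxel indices.

    Returns ``(a, z)`` where ``a`` is the x (anterior) or y (lateral)
    voxel index.  Rounds half-up and clips to the volume bounds, so
    points in the zero-padding map to the nearest in-bounds voxel.
    """
    _require_bookkeeping(mip_image)
    row, col = point2d
    nz, na = mip_image.axis_extents()
    src_row = _px_to_src(row, mip_image.pad_before[0], mip_image.scale[0])
    src_col = _px_to_src(col, mip_image.pad_before[1], mip_image.scale[1])
    z = int(np.clip(np.floor((nz - 1 - src_row) + 0.5), 0, nz - 1))
    a = int(np.clip(np.floor(src_col + 0.5), 0, na - 1))
    return a, z


def voxel_to_pixel(mip_image: MIPImage, voxel) -> tuple[int, int]:
    """Inverse of :func:`pixel_to_voxel` (voxel ``(a, z)`` -> (row, col))."""
    _require_bookkeeping(mip_image)
    a, z = voxel
    nz, _ = mip_image.axis_extents()
    row = _src_to_px(nz - 1 - z, mip_image.pad_before[0], mip_image.scale[0])
    col = _src_to_px(a, mip_image.pad_before[1], mip_image.scale[1])
    return int(np.floor(row + 0.5)), int(np.floor(col + 0.5))


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random training-time augmentations."""

    intensity: tuple[float, float] = (0.8, 1.2)
    gamma: tuple[float, float] = (0.8, 1.25)
    scale: tuple[float, float] = (0.9, 1.1)
    translate_px: float = 10.0


def _geometric_warp(pixels: np.ndarray, s: float, t: tuple[float, float]) -> np.ndarray:
    """Scale about the image centre by s, then translate by t (row, col)."""
    if s == 1.0 and t == (0.0, 0.0):
        return pixels
    c = (np.array(pixels.shape, dtype=float) - 1.0) / 2.0
    # output p samples input (p - c - t)/s + c
    offset = c - (c + np.asarray(t)) / s
    return ndimage.affine_transform(
        pixels, np.eye(2) / s, offset=offset, order=1, mode="constant", cval=0.0
    )


def transform_point(point, s: float, t, image_side: int = TARGET_SIZE):
    """Forward map of a pixel point under the scale+translate augmentation."""
    c = (image_side - 1.0) / 2.0
    p = np.asarray(point, dtype=float)
    return s * (p - c) + c + np.asarray(t, dtype=float)


def augment(
    mip_image: MIPImage,
    seed=None,
    params: AugmentParams = AugmentParams(),
    box=None,
    geometry: tuple[float, float, float] | None = None,
):
    """Randomly augment a preprocessed MIP (and its paired box label).

    Applies intensity multiplication, gamma contrast, isotropic scaling
    about the image centre and translation.  ``box``, when given as
    ``(min_row, min_col, size_rows, size_cols)`` in pixels, is
    transformed identically for the geometric part and returned
    alongside.  ``geometry`` forces (s, t_row, t_col), used to share
    one geometric draw across the two views of a sample.
    """
    _require_bookkeeping(mip_image)
    rng = np.random.default_rng(seed)
    m = rng.uniform(*params.intensity)
    g = rng.uniform(*params.gamma)
    if geometry is None:
        s = rng.uniform(*params.scale)
        t = (rng.uniform(-params.translate_px, params.translate_px),
             rng.uniform(-params.translate_px, params.translate_px))
    else:
        s, t = geometry[0], (geometry[1], geometry[2])

    px = np.asarray(mip_image.pixels, dtype=np.float64)
    px = np.clip(px * m, 0.0, 255.0)
    if g != 1.0:
        px = 255.0 * np.power(px / 255.0, g)
    px = _geometric_warp(px, s, t)
    out = dc_replace(mip_image, pixels=px.astype(np.float32))
    if box is None:
        return out
    r0, c0, sr, sc = box
    lo = transform_point((r0, c0), s, t)
    hi = transform_point((r0 + sr, c0 + sc), s, t)
    new_box = (lo[0], lo[1], hi[0] - lo[0], hi[1] - lo[1])
    return out, new_box
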