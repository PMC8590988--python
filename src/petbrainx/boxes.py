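"""Axis-aligned bounding-box geometry and annotation I/O.

Boxes are stored as an integer min-corner plus a positive integer size
and cover the half-open voxel interval ``[min, min + size)`` on every
axis.  2-D boxes live in a named view frame (``anterior`` = (x, z)
columns/rows, ``lateral`` = (y, z)); 3-D boxes live on the volume grid.
The network regresses a 6-vector ``(min_x, min_y, min_z, size_x,
size_y, size_z)`` normalized by the grid extent so every component lies
in [0, 1] regardless of scan coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

ANTERIOR = "anterior"
LATERAL = "lateral"


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class Box2D:
    min_corner: tuple[int, int]
    size: tuple[int, int]
    frame: str = ANTERIOR

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError(f"Box2D size must be positive, got {self.size}")

    @property
    def max_corner(self) -> tuple[int, int]:
        return tuple(m + s for m, s in zip(self.min_corner, self.size))


@dataclass(frozen=True)
class Box3D:
    min_corner: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError(f"Box3D size must be positive, got {self.size}")

    @property
    def max_corner(self) -> tuple[int, int, int]:
        return tuple(m + s for m, s in zip(self.min_corner, self.size))

    def volume(self) -> int:
        return int(np.prod(self.size))

    def contains(self, voxel) -> bool:
        return all(m <= v < M for m, v, M in zip(self.min_corner, voxel, self.max_corner))

    def to_dict(self) -> dict:
        return {"min_corner": list(self.min_corner), "size": list(self.size)}

    @classmethod
    def from_dict(cls, d: dict) -> "Box3D":
        return cls(tuple(int(v) for v in d["min_corner"]), tuple(int(v) for v in d["size"]))


def from_mask(mask: np.ndarray) -> Box3D:
    """Tight 3-D bounding box of the True voxels of a binary mask."""
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("mask has no foreground voxels")
    mins = [int(ax.min()) for ax in idx]
    maxs = [int(ax.max()) + 1 for ax in idx]
    return Box3D(tuple(mins), tuple(M - m for m, M in zip(mins, maxs)))


def merge_views(anterior: Box2D, lateral: Box2D) -> Box3D:
    """Merge anterior (x, z) and lateral (y, z) 2-D boxes into a 3-D box.

    The x extent comes from the anterior view and the y extent from the
    lateral view.  The two views each constrain z; they are reconciled
    by the union (smallest z-min to largest z-max) so the merged box is
    guaranteed to contain any 3-D box whose projections are the inputs.
    """
    if anterior.frame != ANTERIOR or lateral.frame != LATERAL:
        raise ValueError(
            f"expected frames ({ANTERIOR}, {LATERAL}), got ({anterior.frame}, {lateral.frame})"
        )
    x0, az0 = anterior.min_corner
    x1, az1 = anterior.max_corner
    y0, lz0 = lateral.min_corner
    y1, lz1 = lateral.max_corner
    z0, z1 = min(az0, lz0), max(az1, lz1)
    return Box3D((x0, y0, z0), (x1 - x0, y1 - y0, z1 - z0))


def encode(box: Box3D, grid_shape) -> np.ndarray:
    """Normalize a box to a 6-vector in [0, 1] by the grid extent."""
    g = np.asarray(grid_shape, dtype=float)
    mn = np.asarray(box.min_corner, dtype=float)
    sz = np.asarray(box.size, dtype=float)
    return np.concatenate([mn / g, sz / g])


def decode(vector, grid_shape) -> Box3D:
    """Invert :func:`encode` with round-half-up, clipping to the grid.

    Components far outside [0, 1] are rejected as implausible
    predictions rather than silently clipped.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (6,):
        raise ValueError(f"expected a 6-vector, got shape {v.shape}")
    if np.any(v < -0.5) or np.any(v > 1.5):
        raise ValueError(f"implausible box vector (components outside [-0.5, 1.5]): {v}")
    g = np.asarray(grid_shape, dtype=int)
    mn = np.clip(_round_half_up(v[:3] * g), 0, g - 1)
    mx = np.clip(_round_half_up((v[:3] + v[3:]) * g), mn + 1, g)
    return Box3D(tuple(int(m) for m in mn), tuple(int(s) for s in mx - mn))


def iou3d(a: Box3D, b: Box3D) -> float:
    """Intersection-over-union of two half-open 3-D boxes."""
    inter = 1
    for (am, asz), (bm, bsz) in zip(
        zip(a.min_corner, a.size), zip(b.min_corner, b.size)
    ):
        lo = max(am, bm)
        hi = min(am + asz, bm + bsz)
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    union = a.volume() + b.volume() - inter
    return inter / union


def project(box: Box3D, frame: str) -> Box2D:
    """Project a 3-D box into a MIP view frame."""
    (x0, y0, z0), (sx, sy, sz) = box.min_corner, box.size
    if frame == ANTERIOR:
        return Box2D((x0, z0), (sx, sz), ANTERIOR)
    if frame == LATERAL:
        return Box2D((y0, z0), (sy, sz), LATERAL)
    raise ValueError(f"unknown frame {frame!r}")


def read_via_annotations(path) -> dict[str, dict]:
    """Read a VGG Image Annotator (VIA) project export.

    Returns a mapping from image filename to a record with keys
    ``whole_brain_present`` (bool) and, when annotated, ``anterior``
    and ``lateral`` :class:`Box2D`.  Rectangle regions must carry a
    ``view`` region attribute naming the MIP view; an image with zero
    regions is flagged as not containing the entire brain.
    """
    with open(path) as fh:
        doc = json.load(fh)
    # VIA project exports nest under "_via_img_metadata"; plain region
    # exports are the mapping itself.
    meta = doc.get("_via_img_metadata", doc)
    out: dict[str, dict] = {}
    for key, entry in meta.items():
        name = entry.get("filename", key)
        regions = entry.get("regions", [])
        if not regions:
            out[name] = {"whole_brain_present": False}
            continue
        rec: dict = {"whole_brain_present": True}
        for region in regions:
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "rect":
                raise ValueError(
                    f"{name}: unsupported region type {shape.get('name')!r}; only 'rect'"
                )
            view = region.get("region_attributes", {}).get("view")
            if view not in (ANTERIOR, LATERAL):
                raise ValueError(f"{name}: region lacks a valid 'view' attribute")
            rec[view] = Box2D(
                (int(shape["x"]), int(shape["y"])),
                (int(shape["width"]), int(shape["height"])),
                frame=view,
            )
        out[name] = rec
    return out
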