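"""Pixel-grid primitives shared by every pipeline stage.

Conventions used throughout the package:

* Images are ``(H, W, 3)`` uint8 arrays, row-major, origin at the top-left,
  red-green-blue channel order.
* Binary masks are ``(H, W)`` bool arrays on the same grid.
* Bounding boxes are half-open integer rectangles ``[x0, x1) x [y0, y1)``,
  so ``area == (x1 - x0) * (y1 - y0)`` with no off-by-one corrections.
* Pixel ``(i, j)`` (row i, column j) covers the unit square
  ``[j, j+1) x [i, i+1)`` and has its center at ``(j + 0.5, i + 0.5)``.
* Polygon vertices are stored normalized to ``[0, 1]`` relative to the
  image width/height; denormalization multiplies x by width and y by height.

Rasterization follows the pixel-center even-odd rule: a pixel belongs to a
polygon iff its center lies inside under even-odd (crossing-number) counting.
This rule is the package's contract — it is unambiguous and directly
verifiable by brute-force point-in-polygon testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image as _PILImage

__all__ = [
    "BoundingBox",
    "PolygonOutline",
    "Crop",
    "InvalidAnnotationError",
    "rasterize_polygon",
    "mask_iou",
    "box_iou",
    "crop",
    "mask_to_box",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
]


class InvalidAnnotationError(ValueError):
    """An annotation violates its structural contract (e.g. < 3 vertices)."""


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Half-open integer pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate box ({self.x0},{self.y0},{self.x1},{self.y1}): "
                "need x0 < x1 and y0 < y1"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x1, other.x1) - max(self.x0, other.x0)
        ih = min(self.y1, other.y1) - max(self.y0, other.y0)
        return iw * ih if iw > 0 and ih > 0 else 0

    def expand(self, pad: int) -> "BoundingBox":
        return BoundingBox(self.x0 - pad, self.y0 - pad, self.x1 + pad, self.y1 + pad)

    def clip(self, width: int, height: int) -> "BoundingBox":
        """Clip to an image grid; raises if nothing remains."""
        x0, y0 = max(self.x0, 0), max(self.y0, 0)
        x1, y1 = min(self.x1, width), min(self.y1, height)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"box {self} lies fully outside a {width}x{height} image")
        return BoundingBox(x0, y0, x1, y1)

    def to_yolo(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Normalized (cx, cy, w, h) center-size representation."""
        return (
            (self.x0 + self.x1) / 2 / width,
            (self.y0 + self.y1) / 2 / height,
            self.width / width,
            self.height / height,
        )

    @classmethod
    def from_yolo(
        cls, cx: float, cy: float, w: float, h: float, width: int, height: int
    ) -> "BoundingBox":
        """Nearest-integer box from normalized center-size coordinates."""
        x0 = int(round((cx - w / 2) * width))
        x1 = int(round((cx + w / 2) * width))
        y0 = int(round((cy - h / 2) * height))
        y1 = int(round((cy + h / 2) * height))
        return cls(x0, y0, max(x1, x0 + 1), max(y1, y0 + 1))


@dataclass(frozen=True)
class PolygonOutline:
    """Closed polygon with vertices normalized to [0, 1].

    The outline is implicitly closed (last vertex connects to the first).
    Predictions may carry a confidence score; ground truth leaves it None.
    """

    vertices: tuple[tuple[float, float], ...]
    class_id: int = 0
    confidence: float | None = None

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise InvalidAnnotationError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized over points.

    ``px``/``py`` are flat coordinate arrays; ``poly`` is (V, 2) in the same
    (pixel) coordinate frame. A horizontal ray is cast toward +x; the half-open
    vertex rule (y0 <= y) != (y1 <= y) counts each crossing exactly once.
    """
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    dy = y1 - y0
    # Horizontal edges never straddle the ray; keep dy nonzero to avoid 0/0.
    safe_dy = np.where(dy == 0, 1.0, dy)
    px = px[:, None]
    py = py[:, None]
    straddles = (y0[None, :] <= py) != (y1[None, :] <= py)
    x_at_y = x0[None, :] + (py - y0[None, :]) * (x1 - x0)[None, :] / safe_dy[None, :]
    crossings = np.count_nonzero(straddles & (x_at_y > px), axis=1)
    return crossings % 2 == 1


def rasterize_polygon(poly: PolygonOutline, width: int, height: int) -> np.ndarray:
    """Rasterize a normalized polygon onto a ``(height, width)`` bool mask.

    A pixel is a member iff its center lies inside the denormalized polygon
    under the even-odd rule. Work is confined to the polygon's bounding
    window and chunked by rows to bound memory.
    """
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    pts = poly.as_array() * np.array([width, height], dtype=float)
    mask = np.zeros((height, width), dtype=bool)

    c_lo = max(int(np.floor(pts[:, 0].min() - 1)), 0)
    c_hi = min(int(np.ceil(pts[:, 0].max() + 1)), width)
    r_lo = max(int(np.floor(pts[:, 1].min() - 1)), 0)
    r_hi = min(int(np.ceil(pts[:, 1].max() + 1)), height)
    if c_lo >= c_hi or r_lo >= r_hi:
        return mask

    xs = np.arange(c_lo, c_hi) + 0.5
    chunk = max(1, int(2_000_000 / max(len(xs) * len(pts), 1)))
    for r0 in range(r_lo, r_hi, chunk):
        r1 = min(r0 + chunk, r_hi)
        ys = np.arange(r0, r1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = _points_in_polygon(gx.ravel(), gy.ravel(), pts)
        mask[r0:r1, c_lo:c_hi] = inside.reshape(r1 - r0, len(xs))
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks on the same grid.

    Returns 0.0 when the union is empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open integer boxes."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass
class Crop:
    """A sub-image plus the bookkeeping needed to map results back.

    ``offset`` is the (x, y) of this crop's top-left corner on the parent
    grid; ``parent_size`` is the parent's (width, height). Masks computed on
    the crop are placed back on the parent grid with :meth:`place_mask`.
    ``image_id`` travels along so file-based prediction backends can look up
    stored predictions for the right plate.
    """

    image: np.ndarray
    offset: tuple[int, int] = (0, 0)
    parent_size: tuple[int, int] | None = None
    image_id: str | None = None

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def place_mask(self, mask: np.ndarray) -> np.ndarray:
        """Embed a crop-grid mask back onto the parent grid."""
        if self.parent_size is None:
            raise ValueError("crop has no recorded parent size")
        pw, ph = self.parent_size
        out = np.zeros((ph, pw), dtype=bool)
        ox, oy = self.offset
        out[oy : oy + self.height, ox : ox + self.width] = mask
        return out

    def take_mask(self, plate_mask: np.ndarray) -> np.ndarray:
        """Slice a parent-grid mask down to this crop's window."""
        ox, oy = self.offset
        return plate_mask[oy : oy + self.height, ox : ox + self.width]


def crop(img: np.ndarray, box: BoundingBox, pad: int = 4, image_id: str | None = None) -> Crop:
    """Extract ``box`` expanded by ``pad`` on all sides, clipped to the image.

    Raises ValueError if the box does not intersect the image at all.
    """
    h, w = img.shape[:2]
    clipped = box.expand(pad).clip(w, h)
    return Crop(
        image=img[clipped.y0 : clipped.y1, clipped.x0 : clipped.x1],
        offset=(clipped.x0, clipped.y0),
        parent_size=(w, h),
        image_id=image_id,
    )


def mask_to_box(mask: np.ndarray) -> BoundingBox:
    """Tight half-open bounding box of a nonempty mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot box an empty mask")
    return BoundingBox(int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def read_image(path: str | Path) -> np.ndarray:
    with _PILImage.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(img: np.ndarray, path: str | Path) -> None:
    _PILImage.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Export a binary mask as a single-channel PNG with values 0/255."""
    _PILImage.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    with _PILImage.open(path) as im:
        return np.asarray(im.convert("L")) >= 128
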