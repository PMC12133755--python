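"""YOLO-dialect label files, deterministic dataset splits, and augmentation.

Label dialect (one text file per image, same stem):

* box line: ``class_id cx cy w h [confidence]`` — normalized center-size;
* polygon line: ``class_id x1 y1 x2 y2 ... [confidence]`` — >= 3 normalized
  vertex pairs.

Ground-truth records carry no confidence; prediction records carry one as a
trailing field. For polygons the token-count parity disambiguates the two
(class + even coordinate count = odd token total for truth, even for
predictions), but the caller states ``source`` explicitly and mismatches are
parse errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage import color as _skcolor
from skimage import exposure as _skexposure
from skimage import transform as _sktransform

from .raster_core import PolygonOutline

__all__ = [
    "BoxRecord",
    "AnnotationSet",
    "SplitPlan",
    "LabelParseError",
    "read_labels",
    "write_labels",
    "split_dataset",
    "augment",
    "flip_annotated",
    "rotate_annotated",
    "photometric",
    "AUGMENT_OPS",
]

_COORD_TOL = 1e-6


class LabelParseError(ValueError):
    """A label file line violates the dialect; the message names the line."""


@dataclass(frozen=True)
class BoxRecord:
    """One normalized center-size detection record."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None


@dataclass
class AnnotationSet:
    """All labels for one image, either ground truth or predictions."""

    image_id: str
    boxes: list[BoxRecord] = field(default_factory=list)
    polygons: list[PolygonOutline] = field(default_factory=list)
    source: str = "ground-truth"  # or "prediction"


def _check_unit(values: Iterable[float], path: Path, lineno: int) -> list[float]:
    out = []
    for v in values:
        if v < -_COORD_TOL or v > 1 + _COORD_TOL:
            raise LabelParseError(
                f"{path}:{lineno}: coordinate {v} outside [0, 1]"
            )
        out.append(min(max(v, 0.0), 1.0))
    return out


def read_labels(
    path: str | Path, kind: str, source: str = "ground-truth"
) -> AnnotationSet:
    """Parse one label file. ``kind`` is ``"box"`` or ``"polygon"``."""
    path = Path(path)
    if kind not in ("box", "polygon"):
        raise ValueError(f"kind must be 'box' or 'polygon', got {kind!r}")
    aset = AnnotationSet(image_id=path.stem, source=source)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            try:
                class_id = int(tokens[0])
                values = [float(t) for t in tokens[1:]]
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: unparseable token ({exc})")
            if kind == "box":
                expected = 6 if source == "prediction" else 5
                if len(tokens) != expected:
                    raise LabelParseError(
                        f"{path}:{lineno}: box record needs {expected} fields, "
                        f"got {len(tokens)}"
                    )
                conf = values.pop() if source == "prediction" else None
                cx, cy, w, h = _check_unit(values, path, lineno)
                aset.boxes.append(BoxRecord(class_id, cx, cy, w, h, conf))
            else:
                conf = None
                if source == "prediction":
                    if len(values) % 2 != 1:
                        raise LabelParseError(
                            f"{path}:{lineno}: prediction polygon needs an even "
                            "coordinate count plus a trailing confidence"
                        )
                    conf = values.pop()
                if len(values) % 2 != 0 or len(values) < 6:
                    raise LabelParseError(
                        f"{path}:{lineno}: polygon needs an even coordinate "
                        f"count >= 6, got {len(values)}"
                    )
                coords = _check_unit(values, path, lineno)
                verts = tuple(zip(coords[0::2], coords[1::2]))
                aset.polygons.append(
                    PolygonOutline(verts, class_id=class_id, confidence=conf)
                )
    return aset


def write_labels(aset: AnnotationSet, path: str | Path, kind: str) -> Path:
    """Write labels with 6-decimal coordinates; stable record order."""
    path = Path(path)
    lines = []
    if kind == "box":
        for b in aset.boxes:
            fields = [str(b.class_id)] + [f"{v:.6f}" for v in (b.cx, b.cy, b.w, b.h)]
            if aset.source == "prediction":
                fields.append(f"{b.confidence if b.confidence is not None else 1.0:.6f}")
            lines.append(" ".join(fields))
    elif kind == "polygon":
        for p in aset.polygons:
            coords = [f"{v:.6f}" for xy in p.vertices for v in xy]
            fields = [str(p.class_id)] + coords
            if aset.source == "prediction":
                fields.append(f"{p.confidence if p.confidence is not None else 1.0:.6f}")
            lines.append(" ".join(fields))
    else:
        raise ValueError(f"kind must be 'box' or 'polygon', got {kind!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


@dataclass
class SplitPlan:
    """Deterministic train/validation/test partition of image ids."""

    train: list[str]
    validation: list[str]
    test: list[str]
    ratio: tuple[float, float, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train,
                    "validation": self.validation,
                    "test": self.test,
                    "ratio": list(self.ratio),
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["validation"], d["test"], tuple(d["ratio"]), d["seed"])


def split_dataset(
    image_ids: Sequence[str],
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Shuffle-and-slice split: floor sizes for validation/test, remainder
    to train. 185 images at 8:1:1 give the canonical 149/18/18 partition.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratio}")
    if len(image_ids) < 3:
        raise ValueError("need at least 3 images to split")
    ids = list(image_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_val = int(math.floor(n * ratio[1] + 1e-9))
    n_test = int(math.floor(n * ratio[2] + 1e-9))
    n_train = n - n_val - n_test
    return SplitPlan(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        ratio=tuple(ratio),
        seed=seed,
    )


# --- annotation-preserving augmentation ------------------------------------

AUGMENT_OPS = (
    "hflip",
    "vflip",
    "rotate",
    "saturation",
    "brightness",
    "exposure",
)


def _transform_boxes(boxes, fn):
    """Rebuild each box as the axis-aligned hull of its transformed corners."""
    out = []
    for b in boxes:
        corners = np.array(
            [
                [b.cx - b.w / 2, b.cy - b.h / 2],
                [b.cx + b.w / 2, b.cy - b.h / 2],
                [b.cx + b.w / 2, b.cy + b.h / 2],
                [b.cx - b.w / 2, b.cy + b.h / 2],
            ]
        )
        t = np.clip(fn(corners), 0.0, 1.0)
        x0, y0 = t.min(axis=0)
        x1, y1 = t.max(axis=0)
        out.append(
            BoxRecord(b.class_id, (x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0,
                      b.confidence)
        )
    return out


def _transform_polygons(polys, fn):
    out = []
    for p in polys:
        verts = np.clip(fn(p.as_array()), 0.0, 1.0)
        out.append(PolygonOutline(tuple(map(tuple, verts)), p.class_id, p.confidence))
    return out


def _apply_geometric(aset: AnnotationSet, fn) -> AnnotationSet:
    return AnnotationSet(
        image_id=aset.image_id,
        boxes=_transform_boxes(aset.boxes, fn),
        polygons=_transform_polygons(aset.polygons, fn),
        source=aset.source,
    )


def flip_annotated(
    image: np.ndarray, aset: AnnotationSet, axis: str
) -> tuple[np.ndarray, AnnotationSet]:
    """Mirror image and annotations horizontally or vertically."""
    if axis == "horizontal":
        img = image[:, ::-1].copy()
        fn = lambda v: np.stack([1.0 - v[:, 0], v[:, 1]], axis=1)
    elif axis == "vertical":
        img = image[::-1].copy()
        fn = lambda v: np.stack([v[:, 0], 1.0 - v[:, 1]], axis=1)
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return img, _apply_geometric(aset, fn)


def rotate_annotated(
    image: np.ndarray,
    aset: AnnotationSet,
    angle_deg: float,
    background: tuple[int, int, int] = (245, 245, 240),
) -> tuple[np.ndarray, AnnotationSet]:
    """Rotate counter-clockwise about the image center, canvas size kept.

    Exposed pixels are filled with the background reference color. Exact
    multiples of 90 degrees go through lattice transposition so mask areas
    are preserved bit-exactly; annotations are transformed analytically in
    either path.
    """
    h, w = image.shape[:2]
    k = angle_deg / 90.0
    if abs(k - round(k)) < 1e-9 and h == w:
        img = np.rot90(image, k=int(round(k)) % 4).copy()
    else:
        valid = _sktransform.rotate(
            np.ones(image.shape[:2]), angle_deg, resize=False, order=0
        )
        img = _sktransform.rotate(
            image.astype(float), angle_deg, resize=False, order=1, mode="constant",
            cval=0.0, preserve_range=True,
        )
        img[valid < 0.5] = np.asarray(background, dtype=float)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # Vertex map in pixel coordinates. A content point p moves to
    # c + R(-a) (p - c) in (x, y-down) coordinates for a CCW visual rotation,
    # matching both np.rot90 and skimage.transform.rotate.
    a = math.radians(angle_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)
    cx, cy = w / 2.0, h / 2.0

    def fn(verts: np.ndarray) -> np.ndarray:
        px = verts[:, 0] * w - cx
        py = verts[:, 1] * h - cy
        qx = cos_a * px + sin_a * py + cx
        qy = -sin_a * px + cos_a * py + cy
        return np.stack([qx / w, qy / h], axis=1)

    return img, _apply_geometric(aset, fn)


def photometric(
    image: np.ndarray, op: str, scale: float
) -> np.ndarray:
    """Saturation / brightness / exposure adjustment; annotations unchanged."""
    img = image.astype(float) / 255.0
    if op == "saturation":
        hsv = _skcolor.rgb2hsv(img)
        hsv[..., 1] = np.clip(hsv[..., 1] * scale, 0, 1)
        out = _skcolor.hsv2rgb(hsv)
    elif op == "brightness":
        out = np.clip(img * scale, 0, 1)
    elif op == "exposure":
        out = _skexposure.adjust_gamma(img, gamma=1.0 / scale)
    else:
        raise ValueError(f"unknown photometric op {op!r}")
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def augment(
    image: np.ndarray,
    aset: AnnotationSet,
    ops: Sequence[str],
    seed: int = 0,
    n_copies: int = 3,
    keep_original: bool = False,
    background: tuple[int, int, int] = (245, 245, 240),
) -> list[tuple[np.ndarray, AnnotationSet]]:
    """Produce ``n_copies`` augmented (image, annotations) pairs.

    Each copy applies every requested op family with randomly drawn
    parameters: flips with probability 1/2 each, rotation uniform in
    [-180, 180) degrees, photometric scales uniform in [0.7, 1.3].
    ``keep_original = False`` follows the convention that "augmented three
    times" means the final set is three augmented copies per original.
    """
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {op!r}; choose from {AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, AnnotationSet]] = []
    if keep_original:
        out.append((image, aset))
    for c in range(n_copies):
        img, cur = image, aset
        for op in ops:
            if op == "hflip":
                if rng.random() < 0.5:
                    img, cur = flip_annotated(img, cur, "horizontal")
            elif op == "vflip":
                if rng.random() < 0.5:
                    img, cur = flip_annotated(img, cur, "vertical")
            elif op == "rotate":
                angle = rng.uniform(-180.0, 180.0)
                img, cur = rotate_annotated(img, cur, angle, background)
            else:
                scale = rng.uniform(0.7, 1.3)
                img = photometric(img, op, scale)
        cur = AnnotationSet(
            image_id=f"{aset.image_id}_aug{c + 1}",
            boxes=cur.boxes,
            polygons=cur.polygons,
            source=cur.source,
        )
        out.append((img, cur))
    return out
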