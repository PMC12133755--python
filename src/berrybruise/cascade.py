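"""The three-stage bruising pipeline: detect, segment berry, segment bruise.

The pipeline mirrors a detect-then-refine cascade: a detector proposes one
bounding box per berry half on the plate; each box is cropped (with padding)
and a cross-section segmenter isolates the berry from the background; a
bruise segmenter then marks discolored flesh inside that cross-section. The
per-berry phenotype is the bruising ratio = bruise pixels / cross-section
pixels, always in [0, 1] after the bruise mask is clipped to the berry mask.

Engines are pluggable behind a minimal contract (``predict`` on a
:class:`~berrybruise.raster_core.Crop`), so the same orchestration runs on:

* ``classical`` backends — deterministic thresholding/morphology reference
  implementations suited to the plain white-background imaging setup;
* ``file`` backends — externally produced predictions (e.g. from trained
  instance-segmentation models) ingested as YOLO-dialect label files;
* ground-truth backends — the generator's exact masks, the identity path
  used to validate the orchestration itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from PIL import Image as _PILImage, ImageDraw as _PILDraw
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters, morphology

from . import annot_io
from .raster_core import (
    BoundingBox,
    Crop,
    crop as crop_image,
    mask_to_box,
    rasterize_polygon,
)

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationFailure",
    "ClassicalDetector",
    "ClassicalBerrySegmenter",
    "ClassicalBruiseSegmenter",
    "FileDetector",
    "FileBerrySegmenter",
    "FileBruiseSegmenter",
    "ground_truth_backends",
    "BerryResult",
    "PlateResult",
    "PipelineParams",
    "run_plate",
    "classical_backends",
    "file_backends",
]


class SegmentationFailure(RuntimeError):
    """A segmenter could not produce a nonempty mask for one berry."""


class Detector(Protocol):
    task = "detect"

    def predict(self, plate: Crop) -> list[tuple[BoundingBox, float]]: ...


class Segmenter(Protocol):
    task: str

    def predict(self, crop: Crop) -> np.ndarray: ...


# --- classical reference backends ------------------------------------------


@dataclass
class ClassicalDetector:
    """Otsu + morphology + connected components on the grayscale plate.

    Berries are dark-rimmed objects on a light background: the global Otsu
    cut isolates the dark skin annulus, opening removes speckle, closing and
    hole-filling solidify each berry (the pale flesh interior thresholds as
    background), and components are filtered by area. Confidence is an
    area-based score, ``min(1, area / (2 * area_min))``.
    """

    morph_radius: int = 3
    area_min: int = 500
    area_max: int | None = None
    task: str = "detect"

    def predict(self, plate: Crop) -> list[tuple[BoundingBox, float]]:
        gray = skcolor.rgb2gray(plate.image)
        thresh = filters.threshold_otsu(gray)
        fg = gray < thresh
        disk = morphology.disk(self.morph_radius)
        # Close and fill before opening: the dark skin is a thin annulus
        # around pale flesh, and opening a broken ring loses the berry.
        fg = ndi.binary_closing(fg, structure=disk)
        fg = ndi.binary_fill_holes(fg)
        fg = ndi.binary_opening(fg, structure=disk)
        labels, n = ndi.label(fg)
        out: list[tuple[BoundingBox, float]] = []
        for sl in ndi.find_objects(labels):
            area = int((labels[sl] > 0).sum())
            if area < self.area_min:
                continue
            if self.area_max is not None and area > self.area_max:
                continue
            box = BoundingBox(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)
            conf = min(1.0, area / (2.0 * self.area_min))
            out.append((box, conf))
        return out


@dataclass
class ClassicalBerrySegmenter:
    """Color distance to a border-estimated background, Otsu cut, largest CC.

    The background color is the median of the crop's border pixels; the
    foreground is everything whose RGB distance from it clears the Otsu cut.
    If even the Otsu threshold sits below ``min_color_dist`` the crop is
    deemed background-only and a :class:`SegmentationFailure` is raised.
    """

    min_color_dist: float = 20.0
    task: str = "segment-berry"

    def predict(self, crop: Crop) -> np.ndarray:
        img = crop.image.astype(float)
        border = np.concatenate(
            [img[0], img[-1], img[:, 0], img[:, -1]], axis=0
        )
        bg = np.median(border, axis=0)
        dist = np.sqrt(((img - bg) ** 2).sum(axis=-1))
        thresh = filters.threshold_otsu(dist)
        if thresh < self.min_color_dist:
            raise SegmentationFailure("crop appears to contain no berry")
        fg = dist > thresh
        labels, n = ndi.label(fg)
        if n == 0:
            raise SegmentationFailure("no foreground component in crop")
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        return ndi.binary_fill_holes(mask)


@dataclass
class ClassicalBruiseSegmenter:
    """Redness-index thresholding inside the estimated flesh region.

    The berry mask is shrunk past the skin annulus (depth ``skin_frac`` times
    the equivalent radius, via the Euclidean distance transform); within the
    remaining flesh a redness index (red minus green) separates discolored
    from healthy tissue by Otsu. A contrast guard keeps unbruised berries
    from being split on noise: if the index spread inside the flesh is below
    ``min_contrast`` the berry is declared bruise-free. Components smaller
    than ``min_bruise_area`` are dropped; the result is clipped to the berry.
    """

    skin_frac: float = 0.13
    min_contrast: float = 30.0
    min_bruise_area: int = 40
    task: str = "segment-bruise"

    def predict(self, crop: Crop, berry_mask: np.ndarray) -> np.ndarray:
        if not berry_mask.any():
            raise ValueError("bruise segmentation needs a nonempty berry mask")
        r_eq = float(np.sqrt(berry_mask.sum() / np.pi))
        depth = self.skin_frac * r_eq
        flesh = ndi.distance_transform_edt(berry_mask) > depth
        if not flesh.any():
            return np.zeros_like(berry_mask)
        img = crop.image.astype(float)
        redness = img[..., 0] - img[..., 1]
        vals = redness[flesh]
        if np.percentile(vals, 99.5) - np.percentile(vals, 50.0) < self.min_contrast:
            return np.zeros_like(berry_mask)
        thresh = filters.threshold_otsu(vals)
        mask = flesh & (redness > thresh)
        labels, n = ndi.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            mask = sizes[labels] >= self.min_bruise_area
            mask &= labels > 0
        return mask & berry_mask


# --- file-based prediction backends -----------------------------------------


class _FilePredictionStore:
    """Cached per-image predictions read from a directory of label files."""

    def __init__(self, directory: str | Path, kind: str):
        self.directory = Path(directory)
        self.kind = kind
        self._cache: dict[str, annot_io.AnnotationSet] = {}

    def load(self, image_id: str) -> annot_io.AnnotationSet:
        if image_id not in self._cache:
            path = self.directory / f"{image_id}.txt"
            if not path.exists():
                log.warning("no prediction file for image %r in %s", image_id, self.directory)
                self._cache[image_id] = annot_io.AnnotationSet(image_id, source="prediction")
            else:
                try:
                    aset = annot_io.read_labels(path, kind=self.kind, source="prediction")
                except annot_io.LabelParseError:
                    # Files written without confidences are accepted as
                    # unit-confidence predictions.
                    aset = annot_io.read_labels(path, kind=self.kind, source="ground-truth")
                    aset.source = "prediction"
                self._cache[image_id] = aset
        return self._cache[image_id]


@dataclass
class FileDetector:
    """Detector backed by stored box predictions, keyed by image id."""

    directory: str | Path
    task: str = "detect"

    def __post_init__(self) -> None:
        self._store = _FilePredictionStore(self.directory, "box")

    def predict(self, plate: Crop) -> list[tuple[BoundingBox, float]]:
        aset = self._store.load(plate.image_id or "")
        w, h = plate.width, plate.height
        return [
            (
                BoundingBox.from_yolo(b.cx, b.cy, b.w, b.h, w, h),
                b.confidence if b.confidence is not None else 1.0,
            )
            for b in aset.boxes
        ]


class _FileSegmenter:
    """Shared machinery: rasterize stored polygons, pick the one that best
    covers the current crop window, return its crop-grid slice."""

    def __init__(self, directory: str | Path):
        self._store = _FilePredictionStore(directory, "polygon")
        self._mask_cache: dict[str, list[np.ndarray]] = {}

    def _masks(self, image_id: str, parent_size: tuple[int, int]) -> list[np.ndarray]:
        if image_id not in self._mask_cache:
            aset = self._store.load(image_id)
            w, h = parent_size
            self._mask_cache[image_id] = [
                rasterize_polygon(p, w, h) for p in aset.polygons
            ]
        return self._mask_cache[image_id]

    def best_for_crop(self, crop: Crop) -> np.ndarray | None:
        if crop.parent_size is None or crop.image_id is None:
            raise ValueError("file-backed segmentation needs crop provenance")
        masks = self._masks(crop.image_id, crop.parent_size)
        best, best_n = None, 0
        for m in masks:
            n = int(crop.take_mask(m).sum())
            if n > best_n:
                best, best_n = m, n
        if best is None:
            return None
        return crop.take_mask(best)


@dataclass
class FileBerrySegmenter:
    directory: str | Path
    task: str = "segment-berry"

    def __post_init__(self) -> None:
        self._seg = _FileSegmenter(self.directory)

    def predict(self, crop: Crop) -> np.ndarray:
        mask = self._seg.best_for_crop(crop)
        if mask is None or not mask.any():
            raise SegmentationFailure(
                f"no stored cross-section prediction covers crop at {crop.offset}"
            )
        return mask


@dataclass
class FileBruiseSegmenter:
    directory: str | Path
    task: str = "segment-bruise"

    def __post_init__(self) -> None:
        self._seg = _FileSegmenter(self.directory)

    def predict(self, crop: Crop, berry_mask: np.ndarray) -> np.ndarray:
        mask = self._seg.best_for_crop(crop)
        if mask is None:
            return np.zeros_like(berry_mask)
        return mask & berry_mask


# --- ground-truth (identity) backends ---------------------------------------


def ground_truth_backends(berries) -> tuple[Detector, Segmenter, Segmenter]:
    """Backends that replay exact ground truth; the pipeline identity path.

    Given the generator's :class:`GroundTruthBerry` list for a plate, the
    detector returns the true boxes with confidence 1 and the segmenters
    slice the true plate-grid masks down to each crop, so pipeline ratios
    must reproduce ``true_ratio`` bit-exactly.
    """

    class _GTDetector:
        task = "detect"

        def predict(self, plate: Crop) -> list[tuple[BoundingBox, float]]:
            return [(gt.box, 1.0) for gt in berries]

    class _GTSegmenter:
        def __init__(self, which: str, task: str):
            self.which = which
            self.task = task

        def _pick(self, crop: Crop) -> np.ndarray:
            best, best_n = None, -1
            for gt in berries:
                n = int(crop.take_mask(gt.berry_mask).sum())
                if n > best_n:
                    best, best_n = gt, n
            return crop.take_mask(getattr(best, self.which))

        def predict(self, crop: Crop, berry_mask: np.ndarray | None = None) -> np.ndarray:
            mask = self._pick(crop)
            if self.which == "bruise_mask" and berry_mask is not None:
                return mask & berry_mask
            return mask

    return (
        _GTDetector(),
        _GTSegmenter("berry_mask", "segment-berry"),
        _GTSegmenter("bruise_mask", "segment-bruise"),
    )


# --- orchestration -----------------------------------------------------------


@dataclass(frozen=True)
class PipelineParams:
    """Orchestration knobs: detection confidence cut and crop padding."""

    conf_threshold: float = 0.25
    pad: int = 4


@dataclass
class BerryResult:
    """One berry half: plate-grid masks and its bruising ratio.

    ``ratio`` is None when segmentation failed for this berry; such berries
    are excluded from aggregates but kept in the record for auditability.
    """

    index: int
    box: BoundingBox
    confidence: float
    berry_mask: np.ndarray | None
    bruise_mask: np.ndarray | None
    ratio: float | None

    @property
    def berry_area(self) -> int:
        return int(self.berry_mask.sum()) if self.berry_mask is not None else 0

    @property
    def bruise_area(self) -> int:
        return int(self.bruise_mask.sum()) if self.bruise_mask is not None else 0


@dataclass
class PlateResult:
    """All berries of one plate plus run provenance."""

    image_id: str
    berries: list[BerryResult]
    backend_names: tuple[str, str, str]
    params: PipelineParams

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": self.image_id,
                "berry_index": b.index,
                "x0": b.box.x0,
                "y0": b.box.y0,
                "x1": b.box.x1,
                "y1": b.box.y1,
                "berry_area_px": b.berry_area,
                "bruise_area_px": b.bruise_area,
                "ratio": b.ratio,
            }
            for b in self.berries
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "image_id", "berry_index", "x0", "y0", "x1", "y1",
                "berry_area_px", "bruise_area_px", "ratio",
            ],
        )

    def overlay(self, image: np.ndarray) -> np.ndarray:
        """Render the review overlay: green healthy tissue, red bruise,
        index and ratio printed above each box."""
        out = image.astype(float).copy()
        green = np.array([40.0, 200.0, 40.0])
        red = np.array([220.0, 30.0, 30.0])
        alpha = 0.45
        for b in self.berries:
            if b.berry_mask is None:
                continue
            healthy = b.berry_mask & ~(b.bruise_mask if b.bruise_mask is not None else False)
            out[healthy] = (1 - alpha) * out[healthy] + alpha * green
            if b.bruise_mask is not None:
                out[b.bruise_mask] = (1 - alpha) * out[b.bruise_mask] + alpha * red
        pil = _PILImage.fromarray(np.clip(np.round(out), 0, 255).astype(np.uint8))
        draw = _PILDraw.Draw(pil)
        for b in self.berries:
            draw.rectangle([b.box.x0, b.box.y0, b.box.x1 - 1, b.box.y1 - 1],
                           outline=(30, 60, 220), width=2)
            label = f"{b.index}: " + (f"{b.ratio:.2f}" if b.ratio is not None else "n/a")
            draw.text((b.box.x0, max(b.box.y0 - 12, 0)), label, fill=(10, 10, 10))
        return np.asarray(pil)


def run_plate(
    image: np.ndarray,
    detector: Detector,
    berry_segmenter: Segmenter,
    bruise_segmenter,
    params: PipelineParams = PipelineParams(),
    image_id: str = "plate",
) -> PlateResult:
    """Run the full cascade on one plate image.

    Detections below the confidence threshold are dropped; each survivor is
    cropped with padding, segmented, its bruise mask clipped to its
    cross-section mask, and its ratio computed. Per-berry segmentation
    failures are recorded with a null ratio and logged rather than aborting
    the plate. Berry indices follow reading order (box top-left, row-major).
    """
    for backend, want in (
        (detector, "detect"),
        (berry_segmenter, "segment-berry"),
        (bruise_segmenter, "segment-bruise"),
    ):
        got = getattr(backend, "task", None)
        if got != want:
            raise ValueError(f"backend task mismatch: expected {want!r}, got {got!r}")

    h, w = image.shape[:2]
    plate = Crop(image, (0, 0), (w, h), image_id)
    detections = [
        (box, conf) for box, conf in detector.predict(plate)
        if conf >= params.conf_threshold
    ]
    detections.sort(key=lambda d: (d[0].y0, d[0].x0))

    results: list[BerryResult] = []
    for idx, (box, conf) in enumerate(detections):
        try:
            c = crop_image(image, box, pad=params.pad, image_id=image_id)
            local_berry = berry_segmenter.predict(c)
            if not local_berry.any():
                raise SegmentationFailure("empty cross-section mask")
            local_bruise = bruise_segmenter.predict(c, local_berry) & local_berry
            berry_mask = c.place_mask(local_berry)
            bruise_mask = c.place_mask(local_bruise)
            ratio = int(local_bruise.sum()) / int(local_berry.sum())
            results.append(BerryResult(idx, box, conf, berry_mask, bruise_mask, ratio))
        except SegmentationFailure as exc:
            log.warning("%s berry %d at %s: %s", image_id, idx, box, exc)
            results.append(BerryResult(idx, box, conf, None, None, None))
    names = tuple(
        type(b).__name__ for b in (detector, berry_segmenter, bruise_segmenter)
    )
    return PlateResult(image_id, results, names, params)


def classical_backends(**overrides) -> tuple[Detector, Segmenter, Segmenter]:
    """The deterministic thresholding/morphology reference cascade."""
    det_keys = {k: v for k, v in overrides.items() if k in ("morph_radius", "area_min", "area_max")}
    seg_keys = {k: v for k, v in overrides.items() if k in ("min_color_dist",)}
    br_keys = {k: v for k, v in overrides.items() if k in ("skin_frac", "min_contrast", "min_bruise_area")}
    return (
        ClassicalDetector(**det_keys),
        ClassicalBerrySegmenter(**seg_keys),
        ClassicalBruiseSegmenter(**br_keys),
    )


def file_backends(
    boxes_dir: str | Path, berry_dir: str | Path, bruise_dir: str | Path
) -> tuple[Detector, Segmenter, Segmenter]:
    """Cascade fed entirely from stored prediction label files."""
    return (
        FileDetector(boxes_dir),
        FileBerrySegmenter(berry_dir),
        FileBruiseSegmenter(bruise_dir),
    )
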