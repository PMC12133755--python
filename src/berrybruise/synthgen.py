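"""Synthetic plate images of sliced berries with exact per-berry ground truth.

The generator emulates the imaging protocol the rest of the package is built
for: ~dozens of berry halves cut along the equator and laid flesh-up on white
paper, photographed from above. Each synthetic berry half is a filled,
randomly oriented ellipse with a dark blue-purple skin annulus and pale
flesh; impact bruising is rendered as a discolored wedge (circular sector)
anchored at the rim and reaching toward the center — impact damage starts at
the contact point on the skin and spreads into the inner tissue, giving the
characteristic triangular cross-section.

The wedge's angular width is solved numerically per berry so that the
rasterized bruise area hits a target fraction of the rasterized berry area;
that exact pixel fraction is recorded as ``true_ratio`` and is the ground
truth every downstream accuracy claim is measured against.

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``(seed, plate_index)``, so identical configurations reproduce bit-identical
plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .raster_core import BoundingBox, PolygonOutline, mask_to_box

__all__ = [
    "ColorModel",
    "SynthConfig",
    "GroundTruthBerry",
    "CultivarSimSpec",
    "PlacementError",
    "generate_plate",
    "mask_to_polygon",
    "export_annotations",
    "simulate_cultivars",
]


class PlacementError(RuntimeError):
    """Requested berry count cannot be placed without overlap."""


@dataclass(frozen=True)
class ColorModel:
    """Reference RGB colors for the four plate materials, with jitter.

    Defaults echo white photographic paper, dark blue-purple berry skin,
    pale yellow-green flesh, and reddish-brown bruised tissue. ``jitter``
    is the half-width of the uniform per-berry color perturbation (8-bit
    units) that mimics cultivar-to-cultivar and berry-to-berry variation.
    """

    background: tuple[int, int, int] = (245, 245, 240)
    skin: tuple[int, int, int] = (45, 35, 80)
    flesh: tuple[int, int, int] = (225, 230, 190)
    bruise: tuple[int, int, int] = (150, 75, 60)
    jitter: float = 10.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic plate.

    ``bruise_fraction_dist`` is a distribution spec ``(family, *params)``
    over target bruise-area fractions in [0, 0.9]:

    * ``("constant", v)`` — every berry targets fraction v;
    * ``("uniform", lo, hi)`` — uniform draw per berry;
    * ``("beta", a, b, scale)`` — scaled Beta draw, clipped to [0, 0.9].

    The achievable fraction is additionally capped by the flesh fraction
    (bruising discolors flesh, never the skin annulus), so very large
    targets saturate near ``(1 - skin_thickness_frac)^2``.
    """

    seed: int = 0
    n_berries: int = 20
    image_size: int = 960
    berry_radius_range: tuple[float, float] = (40.0, 60.0)
    ellipse_axis_ratio_range: tuple[float, float] = (0.72, 0.98)
    skin_thickness_frac: float = 0.12
    bruise_fraction_dist: tuple = ("uniform", 0.05, 0.35)
    color_model: ColorModel = field(default_factory=ColorModel)
    noise_sd: float = 3.0
    plate_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.skin_thickness_frac < 0.5:
            raise ValueError("skin_thickness_frac must be in (0, 0.5)")
        if self.berry_radius_range[0] > self.berry_radius_range[1]:
            raise ValueError("berry_radius_range must be (lo, hi) with lo <= hi")


@dataclass
class GroundTruthBerry:
    """Exact ground truth for one berry half on the plate grid."""

    box: BoundingBox
    berry_mask: np.ndarray
    bruise_mask: np.ndarray
    true_ratio: float


def _draw_bruise_fraction(dist: tuple, rng: np.random.Generator) -> float:
    family = dist[0]
    if family == "constant":
        value = float(dist[1])
    elif family == "uniform":
        value = float(rng.uniform(dist[1], dist[2]))
    elif family == "beta":
        a, b, scale = dist[1], dist[2], dist[3]
        value = float(rng.beta(a, b) * scale)
    else:
        raise ValueError(f"unknown bruise fraction distribution {family!r}")
    return float(np.clip(value, 0.0, 0.9))


def _place_centers(cfg: SynthConfig, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping berry centers; raise if infeasible."""
    size = cfg.image_size
    margin = 6.0  # clearance between bounding circles
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        lo, hi = r + 4.0, size - r - 4.0
        if lo >= hi:
            raise PlacementError(
                f"berry radius {r:.0f}px cannot fit in a {size}px image"
            )
        for _ in range(8000):
            cx, cy = rng.uniform(lo, hi, size=2)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= (r + pr + margin) ** 2
                for (px, py), pr in zip(centers, placed_r)
            ):
                centers.append((cx, cy))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {cfg.n_berries} berries of radius up to "
                f"{radii.max():.0f}px on a {size}px plate"
            )
    return np.asarray(centers)


def generate_plate(cfg: SynthConfig) -> tuple[np.ndarray, list[GroundTruthBerry]]:
    """Render one plate and its exact ground truth.

    Returns the RGB uint8 image and one :class:`GroundTruthBerry` per berry,
    sorted in reading order (top-left first). Identical configs produce
    bit-identical output.
    """
    rng = np.random.default_rng([cfg.seed, cfg.plate_index])
    size = cfg.image_size
    cm = cfg.color_model

    # Large berries placed first: tightens packing and speeds rejection.
    radii = np.sort(rng.uniform(*cfg.berry_radius_range, size=cfg.n_berries))[::-1]
    centers = _place_centers(cfg, radii, rng) if cfg.n_berries else np.empty((0, 2))

    img = np.empty((size, size, 3), dtype=float)
    img[:] = cm.background

    berries: list[GroundTruthBerry] = []
    for k in range(cfg.n_berries):
        cx, cy = centers[k]
        a = radii[k]
        b = a * rng.uniform(*cfg.ellipse_axis_ratio_range)
        tilt = rng.uniform(0, np.pi)
        target = _draw_bruise_fraction(cfg.bruise_fraction_dist, rng)
        jit = rng.uniform(-cm.jitter, cm.jitter, size=(3, 3))

        # Work on a window just covering the ellipse.
        x0 = max(int(np.floor(cx - a - 2)), 0)
        x1 = min(int(np.ceil(cx + a + 2)), size)
        y0 = max(int(np.floor(cy - a - 2)), 0)
        y1 = min(int(np.ceil(cy + a + 2)), size)
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        gx, gy = np.meshgrid(xs - cx, ys - cy)
        # Rotate into the ellipse's canonical frame.
        u = gx * np.cos(tilt) + gy * np.sin(tilt)
        v = -gx * np.sin(tilt) + gy * np.cos(tilt)
        rad2 = (u / a) ** 2 + (v / b) ** 2
        berry_w = rad2 <= 1.0
        inner = 1.0 - cfg.skin_thickness_frac
        flesh_w = rad2 <= inner**2

        berry_area = int(berry_w.sum())
        if berry_area == 0:
            continue

        bruise_w = np.zeros_like(berry_w)
        if target > 0 and flesh_w.any():
            theta = np.arctan2(v, u)  # canonical-frame angle of each pixel
            psi = rng.uniform(-np.pi, np.pi)  # impact point angle on the rim
            delta = np.abs(np.angle(np.exp(1j * (theta - psi))))
            max_frac = flesh_w.sum() / berry_area
            goal = min(target, 0.98 * max_frac)
            # Bisection on the sector half-width; area is monotone in it.
            lo, hi = 0.0, np.pi
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                frac = np.count_nonzero(flesh_w & (delta <= mid)) / berry_area
                if frac < goal:
                    lo = mid
                else:
                    hi = mid
            bruise_w = flesh_w & (delta <= 0.5 * (lo + hi))

        window = img[y0:y1, x0:x1]
        window[berry_w] = np.asarray(cm.skin, dtype=float) + jit[0]
        window[flesh_w & ~bruise_w] = np.asarray(cm.flesh, dtype=float) + jit[1]
        window[bruise_w] = np.asarray(cm.bruise, dtype=float) + jit[2]

        berry_mask = np.zeros((size, size), dtype=bool)
        berry_mask[y0:y1, x0:x1] = berry_w
        bruise_mask = np.zeros((size, size), dtype=bool)
        bruise_mask[y0:y1, x0:x1] = bruise_w
        berries.append(
            GroundTruthBerry(
                box=mask_to_box(berry_mask),
                berry_mask=berry_mask,
                bruise_mask=bruise_mask,
                true_ratio=int(bruise_w.sum()) / berry_area,
            )
        )

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    berries.sort(key=lambda gt: (gt.box.y0, gt.box.x0))
    return image, berries


def mask_to_polygon(mask: np.ndarray, tolerance: float = 0.4, class_id: int = 0) -> PolygonOutline:
    """Trace a mask's outer contour as a normalized polygon.

    The marching-squares contour at level 0.5 runs along the geometric
    boundary between member and non-member pixels; vertices are simplified
    with chordal deviation <= ``tolerance`` pixels. Only the longest contour
    is kept (masks here are single connected regions).
    """
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    contour = measure.approximate_polygon(contour, tolerance=tolerance)
    h, w = mask.shape
    # find_contours indexes pixel centers; +0.5 converts to pixel-edge coords.
    verts = np.stack([(contour[:, 1] + 0.5) / w, (contour[:, 0] + 0.5) / h], axis=1)
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    verts = np.clip(verts, 0.0, 1.0)
    return PolygonOutline(tuple(map(tuple, verts)), class_id=class_id)


def export_annotations(
    image_id: str,
    berries: list[GroundTruthBerry],
    out_dir: str | Path,
    image_size: tuple[int, int],
) -> dict[str, Path]:
    """Write detection boxes and segmentation polygons in the YOLO dialect.

    Creates ``det_labels/<id>.txt`` (class cx cy w h), ``seg_berry/<id>.txt``
    and ``seg_bruise/<id>.txt`` (class x1 y1 x2 y2 ...). Empty plates yield
    empty files; unbruised berries contribute no bruise polygon.
    """
    from .annot_io import AnnotationSet, BoxRecord, write_labels

    out_dir = Path(out_dir)
    w, h = image_size
    boxes = [BoxRecord(0, *gt.box.to_yolo(w, h)) for gt in berries]
    berry_polys = [mask_to_polygon(gt.berry_mask) for gt in berries]
    bruise_polys = [
        mask_to_polygon(gt.bruise_mask) for gt in berries if gt.bruise_mask.any()
    ]

    paths = {}
    for sub, aset in [
        ("det_labels", AnnotationSet(image_id, boxes=boxes)),
        ("seg_berry", AnnotationSet(image_id, polygons=berry_polys)),
        ("seg_bruise", AnnotationSet(image_id, polygons=bruise_polys)),
    ]:
        d = out_dir / sub
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{image_id}.txt"
        kind = "box" if sub == "det_labels" else "polygon"
        write_labels(aset, path, kind=kind)
        paths[sub] = path
    return paths


@dataclass(frozen=True)
class CultivarSimSpec:
    """Two-group cultivar population with a firmness covariate.

    Cultivars split evenly between a bruise-resistant group (low mean
    ratio) and a bruise-susceptible group (high mean ratio); group labels
    are a random permutation of a balanced label vector, giving the two
    comparable-size clusters the screen expects. Each cultivar's mean is
    drawn around its group level with sd ``between_cultivar_sd`` (default:
    a quarter of the within-cultivar sd, keeping groups well separated so
    label recovery is a property of the analysis, not of lucky draws),
    berry ratios come from a normal truncated to [0, 1], and firmness
    follows a negative linear trend on the cultivar mean ratio — firmer
    berries bruise less. Default firmness parameters put values in the
    few-MPa/% range typical of a force-deformation slope index.
    """

    n_cultivars: int = 20
    group_means: tuple[float, float] = (0.12, 0.32)
    within_cultivar_sd: float = 0.03
    between_cultivar_sd: float | None = None
    berries_per_cultivar: int = 20
    firmness_intercept: float = 5.0
    firmness_slope: float = -10.0
    firmness_noise_sd: float = 0.4
    seed: int = 0
    year: str = "2021"

    def __post_init__(self) -> None:
        lo, hi = self.group_means
        if not (0 < lo < hi < 1):
            raise ValueError("group means must satisfy 0 < resistant < susceptible < 1")
        if self.firmness_slope >= 0:
            raise ValueError("firmness_slope must be negative (firmer = less bruising)")


def simulate_cultivars(spec: CultivarSimSpec) -> pd.DataFrame:
    """Draw a per-berry ratio table with known generating labels.

    Returns one row per berry with columns ``cultivar, year, sample_id,
    ratio, true_group, cultivar_mean, firmness``; ``true_group`` is
    "resistant" or "susceptible" as generated, for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    half = spec.n_cultivars // 2
    groups = np.array(
        ["resistant"] * (spec.n_cultivars - half) + ["susceptible"] * half
    )
    rng.shuffle(groups)

    between_sd = (
        spec.between_cultivar_sd
        if spec.between_cultivar_sd is not None
        else spec.within_cultivar_sd / 4.0
    )
    for i, group in enumerate(groups):
        level = spec.group_means[0 if group == "resistant" else 1]
        mu = level + rng.normal(0.0, between_sd)
        mu = float(np.clip(mu, 1e-6, 1 - 1e-6))
        if spec.within_cultivar_sd > 0:
            a, b = (0 - mu) / spec.within_cultivar_sd, (1 - mu) / spec.within_cultivar_sd
            ratios = stats.truncnorm.rvs(
                a, b, loc=mu, scale=spec.within_cultivar_sd,
                size=spec.berries_per_cultivar, random_state=rng,
            )
        else:
            ratios = np.full(spec.berries_per_cultivar, mu)
        firmness = (
            spec.firmness_intercept
            + spec.firmness_slope * mu
            + rng.normal(0.0, spec.firmness_noise_sd)
        )
        name = f"cv{i + 1:03d}"
        for j, r in enumerate(ratios):
            rows.append(
                {
                    "cultivar": name,
                    "year": spec.year,
                    "sample_id": f"{name}_s{j + 1:03d}",
                    "ratio": float(r),
                    "true_group": group,
                    "cultivar_mean": mu,
                    "firmness": float(firmness),
                }
            )
    return pd.DataFrame(rows)
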