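"""Single-nucleus patch extraction and QC from an image + label mask.

The homogenization pipeline mirrors the preprocessing used for CNN-based
micronucleus counting: tight per-label bounding boxes are read off the
segmentation mask, expanded by a fixed margin to capture peri-nuclear
micronuclei, the smallest boxes (segmentation debris) are dropped by an area
percentile filter, and each crop is rescaled so the nucleus occupies a fixed
fraction of a square output patch, centered, padded and brightness-normalized.

Conventions: 0-based, half-open pixel rectangles ``[y_min, y_max) x
[x_min, x_max)``, row-major (y before x).

The scaling factor recorded per patch is
``ratio * max(width, height) / final_size``; the resampling applied to the
crop is its reciprocal, so that the nucleus's larger tight-box dimension
occupies ``ratio * final_size`` output pixels (e.g. 166 px of a 256 px patch
at the default ratio 0.65).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel rectangle circumscribing one labeled nucleus."""

    label: int
    y_min: int
    y_max: int
    x_min: int
    x_max: int

    def __post_init__(self):
        if self.y_min >= self.y_max or self.x_min >= self.x_max:
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return ((self.y_min + self.y_max) / 2.0, (self.x_min + self.x_max) / 2.0)


@dataclasses.dataclass(frozen=True)
class PatchExtractionConfig:
    expansion: int = 20
    area_percentile: float = 5.0
    nucleus_to_image_ratio: float = 0.65
    final_size: int = 256
    normalize_brightness: bool = True
    iou_threshold: float = 0.5
    blur_threshold: float = 1e-4

    def validate(self) -> None:
        if not (0.0 < self.nucleus_to_image_ratio < 1.0):
            raise ValueError("nucleus_to_image_ratio must be in (0, 1)")
        if self.final_size < 32:
            raise ValueError("final_size must be >= 32")
        if not (0.0 <= self.area_percentile < 100.0):
            raise ValueError("area_percentile must be in [0, 100)")
        if self.expansion < 0:
            raise ValueError("expansion must be >= 0")
        if not (0.0 <= self.iou_threshold <= 1.0):
            raise ValueError("iou_threshold must be in [0, 1]")


@dataclasses.dataclass
class NucleusPatch:
    """A homogenized fixed-size single-nucleus image with provenance."""

    label: int
    pixels: np.ndarray
    scaling_factor: float
    source_bbox: BoundingBox  # expanded box, original image coordinates
    blur_score: float = float("nan")
    source_image_id: str = ""


def mask_to_bboxes(mask: np.ndarray) -> list[BoundingBox]:
    """Tight circumscribing boxes for every non-zero label, sorted by label.

    Labels need not be consecutive.  An all-background mask yields an empty
    list; negative labels are rejected.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"mask must be integer-typed, got {mask.dtype}")
    if mask.min() < 0:
        raise ValueError("mask contains negative labels")
    slices = ndi.find_objects(mask)
    boxes = []
    for label_minus_1, sl in enumerate(slices):
        if sl is None:
            continue
        ys, xs = sl
        boxes.append(
            BoundingBox(label=label_minus_1 + 1, y_min=ys.start, y_max=ys.stop,
                        x_min=xs.start, x_max=xs.stop)
        )
    return boxes


def expand_bbox(bbox: BoundingBox, expansion: int, image_shape: tuple[int, int]) -> BoundingBox:
    """Grow each side by ``expansion`` pixels, clipped to the image bounds."""
    if expansion < 0:
        raise ValueError("expansion must be >= 0")
    rows, cols = image_shape
    return BoundingBox(
        label=bbox.label,
        y_min=max(0, bbox.y_min - expansion),
        y_max=min(rows, bbox.y_max + expansion),
        x_min=max(0, bbox.x_min - expansion),
        x_max=min(cols, bbox.x_max + expansion),
    )


def filter_by_area_percentile(
    bboxes: list[BoundingBox], percentile: float
) -> tuple[list[BoundingBox], list[BoundingBox]]:
    """Split boxes into (kept, removed) around an area-percentile cutoff.

    The cutoff is the linear-interpolation percentile of all box areas;
    removal is strict-below, so an all-equal-area input is a no-op.  Intended
    to drop segmentation debris (the smallest few percent of boxes).
    """
    if not (0.0 <= percentile < 100.0):
        raise ValueError("percentile must be in [0, 100)")
    if percentile == 0.0 or not bboxes:
        return list(bboxes), []
    areas = np.array([b.area for b in bboxes], dtype=float)
    cutoff = np.percentile(areas, percentile)  # linear interpolation
    kept = [b for b in bboxes if b.area >= cutoff]
    removed = [b for b in bboxes if b.area < cutoff]
    return kept, removed


def compute_scaling_factor(bbox: BoundingBox, ratio: float = 0.65, final_size: int = 256) -> float:
    """``ratio * max(width, height) / final_size`` for a tight box."""
    if bbox.width <= 0 or bbox.height <= 0:
        raise ValueError("degenerate bounding box")
    return ratio * max(bbox.width, bbox.height) / final_size


def _patch_geometry(
    bbox_tight: BoundingBox, config: PatchExtractionConfig, image_shape: tuple[int, int]
):
    """Resolved transform parameters shared by crop resampling and point
    mapping: the expanded box, resized crop shape and canvas offsets."""
    ebox = expand_bbox(bbox_tight, config.expansion, image_shape)
    scale = config.nucleus_to_image_ratio * config.final_size / max(
        bbox_tight.width, bbox_tight.height
    )
    out_h = max(1, round(ebox.height * scale))
    out_w = max(1, round(ebox.width * scale))
    cy, cx = bbox_tight.center
    scy = (cy - ebox.y_min) * out_h / ebox.height
    scx = (cx - ebox.x_min) * out_w / ebox.width
    oy = round(config.final_size / 2 - scy)
    ox = round(config.final_size / 2 - scx)
    return ebox, scale, out_h, out_w, oy, ox


def map_point_to_patch(
    point_yx: tuple[float, float],
    bbox_tight: BoundingBox,
    config: PatchExtractionConfig,
    image_shape: tuple[int, int],
) -> tuple[float, float]:
    """Map an original-image coordinate into patch coordinates.

    Useful for localizing known structures (e.g. micronucleus centers) in a
    homogenized patch.  The returned point may fall outside [0, final_size)
    if the structure was cropped away.
    """
    ebox, _, out_h, out_w, oy, ox = _patch_geometry(bbox_tight, config, image_shape)
    py = (point_yx[0] - ebox.y_min) * out_h / ebox.height + oy
    px = (point_yx[1] - ebox.x_min) * out_w / ebox.width + ox
    return py, px


def patch_scale(
    bbox_tight: BoundingBox, config: PatchExtractionConfig
) -> float:
    """Resampling factor from original-image to patch pixels."""
    return config.nucleus_to_image_ratio * config.final_size / max(
        bbox_tight.width, bbox_tight.height
    )


def _transform_crop(
    array: np.ndarray,
    bbox_tight: BoundingBox,
    config: PatchExtractionConfig,
    order: int,
    pad_value: float,
) -> np.ndarray:
    """Crop the expanded box, rescale and recenter onto a final-size canvas.

    Shared by intensity patches (``order=1``) and label-mask projection
    (``order=0``); the tight-box center lands on the patch center.
    """
    ebox, scale, out_h, out_w, oy, ox = _patch_geometry(
        bbox_tight, config, array.shape
    )
    crop = array[ebox.y_min : ebox.y_max, ebox.x_min : ebox.x_max].astype(np.float64)
    resized = _sk_resize(
        crop,
        (out_h, out_w),
        order=order,
        preserve_range=True,
        anti_aliasing=(order > 0 and scale < 1.0),
    )
    size = config.final_size
    canvas = np.full((size, size), pad_value, dtype=np.float64)
    ys0, ys1 = max(0, oy), min(size, oy + out_h)
    xs0, xs1 = max(0, ox), min(size, ox + out_w)
    if ys1 > ys0 and xs1 > xs0:
        canvas[ys0:ys1, xs0:xs1] = resized[ys0 - oy : ys1 - oy, xs0 - ox : xs1 - ox]
    return canvas


def extract_patch(
    image: np.ndarray,
    bbox_tight: BoundingBox,
    config: PatchExtractionConfig | None = None,
    source_image_id: str = "",
) -> NucleusPatch:
    """Homogenize one nucleus into a ``final_size`` square patch.

    Steps: expand the tight box, crop, resample by ``ratio * final_size /
    max(w, h)`` (reciprocal of the stored scaling factor), pad/center-crop to
    the final size with the nucleus tight-box center at the patch center, and
    optionally min–max normalize intensities to [0, 1] (a constant crop maps
    to all zeros).  Border padding uses the crop's minimum as background.
    """
    config = config or PatchExtractionConfig()
    config.validate()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    rows, cols = image.shape
    if not (0 <= bbox_tight.y_min < bbox_tight.y_max <= rows
            and 0 <= bbox_tight.x_min < bbox_tight.x_max <= cols):
        raise ValueError(f"bounding box {bbox_tight} outside image of shape {image.shape}")
    crop_region = image[bbox_tight.y_min : bbox_tight.y_max, bbox_tight.x_min : bbox_tight.x_max]
    if not np.all(np.isfinite(image[max(0, bbox_tight.y_min - config.expansion):bbox_tight.y_max + config.expansion,
                                    max(0, bbox_tight.x_min - config.expansion):bbox_tight.x_max + config.expansion])):
        raise ValueError("non-finite pixels in the patch region")
    del crop_region

    ebox = expand_bbox(bbox_tight, config.expansion, (rows, cols))
    pad_value = float(image[ebox.y_min : ebox.y_max, ebox.x_min : ebox.x_max].min())
    patch = _transform_crop(image, bbox_tight, config, order=1, pad_value=pad_value)
    if config.normalize_brightness:
        lo, hi = patch.min(), patch.max()
        patch = (patch - lo) / (hi - lo) if hi > lo else np.zeros_like(patch)
    patch = patch.astype(np.float32)
    np_patch = NucleusPatch(
        label=bbox_tight.label,
        pixels=patch,
        scaling_factor=compute_scaling_factor(
            bbox_tight, config.nucleus_to_image_ratio, config.final_size
        ),
        source_bbox=ebox,
        source_image_id=source_image_id,
    )
    np_patch.blur_score = blur_score(np_patch)
    return np_patch


def project_mask_patch(
    mask: np.ndarray, bbox_tight: BoundingBox, config: PatchExtractionConfig | None = None
) -> np.ndarray:
    """Project the label mask through the same transform as the patch.

    Nearest-neighbour resampling; useful for measuring the nucleus footprint
    in patch coordinates and for localization checks on saliency maps.
    """
    config = config or PatchExtractionConfig()
    out = _transform_crop(np.asarray(mask, dtype=np.float64), bbox_tight, config,
                          order=0, pad_value=0.0)
    return out.astype(np.int64)


def bbox_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes."""
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    inter = iy * ix
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def iou_audit(
    expanded_bboxes: list[BoundingBox], threshold: float = 0.5
) -> tuple[float, list[tuple[int, int, float]]]:
    """Double-counting audit over all unordered patch-footprint pairs.

    Returns the fraction of pairs with IoU >= ``threshold`` and the flagged
    (label_i, label_j, iou) triples.  With fewer than two boxes the fraction
    is 0 and no pairs are flagged.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    n = len(expanded_bboxes)
    if n < 2:
        return 0.0, []
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            iou = bbox_iou(expanded_bboxes[i], expanded_bboxes[j])
            if iou >= threshold:
                flagged.append((expanded_bboxes[i].label, expanded_bboxes[j].label, iou))
    return len(flagged) / (n * (n - 1) / 2), flagged


def blur_score(patch: NucleusPatch | np.ndarray) -> float:
    """Focus metric: variance of the Laplacian of the [0, 1]-normalized patch.

    Parameter-free and strictly decreasing under Gaussian blur; a constant
    patch scores 0.
    """
    pixels = patch.pixels if isinstance(patch, NucleusPatch) else np.asarray(patch)
    if pixels.size == 0:
        raise ValueError("empty patch")
    p = pixels.astype(np.float64)
    lo, hi = p.min(), p.max()
    if hi <= lo:
        return 0.0
    p = (p - lo) / (hi - lo)
    return float(ndi.laplace(p).var())


def pct_out_of_focus(patches: list[NucleusPatch], threshold: float) -> float:
    """Percentage of patches whose blur score falls below ``threshold``."""
    if not patches:
        return 0.0
    n_blurry = sum(1 for p in patches if blur_score(p) < threshold)
    return 100.0 * n_blurry / len(patches)


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    config: PatchExtractionConfig | None = None,
    source_image_id: str = "",
) -> tuple[list[NucleusPatch], list[BoundingBox]]:
    """Full image-level extraction: bboxes -> area filter -> patches.

    Returns the kept patches (sorted by label) and the removed boxes.
    """
    config = config or PatchExtractionConfig()
    config.validate()
    if np.asarray(image).shape != np.asarray(mask).shape:
        raise ValueError(
            f"image shape {np.asarray(image).shape} != mask shape {np.asarray(mask).shape}"
        )
    boxes = mask_to_bboxes(mask)
    kept, removed = filter_by_area_percentile(boxes, config.area_percentile)
    patches = [extract_patch(image, b, config, source_image_id) for b in kept]
    return patches, removed


def patch_manifest(patches: list[NucleusPatch]) -> pd.DataFrame:
    """Tabular provenance for a set of patches (expanded-box coordinates)."""
    return pd.DataFrame(
        [
            {
                "image_id": p.source_image_id,
                "label": p.label,
                "y_min": p.source_bbox.y_min,
                "y_max": p.source_bbox.y_max,
                "x_min": p.source_bbox.x_min,
                "x_max": p.source_bbox.x_max,
                "scaling_factor": p.scaling_factor,
                "blur_score": p.blur_score,
            }
            for p in patches
        ],
        columns=["image_id", "label", "y_min", "y_max", "x_min", "x_max",
                 "scaling_factor", "blur_score"],
    )
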