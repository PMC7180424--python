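"""Sliding-window patch enumeration, extraction and the augmentation stack.

Patches are fixed-size squares (default 224x224 px) enumerated over a box in
row-major order; windows that would extend past the box are dropped, not
padded. At a 0.25 um/px scan, 224 px = 448 um requires extraction at 1/8 of
scan resolution, hence the ``extraction_downsample`` field; procedurally
generated slides are drawn at extraction resolution already and use factor 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .wsi_io import PATCH_CLASSES, BoundingBoxAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchSpec:
    patch_size: int = 224
    stride: int = 224  # = patch_size: non-overlapping tiling
    extraction_downsample: int = 8

    def __post_init__(self):
        if self.patch_size < 1 or self.stride < 1:
            raise ValueError("patch_size and stride must be >= 1")
        if self.extraction_downsample < 1:
            raise ValueError("extraction_downsample must be >= 1")


@dataclass(frozen=True)
class AugmentSpec:
    """Random rotations/flips plus color jitter on brightness, contrast,
    saturation and hue.

    Jitter values are drawn uniformly from ``[-half_range, +half_range]``;
    brightness/contrast/saturation jitters are additive/multiplicative on the
    [0, 1] intensity scale, hue jitter is a shift of the HSV hue channel
    (fraction of a full turn). Augmented pixels are clipped to the valid range.
    """

    rotations: tuple[int, ...] = (0, 90, 180, 270)
    hflip: bool = True
    vflip: bool = True
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    hue: float = 0.05

    def __post_init__(self):
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} jitter half-range must be >= 0")
        for r in self.rotations:
            if r % 90 != 0:
                raise ValueError("rotations must be multiples of 90 degrees")

    @classmethod
    def disabled(cls) -> "AugmentSpec":
        return cls(rotations=(0,), hflip=False, vflip=False,
                   brightness=0.0, contrast=0.0, saturation=0.0, hue=0.0)


@dataclass
class PatchSet:
    """Labeled training patches: uint8 RGB stack plus parallel metadata."""

    patches: np.ndarray          # (n, size, size, 3) uint8
    labels: np.ndarray           # (n,) of PATCH_CLASSES strings
    slide_ids: np.ndarray        # (n,) str
    origins: np.ndarray          # (n, 2) int (x, y)
    n_skipped_conflicts: int = 0

    def __len__(self) -> int:
        return len(self.labels)


def sliding_window(box: tuple[int, int, int, int], spec: PatchSpec) -> list[tuple[int, int]]:
    """Enumerate patch origins tiling a half-open box ``(x0, y0, x1, y1)``.

    Origins are ``(x0 + i*stride, y0 + j*stride)`` for every window that fits
    fully inside the box, in row-major order (y outer, x inner). A box smaller
    than the patch in either dimension yields an empty list.
    """
    x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"invalid box {box}")
    s, k = spec.stride, spec.patch_size
    if x1 - x0 < k or y1 - y0 < k:
        return []
    xs = range(x0, x1 - k + 1, s)
    ys = range(y0, y1 - k + 1, s)
    return [(x, y) for y in ys for x in xs]


def window_count(length: int, spec: PatchSpec) -> int:
    """Closed-form number of windows along one axis of length ``length``."""
    if length < spec.patch_size:
        return 0
    return (length - spec.patch_size) // spec.stride + 1


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample of a uint8 RGB image by an integer factor."""
    if factor == 1:
        return image
    from skimage.measure import block_reduce

    h, w = image.shape[:2]
    img = image[: h - h % factor, : w - w % factor]
    out = block_reduce(img.astype(np.float32), (factor, factor, 1), np.mean)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_patch(image: np.ndarray, x: int, y: int, size: int) -> np.ndarray:
    if x < 0 or y < 0 or x + size > image.shape[1] or y + size > image.shape[0]:
        raise ValueError(f"patch [{x},{x+size})x[{y},{y+size}) outside image bounds")
    return image[y : y + size, x : x + size]


def extract_training_patches(
    image: np.ndarray,
    annotations: list[BoundingBoxAnnotation],
    spec: PatchSpec = PatchSpec(extraction_downsample=1),
    balance_to: int | None = None,
    seed: int = 0,
) -> PatchSet:
    """Extract labeled patches from annotated ROIs via the sliding window.

    Every returned patch lies fully inside at least one ROI and carries that
    ROI's label. A patch position reachable from two ROIs with conflicting
    labels is skipped (counted in ``n_skipped_conflicts``). With ``balance_to``
    set, each class present is down-/up-sampled (with replacement) to exactly
    that count, seeded.
    """
    if spec.extraction_downsample > 1:
        image = downsample_image(image, spec.extraction_downsample)
        f = spec.extraction_downsample
        annotations = [
            BoundingBoxAnnotation(a.slide_id, a.x0 // f, a.y0 // f, a.x1 // f, a.y1 // f,
                                  a.label, a.annotator_id)
            for a in annotations
            if a.x1 // f > a.x0 // f and a.y1 // f > a.y0 // f
        ]
    slide_ids = {a.slide_id for a in annotations}
    if len(slide_ids) > 1:
        raise ValueError(f"annotations span multiple slides: {sorted(slide_ids)}")

    k = spec.patch_size
    by_origin: dict[tuple[int, int], set[str]] = {}
    for ann in annotations:
        if ann.x1 > image.shape[1] or ann.y1 > image.shape[0]:
            raise ValueError(f"annotation box extends past image bounds: {ann}")
        for origin in sliding_window((ann.x0, ann.y0, ann.x1, ann.y1), spec):
            by_origin.setdefault(origin, set()).add(ann.label)

    origins, labels = [], []
    n_conflicts = 0
    for origin in sorted(by_origin, key=lambda o: (o[1], o[0])):
        cand = by_origin[origin]
        if len(cand) > 1:
            n_conflicts += 1
            continue
        origins.append(origin)
        labels.append(next(iter(cand)))
    if n_conflicts:
        logger.warning("skipped %d patches with conflicting ROI labels", n_conflicts)

    labels_arr = np.array(labels, dtype=object)
    origins_arr = np.array(origins, dtype=int).reshape(-1, 2)
    if balance_to is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for cls in PATCH_CLASSES:
            idx = np.flatnonzero(labels_arr == cls)
            if len(idx) == 0:
                continue
            keep.append(rng.choice(idx, size=balance_to, replace=len(idx) < balance_to)
                        if len(idx) != balance_to else idx)
        order = np.concatenate(keep) if keep else np.array([], dtype=int)
        labels_arr, origins_arr = labels_arr[order], origins_arr[order]

    slide_id = next(iter(slide_ids)) if slide_ids else ""
    patches = np.stack(
        [extract_patch(image, x, y, k) for x, y in origins_arr]
    ) if len(origins_arr) else np.empty((0, k, k, 3), dtype=np.uint8)
    return PatchSet(
        patches=patches,
        labels=labels_arr.astype(str) if len(labels_arr) else np.array([], dtype=str),
        slide_ids=np.array([slide_id] * len(labels_arr)),
        origins=origins_arr,
        n_skipped_conflicts=n_conflicts,
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _rgb_to_hsv(x: np.ndarray) -> np.ndarray:
    from skimage.color import rgb2hsv

    return rgb2hsv(x)


def _hsv_to_rgb(x: np.ndarray) -> np.ndarray:
    from skimage.color import hsv2rgb

    return hsv2rgb(x)


def augment(patch: np.ndarray, spec: AugmentSpec, seed: int) -> np.ndarray:
    """Apply one random draw of the augmentation stack to a square patch.

    Deterministic given ``seed``. Rotation and flips are drawn uniformly from
    the enabled set; each color jitter is drawn uniformly within its
    half-range. Output has the same shape and dtype as the input.
    """
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augment requires a square patch")
    rng = np.random.default_rng(seed)
    was_uint8 = patch.dtype == np.uint8
    x = patch.astype(np.float64) / 255.0 if was_uint8 else patch.astype(np.float64)

    rot = int(rng.choice(np.asarray(spec.rotations)))
    if rot % 360:
        x = np.rot90(x, k=(rot // 90) % 4)
    if spec.hflip and rng.random() < 0.5:
        x = x[:, ::-1]
    if spec.vflip and rng.random() < 0.5:
        x = x[::-1, :]

    db = rng.uniform(-spec.brightness, spec.brightness) if spec.brightness else 0.0
    dc = rng.uniform(-spec.contrast, spec.contrast) if spec.contrast else 0.0
    ds = rng.uniform(-spec.saturation, spec.saturation) if spec.saturation else 0.0
    dh = rng.uniform(-spec.hue, spec.hue) if spec.hue else 0.0

    if db:
        x = x + db
    if dc:
        x = (x - x.mean()) * (1.0 + dc) + x.mean()
    if ds or dh:
        hsv = _rgb_to_hsv(np.clip(x, 0.0, 1.0))
        if dh:
            hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        if ds:
            hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + ds), 0.0, 1.0)
        x = _hsv_to_rgb(hsv)
    x = np.clip(x, 0.0, 1.0)

    x = np.ascontiguousarray(x)
    if was_uint8:
        return np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8)
    return x.astype(patch.dtype)
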