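"""Confidence-shaded class heatmaps and lesion-highlight overlays.

Each predicted patch region is tinted with its argmax class color at an
opacity that increases monotonically with prediction confidence (the maximum
probability): more confident predictions are darker. The lesion overlay
binarizes this to the patches whose argmax lies in the highlight set (the
four polyp classes by default), leaving normal tissue untouched. Rendering is
purely local: pixels outside predicted patch boxes are returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wsi_io import PATCH_CLASSES, SLIDE_CLASSES, PatchPrediction

#: Default overlay colors per patch class (RGB, uint8).
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "TA": (214, 39, 40),     # red
    "TVA": (148, 26, 190),   # purple
    "HP": (255, 160, 14),    # orange
    "SSA": (31, 119, 180),   # blue
    "NORM": (120, 200, 120), # green
}


@dataclass(frozen=True)
class OverlayStyle:
    """Colors and the confidence -> alpha mapping (linear, monotone)."""

    colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS))
    alpha_floor: float = 0.15
    alpha_slope: float = 0.6
    highlight_classes: tuple[str, ...] = SLIDE_CLASSES
    highlight_alpha: float = 0.45
    highlight_color: tuple[int, int, int] = (220, 20, 60)

    def __post_init__(self):
        if self.alpha_slope < 0:
            raise ValueError("alpha mapping must be monotone increasing")
        if not 0.0 <= self.alpha_floor <= 1.0:
            raise ValueError("alpha_floor must lie in [0, 1]")
        if self.alpha_floor + self.alpha_slope > 1.0 + 1e-9:
            raise ValueError("alpha mapping must stay within [0, 1]")
        for c in self.highlight_classes:
            if c not in PATCH_CLASSES:
                raise ValueError(f"unknown highlight class {c!r}")

    def alpha(self, confidence: float) -> float:
        return self.alpha_floor + self.alpha_slope * confidence


def _check_bounds(image: np.ndarray, pred: PatchPrediction) -> None:
    h, w = image.shape[:2]
    if pred.x < 0 or pred.y < 0 or pred.x + pred.size > w or pred.y + pred.size > h:
        raise ValueError(
            f"patch at ({pred.x},{pred.y}) size {pred.size} outside image "
            f"bounds {w}x{h}"
        )


def _blend(region: np.ndarray, color: tuple[int, int, int], alpha: float) -> np.ndarray:
    col = np.array(color, dtype=np.float64)
    out = (1.0 - alpha) * region.astype(np.float64) + alpha * col
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_heatmap(
    image: np.ndarray,
    preds: list[PatchPrediction],
    style: OverlayStyle = OverlayStyle(),
) -> np.ndarray:
    """Tint each predicted patch with its argmax class color; opacity scales
    with prediction confidence (darker = more confident)."""
    out = image.copy()
    for p in preds:
        _check_bounds(image, p)
        a = style.alpha(p.confidence)
        region = out[p.y : p.y + p.size, p.x : p.x + p.size]
        out[p.y : p.y + p.size, p.x : p.x + p.size] = _blend(
            region, style.colors[p.label], a)
    return out


def lesion_mask(
    shape: tuple[int, int],
    preds: list[PatchPrediction],
    style: OverlayStyle = OverlayStyle(),
) -> np.ndarray:
    """Boolean mask of pixels covered by patches whose argmax class is in the
    highlight set."""
    mask = np.zeros(shape[:2], dtype=bool)
    for p in preds:
        if p.x < 0 or p.y < 0 or p.x + p.size > shape[1] or p.y + p.size > shape[0]:
            raise ValueError(f"patch at ({p.x},{p.y}) outside mask bounds")
        if p.label in style.highlight_classes:
            mask[p.y : p.y + p.size, p.x : p.x + p.size] = True
    return mask


def render_lesion_mask(
    image: np.ndarray,
    preds: list[PatchPrediction],
    style: OverlayStyle = OverlayStyle(),
) -> np.ndarray:
    """Binary highlight of predicted lesion patches; normal tissue untouched."""
    for p in preds:
        _check_bounds(image, p)
    mask = lesion_mask(image.shape, preds, style)
    out = image.copy()
    col = np.array(style.highlight_color, dtype=np.float64)
    blended = (1.0 - style.highlight_alpha) * image.astype(np.float64) \
        + style.highlight_alpha * col
    out[mask] = np.clip(np.rint(blended[mask]), 0, 255).astype(np.uint8)
    return out
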