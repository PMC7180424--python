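"""Hierarchical slide-level diagnosis from patch-class counts.

A whole slide is diagnosed in two stages that mirror how pathologists
subclassify polyps:

1. branch: the slide is adenomatous if adenomatous patch predictions
   (TA + TVA) are at least as numerous as serrated ones (HP + SSA), else
   serrated (ties go to the adenomatous branch — the clinically more
   consequential call);
2. subtype: within the adenomatous branch, a villous fraction above a strict
   threshold (default > 0.30) gives TVA, else TA; within the serrated branch,
   a sessile-serrated fraction above a strict threshold (default > 0.015)
   gives SSA, else HP.

NORM patch predictions are counted but never enter the branch comparison or
the fractions. Both thresholds are calibrated by grid search on a training
cohort. The fraction denominator is the winning branch's patch count by
default ("branch"); "all_polyp" divides by all non-NORM patches instead.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .wsi_io import PATCH_CLASSES, SLIDE_CLASSES, PatchPrediction

DENOMINATOR_MODES = ("branch", "all_polyp")


class NoLesionError(ValueError):
    """Raised when a slide contains no polyp patch predictions at all."""


@dataclass(frozen=True)
class ClassCounts:
    """Per-slide tally of predicted patch classes."""

    slide_id: str
    n_TA: int = 0
    n_TVA: int = 0
    n_HP: int = 0
    n_SSA: int = 0
    n_NORM: int = 0

    def __post_init__(self):
        for c in PATCH_CLASSES:
            if getattr(self, f"n_{c}") < 0:
                raise ValueError("patch counts must be nonnegative")

    @property
    def adenomatous(self) -> int:
        return self.n_TA + self.n_TVA

    @property
    def serrated(self) -> int:
        return self.n_HP + self.n_SSA

    @property
    def total(self) -> int:
        return self.adenomatous + self.serrated + self.n_NORM

    @classmethod
    def from_labels(cls, slide_id: str, labels) -> "ClassCounts":
        labels = list(labels)
        return cls(slide_id, *(labels.count(c) for c in PATCH_CLASSES))


@dataclass(frozen=True)
class ThresholdConfig:
    """Villous and sessile-serrated fraction cutoffs, applied as strict >."""

    villous_threshold: float = 0.30
    ssa_threshold: float = 0.015
    denominator: str = "branch"

    def __post_init__(self):
        for t in (self.villous_threshold, self.ssa_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.denominator not in DENOMINATOR_MODES:
            raise ValueError(f"denominator must be one of {DENOMINATOR_MODES}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "villous_threshold": self.villous_threshold,
                    "ssa_threshold": self.ssa_threshold,
                    "denominator": self.denominator,
                },
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class GridSpec:
    """Grid-search space for threshold calibration.

    The SSA grid is finer than the villous grid because the operating value
    of the SSA threshold is small (on the order of 1%).
    """

    villous_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 3))
    ssa_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.1001, 0.005), 4))
    objective: str = "mean_class_accuracy"

    def __post_init__(self):
        if not self.villous_grid or not self.ssa_grid:
            raise ValueError("threshold grids must be nonempty")
        for g in (self.villous_grid, self.ssa_grid):
            if any(not 0.0 <= t <= 1.0 for t in g):
                raise ValueError("grid values must lie in [0, 1]")
        if self.objective not in ("mean_class_accuracy", "overall_accuracy"):
            raise ValueError(f"unknown objective {self.objective!r}")


def count_patch_classes(preds: list[PatchPrediction]) -> ClassCounts:
    """Tally argmax patch labels for one slide."""
    if not preds:
        return ClassCounts("")
    slide_ids = {p.slide_id for p in preds}
    if len(slide_ids) > 1:
        raise ValueError(f"predictions span multiple slides: {sorted(slide_ids)}")
    return ClassCounts.from_labels(next(iter(slide_ids)), (p.label for p in preds))


def branch_fractions(counts: ClassCounts, denominator: str = "branch"
                     ) -> tuple[float, float]:
    """(villous fraction, ssa fraction) under the chosen denominator mode.

    A fraction with a zero denominator is reported as 0.
    """
    polyp = counts.adenomatous + counts.serrated
    v_den = counts.adenomatous if denominator == "branch" else polyp
    s_den = counts.serrated if denominator == "branch" else polyp
    v = counts.n_TVA / v_den if v_den else 0.0
    s = counts.n_SSA / s_den if s_den else 0.0
    return v, s


def hierarchical_classify(counts: ClassCounts, thr: ThresholdConfig = ThresholdConfig()
                          ) -> str:
    """Diagnose one slide from its patch-class counts (see module docstring)."""
    if counts.adenomatous + counts.serrated == 0:
        raise NoLesionError(
            f"no lesion detected on slide {counts.slide_id!r}: zero polyp patches"
        )
    villous_frac, ssa_frac = branch_fractions(counts, thr.denominator)
    if counts.adenomatous >= counts.serrated:
        return "TVA" if villous_frac > thr.villous_threshold else "TA"
    return "SSA" if ssa_frac > thr.ssa_threshold else "HP"


# ---------------------------------------------------------------------------
# Grid-search calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    thresholds: ThresholdConfig
    surface: np.ndarray          # (len(villous_grid), len(ssa_grid)) objective
    villous_grid: tuple[float, ...]
    ssa_grid: tuple[float, ...]
    objective: str


def calibrate_thresholds(
    slides: list[tuple[ClassCounts, str]],
    grid: GridSpec = GridSpec(),
    denominator: str = "branch",
) -> CalibrationResult:
    """Grid-search the threshold pair maximizing the objective on a training
    cohort; ties broken toward the smallest (villous, ssa) pair
    lexicographically. The full objective surface is returned for inspection.
    """
    if not slides:
        raise ValueError("calibration requires at least one slide")
    branches = {"A" if c.adenomatous >= c.serrated else "S" for c, _ in slides}
    if branches != {"A", "S"}:
        raise ValueError("calibration requires at least one slide per branch")

    truths = np.array([t for _, t in slides])
    fracs = np.array([branch_fractions(c, denominator) for c, _ in slides])
    is_aden = np.array([c.adenomatous >= c.serrated for c, _ in slides])

    vg, sg = grid.villous_grid, grid.ssa_grid
    surface = np.empty((len(vg), len(sg)))
    best, best_val = None, -np.inf
    for (i, tv), (j, ts) in itertools.product(enumerate(vg), enumerate(sg)):
        pred = np.where(
            is_aden,
            np.where(fracs[:, 0] > tv, "TVA", "TA"),
            np.where(fracs[:, 1] > ts, "SSA", "HP"),
        )
        if grid.objective == "overall_accuracy":
            val = float(np.mean(pred == truths))
        else:
            accs = [np.mean(pred[truths == c] == c)
                    for c in SLIDE_CLASSES if (truths == c).any()]
            val = float(np.mean(accs))
        surface[i, j] = val
        # strict > keeps the lexicographically smallest maximizer
        if val > best_val + 1e-12:
            best_val, best = val, (tv, ts)
    thr = ThresholdConfig(villous_threshold=best[0], ssa_threshold=best[1],
                          denominator=denominator)
    return CalibrationResult(thr, surface, vg, sg, grid.objective)


# ---------------------------------------------------------------------------
# Whole-slide inference
# ---------------------------------------------------------------------------

def predict_slide_patches(model, image: np.ndarray, patch_spec, slide_id: str = "slide"
                          ) -> list[PatchPrediction]:
    """Run the patch classifier over a sliding window covering the slide."""
    from .patching import downsample_image, extract_patch, sliding_window

    if patch_spec.extraction_downsample > 1:
        image = downsample_image(image, patch_spec.extraction_downsample)
    h, w = image.shape[:2]
    origins = sliding_window((0, 0, w, h), patch_spec)
    if not origins:
        return []
    k = patch_spec.patch_size
    patches = np.stack([extract_patch(image, x, y, k) for x, y in origins])
    probs = model.predict_probs(patches)
    return [
        PatchPrediction(slide_id, x, y, k, probs[i])
        for i, (x, y) in enumerate(origins)
    ]


def infer_slide(
    model,
    image: np.ndarray,
    patch_spec,
    thr: ThresholdConfig = ThresholdConfig(),
    slide_id: str = "slide",
) -> tuple[str, list[PatchPrediction]]:
    """Diagnose a whole slide: sliding-window patch classification followed by
    the hierarchical rule. Returns (diagnosis, per-patch predictions)."""
    preds = predict_slide_patches(model, image, patch_spec, slide_id)
    counts = count_patch_classes(preds) if preds else ClassCounts(slide_id)
    if not preds:
        raise NoLesionError(f"no patches could be extracted from slide {slide_id!r}")
    return hierarchical_classify(counts, thr), preds
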