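"""Readers and writers for slide manifests, ROI annotations and prediction tables.

Coordinate convention used throughout the package: pixel coordinates are
0-based with origin at the top-left corner, x indexes columns and y indexes
rows, and boxes are half-open ``[x0, x1) x [y0, y1)`` so that
``image[y0:y1, x0:x1]`` extracts exactly the box.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Patch-level classes in the fixed order used everywhere (tie-breaks,
#: serialization, probability-vector columns).
PATCH_CLASSES: tuple[str, ...] = ("TA", "TVA", "HP", "SSA", "NORM")

#: Slide-level diagnoses: the four polyp types. Normal tissue is a
#: patch-level class only; whole slides always carry a polyp diagnosis.
SLIDE_CLASSES: tuple[str, ...] = ("TA", "TVA", "HP", "SSA")

#: Adenomatous vs serrated branch membership of the polyp classes.
ADENOMATOUS: tuple[str, ...] = ("TA", "TVA")
SERRATED: tuple[str, ...] = ("HP", "SSA")

SPLITS: tuple[str, ...] = ("train", "validation", "test_internal", "test_external")

PATCH_CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(PATCH_CLASSES)}

MANIFEST_COLUMNS = ["slide_id", "image_path", "microns_per_pixel", "split", "institution_id"]
PREDICTION_COLUMNS = ["slide_id", "x", "y", "size"] + [f"p_{c}" for c in PATCH_CLASSES]
LABEL_TABLE_COLUMNS = ["slide_id", "annotator_id", "label"]


class FormatError(ValueError):
    """Raised when an on-disk table violates the package's format contracts."""


@dataclass(frozen=True)
class SlideRecord:
    """One slide in a cohort manifest.

    ``microns_per_pixel`` defaults to 0.25, the physical resolution of a
    40x scan.
    """

    slide_id: str
    image_path: str
    microns_per_pixel: float = 0.25
    split: str = "train"
    institution_id: str = "internal"

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}; allowed: {SPLITS}")


@dataclass(frozen=True)
class BoundingBoxAnnotation:
    """A labeled rectangular ROI on a slide: the unit of training supervision.

    The box is half-open: ``[x0, x1) x [y0, y1)`` in pixels.
    """

    slide_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    label: str
    annotator_id: str = "annotator_0"

    def __post_init__(self):
        if self.label not in PATCH_CLASSES:
            raise ValueError(
                f"unknown label {self.label!r}; allowed values: {PATCH_CLASSES}"
            )
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(
                f"degenerate box [{self.x0},{self.x1})x[{self.y0},{self.y1}) "
                f"on slide {self.slide_id}"
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


@dataclass
class PatchPrediction:
    """Classifier output for one patch: origin, size and a probability 5-vector."""

    slide_id: str
    x: int
    y: int
    size: int
    probs: np.ndarray  # length 5, order PATCH_CLASSES

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(PATCH_CLASSES),):
            raise ValueError(f"probability vector must have length {len(PATCH_CLASSES)}")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"probabilities must sum to 1 within 1e-6, got {self.probs.sum():.8f}"
            )

    @property
    def label(self) -> str:
        """Hard label: argmax probability, ties broken by fixed class order."""
        return PATCH_CLASSES[int(np.argmax(self.probs))]

    @property
    def confidence(self) -> float:
        return float(self.probs.max())


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[SlideRecord]:
    """Read a slide-manifest CSV into validated :class:`SlideRecord` rows."""
    df = pd.read_csv(path, dtype={"slide_id": str, "institution_id": str})
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest {path} is missing column {col!r}")
    dup = df["slide_id"][df["slide_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate slide_id in manifest: {dup.iloc[0]!r}")
    return [
        SlideRecord(
            slide_id=row.slide_id,
            image_path=row.image_path,
            microns_per_pixel=float(row.microns_per_pixel),
            split=row.split,
            institution_id=row.institution_id,
        )
        for row in df.itertuples()
    ]


def write_manifest(path, records: Sequence[SlideRecord]) -> None:
    seen = set()
    for r in records:
        if r.slide_id in seen:
            raise FormatError(f"duplicate slide_id in manifest: {r.slide_id!r}")
        seen.add(r.slide_id)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI annotations (minimal JSON schema modeled on RectLabel exports)
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[BoundingBoxAnnotation]:
    """Read ROI annotations from JSON.

    Expected schema: a list of objects
    ``{"slide_id": str, "box": [x0, y0, x1, y1], "label": str, "annotator_id": str}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise FormatError(f"annotation file {path} must contain a JSON list")
    out = []
    for i, obj in enumerate(raw):
        try:
            box = obj["box"]
            out.append(
                BoundingBoxAnnotation(
                    slide_id=str(obj["slide_id"]),
                    x0=int(box[0]),
                    y0=int(box[1]),
                    x1=int(box[2]),
                    y1=int(box[3]),
                    label=obj["label"],
                    annotator_id=str(obj.get("annotator_id", "annotator_0")),
                )
            )
        except KeyError as e:
            raise FormatError(f"annotation {i} in {path} is missing field {e}") from e
    return out


def write_annotations(path, annotations: Iterable[BoundingBoxAnnotation]) -> None:
    payload = [
        {
            "slide_id": a.slide_id,
            "box": [a.x0, a.y0, a.x1, a.y1],
            "label": a.label,
            "annotator_id": a.annotator_id,
        }
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Patch-prediction tables
# ---------------------------------------------------------------------------

def write_predictions(path, preds: Sequence[PatchPrediction]) -> None:
    """Write patch predictions as CSV with >=6 significant digits per probability."""
    rows = []
    for p in preds:
        if abs(p.probs.sum() - 1.0) > 1e-6:
            raise FormatError(
                f"prediction at ({p.x},{p.y}) on {p.slide_id}: probabilities sum to "
                f"{p.probs.sum():.8f}, not 1"
            )
        rows.append([p.slide_id, p.x, p.y, p.size] + [f"{v:.8g}" for v in p.probs])
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, index=False)


def read_predictions(path) -> list[PatchPrediction]:
    df = pd.read_csv(path, dtype={"slide_id": str})
    for col in PREDICTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"prediction table {path} is missing column {col!r}")
    prob_cols = [f"p_{c}" for c in PATCH_CLASSES]
    return [
        PatchPrediction(
            slide_id=row.slide_id,
            x=int(row.x),
            y=int(row.y),
            size=int(row.size),
            probs=np.array([getattr(row, c) for c in prob_cols], dtype=float),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Slide-label tables (annotator panels / truth)
# ---------------------------------------------------------------------------

def read_label_table(path) -> pd.DataFrame:
    """Read a slide-label CSV (slide_id, annotator_id, label) into a DataFrame.

    Labels are restricted to the four slide-level classes; at most one label
    per (slide, annotator) pair.
    """
    df = pd.read_csv(path, dtype=str)
    for col in LABEL_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"label table {path} is missing column {col!r}")
    return validate_label_table(df)


def validate_label_table(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["label"]) - set(SLIDE_CLASSES)
    if bad:
        raise FormatError(
            f"unknown slide label(s) {sorted(bad)}; allowed values: {SLIDE_CLASSES}"
        )
    dup = df.duplicated(subset=["slide_id", "annotator_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"multiple labels for slide {row.slide_id!r} by annotator {row.annotator_id!r}"
        )
    return df.reset_index(drop=True)


def write_label_table(path, df: pd.DataFrame) -> None:
    validate_label_table(df)
    df[LABEL_TABLE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a slide image (PNG or plain non-pyramidal TIFF) as uint8 RGB."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return np.ascontiguousarray(img[..., :3].astype(np.uint8))


def write_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))
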