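"""End-to-end orchestration: cohort -> patches -> training -> calibration ->
slide inference -> evaluation -> visualization.

The data flow mirrors a real study: a training split supplies annotated ROIs
for patch extraction and threshold calibration, a held-out split is diagnosed
by sliding-window inference and compared with ground-truth labels (majority
vote when the truth table is a multi-annotator panel). Every run writes a
``run_manifest.json`` sidecar recording the seed, the config hash and every
artifact produced, which makes runs reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, heatmap, slide_inference, wsi_io
from .classifier import (
    SmallCNN,
    SoftmaxEnsemble,
    TrainConfig,
    hard_labels,
    train_patch_classifier,
)
from .patching import PatchSpec, extract_training_patches
from .slide_inference import (
    ClassCounts,
    GridSpec,
    ThresholdConfig,
    calibrate_thresholds,
    count_patch_classes,
    infer_slide,
    predict_slide_patches,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run over an on-disk cohort."""

    manifest: str
    annotations: str
    truth: str
    out_dir: str
    patch: PatchSpec = field(default_factory=lambda: PatchSpec(extraction_downsample=1))
    train: TrainConfig = field(default_factory=TrainConfig)
    thresholds: ThresholdConfig | None = None   # None -> calibrate via grid
    grid: GridSpec = field(default_factory=GridSpec)
    ensemble_size: int = 1
    balance_to: int = 200
    eval_split: str = "test_internal"
    heatmap_count: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "patch" in raw and isinstance(raw["patch"], dict):
            raw["patch"] = PatchSpec(**raw["patch"])
        if "train" in raw and isinstance(raw["train"], dict):
            t = dict(raw["train"])
            if isinstance(t.get("augment"), dict):
                from .patching import AugmentSpec

                a = dict(t["augment"])
                if "rotations" in a:
                    a["rotations"] = tuple(a["rotations"])
                t["augment"] = AugmentSpec(**a)
            if "n_filters" in t:
                t["n_filters"] = tuple(t["n_filters"])
            raw["train"] = TrainConfig(**t)
        if raw.get("thresholds") is not None and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = ThresholdConfig(**raw["thresholds"])
        if "grid" in raw and isinstance(raw["grid"], dict):
            g = dict(raw["grid"])
            for k in ("villous_grid", "ssa_grid"):
                if k in g:
                    g[k] = tuple(g[k])
            raw["grid"] = GridSpec(**g)
        return cls(**raw)


def run_config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str, slide_id: str = ""):
    """Context tag for stage errors: aborts name the stage and the slide."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                where = f"stage {name!r}" + (f", slide {slide_id!r}" if slide_id else "")
                raise RuntimeError(f"{where}: {exc}") from exc
    return _Ctx()


def _load_truth(path) -> pd.DataFrame:
    """Truth table -> consensus (slide_id, label): majority vote for panels,
    pass-through for single-annotator tables."""
    table = wsi_io.read_label_table(path)
    n_ann = table["annotator_id"].nunique()
    if n_ann == 1:
        return table[["slide_id", "label"]].reset_index(drop=True)
    return evaluation.majority_vote(table, n_annotators=n_ann)[["slide_id", "label"]]


def extract_cohort_patches(
    records, annotations, patch_spec: PatchSpec, balance_to: int | None, seed: int,
    split: str = "train",
):
    """Extract and globally class-balance training patches from a split."""
    ann_by_slide: dict[str, list] = {}
    for a in annotations:
        ann_by_slide.setdefault(a.slide_id, []).append(a)
    all_patches, all_labels, index_rows = [], [], []
    for rec in records:
        if rec.split != split or rec.slide_id not in ann_by_slide:
            continue
        with _stage("extract", rec.slide_id):
            image = wsi_io.read_image(rec.image_path)
            ps = extract_training_patches(
                image, ann_by_slide[rec.slide_id], patch_spec, balance_to=None,
                seed=seed,
            )
        all_patches.append(ps.patches)
        all_labels.append(ps.labels)
        for (x, y), lab in zip(ps.origins, ps.labels):
            index_rows.append({"slide_id": rec.slide_id, "x": x, "y": y, "label": lab})
    if not all_patches:
        raise RuntimeError(f"no patches extracted from split {split!r}")
    patches = np.concatenate(all_patches)
    labels = np.concatenate(all_labels)
    if balance_to is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for cls in wsi_io.PATCH_CLASSES:
            idx = np.flatnonzero(labels == cls)
            if len(idx) == 0:
                continue
            keep.append(rng.choice(idx, size=balance_to, replace=len(idx) < balance_to))
        order = np.concatenate(keep)
        patches, labels = patches[order], labels[order]
    return patches, labels, pd.DataFrame(index_rows)


def run_end_to_end(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Outputs: patch_index.csv, model checkpoint(s) + training log, calibrated
    thresholds.json, diagnoses.csv, predictions.csv, evaluation report
    (CSV + JSON), confusion matrix CSV, heatmap PNGs, run_manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    chash = run_config_hash(config)
    logger.info("run start: seed=%d config_hash=%s", config.seed, chash)
    artifacts: dict[str, str] = {}

    with _stage("read_inputs"):
        records = wsi_io.read_manifest(config.manifest)
        annotations = wsi_io.read_annotations(config.annotations)
        truth = _load_truth(config.truth).set_index("slide_id")["label"]

    # 1. training patches
    patches, labels, index = extract_cohort_patches(
        records, annotations, config.patch, config.balance_to, config.seed)
    index.to_csv(out / "patch_index.csv", index=False)
    artifacts["patch_index"] = "patch_index.csv"
    logger.info("extracted %d balanced training patches", len(labels))

    # 2. train (single model or seed-varied ensemble)
    members = []
    for m in range(config.ensemble_size):
        cfg = dataclasses.replace(config.train, seed=(config.seed + 7919 * m) % 2**31)
        with _stage("train"):
            model = train_patch_classifier(
                patches, labels, cfg,
                log_path=out / f"training_log_{m}.csv")
        model.save(out / f"model_{m}.npz")
        artifacts[f"model_{m}"] = f"model_{m}.npz"
        members.append(model)
    model = members[0] if len(members) == 1 else SoftmaxEnsemble(members)

    # 3. calibrate thresholds on the training split
    if config.thresholds is None:
        train_counts = []
        for rec in records:
            if rec.split != "train":
                continue
            with _stage("calibrate", rec.slide_id):
                image = wsi_io.read_image(rec.image_path)
                preds = predict_slide_patches(model, image, config.patch, rec.slide_id)
                train_counts.append(
                    (count_patch_classes(preds), truth[rec.slide_id]))
        with _stage("calibrate"):
            cal = calibrate_thresholds(train_counts, config.grid)
        thresholds = cal.thresholds
        logger.info("calibrated thresholds: %s", thresholds)
    else:
        thresholds = config.thresholds
    thresholds.to_json(out / "thresholds.json")
    artifacts["thresholds"] = "thresholds.json"

    # 4. slide inference on the evaluation split
    diag_rows, all_preds, eval_slides = [], [], []
    for rec in records:
        if rec.split != config.eval_split:
            continue
        with _stage("infer", rec.slide_id):
            image = wsi_io.read_image(rec.image_path)
            diagnosis, preds = infer_slide(
                model, image, config.patch, thresholds, rec.slide_id)
        counts = count_patch_classes(preds)
        v, s = slide_inference.branch_fractions(counts, thresholds.denominator)
        diag_rows.append({
            "slide_id": rec.slide_id, "diagnosis": diagnosis,
            **{f"n_{c}": getattr(counts, f"n_{c}") for c in wsi_io.PATCH_CLASSES},
            "villous_fraction": v, "ssa_fraction": s,
        })
        all_preds.extend(preds)
        eval_slides.append(rec)
    if not diag_rows:
        raise RuntimeError(f"no slides in evaluation split {config.eval_split!r}")
    diagnoses = pd.DataFrame(diag_rows)
    diagnoses.to_csv(out / "diagnoses.csv", index=False)
    wsi_io.write_predictions(out / "predictions.csv", all_preds)
    artifacts["diagnoses"] = "diagnoses.csv"
    artifacts["predictions"] = "predictions.csv"

    # 5. evaluation vs ground truth
    with _stage("evaluate"):
        truth_labels = diagnoses["slide_id"].map(truth).values
        report = evaluation.evaluate(diagnoses["diagnosis"].values, truth_labels)
    report.to_dataframe().to_csv(out / "evaluation_report.csv", index=False)
    with open(out / "evaluation_report.json", "w") as f:
        json.dump(report.to_dict(), f, indent=1)
    report.confusion.to_dataframe().to_csv(out / "confusion_matrix.csv")
    artifacts["evaluation_report"] = "evaluation_report.csv"
    artifacts["confusion_matrix"] = "confusion_matrix.csv"
    logger.info("mean accuracy: %.1f%%", report.mean_accuracy)

    # 6. heatmaps for the first few evaluated slides
    by_slide: dict[str, list] = {}
    for p in all_preds:
        by_slide.setdefault(p.slide_id, []).append(p)
    for rec in eval_slides[: config.heatmap_count]:
        with _stage("visualize", rec.slide_id):
            image = wsi_io.read_image(rec.image_path)
            wsi_io.write_image(out / f"{rec.slide_id}.heatmap.png",
                               heatmap.render_heatmap(image, by_slide[rec.slide_id]))
            wsi_io.write_image(out / f"{rec.slide_id}.lesion.png",
                               heatmap.render_lesion_mask(image, by_slide[rec.slide_id]))
        artifacts[f"heatmap_{rec.slide_id}"] = f"{rec.slide_id}.heatmap.png"

    with open(out / "run_manifest.json", "w") as f:
        json.dump({"seed": config.seed, "config_hash": chash,
                   "artifacts": artifacts}, f, indent=1)
    logging.getLogger().removeHandler(fh)
    fh.close()
    return out


def run_synthetic_end_to_end(
    n_per_class: int = 10,
    seed: int = 0,
    epochs: int = 20,
    balance_to: int = 200,
    slide_size: tuple[int, int] = (2048, 2048),
    split_fractions: tuple[float, float, float] = (0.6, 0.0, 0.4),
    grid: GridSpec | None = None,
) -> dict:
    """In-memory end-to-end experiment on a synthetic cohort.

    Generates a cohort whose planted villous/SSA fractions avoid the decision
    thresholds by at least 0.05, trains the reference patch classifier on the
    training split, calibrates thresholds by grid search on training-slide
    patch predictions, then diagnoses the held-out split. Each slide is
    rendered exactly once; nothing touches disk.

    Returns a dict with the trained-model mean per-class slide accuracy, the
    oracle-patch-label slide accuracy (planted truth fed straight into the
    hierarchical rule), the calibrated thresholds, and held-out patch-level
    accuracy of the classifier.
    """
    from . import synthetic

    ss = np.random.SeedSequence(seed)
    s_cohort, s_train, s_balance = (int(c.generate_state(1)[0] % 2**31)
                                    for c in ss.spawn(3))
    cohort = synthetic.generate_cohort(
        n_per_class, split_fractions=split_fractions, seed=s_cohort,
        slide_size=slide_size)

    # training split: render once, keep the full tile grid of patches
    train_patches, train_labels = [], []
    train_stacks: list[tuple[str, np.ndarray]] = []  # per-slide patch stacks
    patch_spec = PatchSpec(extraction_downsample=1)
    for sid in cohort.slide_ids("train"):
        slide = cohort.render(sid)
        ps = extract_training_patches(slide.image, slide.annotations, patch_spec,
                                      balance_to=None, seed=s_balance)
        train_patches.append(ps.patches)
        train_labels.append(ps.labels)
        train_stacks.append((sid, ps.patches))
    patches = np.concatenate(train_patches)
    labels = np.concatenate(train_labels)

    rng = np.random.default_rng(s_balance)
    keep = []
    for cls in wsi_io.PATCH_CLASSES:
        idx = np.flatnonzero(labels == cls)
        if len(idx):
            keep.append(rng.choice(idx, size=balance_to,
                                   replace=len(idx) < balance_to))
    order = np.concatenate(keep)
    # hold out a slice of the balanced pool for patch-level accuracy
    rng.shuffle(order)
    n_val = max(1, len(order) // 10)
    val_idx, fit_idx = order[:n_val], order[n_val:]

    model = train_patch_classifier(
        patches[fit_idx], labels[fit_idx],
        TrainConfig(epochs=epochs, seed=s_train))
    val_probs = model.predict_probs(patches[val_idx])
    patch_accuracy = float(np.mean(hard_labels(val_probs) == labels[val_idx]))

    # calibrate on training-slide predictions
    train_counts = []
    for sid, stack in train_stacks:
        pred_labels = hard_labels(model.predict_probs(stack))
        train_counts.append(
            (ClassCounts.from_labels(sid, pred_labels), cohort.true_label(sid)))
    cal = calibrate_thresholds(train_counts, grid or GridSpec())
    thresholds = cal.thresholds

    # held-out split: model diagnoses + oracle-label diagnoses
    eval_split = "test_internal"
    pred, oracle_pred, truth = [], [], []
    for sid in cohort.slide_ids(eval_split):
        slide = cohort.render(sid)
        diagnosis, _ = infer_slide(model, slide.image, patch_spec, thresholds, sid)
        pred.append(diagnosis)
        oracle_pred.append(slide_inference.hierarchical_classify(
            slide.oracle_class_counts(), ThresholdConfig()))
        truth.append(slide.true_label)

    pred, oracle_pred, truth = map(np.asarray, (pred, oracle_pred, truth))
    mean_class_acc = float(np.mean(
        [np.mean(pred[truth == c] == c) for c in wsi_io.SLIDE_CLASSES]))
    oracle_acc = float(np.mean(oracle_pred == truth))
    return {
        "n_slides": len(cohort.records),
        "n_eval_slides": len(truth),
        "patch_accuracy": patch_accuracy,
        "mean_class_accuracy": mean_class_acc,
        "oracle_slide_accuracy": oracle_acc,
        "villous_threshold": thresholds.villous_threshold,
        "ssa_threshold": thresholds.ssa_threshold,
    }
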