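"""Multi-annotator ground truthing and diagnostic-performance statistics.

Implements the full reporting battery for slide-level diagnoses:

* majority-vote consensus over an annotator panel (ties resolved by a
  designated reference annotator and flagged),
* one-vs-rest accuracy / sensitivity / specificity per polyp class, their
  unweighted mean, and Wald binomial 95% CIs on mean proportions,
* multiclass Cohen kappa, summarized over all annotator pairs,
* pooled two-proportion z-tests ("t test for proportions"),
* row-normalized confusion matrices.

Percentages are reported rounded to one decimal, half away from zero;
unrounded values are retained in machine-readable output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .wsi_io import SLIDE_CLASSES


def report_round(x: float | None, decimals: int = 1) -> float | None:
    """Round half away from zero (the reporting convention for percentages)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    q = 10**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


# ---------------------------------------------------------------------------
# Majority vote
# ---------------------------------------------------------------------------

def majority_vote(
    panel: pd.DataFrame,
    n_annotators: int = 5,
    reference_annotator: str | None = None,
) -> pd.DataFrame:
    """Consensus labels from an annotator panel (slide_id, annotator_id, label).

    Every slide must carry a label from every annotator. The strict plurality
    winner is the consensus; on a tie, the reference annotator's label decides
    among the tied classes (falling back to fixed class order if the reference
    voted outside the tie), and the slide is flagged. Returns a DataFrame
    (slide_id, label, tie) sorted by slide_id.
    """
    annotators = sorted(panel["annotator_id"].unique())
    if len(annotators) != n_annotators:
        raise ValueError(
            f"expected {n_annotators} annotators, found {len(annotators)}"
        )
    if reference_annotator is None:
        reference_annotator = annotators[0]
    wide = panel.pivot(index="slide_id", columns="annotator_id", values="label")
    missing = wide.isna()
    if missing.any().any():
        sid = missing.any(axis=1).idxmax()
        ann = missing.loc[sid].idxmax()
        raise ValueError(f"slide {sid!r} is missing a label from annotator {ann!r}")

    rows = []
    for sid, votes in wide.iterrows():
        counts = votes.value_counts()
        top = counts.max()
        tied = sorted(counts[counts == top].index, key=SLIDE_CLASSES.index)
        if len(tied) == 1:
            rows.append({"slide_id": sid, "label": tied[0], "tie": False})
        else:
            ref = votes[reference_annotator]
            label = ref if ref in tied else tied[0]
            rows.append({"slide_id": sid, "label": label, "tie": True})
    return pd.DataFrame(rows).sort_values("slide_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# One-vs-rest metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class, in percent (unrounded).

    ``sensitivity`` is None when the class is absent from the truth;
    ``specificity`` is None when there are no negatives.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None


def per_class_metrics(pred, truth, cls: str) -> ClassMetrics:
    """One-vs-rest accuracy, sensitivity and specificity for class ``cls``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    pos_t, pos_p = truth == cls, pred == cls
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    n = len(truth)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    return ClassMetrics(100.0 * (tp + tn) / n, sens, spec)


def mean_metrics(values) -> float | None:
    """Unweighted arithmetic mean of the four per-class values; None if any
    class value is missing."""
    values = list(values)
    if len(values) != len(SLIDE_CLASSES):
        raise ValueError(f"expected {len(SLIDE_CLASSES)} per-class values")
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return None
    return float(np.mean(values))


def wald_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wald binomial CI on proportion ``p`` of ``n`` trials, in percent,
    clipped to [0, 100]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half)))


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

def multiclass_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa over the observed label vocabulary.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the two raters' marginal label frequencies (labels absent from
    both raters contribute nothing, so the full slide-class vocabulary and
    the observed one give the same value). Defined as 1 when p_e = 1 (both
    raters constant and identical).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == c)) * float(np.mean(b == c)) for c in np.union1d(a, b)
    )
    if p_e >= 1.0 - 1e-12:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class KappaResult:
    """Pairwise Cohen kappas over an annotator panel and their mean with a
    normal-approximation 95% CI."""

    pairwise: dict[tuple[str, str], float]
    mean: float
    ci: tuple[float, float]

    def __post_init__(self):
        for k in self.pairwise.values():
            if not -1.0 - 1e-9 <= k <= 1.0 + 1e-9:
                raise ValueError("kappa values must lie in [-1, 1]")


def mean_pairwise_kappa(panel: pd.DataFrame, z: float = 1.96) -> KappaResult:
    """Mean multiclass Cohen kappa over all annotator pairs of a panel."""
    wide = panel.pivot(index="slide_id", columns="annotator_id", values="label")
    if wide.isna().any().any():
        raise ValueError("panel is incomplete")
    annotators = sorted(wide.columns)
    pairwise = {
        (a, b): multiclass_kappa(wide[a].values, wide[b].values)
        for a, b in itertools.combinations(annotators, 2)
    }
    vals = np.array(list(pairwise.values()))
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return KappaResult(pairwise, mean, (mean - z * se, mean + z * se))


# ---------------------------------------------------------------------------
# Two-proportion test
# ---------------------------------------------------------------------------

def two_proportion_test(
    p1: float, n1: int, p2: float, n2: int, pooled: bool = True
) -> tuple[float, float]:
    """Two-sided two-proportion z-test; returns (z, p-value).

    Pooled variance by default: z = (p1 - p2) / sqrt(phat (1-phat) (1/n1 + 1/n2))
    with phat the pooled proportion. ``pooled=False`` uses the unpooled
    standard error. When the standard error degenerates to 0 the p-value is 1
    for equal proportions and 0 otherwise.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if pooled:
        phat = (p1 * n1 + p2 * n2) / (n1 + n2)
        se = math.sqrt(phat * (1.0 - phat) * (1.0 / n1 + 1.0 / n2))
    else:
        se = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    if se == 0.0:
        return (0.0, 1.0) if p1 == p2 else (math.inf, 0.0)
    z = (p1 - p2) / se
    return z, float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """4x4 counts indexed (truth row, predicted column) plus the
    row-normalized agreement-ratio view."""

    counts: np.ndarray
    classes: tuple[str, ...] = SLIDE_CLASSES

    @property
    def ratios(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.counts / sums
        return np.where(sums > 0, r, 0.0)

    def to_dataframe(self, ratios: bool = True) -> pd.DataFrame:
        data = self.ratios if ratios else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(pred, truth) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    idx = {c: i for i, c in enumerate(SLIDE_CLASSES)}
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth, pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class and mean metrics (percent) with Wald 95% CIs on the means."""

    per_class: dict[str, ClassMetrics]
    mean_accuracy: float | None
    mean_sensitivity: float | None
    mean_specificity: float | None
    ci_accuracy: tuple[float, float] | None
    ci_sensitivity: tuple[float, float] | None
    ci_specificity: tuple[float, float] | None
    n_slides: int
    confusion: ConfusionMatrix

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        """Table mirroring the standard report layout: one row per class plus
        a Mean row; accuracy / sensitivity / specificity columns in percent."""
        r = report_round if rounded else (lambda x: x)
        rows = []
        for cls in SLIDE_CLASSES:
            m = self.per_class[cls]
            rows.append({"class": cls, "accuracy": r(m.accuracy),
                         "sensitivity": r(m.sensitivity),
                         "specificity": r(m.specificity)})
        rows.append({"class": "Mean", "accuracy": r(self.mean_accuracy),
                     "sensitivity": r(self.mean_sensitivity),
                     "specificity": r(self.mean_specificity)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_slides": self.n_slides,
            "per_class": {
                c: {"accuracy": m.accuracy, "sensitivity": m.sensitivity,
                    "specificity": m.specificity}
                for c, m in self.per_class.items()
            },
            "mean": {"accuracy": self.mean_accuracy,
                     "sensitivity": self.mean_sensitivity,
                     "specificity": self.mean_specificity},
            "ci": {"accuracy": self.ci_accuracy,
                   "sensitivity": self.ci_sensitivity,
                   "specificity": self.ci_specificity},
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_ratios": self.confusion.ratios.tolist(),
        }


def evaluate(pred, truth) -> EvalReport:
    """Compute the full slide-level report for predicted vs truth labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    per_class = {c: per_class_metrics(pred, truth, c) for c in SLIDE_CLASSES}
    n = len(truth)

    def mean_and_ci(attr):
        vals = [getattr(per_class[c], attr) for c in SLIDE_CLASSES]
        m = mean_metrics(vals)
        return m, (wald_ci(m / 100.0, n) if m is not None else None)

    mean_acc, ci_acc = mean_and_ci("accuracy")
    mean_sens, ci_sens = mean_and_ci("sensitivity")
    mean_spec, ci_spec = mean_and_ci("specificity")
    return EvalReport(
        per_class=per_class,
        mean_accuracy=mean_acc, mean_sensitivity=mean_sens,
        mean_specificity=mean_spec,
        ci_accuracy=ci_acc, ci_sensitivity=ci_sens, ci_specificity=ci_spec,
        n_slides=n,
        confusion=confusion_matrix(pred, truth),
    )
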