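"""Glycemic banding and classification metrics.

Continuous glucose (mmol/L) is mapped onto seven clinically motivated
classes: two hypoglycemic bands, three euglycemic bands (a wide normal
range flanked by thin "closing-to-hypo" / "closing-to-hyper" warning
zones), and two hyperglycemic bands.  The warning zones exist so that a
forecaster can flag a drift towards a dangerous excursion before it
happens, instead of jumping straight from "normal" to "hypo".

All scores are computed from a 7x7 confusion matrix (rows = true class,
columns = predicted class).  Because the class distribution of CGM data
is heavily imbalanced -- hypoglycemic samples are rare -- the headline
score is the class-frequency-weighted F1, not accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Right-open band boundaries in mmol/L.  Class i covers
#: [BAND_BOUNDS[i-1], BAND_BOUNDS[i]) with implicit 0 and +inf at the ends.
BAND_BOUNDS: tuple[float, ...] = (3.0, 3.9, 5.0, 7.8, 10.0, 13.9)

BAND_LABELS: tuple[str, ...] = (
    "very low",
    "low",
    "normal-closing-to-hypo",
    "normal",
    "normal-closing-to-hyper",
    "high",
    "very high",
)

N_CLASSES = 7

#: mg/dL per mmol/L.  The paired band bounds (54 mg/dL <-> 3.0 mmol/L,
#: 90 <-> 5.0, 250 <-> 13.9 within rounding) fix the factor at exactly 18.
MGDL_PER_MMOLL = 18.0


def mgdl_to_mmoll(v: float) -> float:
    """Convert a glucose value from mg/dL to mmol/L (division by 18)."""
    if v < 0:
        raise ValueError(f"glucose in mg/dL must be non-negative, got {v}")
    return v / MGDL_PER_MMOLL


def to_class(g: float) -> int:
    """Map a glucose value in mmol/L to its band id (0-6).

    Boundary values belong to the upper band: the intervals are
    right-open, e.g. 3.9 mmol/L is already class 2 ("closing-to-hypo").
    """
    if not np.isfinite(g) or g <= 0:
        raise ValueError(f"glucose must be finite and positive, got {g}")
    return int(np.searchsorted(BAND_BOUNDS, g, side="right"))


def classify(values: np.ndarray) -> np.ndarray:
    """Vectorised banding; non-finite or non-positive entries map to -1.

    The -1 sentinel marks an impossible prediction: it can never equal a
    true band, so such samples count as misclassified (false negatives of
    their true class) without inflating any real class's false positives.
    """
    values = np.asarray(values, dtype=float)
    out = np.searchsorted(BAND_BOUNDS, values, side="right").astype(np.int64)
    bad = ~np.isfinite(values) | (values <= 0)
    out[bad] = -1
    return out


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """7x7 confusion matrix; predictions of -1 (sentinel) are dropped from
    the columns but their rows still count as errors via class totals."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    ok = y_pred >= 0
    np.add.at(cm, (y_true[ok], y_pred[ok]), 1)
    return cm


def binary_f1(tp: int, fp: int, fn: int) -> float:
    """One-vs-rest F1 = tp / (tp + 0.5*(fp+fn)); 0 when the class is empty."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        return 0.0
    return tp / denom


def _class_counts(cm: np.ndarray):
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return tp, fp, fn


@dataclass
class ScoreReport:
    """Weighted precision/recall/F1 and accuracy from a confusion matrix."""

    confusion: np.ndarray
    per_class_f1: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)
    f1: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion, dtype=np.int64)
        total = cm.sum()
        if total <= 0:
            raise ValueError("confusion matrix is empty")
        tp, fp, fn = _class_counts(cm)
        support = cm.sum(axis=1).astype(float)
        self.weights = support / total
        self.per_class_f1 = np.array(
            [binary_f1(int(t), int(p), int(n)) for t, p, n in zip(tp, fp, fn)]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            prec_i = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
            rec_i = np.where(support > 0, tp / np.maximum(support, 1.0), 0.0)
        self.f1 = float(self.weights @ self.per_class_f1)
        self.precision = float(self.weights @ prec_i)
        self.recall = float(self.weights @ rec_i)
        self.accuracy = float(tp.sum() / total)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "per_class_f1": self.per_class_f1.tolist(),
            "weights": self.weights.tolist(),
            "confusion": np.asarray(self.confusion).tolist(),
        }


def weighted_f1(cm: np.ndarray) -> float:
    """Class-frequency-weighted mean of one-vs-rest F1 scores.

    Weights are the true-class frequencies p_i (empty classes get weight
    zero), so a perfect, purely diagonal matrix scores exactly 1.
    """
    return ScoreReport(cm).f1


def weighted_f1_from_labels(y_true, y_pred) -> float:
    """Weighted F1 directly from label vectors; -1 predictions (sentinel
    for non-finite model output) are pure errors of their true class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    total = len(y_true)
    if total == 0:
        raise ValueError("no samples")
    score = 0.0
    for c in range(N_CLASSES):
        in_c = y_true == c
        support = int(in_c.sum())
        if support == 0:
            continue
        tp = int(np.sum(in_c & (y_pred == c)))
        fp = int(np.sum(~in_c & (y_pred == c)))
        fn = support - tp
        score += (support / total) * binary_f1(tp, fp, fn)
    return score


def score_report(cm: np.ndarray) -> ScoreReport:
    """Full weighted precision/recall/F1/accuracy report for a matrix."""
    return ScoreReport(cm)


def relative_improvement(a: float, b: float) -> float:
    """Percent improvement of score ``a`` over baseline ``b``: 100*(a-b)/b."""
    if b == 0:
        raise ValueError("baseline score must be non-zero")
    return 100.0 * (a - b) / b


def aggregate(scores) -> tuple[float, float]:
    """Mean and standard deviation of a sequence of per-patient scores.

    Uses the population (n-denominator) standard deviation; this is the
    convention the bundled benchmark margins follow.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sequence")
    return float(scores.mean()), float(scores.std(ddof=0))
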