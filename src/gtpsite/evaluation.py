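"""Evaluation: confusion metrics, ROC/AUC, protein-level cross-validation.

Metrics follow the usual confusion-matrix definitions —

    Sensitivity = TP / (TP + FN)            (percent)
    Specificity = TN / (TN + FP)            (percent)
    Accuracy    = (TP + TN) / (TP+FP+TN+FN) (percent)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as undefined (None), not
as 0, so averages are never silently inflated.  Display rounding is one
decimal for percentages and two for MCC; full precision is retained
internally.

Cross-validation folds are assigned at the protein level: residue-level
folds would leak near-identical overlapping windows between training and
test sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import sklearn.metrics

from .io_formats import ParameterError, ConsistencyError, ProteinRecord
from .encoding import WindowFragment


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


@dataclass
class MetricsReport:
    """Full-precision metrics; percentages in [0, 100], MCC in [-1, 1].

    A metric with a zero denominator is ``None`` (undefined).
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float | None
    auc: float | None = None

    def rounded(self) -> Dict[str, float | None]:
        """Display rounding: 1 decimal for percentages, 2 for MCC, 2 for AUC."""
        r = lambda v, nd: None if v is None else round(v, nd)
        return {
            "sensitivity": r(self.sensitivity, 1),
            "specificity": r(self.specificity, 1),
            "accuracy": r(self.accuracy, 1),
            "mcc": r(self.mcc, 2),
            "auc": r(self.auc, 2),
        }

    def to_dict(self) -> Dict[str, float | int | None]:
        return {
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Tally a confusion matrix; the four counts partition the instances."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ConsistencyError(
            f"truth length {truth.shape} != predicted length {predicted.shape}"
        )
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(
    counts: ConfusionCounts, scores=None, truth=None
) -> MetricsReport:
    """Compute the four confusion metrics (and AUC when scores are supplied)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    acc = 100.0 * (tp + tn) / counts.total if counts.total > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    auc_value = None
    if scores is not None:
        if truth is None:
            raise ParameterError("truth labels are required to compute AUC")
        auc_value = auc(roc_curve(scores, truth))
    return MetricsReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        mcc=mcc,
        auc=auc_value,
    )


def roc_curve(scores: Sequence[float], truth: Sequence[int]) -> np.ndarray:
    """Operating points (FPR, TPR) from sweeping the threshold over all
    distinct scores, including the (0, 0) and (1, 1) endpoints.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(truth.tolist())) < 2:
        raise ParameterError("ROC needs both classes in the truth labels")
    fpr, tpr, _ = sklearn.metrics.roc_curve(
        truth, scores, drop_intermediate=False
    )
    points = np.column_stack([fpr, tpr])
    if not np.array_equal(points[0], [0.0, 0.0]):
        points = np.vstack([[0.0, 0.0], points])
    if not np.array_equal(points[-1], [1.0, 1.0]):
        points = np.vstack([points, [1.0, 1.0]])
    return points


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under a ROC point list sorted by FPR.

    Equals the rank statistic P(score_pos > score_neg) + 0.5 P(tie) on
    the underlying scores.
    """
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def plot_roc(points: np.ndarray, path, label: str | None = None) -> None:
    """Thin convenience plot of a ROC curve to ``path`` (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = np.asarray(points, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    name = label or f"AUC = {auc(points):.3f}"
    ax.plot(points[:, 0], points[:, 1], label=name)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cross-validation

FoldAssignment = Dict[str, int]


def protein_kfold(
    records: Sequence[ProteinRecord], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Assign whole proteins to ``k`` folds, balancing positives.

    Proteins are shuffled with ``seed``, stably sorted by positive-residue
    count (descending) and dealt round-robin, so every fold receives one
    of the most positive-rich proteins before any fold receives two.
    Requires at least ``k`` proteins carrying a positive residue so every
    fold holds at least one.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if len(records) < k:
        raise ParameterError(f"{len(records)} proteins cannot fill {k} folds")
    with_pos = sum(1 for r in records if r.n_positive > 0)
    if with_pos < k:
        raise ParameterError(
            f"only {with_pos} proteins have positive residues; need >= {k}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(records)))
    order.sort(key=lambda i: -records[i].n_positive)  # stable: shuffle breaks ties
    assignment: FoldAssignment = {}
    for rank, idx in enumerate(order):
        assignment[records[idx].id] = rank % k
    return assignment


def composition_frequencies(
    fragments: Sequence[WindowFragment],
) -> Dict[int, Dict[str, float]]:
    """Per-class relative frequency of the centre residues.

    Returns ``{1: {...}, 0: {...}}``; each present class sums to 1.
    """
    if not fragments:
        raise ParameterError("no fragments supplied")
    half = (fragments[0].w - 1) // 2
    out: Dict[int, Dict[str, float]] = {}
    for label in (0, 1):
        counts: Dict[str, int] = {}
        total = 0
        for frag in fragments:
            if frag.label != label:
                continue
            centre = frag.residues[half]
            counts[centre] = counts.get(centre, 0) + 1
            total += 1
        if total:
            out[label] = {aa: c / total for aa, c in sorted(counts.items())}
    return out
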