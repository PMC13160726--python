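"""Discrimination, calibration, and decision-curve metrics.

All operations take a vector of predicted event probabilities and the binary
labels. Hard-label metrics threshold at p >= t (ties count as positive). AUC
is the Mann-Whitney concordance probability with ties counted 1/2, with a
seeded stratified percentile bootstrap for its confidence interval. ECE uses
equal-width right-closed bins. Net benefit follows the standard
decision-curve definition NB = TP/n - (FP/n) * p_t / (1 - p_t).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import SingleClassError

__all__ = [
    "ClassificationMetrics",
    "DecisionCurvePoint",
    "MetricReport",
    "classification_metrics",
    "auc",
    "auc_with_ci",
    "brier",
    "ece",
    "decision_curve",
    "compute_report",
]

DEFAULT_DCA_THRESHOLDS = np.round(np.arange(0.01, 0.501, 0.01), 10)


def _validate(probabilities, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("probabilities must lie in [0,1]")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return p, y


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5
    precision_undefined: bool = False

    def __iter__(self):
        return iter((self.accuracy, self.precision, self.recall, self.f1))


def classification_metrics(probabilities, labels, threshold: float = 0.5) -> ClassificationMetrics:
    """Confusion-matrix metrics at a probability threshold (ties positive)."""
    p, y = _validate(probabilities, labels)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    undefined = (tp + fp) == 0
    if undefined:
        warnings.warn("no predicted positives; precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return ClassificationMetrics(accuracy, precision, recall, f1,
                                 threshold=threshold, precision_undefined=undefined)


def auc(probabilities, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    p, y = _validate(probabilities, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC requires both classes")
    ranks = rankdata(p)  # average ranks give the 1/2 tie credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_with_ci(
    probabilities,
    labels,
    resamples: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUC with a seeded stratified percentile-bootstrap confidence interval."""
    p, y = _validate(probabilities, labels)
    point = auc(p, y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    stats = np.empty(resamples)
    for b in range(resamples):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        stats[b] = auc(p[idx], y[idx])
    alpha = (1 - level) / 2
    lower, upper = np.quantile(stats, [alpha, 1 - alpha])
    return point, float(lower), float(upper)


def brier(probabilities, labels) -> float:
    """Mean squared difference between probability and outcome."""
    p, y = _validate(probabilities, labels)
    return float(np.mean((p - y) ** 2))


def ece(probabilities, labels, n_bins: int = 10) -> tuple[float, pd.DataFrame]:
    """Expected calibration error over equal-width right-closed bins.

    Returns the scalar ECE plus the per-bin table (count, mean confidence,
    event rate, gap). Empty bins contribute zero.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    p, y = _validate(probabilities, labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins (lo, hi]; probability 0 falls in the first bin
    idx = np.clip(np.ceil(p * n_bins).astype(int) - 1, 0, n_bins - 1)
    rows, total = [], len(p)
    value = 0.0
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count:
            conf = float(p[mask].mean())
            rate = float(y[mask].mean())
            gap = abs(conf - rate)
            value += count / total * gap
        else:
            conf = rate = gap = np.nan
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1], "count": count,
                     "mean_probability": conf, "event_rate": rate, "gap": gap})
    return float(value), pd.DataFrame(rows)


@dataclass(frozen=True)
class DecisionCurvePoint:
    threshold: float
    nb_model: float
    nb_all: float
    nb_none: float = 0.0


def decision_curve(probabilities, labels, thresholds=None) -> list[DecisionCurvePoint]:
    """Net benefit of the model vs treat-all and treat-none strategies."""
    p, y = _validate(probabilities, labels)
    if thresholds is None:
        thresholds = DEFAULT_DCA_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1) or np.any(thresholds <= 0):
        raise ValueError("threshold probabilities must lie in (0,1)")
    n = len(y)
    pi = float(y.mean())
    points = []
    for pt in thresholds:
        w = pt / (1 - pt)
        pred = p >= pt
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        nb_model = tp / n - fp / n * w
        nb_all = pi - (1 - pi) * w
        points.append(DecisionCurvePoint(float(pt), nb_model, nb_all))
    return points


@dataclass
class MetricReport:
    """Bundle of discrimination, calibration, and utility results."""

    classification: ClassificationMetrics
    auc: float
    auc_ci: tuple[float, float]
    auc_ci_level: float
    brier: float
    ece: float
    ece_bins: pd.DataFrame
    decision_curve: list[DecisionCurvePoint]
    n: int
    bootstrap: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.classification.accuracy,
            "precision": self.classification.precision,
            "recall": self.classification.recall,
            "f1": self.classification.f1,
            "precision_undefined": self.classification.precision_undefined,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "auc_ci_level": self.auc_ci_level,
            "brier": self.brier,
            "ece": self.ece,
            "bootstrap": self.bootstrap,
            "decision_curve": [asdict(pt) for pt in self.decision_curve],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_report(
    probabilities,
    labels,
    threshold: float = 0.5,
    n_bins: int = 10,
    dca_thresholds=None,
    resamples: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricReport:
    """Compute the full metric suite for one prediction vector."""
    cls = classification_metrics(probabilities, labels, threshold=threshold)
    point, lo, hi = auc_with_ci(probabilities, labels, resamples=resamples,
                                level=level, seed=seed)
    ece_value, bins = ece(probabilities, labels, n_bins=n_bins)
    dca = decision_curve(probabilities, labels, thresholds=dca_thresholds)
    return MetricReport(
        classification=cls, auc=point, auc_ci=(lo, hi), auc_ci_level=level,
        brier=brier(probabilities, labels), ece=ece_value, ece_bins=bins,
        decision_curve=dca, n=len(np.asarray(labels)),
        bootstrap={"resamples": resamples, "seed": seed, "stratified": True},
    )
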