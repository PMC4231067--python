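"""Confusion accounting, balanced accuracy, and leave-one-out evaluation.

Multiclass predictions are reduced one-against-others per class: for class c,
a sample is positive when its true label is c.  Then

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    balanced accuracy = (sensitivity + specificity) / 2

Balanced accuracy is the fitness of the model-selection search: with one
class against eleven others the positives are badly outnumbered, and raw
accuracy would reward the always-negative classifier.  Undefined metrics
(zero denominator) raise rather than silently returning 0, since a silent 0
would corrupt fitness ranking.

Overall performance is the unweighted mean of per-class balanced accuracies
from a leave-one-out test: each sample is predicted by an ensemble retrained
on all remaining samples under the same genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, InputError, InvalidGenomeError, UndefinedMetricError
from .genome import Genome
from .svm import OvREnsemble, count_support_vectors, train_ovr_ensemble


@dataclass(frozen=True)
class ConfusionCounts:
    """One-against-others confusion counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    predictions: Sequence[str], truths: Sequence[str], target_class: str
) -> ConfusionCounts:
    """Reduce multiclass predictions to one-vs-rest counts for ``target_class``."""
    if len(predictions) != len(truths):
        raise InputError(
            f"{len(predictions)} predictions for {len(truths)} truths"
        )
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truths):
        if t == target_class:
            if p == target_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == target_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN), as a percentage."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP), as a percentage."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return 100.0 * c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Arithmetic mean of sensitivity and specificity, as a percentage."""
    return (sensitivity(c) + specificity(c)) / 2.0


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    accuracy: float  # raw (TP + TN) / total, also emitted for table parity
    counts: ConfusionCounts


@dataclass
class EvaluationReport:
    """Per-class metrics plus their unweighted mean and variance."""

    per_class: dict[str, ClassMetrics]
    average: float
    variance: float

    @classmethod
    def from_predictions(
        cls, predictions: Sequence[str], truths: Sequence[str], class_order: Sequence[str]
    ) -> "EvaluationReport":
        per_class = {}
        for label in class_order:
            counts = confusion_counts(predictions, truths, label)
            per_class[label] = ClassMetrics(
                sensitivity=sensitivity(counts),
                specificity=specificity(counts),
                balanced_accuracy=balanced_accuracy(counts),
                accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
                counts=counts,
            )
        bas = np.array([m.balanced_accuracy for m in per_class.values()])
        variance = float(np.var(bas, ddof=1)) if bas.size > 1 else 0.0
        return cls(per_class=per_class, average=float(np.mean(bas)), variance=variance)

    def to_frame(self):
        """Tabular layout: one row per class plus Average / Average var. rows."""
        import pandas as pd

        rows = {
            label: {
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "balanced_accuracy": m.balanced_accuracy,
                "accuracy": m.accuracy,
            }
            for label, m in self.per_class.items()
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.loc["Average"] = frame.mean()
        frame.loc["Average var."] = frame.iloc[:-1].var(ddof=1)
        return frame


def loo_evaluate(
    X: np.ndarray,
    y: Sequence[str],
    genome: Genome,
    fold_callback: Callable[[int, OvREnsemble], None] | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation: n retrain-predict cycles under one genome.

    ``fold_callback(fold_index, ensemble)``, when given, is invoked once per
    fold (useful for instrumentation).  Every class needs >= 2 samples so each
    fold still contains all classes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    for c in classes:
        if int(np.sum(y == c)) < 2:
            raise ConfigurationError(
                f"class {c!r} has a single sample; leave-one-out would lose it from "
                "training — use a stratified k-fold protocol instead"
            )
    predictions: list[str] = []
    idx = np.arange(len(y))
    for i in idx:
        keep = idx != i
        ens = train_ovr_ensemble(X[keep], y[keep], genome, class_order=classes)
        predictions.append(ens.predict(X[i : i + 1])[0])
        if fold_callback is not None:
            fold_callback(int(i), ens)
    return EvaluationReport.from_predictions(predictions, list(y), classes)


def accuracy_fitness(X: np.ndarray, y: Sequence[str], genome: Genome) -> float:
    """LOO average balanced accuracy (to maximize); invalid genomes score 0."""
    try:
        return loo_evaluate(X, y, genome).average
    except InvalidGenomeError:
        return 0.0


def sv_count_fitness(X: np.ndarray, y: Sequence[str], genome: Genome) -> float:
    """Support-vector count of the full-data ensemble (to minimize).

    Fewer support vectors means a cheaper, better-generalizing model; invalid
    genomes score +inf so the search simply discards them.
    """
    try:
        ens = train_ovr_ensemble(X, y, genome)
    except InvalidGenomeError:
        return math.inf
    return float(count_support_vectors(ens))
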