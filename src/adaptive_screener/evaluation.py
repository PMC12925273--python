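"""Classification metrics and fixed-length questionnaire baselines.

Positive class is "depressed".  The headline metric is the Youden index,
sensitivity + specificity - 1, reported to full precision; a rate whose
denominator is zero (no positives or no negatives in the evaluation set) is
reported as NaN with a warning, never silently as 0.

Baselines: the full PHQ-9 (total >= 10, 9 questions), the four-item
PHQ-DEP-4 (items phq1, phq2, phq6, phq8; subscore >= 4, 4 questions) and the
two-item PHQ-2 (items phq1, phq2; conventional cutoff >= 3, 2 questions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    DEPRESSION_CUTOFF,
    N_ITEMS,
    Label,
    PhqDataset,
    RespondentRecord,
    ValidationError,
)
from .engine import DecisionTrace

PHQ_DEP4_ITEMS = (1, 2, 6, 8)  # 1-based item numbers
PHQ_DEP4_CUTOFF = 4
PHQ2_ITEMS = (1, 2)
PHQ2_CUTOFF = 3


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    """Metrics of one evaluation run (full precision; round only on display)."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    avg_questions: float
    stop_histogram: dict[int, int]  # question 1..9 -> respondents stopped there

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden": self.youden,
            "avg_questions": self.avg_questions,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "stop_histogram": {str(q): c for q, c in sorted(self.stop_histogram.items())},
        }


def _rate(numerator: int, denominator: int, name: str) -> float:
    if denominator == 0:
        warnings.warn(
            f"{name} is undefined (empty denominator); reporting NaN", RuntimeWarning
        )
        return math.nan
    return numerator / denominator


def score_predictions(
    traces: Sequence[DecisionTrace],
    truth: Sequence[Label] | None = None,
) -> EvaluationResult:
    """Confusion-matrix metrics plus question-count summaries for traces.

    ``truth`` defaults to the labels stored on the traces; when given it
    must supply one label per trace.
    """
    traces = list(traces)
    if not traces:
        raise ValidationError("no traces to score")
    if truth is None:
        truth = [t.true_label for t in traces]
        if any(label is None for label in truth):
            raise ValidationError("traces carry no true labels; pass `truth`")
    if len(truth) != len(traces):
        raise ValidationError("need exactly one truth label per trace")
    tp = fp = tn = fn = 0
    histogram = {q: 0 for q in range(1, N_ITEMS + 1)}
    total_questions = 0
    for trace, label in zip(traces, truth):
        positive = trace.predicted is Label.DEPRESSED
        actual = label is Label.DEPRESSED
        if positive and actual:
            tp += 1
        elif positive:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
        histogram[trace.stop_question] += 1
        total_questions += trace.stop_question
    confusion = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    sensitivity = _rate(tp, tp + fn, "sensitivity")
    specificity = _rate(tn, tn + fp, "specificity")
    accuracy = (tp + tn) / confusion.n
    return EvaluationResult(
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        youden=sensitivity + specificity - 1.0,
        avg_questions=total_questions / len(traces),
        stop_histogram=histogram,
    )


def phq9_classify(record: RespondentRecord) -> Label:
    """Full-length rule: positive iff the 9-item total is >= 10."""
    return Label.DEPRESSED if record.total >= DEPRESSION_CUTOFF else Label.NON_DEPRESSED


def phq_dep4_classify(record: RespondentRecord, cutoff: int = PHQ_DEP4_CUTOFF) -> Label:
    """Four-item short form: positive iff phq1+phq2+phq6+phq8 >= cutoff."""
    subscore = sum(record.response(q) for q in PHQ_DEP4_ITEMS)
    return Label.DEPRESSED if subscore >= cutoff else Label.NON_DEPRESSED


def phq2_score(record: RespondentRecord) -> int:
    """Two-item subscore phq1+phq2, in 0..6."""
    return sum(record.response(q) for q in PHQ2_ITEMS)


def phq2_classify(record: RespondentRecord, cutoff: int = PHQ2_CUTOFF) -> Label:
    """Two-item short form: positive iff phq1+phq2 >= cutoff (default 3)."""
    return Label.DEPRESSED if phq2_score(record) >= cutoff else Label.NON_DEPRESSED


_BASELINES = {
    "phq9": (phq9_classify, N_ITEMS),
    "phqdep4": (phq_dep4_classify, len(PHQ_DEP4_ITEMS)),
    "phq2": (phq2_classify, len(PHQ2_ITEMS)),
}


def evaluate_baseline(dataset: PhqDataset, model: str) -> EvaluationResult:
    """Evaluate a fixed-length baseline over a dataset.

    ``model`` is one of ``phq9``, ``phqdep4``, ``phq2``.  Question counts are
    constant (9, 4, 2); ground truth is the full-total >= 10 rule, so the
    PHQ-9 baseline is perfect by construction.
    """
    if model not in _BASELINES:
        raise ValidationError(f"unknown baseline {model!r}; choose from {sorted(_BASELINES)}")
    if len(dataset) == 0:
        raise ValidationError("cannot evaluate on an empty dataset")
    classify, n_questions = _BASELINES[model]
    tp = fp = tn = fn = 0
    for record in dataset:
        positive = classify(record) is Label.DEPRESSED
        actual = record.label is Label.DEPRESSED
        if positive and actual:
            tp += 1
        elif positive:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    confusion = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    sensitivity = _rate(tp, tp + fn, "sensitivity")
    specificity = _rate(tn, tn + fp, "specificity")
    histogram = {q: 0 for q in range(1, N_ITEMS + 1)}
    histogram[n_questions] = len(dataset)
    return EvaluationResult(
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=(tp + tn) / confusion.n,
        youden=sensitivity + specificity - 1.0,
        avg_questions=float(n_questions),
        stop_histogram=histogram,
    )
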