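"""Per-question lower/upper classification thresholds.

The lower threshold TL for the next item is the smallest response level r
whose joint left tail P(depressed, next response <= r | history) exceeds the
loss parameter λ; the upper threshold TU is the largest r whose joint right
tail P(non-depressed, next response >= r | history) exceeds λ.  Both
probabilities condition on the respondents whose answers so far match the
current respondent's history exactly.  For the first item the same rules are
applied unconditionally.  When no historical record shares the history, the
K nearest records by Euclidean distance over the answered items supply the
threshold instead: the non-depressed group for TL (their next answer is a
safe level to classify non-depressed at) and the depressed group for TU.

All probabilities are exact ratios of integer counts; comparisons against λ
are carried out in integer arithmetic so results are independent of float
rounding.

A threshold can be UNDEFINED (no level qualifies and the degenerate
all-one-group branch does not apply); the sequential engine then simply
continues to the next question.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .core import (
    History,
    Label,
    PhqDataset,
    RespondentRecord,
    ValidationError,
    validate_history,
    validate_response,
)

LAMBDA_MIN, LAMBDA_MAX = 0.01, 0.1


class EstimationError(RuntimeError):
    """No data available to estimate a threshold (empty history match and
    empty KNN reference group)."""


class HistoryUnseenError(EstimationError):
    """The conditioning history matches no record; the caller must fall back
    to the KNN estimate."""


@dataclass(frozen=True)
class ThresholdValue:
    """A per-question threshold level in {0,1,2,3}, or UNDEFINED (None).

    ``source`` records provenance: ``conditional`` (exact-match tail
    probabilities), ``knn`` (nearest-neighbour fallback) or ``first_item``.
    """

    value: int | None
    source: Literal["conditional", "knn", "first_item"]

    @property
    def is_defined(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        return "UNDEFINED" if self.value is None else str(self.value)


class JointTailProbability(NamedTuple):
    """An exact joint tail probability P(group, next resp in tail | history)."""

    value: Fraction
    tail: Literal["left", "right"]
    group: Literal["depressed", "non-depressed"]


def _check_lambda(lam: float) -> float:
    if not (0.0 < lam < 1.0):
        raise ValidationError(f"loss parameter λ must lie in (0, 1), got {lam}")
    return float(lam)


def _exceeds(count: int, n: int, lam: float) -> bool:
    """Exact test of count/n > λ using λ's binary integer ratio."""
    num, den = float(lam).as_integer_ratio()
    return int(count) * den > num * int(n)


def matching_subset(dataset: PhqDataset, history: Sequence[int]) -> tuple[RespondentRecord, ...]:
    """Records whose first len(history) answers equal ``history`` exactly.

    The empty history matches every record.  Input order is preserved.
    """
    history = validate_history(history)
    i = len(history)
    return tuple(rec for rec in dataset if rec.responses[:i] == history)


def left_tail_prob(
    dataset: PhqDataset, history: Sequence[int], r: int
) -> JointTailProbability:
    """P(depressed, next response <= r | history), an exact Fraction."""
    history = validate_history(history)
    r = validate_response(r)
    match = matching_subset(dataset, history)
    if not match:
        raise HistoryUnseenError(f"no record matches history {history}")
    i = len(history)
    hits = sum(
        1 for rec in match if rec.label is Label.DEPRESSED and rec.responses[i] <= r
    )
    return JointTailProbability(Fraction(hits, len(match)), "left", "depressed")


def right_tail_prob(
    dataset: PhqDataset, history: Sequence[int], r: int
) -> JointTailProbability:
    """P(non-depressed, next response >= r | history), an exact Fraction."""
    history = validate_history(history)
    r = validate_response(r)
    match = matching_subset(dataset, history)
    if not match:
        raise HistoryUnseenError(f"no record matches history {history}")
    i = len(history)
    hits = sum(
        1 for rec in match if rec.label is Label.NON_DEPRESSED and rec.responses[i] >= r
    )
    return JointTailProbability(Fraction(hits, len(match)), "right", "non-depressed")


def _lower_from_counts(
    dep_counts: Sequence[int], n: int, lam: float, source: str
) -> ThresholdValue:
    """TL from per-level depressed counts of the next item among n matches."""
    cum = 0
    for r in range(4):
        cum += int(dep_counts[r])
        if _exceeds(cum, n, lam):
            return ThresholdValue(r, source)  # type: ignore[arg-type]
    # no level qualified; cum is now the depressed count in the match
    if cum == 0:
        return ThresholdValue(3, source)  # type: ignore[arg-type]
    return ThresholdValue(None, source)  # type: ignore[arg-type]


def _upper_from_counts(
    non_counts: Sequence[int], n: int, lam: float, source: str
) -> ThresholdValue:
    """TU from per-level non-depressed counts of the next item."""
    cum = 0
    for r in range(3, -1, -1):
        cum += int(non_counts[r])
        if _exceeds(cum, n, lam):
            return ThresholdValue(r, source)  # type: ignore[arg-type]
    if cum == 0:
        return ThresholdValue(0, source)  # type: ignore[arg-type]
    return ThresholdValue(None, source)  # type: ignore[arg-type]


def _next_item_counts(
    match: Sequence[RespondentRecord], item_index: int
) -> tuple[list[int], list[int]]:
    """Counts per response level of item ``item_index`` (0-based), split by label."""
    dep = [0, 0, 0, 0]
    non = [0, 0, 0, 0]
    for rec in match:
        v = rec.responses[item_index]
        if rec.label is Label.DEPRESSED:
            dep[v] += 1
        else:
            non[v] += 1
    return dep, non


def lower_threshold_first(dataset: PhqDataset, lam: float) -> ThresholdValue:
    """TL for phq1: min r with P(depressed, phq1 <= r) > λ.

    Returns 3 when the dataset has no depressed record, UNDEFINED when no
    level qualifies despite depressed records being present.
    """
    _check_lambda(lam)
    if len(dataset) == 0:
        raise ValidationError("cannot estimate thresholds from an empty dataset")
    dep, _ = _next_item_counts(dataset.records, 0)
    return _lower_from_counts(dep, len(dataset), lam, "first_item")


def upper_threshold_first(dataset: PhqDataset, lam: float) -> ThresholdValue:
    """TU for phq1: max r with P(non-depressed, phq1 >= r) > λ."""
    _check_lambda(lam)
    if len(dataset) == 0:
        raise ValidationError("cannot estimate thresholds from an empty dataset")
    _, non = _next_item_counts(dataset.records, 0)
    return _upper_from_counts(non, len(dataset), lam, "first_item")


def knn_threshold(
    group: Sequence[RespondentRecord],
    history: Sequence[int],
    k: int,
    direction: Literal["lower", "upper"],
) -> ThresholdValue:
    """Nearest-neighbour threshold for the next item.

    Orders ``group`` by (Euclidean distance over the first len(history)
    items, input order), takes the first ``k`` members, and returns the
    minimum (``direction="lower"``) or maximum (``"upper"``) of their
    responses to the next item.  The stable tie-break makes the result a
    deterministic function of the group's input order.
    """
    history = validate_history(history)
    if len(history) < 1:
        raise ValidationError("KNN fallback requires at least one answered item")
    group = tuple(group)
    if not group:
        raise EstimationError("KNN reference group is empty")
    if not (1 <= k <= len(group)):
        raise ValidationError(f"K must lie in 1..{len(group)} (group size), got {k}")
    i = len(history)
    h = np.asarray(history, dtype=np.int16)
    mat = np.array([rec.responses[:i] for rec in group], dtype=np.int16)
    sq_dist = ((mat - h) ** 2).sum(axis=1)
    order = np.argsort(sq_dist, kind="stable")
    neighbour_next = [group[j].responses[i] for j in order[:k]]
    value = min(neighbour_next) if direction == "lower" else max(neighbour_next)
    return ThresholdValue(int(value), "knn")


def lower_threshold_next(
    dataset: PhqDataset, history: Sequence[int], lam: float, k: int
) -> ThresholdValue:
    """TL for the item after a non-empty history.

    Exact-match path: min r with left tail > λ; 3 when no matching record is
    depressed; UNDEFINED when no level qualifies but depressed matches exist.
    When the history matches nothing, delegates to the KNN fallback over the
    non-depressed group.
    """
    _check_lambda(lam)
    history = validate_history(history)
    if len(history) < 1:
        raise ValidationError("use lower_threshold_first for the first item")
    match = matching_subset(dataset, history)
    if match:
        dep, _ = _next_item_counts(match, len(history))
        return _lower_from_counts(dep, len(match), lam, "conditional")
    return knn_threshold(dataset.non_depressed(), history, k, "lower")


def upper_threshold_next(
    dataset: PhqDataset, history: Sequence[int], lam: float, k: int
) -> ThresholdValue:
    """TU mirror of :func:`lower_threshold_next` (right tails over the
    non-depressed matches; KNN fallback over the depressed group)."""
    _check_lambda(lam)
    history = validate_history(history)
    if len(history) < 1:
        raise ValidationError("use upper_threshold_first for the first item")
    match = matching_subset(dataset, history)
    if match:
        _, non = _next_item_counts(match, len(history))
        return _upper_from_counts(non, len(match), lam, "conditional")
    return knn_threshold(dataset.depressed(), history, k, "upper")


def threshold_schedule(
    dataset: PhqDataset, history: Sequence[int], lam: float, k: int
) -> tuple[ThresholdValue, ThresholdValue]:
    """(TL, TU) for the next question given the answers so far.

    Dispatches to the first-item rules for an empty history, otherwise to
    the conditional rules with KNN fallback.
    """
    history = validate_history(history)
    if len(history) == 0:
        return lower_threshold_first(dataset, lam), upper_threshold_first(dataset, lam)
    return (
        lower_threshold_next(dataset, history, lam, k),
        upper_threshold_next(dataset, history, lam, k),
    )


class LeaveOneOutThresholdProvider:
    """Vectorized threshold estimation with each respondent held out.

    Next-item response counts conditioned on each history are computed once
    over the full dataset (a single vectorized prefix scan per distinct
    history) and cached; the held-out respondent's own contribution is then
    subtracted, which is exactly equivalent to recounting over the dataset
    minus that record.  The KNN fallback runs on the label group with the
    held-out row removed.
    """

    def __init__(self, dataset: PhqDataset, lam: float, k: int):
        if len(dataset) < 2:
            raise ValidationError("leave-one-out needs at least 2 records")
        self.dataset = dataset
        self.lam = _check_lambda(lam)
        self.k = int(k)
        self._R = dataset.response_matrix
        self._dep = dataset.depressed_mask
        self._dep_idx = np.flatnonzero(self._dep)
        self._non_idx = np.flatnonzero(~self._dep)
        # history -> (dep_counts[4], non_counts[4]) over the FULL dataset
        self._cache: dict[History, tuple[np.ndarray, np.ndarray]] = {}

    def _counts(self, history: History) -> tuple[np.ndarray, np.ndarray]:
        cached = self._cache.get(history)
        if cached is not None:
            return cached
        i = len(history)
        if i == 0:
            mask = np.ones(len(self.dataset), dtype=bool)
        else:
            mask = (self._R[:, :i] == np.asarray(history, dtype=np.int8)).all(axis=1)
        nxt = self._R[mask, i]
        lab = self._dep[mask]
        dep_counts = np.bincount(nxt[lab], minlength=4)
        non_counts = np.bincount(nxt[~lab], minlength=4)
        self._cache[history] = (dep_counts, non_counts)
        return dep_counts, non_counts

    def _knn(self, holdout: int, history: History, direction: str) -> ThresholdValue:
        group = self._non_idx if direction == "lower" else self._dep_idx
        group = group[group != holdout]
        if group.size == 0:
            raise EstimationError(
                "history unseen and the KNN reference group is empty"
            )
        if self.k > group.size:
            raise ValidationError(
                f"K={self.k} exceeds the KNN reference group size {group.size}"
            )
        i = len(history)
        h = np.asarray(history, dtype=np.int16)
        sq_dist = ((self._R[group, :i].astype(np.int16) - h) ** 2).sum(axis=1)
        order = np.argsort(sq_dist, kind="stable")  # ties: ascending row index
        vals = self._R[group[order[: self.k]], i]
        value = int(vals.min() if direction == "lower" else vals.max())
        return ThresholdValue(value, "knn")

    def thresholds_for(
        self, holdout: int, history: Sequence[int]
    ) -> tuple[ThresholdValue, ThresholdValue]:
        """(TL, TU) for record ``holdout`` (row index) given its history."""
        history = tuple(int(x) for x in history)
        i = len(history)
        dep_counts, non_counts = self._counts(history)
        # remove the held-out record, which necessarily matches its own prefix
        dep_counts = dep_counts.copy()
        non_counts = non_counts.copy()
        own_next = int(self._R[holdout, i])
        if self._dep[holdout]:
            dep_counts[own_next] -= 1
        else:
            non_counts[own_next] -= 1
        n = int(dep_counts.sum() + non_counts.sum())
        if i == 0:
            return (
                _lower_from_counts(dep_counts, n, self.lam, "first_item"),
                _upper_from_counts(non_counts, n, self.lam, "first_item"),
            )
        if n == 0:
            return self._knn(holdout, history, "lower"), self._knn(
                holdout, history, "upper"
            )
        return (
            _lower_from_counts(dep_counts, n, self.lam, "conditional"),
            _upper_from_counts(non_counts, n, self.lam, "conditional"),
        )


class DatasetThresholdProvider:
    """Threshold provider over a fixed historical dataset (no hold-out).

    Callable with a history; used to trace a new respondent against an
    existing dataset.
    """

    def __init__(self, dataset: PhqDataset, lam: float, k: int):
        self.dataset = dataset
        self.lam = _check_lambda(lam)
        self.k = int(k)

    def __call__(self, history: Sequence[int]) -> tuple[ThresholdValue, ThresholdValue]:
        return threshold_schedule(self.dataset, history, self.lam, self.k)
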