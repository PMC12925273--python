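"""Core domain types for PHQ-9 screening data.

The PHQ-9 is a nine-item depression questionnaire; each item is answered on
an ordinal 0-3 scale, the total score ranges 0-27, and a total of 10 or more
is the conventional cutoff for probable major depression.  These types are
shared by every other module: a validated respondent record, a dataset with
fast array views, and the ordered response history that conditions all
threshold estimates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

N_ITEMS = 9
VALID_RESPONSES = (0, 1, 2, 3)
MAX_TOTAL = N_ITEMS * max(VALID_RESPONSES)
DEPRESSION_CUTOFF = 10

#: A response history: the ordered answers to the first ``i`` items,
#: 0 <= i <= 8.  The empty tuple is the pre-phq1 state.
History = tuple[int, ...]


class ValidationError(ValueError):
    """Raised when a response, record or history violates the PHQ-9 domain."""


class Label(enum.Enum):
    """Binary ground-truth / predicted class (positive class = depressed)."""

    NON_DEPRESSED = "non-depressed"
    DEPRESSED = "depressed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def validate_response(value: int, question: int | None = None) -> int:
    """Check that ``value`` is a valid ordinal item response (0..3).

    ``question`` is the 1-based item number, used only for the error message.
    """
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ValidationError(
            f"item response must be an integer in {VALID_RESPONSES}, got {value!r}"
            + (f" at phq{question}" if question else "")
        )
    if not (0 <= int(value) <= 3):
        where = f" at phq{question}" if question else ""
        raise ValidationError(f"item response {value!r}{where} outside {VALID_RESPONSES}")
    return int(value)


def total_score(responses: Sequence[int]) -> int:
    """Sum a complete 9-item response vector (result in [0, 27]).

    Raises :class:`ValidationError` naming the offending 1-based position if
    the vector is incomplete or contains an out-of-range value.
    """
    responses = tuple(responses)
    if len(responses) != N_ITEMS:
        raise ValidationError(
            f"expected {N_ITEMS} responses (phq1..phq9), got {len(responses)}"
        )
    return sum(validate_response(r, question=q) for q, r in enumerate(responses, start=1))


def label_record(total: int) -> Label:
    """Ground-truth labelling rule: depressed iff total score >= 10."""
    if not (0 <= total <= MAX_TOTAL):
        raise ValidationError(f"total score {total!r} outside [0, {MAX_TOTAL}]")
    return Label.DEPRESSED if total >= DEPRESSION_CUTOFF else Label.NON_DEPRESSED


def validate_history(history: Sequence[int]) -> History:
    """Validate a response history (answers to the first i items, i <= 8)."""
    history = tuple(history)
    if len(history) >= N_ITEMS:
        raise ValidationError(
            f"a history covers at most {N_ITEMS - 1} items, got {len(history)}"
        )
    return tuple(validate_response(r, question=q) for q, r in enumerate(history, start=1))


@dataclass(frozen=True)
class RespondentRecord:
    """One complete 9-item response vector with derived total and label.

    Item positions are 1-based in the public API (``responses[0]`` is phq1).
    """

    id: object
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        total_score(self.responses)  # validates length and range

    @property
    def total(self) -> int:
        return sum(self.responses)

    @property
    def label(self) -> Label:
        return label_record(self.total)

    def response(self, question: int) -> int:
        """Answer to the 1-based item number ``question``."""
        if not (1 <= question <= N_ITEMS):
            raise ValidationError(f"question number {question} outside 1..{N_ITEMS}")
        return self.responses[question - 1]

    def history(self, length: int) -> History:
        """The first ``length`` answers, as a conditioning history."""
        return validate_history(self.responses[:length])


class PhqDataset:
    """A collection of complete respondent records with cached array views.

    The record order is preserved everywhere (it is the deterministic
    tie-break for the KNN fallback), and the depressed / non-depressed
    partition is derived, never stored.
    """

    def __init__(self, records: Iterable[RespondentRecord]):
        self.records: tuple[RespondentRecord, ...] = tuple(records)
        self._matrix: np.ndarray | None = None
        self._depressed_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RespondentRecord]:
        return iter(self.records)

    def __getitem__(self, index: int) -> RespondentRecord:
        return self.records[index]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhqDataset):
            return NotImplemented
        return [(r.id, r.responses) for r in self.records] == [
            (r.id, r.responses) for r in other.records
        ]

    @property
    def response_matrix(self) -> np.ndarray:
        """(n, 9) int8 array of responses, rows in input order."""
        if self._matrix is None:
            self._matrix = np.array(
                [rec.responses for rec in self.records], dtype=np.int8
            ).reshape(len(self.records), N_ITEMS)
        return self._matrix

    @property
    def depressed_mask(self) -> np.ndarray:
        """(n,) boolean array, True where total >= 10."""
        if self._depressed_mask is None:
            self._depressed_mask = (
                self.response_matrix.sum(axis=1, dtype=np.int32) >= DEPRESSION_CUTOFF
            )
        return self._depressed_mask

    def depressed(self) -> tuple[RespondentRecord, ...]:
        return tuple(r for r in self.records if r.label is Label.DEPRESSED)

    def non_depressed(self) -> tuple[RespondentRecord, ...]:
        return tuple(r for r in self.records if r.label is Label.NON_DEPRESSED)

    def prevalence(self) -> float:
        """Fraction of records with total >= 10."""
        if not self.records:
            raise ValidationError("prevalence of an empty dataset is undefined")
        return float(self.depressed_mask.mean())


def split_by_label(
    dataset: PhqDataset,
) -> tuple[tuple[RespondentRecord, ...], tuple[RespondentRecord, ...]]:
    """Partition into (depressed, non-depressed), preserving input order."""
    if len(dataset) == 0:
        raise ValidationError("cannot split an empty dataset")
    return dataset.depressed(), dataset.non_depressed()
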