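"""Sequential decision engine: administer items, compare cumulative score to
cumulative thresholds, stop early and classify.

Items are presented in their original order.  After each answer the running
total is compared first to the running sum of lower thresholds (at or below
it: stop, non-depressed), then to the running sum of upper thresholds (above
it: stop, depressed).  Two gates modulate the checks: the lower/upper check
is suppressed for the first ``start_neg`` / ``start_pos`` questions, and a
respondent whose count of zero answers strictly exceeds ``zero_count`` is
classified non-depressed.  Whoever answers all nine items without a stop is
classified depressed by default.

An UNDEFINED per-question threshold must never trigger a stop at that
question; it contributes -1 to the cumulative lower threshold (unreachable,
since scores are non-negative and earlier checks already failed) and +4 to
the cumulative upper threshold (one above the per-item maximum).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core import (
    N_ITEMS,
    History,
    Label,
    PhqDataset,
    ValidationError,
    validate_response,
)
from .thresholds import LeaveOneOutThresholdProvider, ThresholdValue

#: Contribution of an UNDEFINED threshold to the cumulative sums.
UNDEFINED_TL_CONTRIBUTION = -1
UNDEFINED_TU_CONTRIBUTION = 4

ThresholdProvider = Callable[[History], tuple[ThresholdValue, ThresholdValue]]


@dataclass(frozen=True)
class HyperParams:
    """The five tuned parameters of the dynamic questionnaire.

    zero_count : stop non-depressed once strictly more than this many zero
        answers have been given (0..9; 9 disables the rule).
    start_neg / start_pos : number of initial questions during which the
        lower / upper threshold check is suppressed (0..3; 0 means the check
        is active from phq1).  The reported optimum — negative stops from
        phq2, positive stops from phq3 — is start_neg=1, start_pos=2.
    k : neighbour count for the KNN fallback (1..4).
    lam : loss parameter λ, the joint tail probability tolerated before a
        threshold level is selected (0.01..0.1).

    Defaults are the configuration found optimal on both study populations.
    """

    zero_count: int = 6
    start_neg: int = 1
    start_pos: int = 2
    k: int = 1
    lam: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.zero_count <= 9):
            raise ValidationError(f"zero_count outside 0..9: {self.zero_count}")
        if not (0 <= self.start_neg <= 3):
            raise ValidationError(f"start_neg outside 0..3: {self.start_neg}")
        if not (0 <= self.start_pos <= 3):
            raise ValidationError(f"start_pos outside 0..3: {self.start_pos}")
        if not (1 <= self.k <= 4):
            raise ValidationError(f"k outside 1..4: {self.k}")
        if not (0.01 <= self.lam <= 0.1):
            raise ValidationError(f"λ outside [0.01, 0.1]: {self.lam}")


class StopReason(enum.Enum):
    LOWER_THRESHOLD = "lower_threshold"
    UPPER_THRESHOLD = "upper_threshold"
    ZERO_COUNT = "zero_count"
    EXHAUSTED_DEFAULT_DEPRESSED = "exhausted_default_depressed"


@dataclass(frozen=True)
class TraceEntry:
    """State after one administered question."""

    question: int  # 1-based
    answer: int
    cum_score: int
    tl: ThresholdValue
    tu: ThresholdValue
    cum_tl: int
    cum_tu: int
    zero_count: int
    lower_check_active: bool
    upper_check_active: bool


@dataclass(frozen=True)
class DecisionTrace:
    """Full audit trail of one adaptive administration."""

    respondent_id: object
    entries: tuple[TraceEntry, ...]
    stop_question: int
    predicted: Label
    reason: StopReason
    true_label: Label | None = None

    @property
    def questions_asked(self) -> int:
        return self.stop_question


def administer(
    answers: Sequence[int],
    threshold_provider: ThresholdProvider,
    params: HyperParams,
    respondent_id: object = None,
    true_label: Label | None = None,
) -> DecisionTrace:
    """Run the sequential procedure over ``answers`` (up to 9 items).

    ``threshold_provider`` maps the history of answers given so far to the
    next question's (TL, TU).  Answers must cover every question actually
    reached; running out of answers before a stop is an input error.
    """
    answers = tuple(answers)
    if len(answers) > N_ITEMS:
        raise ValidationError(f"at most {N_ITEMS} answers, got {len(answers)}")
    entries: list[TraceEntry] = []
    cum_score = 0
    cum_tl = 0
    cum_tu = 0
    zeros = 0
    for q in range(1, N_ITEMS + 1):
        if q > len(answers):
            raise ValidationError(
                f"no answer supplied for phq{q}, which was reached without a stop"
            )
        history: History = answers[: q - 1]
        tl, tu = threshold_provider(history)
        answer = validate_response(answers[q - 1], question=q)
        cum_score += answer
        zeros += answer == 0
        cum_tl += tl.value if tl.is_defined else UNDEFINED_TL_CONTRIBUTION
        cum_tu += tu.value if tu.is_defined else UNDEFINED_TU_CONTRIBUTION
        lower_active = q > params.start_neg
        upper_active = q > params.start_pos
        entries.append(
            TraceEntry(
                question=q,
                answer=answer,
                cum_score=cum_score,
                tl=tl,
                tu=tu,
                cum_tl=cum_tl,
                cum_tu=cum_tu,
                zero_count=zeros,
                lower_check_active=lower_active,
                upper_check_active=upper_active,
            )
        )
        if lower_active and cum_score <= cum_tl:
            return DecisionTrace(
                respondent_id, tuple(entries), q, Label.NON_DEPRESSED,
                StopReason.LOWER_THRESHOLD, true_label,
            )
        if upper_active and cum_score > cum_tu:
            return DecisionTrace(
                respondent_id, tuple(entries), q, Label.DEPRESSED,
                StopReason.UPPER_THRESHOLD, true_label,
            )
        if zeros > params.zero_count:
            return DecisionTrace(
                respondent_id, tuple(entries), q, Label.NON_DEPRESSED,
                StopReason.ZERO_COUNT, true_label,
            )
    # all nine questions answered without a stop: default positive
    return DecisionTrace(
        respondent_id, tuple(entries), N_ITEMS, Label.DEPRESSED,
        StopReason.EXHAUSTED_DEFAULT_DEPRESSED, true_label,
    )


def loo_predict(dataset: PhqDataset, params: HyperParams) -> list[DecisionTrace]:
    """Leave-one-out prediction over a complete-record dataset.

    Each respondent's thresholds are estimated from the dataset minus that
    respondent; their stored answers drive the sequential procedure.  The
    true label always comes from the full stored 9-item total, even when the
    engine stops early.  Traces are returned in input order.
    """
    if len(dataset) < 2:
        raise ValidationError("leave-one-out needs at least 2 records")
    provider = LeaveOneOutThresholdProvider(dataset, params.lam, params.k)
    traces: list[DecisionTrace] = []
    for j, record in enumerate(dataset):
        traces.append(
            administer(
                record.responses,
                lambda h, _j=j: provider.thresholds_for(_j, h),
                params,
                respondent_id=record.id,
                true_label=record.label,
            )
        )
    return traces
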