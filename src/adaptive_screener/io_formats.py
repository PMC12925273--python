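"""Reading and writing questionnaire tables, traces and metrics.

Datasets are plain CSV with a header.  Two dialects ship as presets: the
generic ``phq1..phq9`` layout and the NHANES depression-screener layout
(``DPQ010..DPQ090`` with ``SEQN`` ids), where the codes 7 (refused) and
9 (don't know) are excluded.  Exclusion is row-wise — any offending cell
drops the whole record — and every read returns an exclusion report whose
counts conserve the input row count exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import PhqDataset, RespondentRecord, ValidationError
from .engine import DecisionTrace
from .evaluation import EvaluationResult


class FormatError(ValueError):
    """The file does not conform to the requested CSV dialect."""


@dataclass(frozen=True)
class CsvDialect:
    """Column layout and exclusion codes of a questionnaire CSV."""

    column_names: tuple[str, ...]
    id_column: str | None = None
    invalid_codes: frozenset[int] = frozenset()
    treat_missing_as_exclusion: bool = True

    def __post_init__(self) -> None:
        if len(self.column_names) != 9:
            raise ValidationError("a dialect needs exactly 9 questionnaire columns")
        object.__setattr__(self, "invalid_codes", frozenset(self.invalid_codes))


GENERIC = CsvDialect(
    column_names=tuple(f"phq{q}" for q in range(1, 10)),
    id_column="id",
)

#: NHANES DPQ_* depression-screener layout; 7 = refused, 9 = don't know.
NHANES = CsvDialect(
    column_names=tuple(f"DPQ{q:03d}" for q in range(10, 100, 10)),
    id_column="SEQN",
    invalid_codes=frozenset({7, 9}),
)

DIALECTS = {"generic": GENERIC, "nhanes": NHANES}


@dataclass
class ExclusionReport:
    """Per-reason counts of rows dropped during a read."""

    rows_read: int = 0
    rows_kept: int = 0
    missing: int = 0
    unparseable: int = 0
    invalid_code: int = 0
    out_of_range: int = 0

    @property
    def rows_excluded(self) -> int:
        return self.missing + self.unparseable + self.invalid_code + self.out_of_range

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "missing": self.missing,
            "unparseable": self.unparseable,
            "invalid_code": self.invalid_code,
            "out_of_range": self.out_of_range,
        }


def _parse_cell(cell) -> int | None:
    """Integer value of a CSV cell, or None when not an integral number."""
    if isinstance(cell, float) and math.isnan(cell):
        return None
    try:
        value = float(cell)
    except (TypeError, ValueError):
        return None
    if not value.is_integer():
        return None
    return int(value)


def read_dataset(
    path: str | Path, dialect: CsvDialect = GENERIC
) -> tuple[PhqDataset, ExclusionReport]:
    """Read a questionnaire CSV, returning complete in-range records only.

    Rows are classified per record, first offending reason wins, checked in
    the order: missing cell, unparseable cell, excluded code, out of range.
    ``treat_missing_as_exclusion=False`` makes a missing cell a fatal
    :class:`FormatError` instead of an exclusion.
    """
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    absent = [c for c in dialect.column_names if c not in frame.columns]
    if absent:
        raise FormatError(f"missing questionnaire columns: {absent}")
    has_ids = dialect.id_column is not None and dialect.id_column in frame.columns
    report = ExclusionReport(rows_read=len(frame))
    records: list[RespondentRecord] = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        cells = [row[c] for c in dialect.column_names]
        if any(pd.isna(c) or (isinstance(c, str) and not c.strip()) for c in cells):
            if not dialect.treat_missing_as_exclusion:
                raise FormatError(f"missing value in data row {pos + 1}")
            report.missing += 1
            continue
        values = [_parse_cell(c) for c in cells]
        if any(v is None for v in values):
            report.unparseable += 1
            continue
        if any(v in dialect.invalid_codes for v in values):
            report.invalid_code += 1
            continue
        if any(not (0 <= v <= 3) for v in values):
            report.out_of_range += 1
            continue
        rec_id = row[dialect.id_column] if has_ids else pos
        records.append(RespondentRecord(id=rec_id, responses=tuple(values)))
    report.rows_kept = len(records)
    return PhqDataset(records), report


def write_dataset(
    dataset: PhqDataset, path: str | Path, dialect: CsvDialect = GENERIC
) -> None:
    """Write a dataset in the given dialect (inverse of :func:`read_dataset`)."""
    data: dict[str, list] = {}
    if dialect.id_column is not None:
        data[dialect.id_column] = [rec.id for rec in dataset]
    for j, col in enumerate(dialect.column_names):
        data[col] = [rec.responses[j] for rec in dataset]
    pd.DataFrame(data).to_csv(path, index=False)


def write_traces(traces: Sequence[DecisionTrace], path: str | Path) -> None:
    """One CSV row per respondent with stop point, labels and the running
    cumulative score / lower / upper thresholds per administered question."""
    traces = list(traces)
    if not traces:
        raise ValidationError("no traces to write")
    rows = []
    for trace in traces:
        row: dict = {
            "id": trace.respondent_id,
            "stop_question": trace.stop_question,
            "questions_asked": trace.questions_asked,
            "predicted": trace.predicted.value,
            "true_label": trace.true_label.value if trace.true_label else "",
            "reason": trace.reason.value,
        }
        for entry in trace.entries:
            q = entry.question
            row[f"cum_score_q{q}"] = entry.cum_score
            row[f"cum_tl_q{q}"] = entry.cum_tl
            row[f"cum_tu_q{q}"] = entry.cum_tu
        rows.append(row)
    columns = ["id", "stop_question", "questions_asked", "predicted", "true_label", "reason"]
    for q in range(1, 10):
        columns += [f"cum_score_q{q}", f"cum_tl_q{q}", f"cum_tu_q{q}"]
    pd.DataFrame(rows).reindex(columns=columns).to_csv(path, index=False)


def write_metrics(metrics: EvaluationResult, path: str | Path) -> None:
    """Serialize an evaluation result to JSON (full precision)."""
    with open(path, "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
        fh.write("\n")
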