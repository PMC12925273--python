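"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over record lists with
exact rational arithmetic, deliberately sharing no code with the package's
counting or vectorized paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

from adaptive_screener import Label, PhqDataset, RespondentRecord


def brute_left_tail(dataset: PhqDataset, history: tuple[int, ...], r: int) -> Fraction:
    i = len(history)
    matches = [rec for rec in dataset if tuple(rec.responses[:i]) == tuple(history)]
    if not matches:
        raise ValueError("history unseen")
    hits = 0
    for rec in matches:
        if sum(rec.responses) >= 10 and rec.responses[i] <= r:
            hits += 1
    return Fraction(hits, len(matches))


def brute_right_tail(dataset: PhqDataset, history: tuple[int, ...], r: int) -> Fraction:
    i = len(history)
    matches = [rec for rec in dataset if tuple(rec.responses[:i]) == tuple(history)]
    if not matches:
        raise ValueError("history unseen")
    hits = 0
    for rec in matches:
        if sum(rec.responses) < 10 and rec.responses[i] >= r:
            hits += 1
    return Fraction(hits, len(matches))


def brute_lower_threshold(dataset, history, lam) -> int | None:
    """Literal TL rule via the tail oracle; None encodes UNDEFINED."""
    for r in range(4):
        if brute_left_tail(dataset, history, r) > Fraction(*float(lam).as_integer_ratio()):
            return r
    if brute_left_tail(dataset, history, 3) == 0:
        return 3
    return None


def brute_upper_threshold(dataset, history, lam) -> int | None:
    for r in range(3, -1, -1):
        if brute_right_tail(dataset, history, r) > Fraction(*float(lam).as_integer_ratio()):
            return r
    if brute_right_tail(dataset, history, 0) == 0:
        return 0
    return None


def brute_knn(
    group: list[RespondentRecord], history: tuple[int, ...], k: int, direction: str
) -> int:
    """Exhaustive distance scan with stable (distance, position) ordering."""
    i = len(history)
    scored = []
    for pos, rec in enumerate(group):
        d = math.sqrt(sum((rec.responses[j] - history[j]) ** 2 for j in range(i)))
        scored.append((d, pos, rec.responses[i]))
    scored.sort(key=lambda t: (t[0], t[1]))
    nxt = [v for _, _, v in scored[:k]]
    return min(nxt) if direction == "lower" else max(nxt)
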