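import numpy as np
import pytest

from adaptive_screener import PhqDataset, RespondentRecord

# Six hand-built records spanning both label groups; totals 0,2,9,11,11,12.
TOY_ROWS = {
    "A": (0, 0, 0, 0, 0, 0, 0, 0, 0),
    "B": (1, 0, 1, 0, 0, 0, 0, 0, 0),
    "C": (1, 1, 1, 1, 1, 1, 1, 1, 1),
    "D": (2, 2, 1, 1, 1, 1, 1, 1, 1),
    "E": (3, 3, 2, 1, 1, 1, 0, 0, 0),
    "F": (1, 2, 2, 2, 1, 1, 1, 1, 1),
}


@pytest.fixture
def toy_dataset() -> PhqDataset:
    return PhqDataset(RespondentRecord(k, v) for k, v in TOY_ROWS.items())


def random_dataset(rng: np.random.Generator, n: int | None = None) -> PhqDataset:
    """A small random dataset with both high and low scorers represented."""
    if n is None:
        n = int(rng.integers(2, 51))
    # mixture: mostly low scores, a depressed-leaning tail
    probs_low = np.array([0.55, 0.25, 0.13, 0.07])
    probs_high = np.array([0.10, 0.25, 0.35, 0.30])
    rows = []
    for i in range(n):
        p = probs_high if rng.random() < 0.35 else probs_low
        rows.append(tuple(int(v) for v in rng.choice(4, size=9, p=p)))
    return PhqDataset(RespondentRecord(i, row) for i, row in enumerate(rows))
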