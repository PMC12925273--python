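from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptive_screener import (
    HistoryUnseenError,
    LeaveOneOutThresholdProvider,
    PhqDataset,
    RespondentRecord,
    ValidationError,
    knn_threshold,
    left_tail_prob,
    lower_threshold_first,
    lower_threshold_next,
    matching_subset,
    right_tail_prob,
    threshold_schedule,
    upper_threshold_first,
    upper_threshold_next,
)
from conftest import random_dataset
from oracles import brute_knn, brute_left_tail, brute_right_tail


class TestMatchingSubset:
    def test_exact_prefix_match(self, toy_dataset):
        assert [r.id for r in matching_subset(toy_dataset, (1,))] == ["B", "C", "F"]

    def test_empty_history_matches_all(self, toy_dataset):
        assert len(matching_subset(toy_dataset, ())) == 6

    def test_unseen_history_gives_empty_set(self, toy_dataset):
        assert matching_subset(toy_dataset, (3, 2)) == ()


class TestTailProbabilities:
    @pytest.mark.parametrize(
        "history, r, expected",
        [((1,), 2, Fraction(1, 3)), ((1,), 3, Fraction(1, 3)), ((0,), 1, Fraction(0))],
    )
    def test_left_tail_on_toy(self, toy_dataset, history, r, expected):
        assert left_tail_prob(toy_dataset, history, r).value == expected

    @pytest.mark.parametrize(
        "history, r, expected",
        [((1,), 1, Fraction(1, 3)), ((1,), 0, Fraction(2, 3)), ((1,), 3, Fraction(0))],
    )
    def test_right_tail_on_toy(self, toy_dataset, history, r, expected):
        assert right_tail_prob(toy_dataset, history, r).value == expected

    def test_unseen_history_signals_knn_path(self, toy_dataset):
        with pytest.raises(HistoryUnseenError):
            left_tail_prob(toy_dataset, (3, 2), 1)

    def test_tails_monotone_and_complementary(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ds = random_dataset(rng)
            hist = tuple(int(v) for v in ds[0].responses[: int(rng.integers(0, 4))])
            lefts = [left_tail_prob(ds, hist, r).value for r in range(4)]
            rights = [right_tail_prob(ds, hist, r).value for r in range(4)]
            assert lefts == sorted(lefts)
            assert rights == sorted(rights, reverse=True)
            # left tail at 3 and right tail at 0 partition the matching set
            assert lefts[3] + rights[0] == 1


class TestTailOracleEquivalence:
    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ds = random_dataset(rng)
            rec = ds[int(rng.integers(len(ds)))]
            hist = tuple(int(v) for v in rec.responses[: int(rng.integers(0, 5))])
            for r in range(4):
                assert left_tail_prob(ds, hist, r).value == brute_left_tail(ds, hist, r)
                assert right_tail_prob(ds, hist, r).value == brute_right_tail(ds, hist, r)


class TestFirstItemThresholds:
    def test_toy_values(self, toy_dataset):
        # P(D, phq1<=r) = 0, 1/6, 2/6, 3/6 → first level above 0.4 is r=3
        assert lower_threshold_first(toy_dataset, 0.4).value == 3
        # P(nonD, phq1>=r) = 3/6, 2/6, 0, 0 → highest level above 0.1 is r=1
        assert upper_threshold_first(toy_dataset, 0.1).value == 1

    def test_all_levels_qualify_selects_lowest(self):
        # every left tail exceeds a tiny λ when depressed mass sits at level 0
        ds = PhqDataset(
            [RespondentRecord(0, (0, 3, 3, 3, 3, 0, 0, 0, 0))]
            + [RespondentRecord(i, (0,) * 9) for i in range(1, 4)]
        )
        assert lower_threshold_first(ds, 0.01).value == 0

    def test_degenerate_groups(self):
        no_dep = PhqDataset(RespondentRecord(i, (0,) * 9) for i in range(4))
        assert lower_threshold_first(no_dep, 0.05).value == 3
        all_dep = PhqDataset(RespondentRecord(i, (3,) * 9) for i in range(4))
        assert upper_threshold_first(all_dep, 0.05).value == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            lower_threshold_first(PhqDataset([]), 0.05)


class TestNextItemThresholds:
    def test_conditional_path_on_toy(self, toy_dataset):
        assert lower_threshold_next(toy_dataset, (1,), 0.02, 1).value == 2
        assert upper_threshold_next(toy_dataset, (1,), 0.02, 1).value == 1

    def test_no_depressed_match_returns_three(self, toy_dataset):
        assert lower_threshold_next(toy_dataset, (0,), 0.02, 1).value == 3

    def test_no_nondepressed_match_returns_zero(self, toy_dataset):
        assert upper_threshold_next(toy_dataset, (2, 2), 0.02, 1).value == 0

    def test_undefined_when_no_level_qualifies(self, toy_dataset):
        tl = lower_threshold_next(toy_dataset, (1,), 0.5, 1)
        assert tl.value is None and not tl.is_defined

    def test_unseen_history_falls_back_to_knn(self, toy_dataset):
        tl = lower_threshold_next(toy_dataset, (3, 2), 0.02, 1)
        tu = upper_threshold_next(toy_dataset, (3, 2), 0.02, 1)
        assert (tl.value, tl.source) == (1, "knn")
        # D=(2,2,..) ties E=(3,3,..) at squared distance 1; stable order → D, phq3=1
        assert (tu.value, tu.source) == (1, "knn")


class TestKnnThreshold:
    def test_nearest_nondepressed_neighbour(self, toy_dataset):
        got = knn_threshold(toy_dataset.non_depressed(), (3, 2), 1, "lower")
        assert (got.value, got.source) == (1, "knn")

    def test_zero_distance_identity(self, toy_dataset):
        group = toy_dataset.non_depressed()
        got = knn_threshold(group, tuple(group[1].responses[:3]), 1, "lower")
        assert got.value == group[1].responses[3]

    def test_invalid_k_rejected(self, toy_dataset):
        group = toy_dataset.depressed()
        for bad in (0, len(group) + 1):
            with pytest.raises(ValidationError):
                knn_threshold(group, (1,), bad, "upper")

    def test_permutation_invariant_when_distances_distinct(self):
        rng = np.random.default_rng(3)
        base = [
            RespondentRecord(i, tuple(int(v) for v in rng.integers(0, 4, 9)))
            for i in range(8)
        ]
        history = (3, 0, 3)
        dists = [sum((r.responses[j] - history[j]) ** 2 for j in range(3)) for r in base]
        if len(set(dists)) == len(dists):  # seed chosen so distances are distinct
            ref = knn_threshold(base, history, 2, "lower").value
            perm = [base[i] for i in rng.permutation(len(base))]
            assert knn_threshold(perm, history, 2, "lower").value == ref

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            ds = random_dataset(rng)
            group = ds.non_depressed() if rng.random() < 0.5 else ds.depressed()
            if not group:
                continue
            i = int(rng.integers(1, 6))
            hist = tuple(int(v) for v in rng.integers(0, 4, i))
            k = int(rng.integers(1, min(4, len(group)) + 1))
            for direction in ("lower", "upper"):
                assert (
                    knn_threshold(group, hist, k, direction).value
                    == brute_knn(list(group), hist, k, direction)
                )


class TestSchedule:
    def test_dispatch(self, toy_dataset):
        first = threshold_schedule(toy_dataset, (), 0.02, 1)
        assert (first[0].source, first[1].source) == ("first_item", "first_item")
        cond = threshold_schedule(toy_dataset, (1,), 0.02, 1)
        assert (cond[0].value, cond[1].value) == (2, 1)
        assert {cond[0].source, cond[1].source} == {"conditional"}
        knn = threshold_schedule(toy_dataset, (3, 2), 0.02, 1)
        assert (knn[0].value, knn[1].value) == (1, 1)
        assert {knn[0].source, knn[1].source} == {"knn"}


# Sentinel ordering for monotonicity: UNDEFINED above 3 for TL, below 0 for TU.
def _tl_order(v):
    return 4 if v is None else v


def _tu_order(v):
    return -1 if v is None else v


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000), hist_len=st.integers(1, 4))
def test_lambda_monotonicity(seed, hist_len):
    """Growing λ can only raise TL and lower TU (qualifying sets shrink)."""
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng)
    rec = ds[int(rng.integers(len(ds)))]
    hist = tuple(int(v) for v in rec.responses[:hist_len])
    lams = [0.01 * i for i in range(1, 11)]
    tls = [_tl_order(lower_threshold_next(ds, hist, lam, 1).value) for lam in lams]
    tus = [_tu_order(upper_threshold_next(ds, hist, lam, 1).value) for lam in lams]
    assert tls == sorted(tls)
    assert tus == sorted(tus, reverse=True)


class TestLeaveOneOutProvider:
    def test_agrees_with_simple_path_on_reduced_dataset(self):
        """Fast cached hold-out counts must equal recomputing the simple
        functions over the dataset with the record physically removed."""
        rng = np.random.default_rng(41)
        for _ in range(15):
            ds = random_dataset(rng)
            provider = LeaveOneOutThresholdProvider(ds, 0.02, 1)
            j = int(rng.integers(len(ds)))
            reduced = PhqDataset(r for i, r in enumerate(ds) if i != j)
            for i in range(0, 5):
                hist = tuple(int(v) for v in ds[j].responses[:i])
                got = provider.thresholds_for(j, hist)
                want = threshold_schedule(reduced, hist, 0.02, 1)
                assert (got[0].value, got[1].value) == (want[0].value, want[1].value)
                assert (got[0].source, got[1].source) == (want[0].source, want[1].source)

    def test_duplicate_records_keep_each_other_visible(self):
        row = (2, 2, 1, 1, 1, 1, 1, 1, 1)
        ds = PhqDataset(
            [RespondentRecord(0, row), RespondentRecord(1, row)]
            + [RespondentRecord(2, (0,) * 9)]
        )
        provider = LeaveOneOutThresholdProvider(ds, 0.02, 1)
        # removing one copy leaves the twin matching the history exactly
        tl, tu = provider.thresholds_for(0, (2, 2))
        assert tl.source == "conditional" and tu.source == "conditional"
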