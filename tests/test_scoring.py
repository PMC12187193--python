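"""Percentile rank-scoring: cutoffs, bands, totals, classes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroscope import (
    TABLE_CUTOFFS,
    TABLE_RANGES,
    classify,
    cutoffs_empirical,
    cutoffs_from_range,
    rank_score,
    score_band_thresholds,
    score_individual,
    temp_bucket,
    total_score,
)
from aeroscope.scoring import PercentileCutoffs, enumerate_total_scores


class TestCutoffs:
    @pytest.mark.parametrize(
        "bucket,expected",
        [
            ("16", (1.75, 2.6, 3.45)),
            ("10", (2.59, 3.68, 4.77)),
            ("high", (3.35, 4.2, 5.05)),
        ],
    )
    def test_packaged_rows_from_their_ranges(self, bucket, expected):
        """Each packaged row is the even interpolation of its (min, max)."""
        lo, hi = TABLE_RANGES[bucket]
        got = cutoffs_from_range(lo, hi, bucket=bucket).as_tuple()
        assert got == pytest.approx(expected, abs=1e-12)
        assert TABLE_CUTOFFS[bucket].as_tuple() == expected

    def test_packaged_rows_serialize_to_printed_values(self):
        printed = {
            "16": ("1.75", "2.6", "3.45"),
            "10": ("2.59", "3.68", "4.77"),
            "high": ("3.35", "4.2", "5.05"),
        }
        for bucket, row in printed.items():
            assert tuple(f"{c:g}" for c in TABLE_CUTOFFS[bucket].as_tuple()) == row

    def test_unit_interval(self):
        assert cutoffs_from_range(0.0, 1.0).as_tuple() == (0.25, 0.5, 0.75)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            cutoffs_from_range(2.0, 2.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        lo=st.floats(min_value=-10, max_value=10),
        span=st.floats(min_value=1e-3, max_value=20),
    )
    def test_range_cutoffs_always_evenly_spaced(self, lo, span):
        c = cutoffs_from_range(lo, lo + span)
        assert (c.c50 - c.c25) == pytest.approx(c.c75 - c.c50, rel=1e-9, abs=1e-12)

    def test_empirical_exact_order_statistics(self):
        assert cutoffs_empirical([1, 2, 3, 4, 5]).as_tuple() == (2.0, 3.0, 4.0)

    def test_empirical_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cutoffs_empirical([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            cutoffs_empirical([1.0, 2.0, 3.0])  # fewer than 4 values

    def test_empirical_large_sample_converges(self):
        vals = np.random.default_rng(1).uniform(0, 1, 100_000)
        got = cutoffs_empirical(vals).as_tuple()
        assert got == pytest.approx((0.25, 0.5, 0.75), abs=0.01)


class TestRankScore:
    @pytest.mark.parametrize(
        "value,bucket,expected",
        [
            (1.5, "16", 1),
            (5.5, "high", 4),
            (2.6, "16", 3),  # exact mid cutoff goes to the higher band
            (-0.4, "10", 1),  # negative scope scores the bottom band
            (3.45, "16", 4),
            (4.76, "10", 3),
        ],
    )
    def test_band_assignment(self, value, bucket, expected):
        assert rank_score(value, TABLE_CUTOFFS[bucket]) == expected

    @settings(derandomize=True, max_examples=80)
    @given(
        a=st.floats(min_value=-5, max_value=10),
        b=st.floats(min_value=-5, max_value=10),
    )
    def test_monotone_in_aerobic_scope(self, a, b):
        cut = TABLE_CUTOFFS["16"]
        lo, hi = sorted((a, b))
        assert rank_score(lo, cut) <= rank_score(hi, cut)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_score(float("nan"), TABLE_CUTOFFS["16"])


class TestTotalsAndClasses:
    @pytest.mark.parametrize(
        "ranks,total",
        [((1, 1, 1), 3), ((4, 4, 4), 12), ((3, 1, 1), 5), ((2, 3, 4), 9)],
    )
    def test_totals(self, ranks, total):
        assert total_score(ranks) == total

    def test_missing_temperature_errors(self):
        with pytest.raises(ValueError):
            total_score((1, 1))
        with pytest.raises(ValueError):
            total_score((1, 1, 5))

    @pytest.mark.parametrize(
        "total,cls",
        [(3, "low"), (5, "low"), (6, "intermediate"), (9, "intermediate"),
         (10, "high"), (12, "high")],
    )
    def test_class_bands(self, total, cls):
        assert classify(total) == cls

    def test_out_of_range_total_errors(self):
        for bad in (2, 13, 7.5):
            with pytest.raises(ValueError):
                classify(bad)

    def test_worked_low_performer_case(self):
        """Intermediate performance only at the optimum (3,1,1) totals 5 and
        still classifies as a low performer."""
        total = total_score((3, 1, 1))
        assert total == 5 and classify(total) == "low"

    def test_bands_partition_achievable_totals(self):
        seen = {t: classify(t) for t in range(3, 13)}
        assert set(seen.values()) == {"low", "intermediate", "high"}
        assert [t for t, c in seen.items() if c == "low"] == [3, 4, 5]
        assert [t for t, c in seen.items() if c == "intermediate"] == [6, 7, 8, 9]
        assert [t for t, c in seen.items() if c == "high"] == [10, 11, 12]

    def test_enumeration_matches_independent_count(self):
        """All 64 rank triples, against an independent brute-force count."""
        result = enumerate_total_scores()
        # independent enumeration with plain loops
        lo = mid = hi = 0
        totals = []
        for a in (1, 2, 3, 4):
            for b in (1, 2, 3, 4):
                for c in (1, 2, 3, 4):
                    s = a + b + c
                    totals.append(s)
                    if s <= 5:
                        lo += 1
                    elif s <= 9:
                        mid += 1
                    else:
                        hi += 1
        assert result["n_triples"] == 64 == len(totals)
        assert result["min_total"] == min(totals) == 3
        assert result["max_total"] == max(totals) == 12
        assert result["class_counts"] == {"low": lo, "intermediate": mid, "high": hi}

    def test_band_thresholds(self):
        t = score_band_thresholds()
        assert t["low_percentile"] == 5.25 and t["low_rounded"] == 5
        assert t["high_percentile"] == 9.75 and t["high_rounded"] == 10
        assert t["midpoint"] == 7.5

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(3, 12), st.integers(3, 12))
    def test_classify_monotone(self, a, b):
        order = {"low": 0, "intermediate": 1, "high": 2}
        lo, hi = sorted((a, b))
        assert order[classify(lo)] <= order[classify(hi)]


class TestBuckets:
    def test_mapping(self):
        assert temp_bucket(16) == "16"
        assert temp_bucket(10) == "10"
        assert temp_bucket(21) == "high" and temp_bucket(24) == "high"
        with pytest.raises(ValueError):
            temp_bucket(30.0)

    def test_21_and_24_share_cutoffs(self):
        """An individual tested at 24 degC is scored against the same pooled
        warm-treatment row as one tested at 21 degC."""
        card21 = score_individual("a", {"16": 3.0, "10": 4.0, "high": 4.5})
        assert rank_score(4.5, TABLE_CUTOFFS[temp_bucket(24.0)]) == card21.score_high

    def test_missing_bucket_errors(self):
        with pytest.raises(ValueError, match="bucket"):
            score_individual("a", {"16": 3.0, "10": 4.0})


def test_cutoffs_invariant_enforced():
    with pytest.raises(ValueError):
        PercentileCutoffs("16", 2.0, 1.0, 3.0)
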