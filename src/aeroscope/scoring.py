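"""Percentile rank-scoring of aerobic performance phenotypes.

Each individual's aerobic scope (AS) at each of three treatment temperatures
is placed against per-temperature cutoffs at the 25th, 50th and 75th
percentiles of the AS range available to the species, earning 1-4 points per
temperature. Points are summed to a total in [3, 12] and the total is
classified: <= 5 low performer, 6-9 intermediate, >= 10 high performer. The
class edges are the 25th/75th percentiles of the achievable interval
(3 + 0.25*9 = 5.25 and 3 + 0.75*9 = 9.75, rounded to 5 and 10).

The packaged cutoffs (per-minute rate scale, one row per temperature bucket,
the 21 and 24 degC treatments pooled)::

    bucket   <25%    <50%    >50%    >75%
    16 degC  (1 pt)  <1.75   <2.6    >2.6    >3.45
    10 degC          <2.59   <3.68   >3.68   >4.77
    21-24 degC       <3.35   <4.2    >4.2    >5.05

All three rows are evenly spaced, i.e. each is the linear interpolation of
its (min, max) AS range — :func:`cutoffs_from_range` regenerates them.
Boundary values are scored lower-inclusive (a value exactly at a cutoff gets
the higher score), which keeps the scoring monotone, total and deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PercentileCutoffs",
    "ScoreCard",
    "TABLE_CUTOFFS",
    "TABLE_RANGES",
    "TEMP_BUCKETS",
    "temp_bucket",
    "cutoffs_from_range",
    "cutoffs_empirical",
    "rank_score",
    "total_score",
    "classify",
    "score_band_thresholds",
    "score_individual",
    "enumerate_total_scores",
]

TEMP_BUCKETS = ("16", "10", "high")


@dataclass(frozen=True)
class PercentileCutoffs:
    """25th/50th/75th-percentile aerobic-scope cutoffs for one temperature."""

    temp_bucket: str
    c25: float
    c50: float
    c75: float
    provenance: str = "table_packaged"

    def __post_init__(self) -> None:
        if not self.c25 < self.c50 < self.c75:
            raise ValueError("cutoffs must satisfy c25 < c50 < c75")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c25, self.c50, self.c75)


#: packaged per-temperature cutoffs (aerobic scope, per-minute rate scale)
TABLE_CUTOFFS: dict[str, PercentileCutoffs] = {
    "16": PercentileCutoffs("16", 1.75, 2.6, 3.45),
    "10": PercentileCutoffs("10", 2.59, 3.68, 4.77),
    "high": PercentileCutoffs("high", 3.35, 4.2, 5.05),
}

#: the (min, max) AS ranges implied by the evenly spaced packaged rows
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "16": (0.9, 4.3),
    "10": (1.50, 5.86),
    "high": (2.50, 5.90),
}


def temp_bucket(temp_c: float) -> str:
    """Map a treatment temperature to its cutoff bucket.

    16 -> "16", 10 -> "10", 21-24 -> "high" (the warm treatments share one
    pooled cutoff row). Small deviations (<= 0.5 degC) are tolerated.
    """
    t = float(temp_c)
    if abs(t - 16.0) <= 0.5:
        return "16"
    if abs(t - 10.0) <= 0.5:
        return "10"
    if 20.5 <= t <= 24.5:
        return "high"
    raise ValueError(f"no cutoff bucket for treatment temperature {temp_c!r}")


def cutoffs_from_range(
    as_min: float,
    as_max: float,
    bucket: str = "custom",
    provenance: str = "range_interpolated",
) -> PercentileCutoffs:
    """Evenly spaced cutoffs: c_p = min + p (max - min), p in {.25, .5, .75}."""
    if not as_min < as_max:
        raise ValueError("require as_min < as_max")
    span = as_max - as_min
    return PercentileCutoffs(
        bucket,
        as_min + 0.25 * span,
        as_min + 0.50 * span,
        as_min + 0.75 * span,
        provenance=provenance,
    )


def cutoffs_empirical(as_values, probs=(0.25, 0.5, 0.75), bucket: str = "custom") -> PercentileCutoffs:
    """Empirical quantile cutoffs (linear interpolation at h = q(n-1))."""
    vals = np.asarray(list(as_values), dtype=float)
    if len(vals) < 4:
        raise ValueError("need at least 4 aerobic-scope values")
    q = np.quantile(vals, probs)
    return PercentileCutoffs(bucket, *map(float, q), provenance="empirical")


def rank_score(as_value: float, cutoffs: PercentileCutoffs) -> int:
    """1-4 points for an AS value against one temperature's cutoffs.

    Lower-inclusive bands: 1 if v < c25; 2 if c25 <= v < c50; 3 if
    c50 <= v < c75; 4 if v >= c75. Negative AS is allowed and scores 1.
    """
    v = float(as_value)
    if not math.isfinite(v):
        raise ValueError("aerobic scope must be finite")
    return 1 + sum(v >= c for c in cutoffs.as_tuple())


def total_score(ranks) -> int:
    """Sum of exactly three per-temperature rank scores; in [3, 12]."""
    ranks = list(ranks)
    if len(ranks) != 3:
        raise ValueError("exactly three per-temperature rank scores are required")
    if any(r not in (1, 2, 3, 4) for r in ranks):
        raise ValueError("rank scores must be integers in 1..4")
    return int(sum(ranks))


def classify(total: int) -> str:
    """low if total <= 5; intermediate if 6-9; high if total >= 10."""
    if total != int(total) or not 3 <= total <= 12:
        raise ValueError("total score must be an integer in [3, 12]")
    total = int(total)
    if total <= 5:
        return "low"
    if total <= 9:
        return "intermediate"
    return "high"


def score_band_thresholds() -> dict:
    """Class-edge thresholds of the achievable total-score interval [3, 12].

    The 25th/75th percentiles by linear interpolation (3 + p*9) give 5.25
    and 9.75; rounded to the integers actually used for banding (5 and 10).
    """

    def _round_half_up(x: float) -> int:
        return int(math.floor(x + 0.5))

    low = 3 + 0.25 * 9
    high = 3 + 0.75 * 9
    return {
        "low_percentile": low,
        "low_rounded": _round_half_up(low),
        "high_percentile": high,
        "high_rounded": _round_half_up(high),
        "midpoint": 3 + 0.5 * 9,
    }


@dataclass(frozen=True)
class ScoreCard:
    """Per-temperature rank scores, total and phenotype for one individual."""

    individual_id: str
    score_16: int
    score_10: int
    score_high: int
    total: int
    phenotype: str

    def __post_init__(self) -> None:
        if self.total != self.score_16 + self.score_10 + self.score_high:
            raise ValueError("total must be the sum of the three rank scores")
        if classify(self.total) != self.phenotype:
            raise ValueError("phenotype inconsistent with total score")


def score_individual(individual_id: str, as_by_bucket, cutoffs=None) -> ScoreCard:
    """Score one individual from its AS values per temperature bucket.

    ``as_by_bucket`` maps each of the buckets "16", "10", "high" to an AS
    value; all three are required (no imputation for missing temperatures).
    ``cutoffs`` maps buckets to :class:`PercentileCutoffs` (default packaged).
    """
    cutoffs = cutoffs or TABLE_CUTOFFS
    missing = [b for b in TEMP_BUCKETS if b not in as_by_bucket]
    if missing:
        raise ValueError(
            f"individual {individual_id!r} lacks temperature bucket(s): {missing}"
        )
    scores = {b: rank_score(as_by_bucket[b], cutoffs[b]) for b in TEMP_BUCKETS}
    total = total_score([scores[b] for b in TEMP_BUCKETS])
    return ScoreCard(
        individual_id=individual_id,
        score_16=scores["16"],
        score_10=scores["10"],
        score_high=scores["high"],
        total=total,
        phenotype=classify(total),
    )


def enumerate_total_scores() -> dict:
    """Brute-force enumeration of all 4^3 rank triples.

    Returns min/max achievable totals and the class counts by band — the
    analytic ground truth for the scoring scheme.
    """
    totals = [total_score(t) for t in itertools.product((1, 2, 3, 4), repeat=3)]
    counts = {"low": 0, "intermediate": 0, "high": 0}
    for t in totals:
        counts[classify(t)] += 1
    return {
        "n_triples": len(totals),
        "min_total": min(totals),
        "max_total": max(totals),
        "class_counts": counts,
    }
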