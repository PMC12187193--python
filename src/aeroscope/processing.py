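"""Per-cycle oxygen-consumption rates from raw traces.

Pipeline: segment a trace into closed measurement cycles, fit an ordinary
least-squares line to the oxygen concentration of each cycle (the first
minute excluded), discard fits with R^2 <= 0.9, and convert the surviving
slopes into whole-animal mass-specific rates, subtracting the fishless
background slope:

    RO2 = ((Vre - M)/W) * (|d[O2a]/dt| * 60)
        - ((Vre - M)/W) * (|d[O2b]/dt| * 60) * (Vre/(Vre - M))

with Vre the chamber volume (l), M the fish displacement volume (l), W the
fish mass (kg), slopes in mg l^-1 min^-1 and RO2 in mg O2 kg^-1 h^-1.
Both slopes enter as magnitudes of decline, so a consuming fish yields a
positive rate; a background slope exceeding the animal signal produces a
negative record which is flagged, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .traces import CLOSED_PHASES, RespTrace

__all__ = [
    "MeasurementCycle",
    "SlopeFit",
    "RO2Record",
    "segment_cycles",
    "fit_slope",
    "filter_slopes",
    "background_slope",
    "ro2",
]

logger = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.9
DEFAULT_EXCLUDE_INITIAL_S = 60.0


@dataclass(frozen=True)
class MeasurementCycle:
    """One maximal contiguous run of closed-phase samples."""

    cycle_index: int
    start: int  # index into the trace arrays, inclusive
    stop: int  # exclusive
    kind: str  # measure | recovery | empty
    t_start_s: float
    t_end_s: float


@dataclass(frozen=True)
class SlopeFit:
    """OLS line through one cycle's oxygen concentration vs time (minutes)."""

    slope_mg_l_min: float  # signed; declines are negative
    intercept_mg_l: float
    r_squared: float
    n_points: int
    cycle_index: int
    kind: str  # animal | background
    t_start_s: float = 0.0


@dataclass(frozen=True)
class RO2Record:
    """One cycle's whole-animal mass-specific oxygen consumption rate."""

    individual_id: str
    treatment_temp_c: float
    cycle_index: int
    ro2_raw: float  # mg O2 kg^-1 h^-1
    elapsed_h: float
    cycle_kind: str = "measure"
    flagged_negative: bool = False


def segment_cycles(trace: RespTrace, schedule: tuple[float, float] | None = None) -> list[MeasurementCycle]:
    """Split a trace into measurement cycles.

    Segmentation is label-driven: one cycle per maximal contiguous run of
    closed-phase ("measure"/"recovery"/"empty") samples. For traces without
    phase labels, ``schedule=(measure_s, flush_s)`` reconstructs the closed
    mask from the protocol cadence; an unlabeled trace without a schedule is
    an error. A trace with no closed samples yields an empty list.
    """
    labels = np.asarray(trace.phase, dtype=object)
    labelled = np.array([bool(str(p)) and str(p) != "nan" for p in labels])
    if not labelled.any():
        if schedule is None:
            raise ValueError("trace has no phase labels and no schedule was given")
        measure_s, flush_s = schedule
        t_mod = trace.time_s % (measure_s + flush_s)
        closed = t_mod < measure_s
        labels = np.where(closed, "measure", "flush").astype(object)
    closed = np.isin(labels, CLOSED_PHASES)
    if not closed.any():
        return []
    edges = np.flatnonzero(np.diff(closed.astype(int)))
    starts = [0] if closed[0] else []
    starts += [int(e) + 1 for e in edges if not closed[e]]
    stops = [int(e) + 1 for e in edges if closed[e]]
    if closed[-1]:
        stops.append(len(closed))
    cycles = []
    for idx, (a, b) in enumerate(zip(starts, stops)):
        cycles.append(
            MeasurementCycle(
                cycle_index=idx,
                start=a,
                stop=b,
                kind=str(labels[a]),
                t_start_s=float(trace.time_s[a]),
                t_end_s=float(trace.time_s[b - 1]),
            )
        )
    return cycles


def _ols_minutes(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope (per minute), intercept and R^2 of y on time.

    R^2 is the squared Pearson correlation; defined as 0 when the response
    has zero variance (a constant trace carries no evidence of a linear
    decline, so the cycle then fails the quality filter).
    """
    x = t_s / 60.0
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy <= 0.0:
        return 0.0, float(np.mean(y)), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    r2 = min(1.0, sxy * sxy / (sxx * syy))
    return float(slope), float(intercept), r2


def fit_slope(
    trace: RespTrace,
    cycle: MeasurementCycle,
    exclude_initial_s: float = DEFAULT_EXCLUDE_INITIAL_S,
) -> SlopeFit | None:
    """OLS fit to one cycle after excluding its first ``exclude_initial_s``.

    Returns None when fewer than 3 samples remain (an unusable cycle, as
    opposed to one that merely fails the R^2 filter).
    """
    t = trace.time_s[cycle.start : cycle.stop]
    y = trace.o2_mg_l[cycle.start : cycle.stop]
    keep = t >= cycle.t_start_s + exclude_initial_s
    t, y = t[keep], y[keep]
    if len(t) < 3:
        return None
    slope, intercept, r2 = _ols_minutes(t, y)
    return SlopeFit(
        slope_mg_l_min=slope,
        intercept_mg_l=intercept,
        r_squared=r2,
        n_points=int(len(t)),
        cycle_index=cycle.cycle_index,
        kind="background" if cycle.kind == "empty" else "animal",
        t_start_s=cycle.t_start_s,
    )


def filter_slopes(fits, r2_min: float = DEFAULT_R2_MIN) -> list[SlopeFit]:
    """Retain fits with R^2 strictly greater than ``r2_min``, order preserved."""
    fits = list(fits)
    kept = [f for f in fits if f.r_squared > r2_min]
    n_discarded = len(fits) - len(kept)
    if n_discarded:
        logger.info("R^2 filter discarded %d of %d cycle fits", n_discarded, len(fits))
    return kept


def background_slope(
    empty_trace: RespTrace, exclude_initial_s: float = DEFAULT_EXCLUDE_INITIAL_S
) -> SlopeFit:
    """Single OLS fit over a fishless (all-'empty') trace.

    The same initial exclusion is applied as for animal cycles, for uniform
    treatment of sensor settling.
    """
    if not all(str(p) == "empty" for p in empty_trace.phase):
        raise ValueError("background trace must contain only 'empty' phase samples")
    cycles = segment_cycles(empty_trace)
    if len(cycles) != 1:
        raise ValueError("background trace must be one continuous window")
    fit = fit_slope(empty_trace, cycles[0], exclude_initial_s=exclude_initial_s)
    if fit is None:
        raise ValueError("background trace too short to fit")
    return fit


def ro2(
    animal_fit: SlopeFit,
    background_fit: SlopeFit | None,
    trace: RespTrace,
) -> RO2Record:
    """Whole-animal mass-specific rate for one cycle (Eq. above).

    ``background_fit=None`` means no background correction (slope 0).
    """
    vre = trace.chamber_volume_l
    m = trace.displacement_l
    w = trace.fish_mass_kg
    if not vre > m:
        raise ValueError("chamber volume must exceed fish displacement volume")
    if not w > 0:
        raise ValueError("fish mass must be > 0 to compute a rate")
    a = abs(animal_fit.slope_mg_l_min) * 60.0
    b = abs(background_fit.slope_mg_l_min) * 60.0 if background_fit is not None else 0.0
    k = (vre - m) / w
    value = k * a - k * b * (vre / (vre - m))
    flagged = value < 0
    if flagged:
        logger.warning(
            "background slope exceeds animal signal in cycle %d of %s (RO2=%.4g)",
            animal_fit.cycle_index,
            trace.individual_id,
            value,
        )
    return RO2Record(
        individual_id=trace.individual_id,
        treatment_temp_c=trace.treatment_temp_c,
        cycle_index=animal_fit.cycle_index,
        ro2_raw=float(value),
        elapsed_h=animal_fit.t_start_s / 3600.0,
        cycle_kind="recovery" if animal_fit.kind == "animal" and _is_recovery(trace, animal_fit) else "measure",
        flagged_negative=bool(flagged),
    )


def _is_recovery(trace: RespTrace, fit: SlopeFit) -> bool:
    i = int(np.searchsorted(trace.time_s, fit.t_start_s))
    i = min(i, len(trace.phase) - 1)
    return str(trace.phase[i]) == "recovery"
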