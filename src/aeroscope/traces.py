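"""Raw oxygen-trace container and its on-disk CSV dialect.

A :class:`RespTrace` holds one individual's oxygen-concentration time series
at one treatment temperature, together with the chamber geometry needed to
convert concentration declines into whole-animal oxygen consumption rates.
Phases follow the intermittent-flow convention: closed ("measure" or
"recovery") phases alternate with open "flush" phases; fishless background
runs are labelled "empty" throughout.

The CSV dialect is a neutral long format (one row per sample) with header::

    individual_id,treatment_temp_c,time_s,o2_mg_l,phase,chamber_volume_l,fish_mass_kg,displacement_l

UTF-8, '.' decimal, phase vocabulary exactly {measure, flush, recovery,
empty}. Lines starting with '#' are comments (used for provenance hashes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RespTrace",
    "TRACE_COLUMNS",
    "CLOSED_PHASES",
    "PHASES",
    "read_traces",
    "write_traces",
]

TRACE_COLUMNS = (
    "individual_id",
    "treatment_temp_c",
    "time_s",
    "o2_mg_l",
    "phase",
    "chamber_volume_l",
    "fish_mass_kg",
    "displacement_l",
)

#: phases during which the chamber is sealed and a slope is meaningful
CLOSED_PHASES = ("measure", "recovery", "empty")
PHASES = ("measure", "flush", "recovery", "empty")


@dataclass
class RespTrace:
    """Timestamped oxygen-concentration series for one individual x temperature.

    Parameters
    ----------
    time_s, o2_mg_l, phase
        Equal-length sample arrays; time strictly increasing.
    chamber_volume_l
        Total respirometer volume ``Vre`` (litres).
    fish_mass_kg
        Wet mass ``W`` (kg); 0 only for fishless background traces.
    displacement_l
        Fish displacement volume ``M`` (litres), conventionally mass x 1 l/kg.
    """

    individual_id: str
    treatment_temp_c: float
    time_s: np.ndarray
    o2_mg_l: np.ndarray
    phase: np.ndarray
    chamber_volume_l: float
    fish_mass_kg: float
    displacement_l: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_mg_l = np.asarray(self.o2_mg_l, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_s) == len(self.o2_mg_l) == len(self.phase)):
            raise ValueError("time_s, o2_mg_l and phase must have equal length")
        self.validate()

    def validate(self) -> None:
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise ValueError(
                f"time not strictly increasing for individual {self.individual_id!r}"
            )
        if not self.chamber_volume_l > self.displacement_l >= 0:
            raise ValueError("require chamber_volume_l > displacement_l >= 0")
        only_empty = len(self.phase) > 0 and all(p == "empty" for p in self.phase)
        if not only_empty and not self.fish_mass_kg > 0:
            raise ValueError("fish_mass_kg must be > 0 unless the trace is all 'empty'")
        unknown = set(map(str, self.phase)) - set(PHASES) - {""}
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "treatment_temp_c": self.treatment_temp_c,
                "time_s": self.time_s,
                "o2_mg_l": self.o2_mg_l,
                "phase": self.phase,
                "chamber_volume_l": self.chamber_volume_l,
                "fish_mass_kg": self.fish_mass_kg,
                "displacement_l": self.displacement_l,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RespTrace":
        first = frame.iloc[0]
        return cls(
            individual_id=str(first["individual_id"]),
            treatment_temp_c=float(first["treatment_temp_c"]),
            time_s=frame["time_s"].to_numpy(dtype=float),
            o2_mg_l=frame["o2_mg_l"].to_numpy(dtype=float),
            phase=frame["phase"].to_numpy(dtype=object),
            chamber_volume_l=float(first["chamber_volume_l"]),
            fish_mass_kg=float(first["fish_mass_kg"]),
            displacement_l=float(first["displacement_l"]),
        )


def read_traces(path) -> list[RespTrace]:
    """Read the trace CSV dialect into one :class:`RespTrace` per
    (individual, temperature, contiguous block).

    Raises
    ------
    ValueError
        Naming the missing column, listing malformed rows by line number, or
        reporting non-monotone time within an individual.
    """
    frame = pd.read_csv(
        path,
        comment="#",
        dtype={"individual_id": str, "phase": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    numeric = [
        "treatment_temp_c",
        "time_s",
        "o2_mg_l",
        "chamber_volume_l",
        "fish_mass_kg",
        "displacement_l",
    ]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"malformed value(s) in column {col!r} at line(s) {lines}")
        frame[col] = coerced
    traces = []
    for (ind, _), group in frame.groupby(["individual_id", "treatment_temp_c"], sort=False):
        t = group["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"time not strictly increasing for individual {ind!r}")
        traces.append(RespTrace.from_frame(group))
    return traces


def write_traces(traces, path, header_comment: str | None = None) -> None:
    """Write traces in the CSV dialect; round-trips through :func:`read_traces`
    at full stored precision."""
    frame = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
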