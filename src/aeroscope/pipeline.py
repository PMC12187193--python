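"""End-to-end cohort runs: simulate or ingest traces, process, correct,
score and summarize.

The pipeline converts a set of oxygen traces (one SMR run and one post-chase
recovery run per individual per temperature, plus one fishless background
run per temperature) into:

* ``indices`` — per individual x temperature SMR/MMR/aerobic scope, both as
  measured (mass-specific, background-corrected) and mass-normalized by the
  cohort allometric exponent, with quality flags;
* ``scorecards`` — per-temperature rank scores, total and phenotype class
  for every individual with a complete three-temperature record;
* ``summary`` — cohort-level counts, percentages and per-class statistics.

Outputs are deterministic in (config, seed) and carry a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correction, processing, scoring
from .synthetic import CohortDraws, TraceConfig, simulate_cohort
from .traces import RespTrace, read_traces, write_traces

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "CohortSummary",
    "run_pipeline",
    "summarize_cohort",
    "score_indices",
    "read_traces",
    "write_traces",
    "write_outputs",
]

logger = logging.getLogger(__name__)

INDEX_COLUMNS = (
    "individual_id",
    "treatment_temp_c",
    "smr",
    "mmr",
    "aerobic_scope",
    "smr_measured",
    "mmr_measured",
    "n_cycles_used",
    "n_cycles_discarded",
    "flags",
)


class PipelineError(RuntimeError):
    """Raised when a run cannot produce any usable output."""


@dataclass
class PipelineConfig:
    """Settings for one cohort run.

    ``unit_scale`` controls the scale of reported indices: "per_minute"
    (default; the scale on which the packaged cutoffs are expressed) divides
    the canonical mg O2 kg^-1 h^-1 rates by 60, "per_hour" leaves them as is.
    Classification cutoffs are interpreted on whatever scale the indices are
    reported in.
    """

    mode: str = "synthetic"  # synthetic | files
    traces_path: str | None = None
    output_dir: str | None = None
    seed: int | None = 0
    n_per_archetype: tuple[int, int, int] = (3, 3, 3)
    temps_c: tuple[float, ...] = (10.0, 16.0, 21.0)
    n_at_24: int = 0
    trace_config: TraceConfig = field(default_factory=TraceConfig)
    draws: CohortDraws = field(default_factory=CohortDraws)
    r2_min: float = 0.9
    exclude_initial_s: float = 60.0
    smr_method: str = "quantile_0.2"
    boltzmann_mode: str = "literal"
    alpha_rate_kinds: tuple[str, ...] = ("smr",)
    alpha_strata: tuple[str, ...] = ("kind", "temperature")
    cutoff_mode: str = "table"  # table | range | empirical
    unit_scale: str = "per_minute"  # per_minute | per_hour

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")
        if self.mode == "files" and not self.traces_path:
            raise ValueError("traces_path is required in files mode")
        if self.unit_scale not in ("per_minute", "per_hour"):
            raise ValueError("unit_scale must be 'per_minute' or 'per_hour'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trace_config"] = dataclasses.asdict(self.trace_config)
        draws = dataclasses.asdict(self.draws)
        d["draws"] = draws
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortSummary:
    """Cohort-level reporting in the style of a results section."""

    n_individuals: int
    class_counts: dict
    class_percent: dict
    pooled_stats: dict  # class -> metric -> {mean, sd, min, max}
    per_temperature_means: dict  # class -> temp -> metric -> mean
    config_hash: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    indices: pd.DataFrame
    scorecards: pd.DataFrame
    summary: CohortSummary
    log: list
    truth: pd.DataFrame | None = None
    config: PipelineConfig | None = None


def _round_half_up_percent(x: float) -> int:
    return int(math.floor(x + 0.5))


def _collect_fits(trace: RespTrace, config: PipelineConfig):
    """Segment, fit and filter one animal trace; returns records per kind."""
    cycles = processing.segment_cycles(trace)
    fits, unusable = [], 0
    for cyc in cycles:
        fit = processing.fit_slope(trace, cyc, exclude_initial_s=config.exclude_initial_s)
        if fit is None:
            unusable += 1
        else:
            fits.append((cyc, fit))
    kept = processing.filter_slopes([f for _, f in fits], r2_min=config.r2_min)
    kept_idx = {f.cycle_index for f in kept}
    discarded = len(fits) - len(kept)
    return cycles, [(c, f) for c, f in fits if f.cycle_index in kept_idx], discarded + unusable


def _process_traces(traces_iter, config: PipelineConfig):
    """First pass: background fits per temperature and slope fits per
    (individual, temperature, cycle kind)."""
    backgrounds: dict[float, processing.SlopeFit] = {}
    per_key: dict[tuple[str, float], dict] = {}
    meta: dict[tuple[str, float], RespTrace] = {}
    for trace in traces_iter:
        if all(str(p) == "empty" for p in trace.phase):
            backgrounds[trace.treatment_temp_c] = processing.background_slope(
                trace, exclude_initial_s=config.exclude_initial_s
            )
            continue
        key = (trace.individual_id, trace.treatment_temp_c)
        entry = per_key.setdefault(key, {"measure": [], "recovery": [], "discarded": 0})
        _, kept, discarded = _collect_fits(trace, config)
        entry["discarded"] += discarded
        bg = backgrounds.get(trace.treatment_temp_c)
        for cyc, fit in kept:
            rec = processing.ro2(fit, bg, trace)
            kind = "recovery" if cyc.kind == "recovery" else "measure"
            entry[kind].append(rec)
        meta[key] = trace
    return backgrounds, per_key, meta


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run a full cohort analysis; see module docstring for outputs."""
    log: list[str] = []
    truth = None
    if config.mode == "synthetic":
        sim = simulate_cohort(
            config.n_per_archetype,
            config=config.trace_config,
            temps_c=config.temps_c,
            seed=int(config.seed),
            draws=config.draws,
            n_at_24=config.n_at_24,
        )
        truth = sim.truth
        traces_iter = sim.iter_traces()
        masses = {p.individual_id: p.mass_kg for p in sim.params}
        log.append(f"simulated cohort of {len(sim.params)} individuals (seed {config.seed})")
    else:
        traces = read_traces(config.traces_path)
        traces_iter = iter(traces)
        masses = {
            t.individual_id: t.fish_mass_kg for t in traces if t.fish_mass_kg > 0
        }
        log.append(f"read {len(traces)} traces from {config.traces_path}")

    backgrounds, per_key, meta = _process_traces(traces_iter, config)
    log.append(f"background slopes for temperatures: {sorted(backgrounds)}")

    rows = []
    for (ind, temp), entry in per_key.items():
        flags = []
        measure = [r for r in entry["measure"]]
        recovery = [r for r in entry["recovery"]]
        if temp not in backgrounds:
            flags.append("no_background")
        if not measure and not recovery:
            flags.append("no_usable_cycles")
            rows.append(
                {
                    "individual_id": ind,
                    "treatment_temp_c": temp,
                    "smr_measured": np.nan,
                    "mmr_measured": np.nan,
                    "n_cycles_used": 0,
                    "n_cycles_discarded": entry["discarded"],
                    "flags": ";".join(flags),
                }
            )
            continue
        smr_val = (
            correction.smr_from_records(measure, method=config.smr_method)
            if measure
            else np.nan
        )
        mmr_val = correction.mmr_from_records(recovery) if recovery else np.nan
        if len(measure) < 5:
            flags.append("sparse_cycles")
        if any(r.flagged_negative for r in measure + recovery):
            flags.append("negative_cycle_rate")
        rows.append(
            {
                "individual_id": ind,
                "treatment_temp_c": temp,
                "smr_measured": smr_val,
                "mmr_measured": mmr_val,
                "n_cycles_used": len(measure) + len(recovery),
                "n_cycles_discarded": entry["discarded"],
                "flags": ";".join(flags),
            }
        )
    indices = pd.DataFrame(rows)
    if indices.empty or not (
        indices["smr_measured"].notna().any() or indices["mmr_measured"].notna().any()
    ):
        raise PipelineError("no individuals with any usable cycles")

    # allometric exponent from temperature-detrended SMR/MMR candidates
    alpha, alpha_note = _estimate_alpha(indices, masses, config)
    log.append(alpha_note)
    indices["mass_kg"] = indices["individual_id"].map(masses)
    mexp = indices["mass_kg"] ** alpha
    indices["smr"] = indices["smr_measured"] / mexp
    indices["mmr"] = indices["mmr_measured"] / mexp
    indices["aerobic_scope"] = indices["mmr"] - indices["smr"]
    neg = indices["aerobic_scope"] < 0
    if neg.any():
        indices.loc[neg, "flags"] = indices.loc[neg, "flags"].apply(
            lambda f: ";".join(filter(None, [f, "negative_aerobic_scope"]))
        )

    scale = 1.0 / 60.0 if config.unit_scale == "per_minute" else 1.0
    for col in ("smr", "mmr", "aerobic_scope", "smr_measured", "mmr_measured"):
        indices[col] = indices[col] * scale
    if truth is not None:
        truth = truth.copy()
        for col in ("true_smr", "true_mmr", "true_aerobic_scope"):
            truth[col] = truth[col] * scale

    indices = indices.sort_values(["individual_id", "treatment_temp_c"]).reset_index(drop=True)
    indices = indices[
        [
            "individual_id",
            "treatment_temp_c",
            "mass_kg",
            "smr",
            "mmr",
            "aerobic_scope",
            "smr_measured",
            "mmr_measured",
            "n_cycles_used",
            "n_cycles_discarded",
            "flags",
        ]
    ]

    scorecards, score_log = score_indices(indices, cutoff_mode=config.cutoff_mode)
    log.extend(score_log)
    summary = summarize_cohort(indices, scorecards)
    summary.config_hash = config.config_hash()
    return PipelineResult(
        indices=indices,
        scorecards=scorecards,
        summary=summary,
        log=log,
        truth=truth,
        config=config,
    )


def _estimate_alpha(indices: pd.DataFrame, masses: dict, config: PipelineConfig):
    recs = []
    for _, row in indices.iterrows():
        mass = masses.get(row["individual_id"])
        if mass is None or not mass > 0:
            continue
        for kind, col in (("smr", "smr_measured"), ("mmr", "mmr_measured")):
            if kind not in config.alpha_rate_kinds:
                continue
            v = row[col]
            if pd.notna(v) and v > 0:
                recs.append((v, mass, kind, row["treatment_temp_c"]))
    if not recs:
        return 0.0, "alpha: no positive candidate rates; mass correction skipped"
    rates = np.array([r[0] for r in recs])
    ms = np.array([r[1] for r in recs])
    if np.unique(ms).size < 2:
        return 0.0, "alpha: fewer than 2 distinct masses; mass correction skipped"
    corrected = correction.boltzmann_correct(
        rates, np.array([r[3] for r in recs]), mode=config.boltzmann_mode
    )
    strata = None
    if config.alpha_strata:
        strata = [
            "|".join(
                [str(r[2]) if "kind" in config.alpha_strata else ""]
                + [str(r[3]) if "temperature" in config.alpha_strata else ""]
            )
            for r in recs
        ]
    try:
        scaling = correction.estimate_mass_exponent(corrected, ms, strata=strata)
    except ValueError as exc:
        return 0.0, f"alpha estimation failed ({exc}); mass correction skipped"
    note = (
        f"alpha = {scaling.alpha:.4f} (R^2 {scaling.r_squared:.3f}, n {scaling.n}, "
        f"strata {config.alpha_strata or 'pooled'})"
    )
    return scaling.alpha, note


def score_indices(indices: pd.DataFrame, cutoff_mode: str = "table"):
    """Score every individual with a complete three-bucket AS triple.

    Returns (scorecards DataFrame, log lines). Individuals with incomplete
    temperature coverage are logged and excluded (never imputed).
    """
    log = []
    cutoffs = _cutoffs_for(indices, cutoff_mode)
    log.append(
        "cutoffs: "
        + "; ".join(
            f"{b}: {tuple(round(c, 4) for c in cutoffs[b].as_tuple())} ({cutoffs[b].provenance})"
            for b in scoring.TEMP_BUCKETS
        )
    )
    cards = []
    for ind, group in indices.groupby("individual_id", sort=True):
        as_by_bucket = {}
        ok = True
        for _, row in group.iterrows():
            if pd.isna(row["aerobic_scope"]):
                ok = False
                continue
            try:
                bucket = scoring.temp_bucket(row["treatment_temp_c"])
            except ValueError:
                continue
            as_by_bucket[bucket] = float(row["aerobic_scope"])
        missing = [b for b in scoring.TEMP_BUCKETS if b not in as_by_bucket]
        if missing or not ok:
            log.append(f"{ind}: not classified (missing buckets {missing})")
            continue
        cards.append(scoring.score_individual(ind, as_by_bucket, cutoffs))
    frame = pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "score_16": c.score_16,
                "score_10": c.score_10,
                "score_high": c.score_high,
                "total": c.total,
                "phenotype": c.phenotype,
            }
            for c in cards
        ],
        columns=["individual_id", "score_16", "score_10", "score_high", "total", "phenotype"],
    )
    return frame, log


def _cutoffs_for(indices: pd.DataFrame, cutoff_mode: str) -> dict:
    if cutoff_mode == "table":
        return scoring.TABLE_CUTOFFS
    cutoffs = {}
    for bucket in scoring.TEMP_BUCKETS:
        sel = indices["treatment_temp_c"].apply(
            lambda t: _bucket_or_none(t) == bucket
        )
        vals = indices.loc[sel, "aerobic_scope"].dropna().to_numpy()
        if cutoff_mode == "range":
            if len(vals) < 2 or vals.min() >= vals.max():
                raise PipelineError(f"cannot derive range cutoffs for bucket {bucket}")
            cutoffs[bucket] = scoring.cutoffs_from_range(
                float(vals.min()), float(vals.max()), bucket=bucket
            )
        elif cutoff_mode == "empirical":
            cutoffs[bucket] = scoring.cutoffs_empirical(vals, bucket=bucket)
        else:
            raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
    return cutoffs


def _bucket_or_none(t):
    try:
        return scoring.temp_bucket(t)
    except ValueError:
        return None


def summarize_cohort(indices: pd.DataFrame, scorecards: pd.DataFrame) -> CohortSummary:
    """Cohort-level counts, percentages and per-class statistics.

    Percentages are rounded half-up to integer percent. Pooled per-class
    statistics use all individual x temperature rows of that class.
    """
    if scorecards.empty:
        raise PipelineError("no classified individuals to summarize")
    n = int(scorecards["individual_id"].nunique())
    counts = {c: 0 for c in ("high", "intermediate", "low")}
    for c, k in scorecards["phenotype"].value_counts().items():
        counts[str(c)] = int(k)
    percent = {c: _round_half_up_percent(100.0 * k / n) for c, k in counts.items()}
    merged = indices.merge(
        scorecards[["individual_id", "phenotype"]], on="individual_id", how="inner"
    )
    pooled: dict = {}
    per_temp: dict = {}
    for cls, group in merged.groupby("phenotype"):
        pooled[cls] = {}
        for metric in ("smr", "mmr", "aerobic_scope"):
            vals = group[metric].dropna()
            pooled[cls][metric] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        per_temp[cls] = {}
        for temp, tgroup in group.groupby("treatment_temp_c"):
            per_temp[cls][str(temp)] = {
                metric: float(tgroup[metric].mean())
                for metric in ("smr", "mmr", "aerobic_scope")
            }
    return CohortSummary(
        n_individuals=n,
        class_counts=counts,
        class_percent=percent,
        pooled_stats=pooled,
        per_temperature_means=per_temp,
    )


def write_outputs(result: PipelineResult, output_dir) -> dict:
    """Write indices.csv, scorecards.csv, summary.json (+ truth.csv, run_log)
    into ``output_dir``; returns {name: path}. CSVs carry the config hash as
    a leading comment line."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash() if result.config else ""
    paths = {}

    def _write_csv(frame: pd.DataFrame, name: str):
        p = outdir / name
        with open(p, "w", encoding="utf-8", newline="") as fh:
            if chash:
                fh.write(f"# config_hash={chash}\n")
            frame.to_csv(fh, index=False)
        paths[name] = p

    _write_csv(result.indices, "indices.csv")
    _write_csv(result.scorecards, "scorecards.csv")
    if result.truth is not None:
        _write_csv(result.truth, "truth.csv")
    summary = result.summary.to_dict()
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["summary.json"] = p
    p = outdir / "run_log.json"
    p.write_text(
        json.dumps({"config_hash": chash, "log": result.log}, indent=2) + "\n",
        encoding="utf-8",
    )
    paths["run_log.json"] = p
    return paths
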