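"""Small deterministic fixture datasets.

Three sets are built programmatically (full-length traces are far too large
to commit as text, so fixtures regenerate on demand and their identity is
guaranteed by seeded determinism and content hashes):

* ``golden`` — a 3-fish noiseless cohort (one per archetype) on a shortened
  protocol, whose pipeline outputs are frozen as expected files;
* ``noisy`` — a 9-fish cohort with sensor noise, exercising the R^2 filter;
* ``worked_examples`` — a hand-checked table of aerobic-scope triples with
  their rank scores, totals and classes, covering every cutoff band edge.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import scoring
from .pipeline import PipelineConfig, run_pipeline, write_outputs
from .synthetic import ArchetypeRanges, CohortDraws, TraceConfig

__all__ = [
    "FixtureSet",
    "build_fixtures",
    "worked_examples",
    "golden_config",
    "noisy_config",
    "recovery_config",
    "classification_config",
]

#: shortened protocol used by fixture cohorts: coarse sampling, 4-h SMR run,
#: 1-h recovery, 1-h background — cheap to regenerate, same code paths
_SHORT_PROTOCOL = dict(
    sample_interval_s=20.0,
    smr_duration_h=4.0,
    recovery_duration_h=1.0,
    background_duration_h=1.0,
)

#: fixture cohorts suppress circadian modulation, use a slow post-chase decay
#: and hold the SMR baseline fixed across fish so the noiseless cohort
#: recovers the planted allometric exponent exactly
_FIXTURE_DRAWS = dict(
    circadian_amp=(0.0, 0.0),
    tau_recovery_s=(21600.0, 21600.0),
    smr_ref=(60.0, 60.0),
    q10_smr=(2.0, 2.0),
)


def golden_config(seed: int = 7) -> PipelineConfig:
    """3-fish noiseless cohort, one individual per archetype."""
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        n_per_archetype=(1, 1, 1),
        trace_config=TraceConfig(noise_sd_mg_l=0.0, **_SHORT_PROTOCOL),
        draws=CohortDraws(**_FIXTURE_DRAWS),
    )


def noisy_config(seed: int = 11) -> PipelineConfig:
    """9-fish cohort with sensor noise (exercises the R^2 filter)."""
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        n_per_archetype=(3, 3, 3),
        trace_config=TraceConfig(noise_sd_mg_l=0.008, **_SHORT_PROTOCOL),
        draws=CohortDraws(**_FIXTURE_DRAWS),
    )


def recovery_config(seed: int, noise_sd_mg_l: float = 0.0) -> PipelineConfig:
    """9-fish parameter-recovery benchmark cohort (full-length protocol).

    Designed to isolate trace-processing error: circadian modulation off, a
    slow (6-h) post-chase decay so the within-cycle excess-rate decline is
    below 1%, heavier fish (still within the chamber's 20-70 ml/g envelope)
    so the weakest cold-treatment declines stay above the sensor noise floor,
    and a slightly widened low-archetype thermal window so true aerobic
    scope stays positive at every test temperature (a maximum-rate MMR
    estimator cannot read below the recovery floor, so negative-scope cases
    are a flagged edge path, not a recovery benchmark).
    """
    draws = CohortDraws(
        mass_kg=(1.25, 1.45),
        circadian_amp=(0.0, 0.0),
        tau_recovery_s=(21600.0, 21600.0),
    )
    draws.archetypes["low"] = ArchetypeRanges((210.0, 234.0), (15.5, 16.5), (4.5, 5.5))
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        n_per_archetype=(3, 3, 3),
        trace_config=TraceConfig(noise_sd_mg_l=noise_sd_mg_l),
        draws=draws,
    )


def classification_config(seed: int, noise_sd_mg_l: float = 0.005) -> PipelineConfig:
    """44-fish cohort drawn with class proportions (8 high, 24 intermediate,
    12 low) at low sensor noise — the whole-chain re-classification
    benchmark, a scaled emulation of a repeated-measures study design."""
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        n_per_archetype=(8, 24, 12),
        trace_config=TraceConfig(noise_sd_mg_l=noise_sd_mg_l),
    )


def worked_examples() -> pd.DataFrame:
    """Hand-checked AS triples (per-minute scale) and their expected scores.

    Columns: AS at 16/10/21-24 degC, expected per-bucket scores, total and
    class under the packaged cutoffs. Rows cover interior values, every
    lower-inclusive band edge, and the worked low-performer case of a
    3-at-optimum / 1 / 1 triple totalling 5.
    """
    rows = [
        # as_16, as_10, as_high, s16, s10, s_high
        (3.0, 4.0, 5.5, 3, 3, 4),
        (1.0, 2.0, 3.0, 1, 1, 1),
        (2.6, 2.59, 3.35, 3, 2, 2),
        (3.45, 4.77, 5.05, 4, 4, 4),
        (2.6, 2.0, 3.0, 3, 1, 1),
        (1.75, 3.68, 4.2, 2, 3, 3),
        (-0.5, 6.0, 4.5, 1, 4, 3),
    ]
    out = []
    for i, (a16, a10, ah, s16, s10, sh) in enumerate(rows, start=1):
        total = s16 + s10 + sh
        out.append(
            {
                "example_id": f"WX{i:02d}",
                "as_16": a16,
                "as_10": a10,
                "as_high": ah,
                "score_16": s16,
                "score_10": s10,
                "score_high": sh,
                "total": total,
                "phenotype": scoring.classify(total),
            }
        )
    return pd.DataFrame(out)


@dataclass
class FixtureSet:
    name: str
    seed: int
    root: Path
    manifest: dict  # relative path -> sha256

    def verify(self) -> None:
        for rel, digest in self.manifest.items():
            actual = _sha256(self.root / rel)
            if actual != digest:
                raise ValueError(f"fixture file {rel} hash mismatch")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_fixtures(output_dir) -> FixtureSet:
    """Build all fixture sets under ``output_dir``; returns the manifest.

    Regeneration from the same seeds reproduces every file bit-identically.
    """
    root = Path(output_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for name, config in (("golden", golden_config()), ("noisy", noisy_config())):
        result = run_pipeline(config)
        paths = write_outputs(result, root / name)
        for fname, p in paths.items():
            manifest[f"{name}/{fname}"] = _sha256(p)

    wx = worked_examples()
    # re-derive the scores with the scoring module and refuse to write a
    # fixture whose hand-checked expectations disagree with the code
    for _, row in wx.iterrows():
        card = scoring.score_individual(
            row["example_id"],
            {"16": row["as_16"], "10": row["as_10"], "high": row["as_high"]},
        )
        expected = (row["score_16"], row["score_10"], row["score_high"], row["total"])
        got = (card.score_16, card.score_10, card.score_high, card.total)
        if expected != got or card.phenotype != row["phenotype"]:
            raise AssertionError(f"worked example {row['example_id']} disagrees: {got}")
    p = root / "worked_examples.csv"
    with open(p, "w", encoding="utf-8", newline="") as fh:
        wx.to_csv(fh, index=False)
    manifest["worked_examples.csv"] = _sha256(p)

    return FixtureSet(name="aeroscope-fixtures", seed=7, root=root, manifest=manifest)
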