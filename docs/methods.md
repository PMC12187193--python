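# Methods

## Scope and data model

The package analyses intermittent-flow respirometry of individual fish
measured repeatedly across treatment temperatures (10, 16, 21 and/or 24 °C,
with 16 °C the acclimation/optimum anchor). One *trace* is a timestamped
oxygen-concentration series (mg l⁻¹) for one individual at one temperature,
with phase labels (`measure`, `flush`, `recovery`, `empty`) and chamber
metadata (volume `Vre`, fish mass `W`, displacement volume `M`; fish density
is taken as 1 kg l⁻¹, so `M` in litres equals mass in kilograms). The
canonical internal rate unit is mg O2 kg⁻¹ h⁻¹; reported indices default to
the per-minute scale because the packaged classification cutoffs are
expressed on it, and cutoffs are always interpreted on whatever scale the
indices are reported in.

## Trace processing

- **Segmentation** is label-driven: one measurement cycle per maximal
  contiguous run of closed-phase samples. A schedule fallback
  (`measure_s`, `flush_s`) reconstructs cycles for unlabeled exports; it
  assumes the protocol clock starts at the first sample.
- **Slope fitting** is ordinary least squares of concentration on time in
  minutes, after excluding the first 60 s of each cycle (sensor settling and
  mixing). Cycles with fewer than 3 retained samples are unusable, which is
  distinct from failing quality control. R² is the squared Pearson
  correlation; for a zero-variance response R² is defined as 0, so constant
  traces fail the filter rather than passing it vacuously — the conservative
  convention where the definition is otherwise ambiguous.
- **Quality filter**: fits with R² strictly greater than 0.9 survive; the
  discard count is logged per individual × temperature.
- **Background**: one fishless trace per temperature batch is fitted over
  its full window (same initial exclusion, uniform treatment) and its slope
  is applied to all animal cycles of that batch; no time interpolation of
  background growth is attempted.
- **Rate equation**: slopes enter as magnitudes of decline, so consuming
  fish yield positive rates; when the background term exceeds the animal
  signal the negative rate is emitted with a flag, never clamped or dropped.

## Corrections and reduction

- **Temperature.** Rates are multiplied by the Boltzmann–Arrhenius factor
  `e^(−E/kT)` with E = 0.63 eV (average ectotherm activation energy) and
  k = 8.617333 × 10⁻⁵ eV K⁻¹. The factor is implemented literally as
  printed; its absolute scale (~10⁻¹¹) is irrelevant because it is used
  solely to de-trend temperature before the mass regression and never
  persists into reported values. The conventional reference-normalized form
  `e^((E/k)(1/T − 1/Tref))` is available (`boltzmann_mode`).
- **Mass.** The allometric exponent `a` is the OLS slope of ln(rate) on
  ln(mass); reported SMR/MMR are raw (not temperature-scaled) rates divided
  by `M^a`, following the printed equation. Two estimation choices are
  deliberate deviations from a naive pooled regression:
  1. *Stratum intercepts.* The cohort-level slope is estimated after
     demeaning both logs within (rate kind × temperature) strata. A naive
     pooled fit regresses through the ~6-fold level gap between SMR and MMR
     and the temperature spread, which dwarfs the mass signal and makes the
     slope estimate effectively noise (SD ≈ 0.5 on realistic cohorts);
     stratum demeaning recovers the usual common-slope ANCOVA estimate.
  2. *SMR records only* (`alpha_rate_kinds=("smr",)` by default). MMR
     carries the designed between-individual phenotype heterogeneity
     (2–3-fold), which within a stratum is pure noise around the mass trend;
     allometry is classically estimated on resting rates for exactly this
     reason. Pooling both kinds remains available.
- **Reduction.** SMR is the q = 0.2 quantile of the day's cycle rates,
  computed by linear interpolation of order statistics at rank h = q(n−1)
  (the phrase "quantile of the lowest 20%" is ambiguous; the mean of the
  lowest 20% is exposed as `smr_method="mean_lowest_20"`). Fewer than 5
  usable cycles sets a `sparse_cycles` flag. MMR is the single highest
  recovery-cycle rate; AS = MMR − SMR, negative values flagged.

## Classification

Per-temperature cutoffs at the 25th/50th/75th percentiles of the species'
AS range assign 1–4 points (lower-inclusive bands: a value exactly at a
cutoff takes the higher score, keeping the map monotone, total and
deterministic). The packaged cutoff rows are exactly evenly spaced, i.e.
each is the linear interpolation of an implied (min, max) AS range, and
`cutoffs_from_range` regenerates them; empirical-quantile cutoffs from
cohort data are an exposed alternative, with provenance recorded. The 21 °C
and 24 °C treatments share one pooled cutoff row, and each individual
contributes exactly one warm-treatment score. Totals over exactly three
temperatures (no imputation) classify as low (≤ 5), intermediate (6–9) or
high (≥ 10); the edges are the 25th/75th percentiles of the achievable
interval [3, 12] (5.25 and 9.75, rounded half-up to 5 and 10). Cohort
percentages are rounded half-up to integer percent.

## Synthetic cohorts

Each simulated individual carries a known thermal performance curve:

- SMR(T) = `smr_ref` · Q10^((T−16)/10) — standard ectotherm kinetics
  anchored at the 16 °C acclimation temperature (default Q10 ≈ 2);
- MMR(T) = `mmr_peak` · exp(−(T − t_opt)²/(2·breadth²)) — a unimodal
  Gaussian peak, the simplest form producing realistic unimodal AS curves.

During a closed phase the concentration declines by the closed-form time
integral of the instantaneous rate times `W/((Vre−M))`, plus microbial
background; noiseless traces are therefore exact to machine precision and
oxygen is conserved within each phase. The 24-h SMR protocol modulates the
instantaneous rate sinusoidally with a diel period (fractional amplitude
`circadian_amp`); the post-chase recovery protocol decays exponentially from
MMR toward SMR with time constant `tau_recovery_s` and begins at chamber
re-entry (the chase itself happens outside the chamber and is not
simulated). Flushes restore saturation instantaneously — the pipeline reads
only closed phases, so intra-flush dynamics are irrelevant. Sensor noise is
i.i.d. Gaussian on concentration; configurations whose noiseless
concentration would cross 0 mg l⁻¹ within a closed phase are rejected as
physically implausible. True AS may be negative at extreme temperatures and
is emitted as-is so downstream edge handling is exercised.

### Default draw ranges (the simulated study conditions)

Chosen once to emulate the study system — a ~1 kg temperate sparid in a
29.72-l chamber — and the trait structure the classification is designed to
detect:

| parameter | default draw | rationale |
|---|---|---|
| mass | U(0.9, 1.3) kg | chamber:fish ratio 23–33 ml g⁻¹, within the protocol's 20–70 envelope |
| smr_ref | U(56, 64) mg kg⁻¹ h⁻¹ | ≈ 1 per-minute unit at 16 °C, coherent with the cutoff table |
| Q10 | U(1.8, 2.2) | typical ectotherm temperature sensitivity |
| circadian amplitude | U(0.05, 0.10) | mild diel modulation of SMR |
| tau_recovery | U(2400, 4800) s | 40–80 min excess-consumption decay; recovery "stabilizes near SMR" within ~5 h |
| high archetype | mmr_peak U(432, 468), t_opt U(16, 17.5), breadth U(10, 11) °C | high scope over a broad window |
| intermediate | mmr_peak U(312, 348), t_opt U(15.5, 17), breadth U(6.5, 7.5) °C | between the extremes |
| low archetype | mmr_peak U(212, 232), t_opt U(15.5, 16.5), breadth U(3.5, 4.5) °C | low peak, narrow window |
| mass exponent | −0.2 about 1.1 kg | mild negative allometry of mass-specific rates, giving the regression a real signal |

Under these draws the cohort's true AS at 16 °C spans a 2–3-fold range
across individuals (checked empirically over 1000 draws); the ratio is
defined at the acclimation temperature because pooling across extreme
temperatures is unbounded by design (low performers' scope approaches zero
outside their window). Each archetype's true AS triple falls in the cutoff
bands that classify it correctly with margins of several percent, so
classification recovery is a genuine whole-chain test rather than a
tautology.

### Benchmark configurations

- **Golden / noisy fixtures** (shortened protocol, coarse sampling): fix the
  SMR baseline across fish and use a slow recovery decay so the noiseless
  cohort recovers the planted allometric exponent exactly; the noisy variant
  (0.008 mg l⁻¹ at 20-s sampling) exercises the R² filter while keeping all
  nine fish classifiable.
- **Parameter-recovery cohort** (9 fish, full-length protocol): circadian
  modulation off, tau = 6 h so the within-cycle decay bias on MMR is < 1%,
  masses 1.25–1.45 kg so the weakest cold-treatment declines stay above the
  0.01 mg l⁻¹ noise floor, and a slightly widened low-archetype window so
  true scope stays positive everywhere (a max-rate MMR estimator cannot read
  below the recovery floor; negative scope is a flagged edge path, not a
  recovery benchmark). Recovery is assessed on the *measured*
  (pre-mass-normalization) rates: the normalized values divide by `M^â`
  with a cohort-level estimate `â`, which would conflate slope-estimation
  noise with trace-processing error.
- **Re-classification cohort** (44 fish drawn 8/24/12 at 0.005 mg l⁻¹
  noise): the whole-chain benchmark; the default pipeline re-classifies it
  to the drawn proportions.

## What the simulations do and do not show

The generator reproduces the features the pipeline is sensitive to: linear
within-cycle declines set by rate, mass and chamber geometry; background
respiration; diel SMR modulation; exponential post-chase recovery;
between-individual heterogeneity; sensor noise. It does not emulate
autocorrelated sensor drift, activity bursts within the chamber, incomplete
flushes, temperature ramping transients, or digestion effects — passing
recovery tests therefore demonstrates correctness of the processing chain,
not robustness of the protocol to every field artifact. Fixture regeneration
identity is byte-level and relies on seeded numpy generators and shortest
round-trip float formatting (trace reading uses pandas'
`float_precision="round_trip"`).

## Numerical and edge conventions

- Quantiles everywhere use linear interpolation at h = q(n−1) (numpy's
  default), making the SMR reducer and empirical cutoffs consistent.
- R² of a zero-variance cycle is 0; a cycle with < 3 retained points is
  unusable; both are counted as discards.
- Boundary AS values score into the higher band; class edges are closed on
  the low side (≤ 5 low, ≥ 10 high).
- Individuals with incomplete temperature coverage are flagged and excluded
  from classification, never imputed.
- Percentages round half-up; totals outside [3, 12] and non-finite AS raise
  errors rather than propagating.
- All randomness flows from explicit integer seeds; identical (config, seed)
  produce byte-identical output files.

## Known limitations

- The MMR estimate inherits the within-cycle decay bias bounded by
  `e^(−measure_s/tau)`; with fast recovery (small tau) MMR is
  underestimated by up to ~7% under the default draws. This is a property of
  the max-rate estimator on cycle-averaged data, shared with the field
  protocol itself.
- The circadian trough pulls the 0.2-quantile SMR a few percent below the
  diel mean; the quantile is the protocol's definition of SMR, so this is
  reported, not corrected.
- The allometric exponent is a cohort-level constant; per-individual
  allometry is not identifiable from one mass per fish.
- Classification cutoffs are packaged constants for one species/protocol;
  other systems should derive cutoffs from their own AS ranges
  (`cutoffs_from_range` / `cutoffs_empirical`).
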