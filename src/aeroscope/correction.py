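"""Temperature and body-mass standardization of metabolic rates, and the
reduction of per-cycle rates to SMR, MMR and aerobic scope.

Temperature: rates are scaled by the Boltzmann-Arrhenius factor
``exp(-E / (k T))`` with the average ectotherm activation energy
E = 0.63 eV and k = 8.617333e-5 eV/K. The literal factor is minute in
absolute terms (~1e-11); only its ratio across temperatures matters, and in
this package it serves purely to de-trend temperature before the allometric
mass regression. The conventional reference-normalized form
``exp((E/k) (1/T - 1/Tref))`` is available as ``mode="reference_normalized"``.

Mass: the allometric exponent a is the OLS slope of ln(rate) on ln(mass);
the corrected rate is ``rate / mass**a``. Because mass-specific SMR and MMR
sit at very different levels, the default cohort-level estimate supports
stratum intercepts (demeaning within rate-kind x temperature strata) so the
level gaps do not swamp the mass signal.

Reduction: SMR is the 0.2 quantile of a day's cycle rates (linear
interpolation at rank h = q(n-1); the mean of the lowest 20% is exposed as
an alternative), MMR is the single highest post-chase recovery rate, and
aerobic scope is their difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrectionConstants",
    "MassScaling",
    "MetabolicIndices",
    "boltzmann_correct",
    "estimate_mass_exponent",
    "mass_correct",
    "smr_from_records",
    "mmr_from_records",
    "aerobic_scope",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class CorrectionConstants:
    activation_energy_ev: float = 0.63
    boltzmann_ev_per_k: float = 8.617333e-5
    celsius_to_kelvin_offset: float = 273.15

    def __post_init__(self) -> None:
        if not (self.activation_energy_ev >= 0 and self.boltzmann_ev_per_k > 0):
            raise ValueError("require E >= 0 and k > 0")


DEFAULT_CONSTANTS = CorrectionConstants()


@dataclass(frozen=True)
class MassScaling:
    """Allometric exponent from the ln-ln regression."""

    alpha: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if self.n < 2:
            raise ValueError("need at least 2 records")


@dataclass
class MetabolicIndices:
    """Per individual x temperature metabolic summary, on a common unit scale."""

    individual_id: str
    treatment_temp_c: float
    smr: float
    mmr: float
    aerobic_scope: float
    n_cycles_used: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isclose(self.aerobic_scope, self.mmr - self.smr, rtol=0, atol=1e-9):
            raise ValueError("aerobic_scope must equal mmr - smr")


def boltzmann_correct(
    ro2_raw,
    temp_c,
    constants: CorrectionConstants = DEFAULT_CONSTANTS,
    mode: str = "literal",
    t_ref_c: float = 16.0,
):
    """Temperature-scale a rate (scalar or array).

    ``mode="literal"``: rate * exp(-E/(kT)).
    ``mode="reference_normalized"``: rate * exp((E/k)(1/T - 1/Tref)), which
    equals 1 at the reference temperature and preserves the rate's scale.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c <= -constants.celsius_to_kelvin_offset):
        raise ValueError("temperature at or below absolute zero")
    t_k = temp_c + constants.celsius_to_kelvin_offset
    e_over_k = constants.activation_energy_ev / constants.boltzmann_ev_per_k
    if mode == "literal":
        factor = np.exp(-e_over_k / t_k)
    elif mode == "reference_normalized":
        t_ref_k = t_ref_c + constants.celsius_to_kelvin_offset
        factor = np.exp(e_over_k * (1.0 / t_k - 1.0 / t_ref_k))
    else:
        raise ValueError(f"unknown boltzmann mode {mode!r}")
    out = np.asarray(ro2_raw, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def estimate_mass_exponent(rates, masses, strata=None) -> MassScaling:
    """Allometric exponent: OLS slope of ln(rate) on ln(mass).

    With ``strata`` (a sequence of hashable labels, one per record) the slope
    is the common within-stratum slope — both logs are demeaned within each
    stratum before the regression — so rate-kind and temperature level
    differences do not contaminate the mass signal. Requires >= 2 distinct
    masses and strictly positive rates and masses.
    """
    rates = np.asarray(rates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if rates.shape != masses.shape or rates.ndim != 1:
        raise ValueError("rates and masses must be 1-d and equal length")
    if len(rates) < 2:
        raise ValueError("need at least 2 records")
    if np.any(rates <= 0) or np.any(masses <= 0):
        raise ValueError("rates and masses must be positive for the ln-ln fit")
    if np.unique(masses).size < 2:
        raise ValueError("allometric slope undefined: all masses identical")
    ln_m = np.log(masses)
    ln_r = np.log(rates)
    if strata is not None:
        strata = np.asarray(strata, dtype=object)
        if strata.shape != rates.shape:
            raise ValueError("strata must match records in length")
        for lab in np.unique(strata.astype(str)):
            sel = strata.astype(str) == lab
            ln_m[sel] = ln_m[sel] - ln_m[sel].mean()
            ln_r[sel] = ln_r[sel] - ln_r[sel].mean()
        if np.allclose(ln_m, 0.0):
            raise ValueError("no within-stratum mass variation")
    fit = stats.linregress(ln_m, ln_r)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return MassScaling(alpha=float(fit.slope), r_squared=r2, n=int(len(rates)))


def mass_correct(ro2_raw, mass_kg, scaling) -> float:
    """Mass-normalized rate ``rate / mass**a`` (applied to raw, not
    temperature-scaled, rates)."""
    if np.any(np.asarray(mass_kg, dtype=float) <= 0):
        raise ValueError("mass must be > 0")
    alpha = scaling.alpha if isinstance(scaling, MassScaling) else float(scaling)
    out = np.asarray(ro2_raw, dtype=float) / np.asarray(mass_kg, dtype=float) ** alpha
    return float(out) if out.ndim == 0 else out


def _rates(records) -> np.ndarray:
    vals = [r.ro2_raw if hasattr(r, "ro2_raw") else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def smr_from_records(records, method: str = "quantile_0.2") -> float:
    """SMR from one individual x temperature's cycle rates.

    Default: the 0.2 quantile (linear interpolation of order statistics at
    rank h = 0.2 (n-1)). ``method="mean_lowest_20"`` averages the smallest
    ceil(0.2 n) records instead. At least one record is required; fewer than
    5 is statistically thin and callers should flag it.
    """
    vals = _rates(records)
    if len(vals) == 0:
        raise ValueError("no records to estimate SMR from")
    if method == "quantile_0.2":
        return float(np.quantile(vals, 0.2))
    if method == "mean_lowest_20":
        k = max(1, int(np.ceil(0.2 * len(vals))))
        return float(np.mean(np.sort(vals)[:k]))
    raise ValueError(f"unknown SMR method {method!r}")


def mmr_from_records(records) -> float:
    """MMR: the single highest rate over the post-chase recovery window."""
    vals = _rates(records)
    if len(vals) == 0:
        raise ValueError("no records to estimate MMR from")
    return float(np.max(vals))


def aerobic_scope(smr: float, mmr: float) -> float:
    """Aerobic scope = MMR - SMR. May be negative (flagged by callers)."""
    if not (np.isfinite(smr) and np.isfinite(mmr)):
        raise ValueError("SMR and MMR must be finite")
    return float(mmr - smr)
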