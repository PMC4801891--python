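"""delta-13C arithmetic, carbonate speciation and 13C-tracer mass balance.

Converts instrument-referenced delta values to the VPDB scale, interconverts
delta notation with absolute 13C atom fractions, turns headspace mole
fractions into per-bottle gas amounts, and assembles the fate budget of an
injected 13C-bicarbonate label across the CH4, headspace-CO2 and residual
bicarbonate pools (amount, percentage of detected, recovery of injected).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "R_VPDB",
    "DeltaValue",
    "InstrumentCalibration",
    "TreatmentConfig",
    "CarbonateSystem",
    "SpeciationResult",
    "IsotopeFateRow",
    "chain_delta_to_vpdb",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "headspace_amount",
    "carbonate_speciation",
    "labeled_amount",
    "total_injected_13c",
    "fate_table",
    "fate_frame",
    "two_pool_mixing",
]

logger = logging.getLogger(__name__)

#: 13C/12C ratio of the VPDB standard (Craig value as commonly used; the
#: alternative 0.011237 can be passed explicitly to the converters).
R_VPDB = 0.0111802

#: Ideal-gas constant in L atm mol^-1 K^-1.
_R_L_ATM = 8.314462 / 101.325


@dataclass(frozen=True)
class DeltaValue:
    """A delta-13C measurement in permil against a named reference."""

    value: float
    reference: str = "VPDB"

    def __post_init__(self) -> None:
        if self.value <= -1000:
            raise ValueError("delta below -1000 permil implies a non-positive ratio")


@dataclass(frozen=True)
class InstrumentCalibration:
    """delta-13C of the instrument reference gas on the VPDB scale."""

    reference_gas_delta_vpdb: float = -23.73

    def __post_init__(self) -> None:
        if not (-1000 < self.reference_gas_delta_vpdb < 1000):
            raise ValueError("reference gas delta outside (-1000, 1000) permil")


@dataclass(frozen=True)
class TreatmentConfig:
    """One incubation treatment: label dose, medium volume and conditions."""

    label: str
    bicarbonate_mM: float
    formate_mM: float = 10.0
    label_atom_fraction: float = 1.0
    liquid_volume_mL: float = 50.0
    bottle_volume_mL: float = 120.0
    temperature_C: float = 55.0
    pH: float = 7.2
    headspace_pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.bottle_volume_mL > self.liquid_volume_mL > 0):
            raise ValueError("need bottle_volume_mL > liquid_volume_mL > 0")
        if not (0 < self.label_atom_fraction <= 1):
            raise ValueError("label_atom_fraction must lie in (0, 1]")

    @property
    def headspace_volume_mL(self) -> float:
        return self.bottle_volume_mL - self.liquid_volume_mL

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


@dataclass(frozen=True)
class CarbonateSystem:
    """Carbonate equilibrium constants used to split DIC into its species.

    Defaults are round-number values appropriate near 55 C; all are
    overridable and the values used are logged by the pipeline.
    """

    temperature_C: float = 55.0
    pH: float = 7.2
    henry_constant: float = 0.0182  # mol L^-1 atm^-1 for CO2
    pK1: float = 6.30
    pK2: float = 10.3

    def __post_init__(self) -> None:
        if self.pK1 >= self.pK2:
            raise ValueError("pK1 must be below pK2")
        if self.henry_constant <= 0:
            raise ValueError("Henry constant must be positive")


@dataclass(frozen=True)
class SpeciationResult:
    """Fractions of the aqueous DIC pool, plus the gas/liquid split of CO2."""

    co2_aq: float
    hco3: float
    co3: float
    gas_fraction: float | None = None  # fraction of (CO2 gas + all DIC) in gas

    @property
    def aqueous_fractions(self) -> tuple[float, float, float]:
        return (self.co2_aq, self.hco3, self.co3)


def chain_delta_to_vpdb(
    sample_vs_reference: DeltaValue | float,
    calibration: InstrumentCalibration = InstrumentCalibration(),
) -> DeltaValue:
    """Chain a delta measured against the instrument reference gas to VPDB.

    Exact chaining: d_s/VPDB = d_s/ref + d_ref/VPDB + d_s/ref * d_ref/VPDB / 1000.
    """
    d_sr = sample_vs_reference.value if isinstance(sample_vs_reference, DeltaValue) else float(sample_vs_reference)
    d_rv = calibration.reference_gas_delta_vpdb
    chained = d_sr + d_rv + d_sr * d_rv / 1000.0
    return DeltaValue(chained, "VPDB")


def delta_to_atom_fraction(delta_vpdb: DeltaValue | float, r_standard: float = R_VPDB) -> float:
    """Absolute 13C atom fraction F from a delta value on the VPDB scale.

    R = R_std * (1 + delta/1000); F = R / (1 + R).
    """
    d = delta_vpdb.value if isinstance(delta_vpdb, DeltaValue) else float(delta_vpdb)
    if d <= -1000:
        raise ValueError("delta below -1000 permil")
    r = r_standard * (1.0 + d / 1000.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(atom_fraction: float, r_standard: float = R_VPDB) -> float:
    """Inverse of :func:`delta_to_atom_fraction` (permil vs VPDB)."""
    if not (0 < atom_fraction < 1):
        raise ValueError("atom fraction must lie in (0, 1)")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / r_standard - 1.0) * 1000.0


def headspace_amount(bottle: TreatmentConfig, mole_fraction: float) -> float:
    """Micromoles of a gas in the bottle headspace from its mole fraction.

    Ideal gas at the configured headspace pressure and incubation
    temperature; headspace volume = bottle volume - liquid volume.
    """
    if not (0 <= mole_fraction <= 1):
        raise ValueError("mole fraction must lie in [0, 1]")
    v_l = bottle.headspace_volume_mL / 1000.0
    n_total_mol = bottle.headspace_pressure_atm * v_l / (_R_L_ATM * bottle.temperature_K)
    return n_total_mol * mole_fraction * 1e6


def carbonate_speciation(
    system: CarbonateSystem,
    liquid_volume_mL: float | None = None,
    headspace_volume_mL: float | None = None,
) -> SpeciationResult:
    """Split DIC into CO2(aq), HCO3- and CO3^2- at the system's pH.

    Henderson-Hasselbalch with the system's two pKa values; the three
    aqueous fractions sum to one.  If phase volumes are given, the Henry
    constant additionally yields the fraction of total carbonate carbon
    (gaseous CO2 + DIC) residing in the gas phase at equilibrium.
    """
    a1 = 10.0 ** (system.pH - system.pK1)  # [HCO3-]/[CO2(aq)]
    a2 = 10.0 ** (system.pH - system.pK2)  # [CO3--]/[HCO3-]
    denom = 1.0 + a1 + a1 * a2
    co2_aq = 1.0 / denom
    hco3 = a1 / denom
    co3 = a1 * a2 / denom
    gas_fraction = None
    if liquid_volume_mL is not None and headspace_volume_mL is not None:
        t_k = system.temperature_C + 273.15
        # mol of gas-phase CO2 per (mol/L of CO2(aq)):  V_g / (KH * R * T)
        v_liq = liquid_volume_mL / 1000.0
        v_gas = headspace_volume_mL / 1000.0
        gas_per_co2aq_conc = v_gas / (_R_L_ATM * t_k) / system.henry_constant
        aq_per_co2aq_conc = v_liq * denom  # all DIC species
        gas_fraction = gas_per_co2aq_conc / (gas_per_co2aq_conc + aq_per_co2aq_conc)
    return SpeciationResult(co2_aq, hco3, co3, gas_fraction)


def labeled_amount(pool_total_umol: float, atom_fraction: float) -> float:
    """Micromoles of 13C in a carbon pool of given size and atom fraction."""
    if pool_total_umol < 0 or atom_fraction < 0:
        raise ValueError("pool size and atom fraction must be nonnegative")
    return pool_total_umol * atom_fraction


def total_injected_13c(config: TreatmentConfig) -> float:
    """Micromoles of 13C injected as labeled bicarbonate.

    bicarbonate (mM) x liquid volume (mL) x label purity; mM x mL = umol.
    """
    return config.bicarbonate_mM * config.liquid_volume_mL * config.label_atom_fraction


@dataclass(frozen=True)
class IsotopeFateRow:
    """One treatment's 13C budget: pools, percentages of detected, recovery."""

    label: str
    total_13c_umol: float
    ch4_13c_umol: float
    co2_13c_umol: float
    bicarbonate_13c_umol: float
    detected_13c_umol: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.total_13c_umol <= 0:
            raise ValueError("total injected 13C must be positive")
        pools = (self.ch4_13c_umol, self.co2_13c_umol, self.bicarbonate_13c_umol)
        if any(p < 0 for p in pools):
            raise ValueError("pool amounts must be nonnegative")
        object.__setattr__(self, "detected_13c_umol", sum(pools))
        object.__setattr__(self, "degenerate", self.detected_13c_umol == 0)
        if self.recovery_fraction > 1 + 1e-9:
            warnings.warn(
                f"{self.label}: detected 13C exceeds injected "
                f"(recovery {self.recovery_fraction:.3f})",
                stacklevel=2,
            )

    def _pct(self, pool: float) -> float:
        if self.degenerate:
            return math.nan
        # half-even at 2 decimals, the table's printed precision
        return round(100.0 * pool / self.detected_13c_umol, 2)

    @property
    def ch4_pct(self) -> float:
        return self._pct(self.ch4_13c_umol)

    @property
    def co2_pct(self) -> float:
        return self._pct(self.co2_13c_umol)

    @property
    def bicarbonate_pct(self) -> float:
        return self._pct(self.bicarbonate_13c_umol)

    @property
    def recovery_fraction(self) -> float:
        return self.detected_13c_umol / self.total_13c_umol


def fate_table(
    pools: tuple[float, float, float],
    total: float,
    label: str = "",
) -> IsotopeFateRow:
    """Assemble a 13C fate budget row from (CH4, CO2, bicarbonate) pools.

    ``detected`` is the exact sum of the three pools; percentages are of the
    detected total; recovery is detected / injected.
    """
    ch4, co2, bic = pools
    return IsotopeFateRow(label, total, ch4, co2, bic)


def fate_frame(rows: list[IsotopeFateRow]) -> pd.DataFrame:
    """Tabulate fate rows (one treatment per row) as a DataFrame."""
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "total_13c_umol": [r.total_13c_umol for r in rows],
            "detected_13c_umol": [r.detected_13c_umol for r in rows],
            "ch4_13c_umol": [r.ch4_13c_umol for r in rows],
            "ch4_pct": [r.ch4_pct for r in rows],
            "co2_13c_umol": [r.co2_13c_umol for r in rows],
            "co2_pct": [r.co2_pct for r in rows],
            "bicarbonate_13c_umol": [r.bicarbonate_13c_umol for r in rows],
            "bicarbonate_pct": [r.bicarbonate_pct for r in rows],
            "recovery_fraction": [r.recovery_fraction for r in rows],
        }
    )


def two_pool_mixing(
    delta_sample: DeltaValue | float,
    delta_source_a: DeltaValue | float,
    delta_source_b: DeltaValue | float,
) -> float:
    """Fraction of carbon from source A in a two-endmember mixture.

    Mixing is linear in atom-fraction space (exact for amounts of 13C), so
    the apportionment is computed there rather than in permil.  The result
    is not clamped; values outside [0, 1] trigger a warning.
    """
    f_s = delta_to_atom_fraction(delta_sample)
    f_a = delta_to_atom_fraction(delta_source_a)
    f_b = delta_to_atom_fraction(delta_source_b)
    if f_a == f_b:
        raise ValueError("degenerate endmembers: sources have equal composition")
    frac = (f_s - f_b) / (f_a - f_b)
    if not (0 <= frac <= 1):
        warnings.warn(f"mixing fraction {frac:.4f} outside [0, 1]", stacklevel=2)
    return frac
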