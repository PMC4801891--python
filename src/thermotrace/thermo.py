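"""Gibbs-energy calculations for anaerobic formate/H2 reactions.

Implements the standard bioenergetics workflow for a methanogenic enrichment:

* ``standard_gibbs_at_temperature`` -- dG0(T) from tabulated anchor values,
  linear in T between anchors (constant dH0/dS0 approximation);
* ``transformed_standard_gibbs`` -- dG0'(T), the pH-transformed standard value,
  obtained by moving H+ out of the reaction quotient at a fixed pH;
* ``actual_gibbs`` -- dG'(T) = dG0'(T) + R*T*ln(Q) under stated concentrations
  and partial pressures;
* ``bicarbonate_sweep`` / ``threshold_concentration`` -- feasibility analysis
  as one species' activity varies, all else fixed.

Conventions (deliberate, documented in docs/methods.md): activities are molar
concentrations for aqueous solutes, partial pressures in atm for gases, and 1
for liquid water; H+ never enters Q -- all pH dependence lives in the
transform; no ionic-strength correction is applied.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "GAS_CONSTANT_KJ",
    "ChemicalSpecies",
    "Reaction",
    "ReactionConditions",
    "GibbsResult",
    "ValidationReport",
    "parse_species_token",
    "validate_reaction",
    "standard_gibbs_at_temperature",
    "transformed_standard_gibbs",
    "reaction_quotient",
    "actual_gibbs",
    "bicarbonate_sweep",
    "threshold_concentration",
    "load_reaction_library",
]

logger = logging.getLogger(__name__)

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.314462e-3

#: Default floor applied to nominally zero aqueous concentrations (mol/L),
#: so that a "0 mM bicarbonate" treatment can still be evaluated.
CONCENTRATION_FLOOR = 1e-6

# charge written as repeated trailing signs ("CO3--"), never digit+sign,
# which would be ambiguous against trailing element counts ("HCO3-")
_TOKEN_RE = re.compile(r"^(?P<formula>(?:[A-Z][a-z]?\d*)+)(?P<charge>[+-]+)?$")
_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

# Species treated as gas-phase by default when parsed from a bare token.
_DEFAULT_GAS = {"H2", "CH4", "CO2", "N2", "CO"}


class SpeciesParseError(ValueError):
    """Raised when a chemical species token cannot be parsed."""


def _parse_formula(formula: str) -> dict[str, int]:
    pos = 0
    counts: dict[str, int] = {}
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise SpeciesParseError(f"malformed species token: {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise SpeciesParseError(f"malformed species token: {formula!r}")
    return counts


def parse_species_token(token: str) -> tuple[dict[str, int], int]:
    """Parse e.g. ``"HCO3-"`` into element counts and a signed charge.

    Charges are written as trailing repeated signs: ``H+``, ``HCO3-``,
    ``CO3--`` (charge -2).
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise SpeciesParseError(f"malformed species token: {token!r}")
    counts = _parse_formula(m.group("formula"))
    charge_s = m.group("charge")
    charge = 0
    if charge_s:
        if len(set(charge_s)) > 1:
            raise SpeciesParseError(f"malformed species token: {token!r}")
        charge = len(charge_s) * (1 if charge_s[0] == "+" else -1)
    return counts, charge


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with elemental composition, phase and charge."""

    identifier: str
    phase: str  # "aqueous" | "gas" | "liquid-water"
    composition: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.phase not in {"aqueous", "gas", "liquid-water"}:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "liquid-water" and self.identifier != "H2O":
            raise ValueError("liquid-water phase is reserved for H2O")
        if self.carbon_atoms < 0:
            raise ValueError("negative carbon count")

    @property
    def carbon_atoms(self) -> int:
        return self.composition.get("C", 0)

    @classmethod
    def from_token(cls, token: str, phase: str | None = None) -> "ChemicalSpecies":
        composition, charge = parse_species_token(token)
        if phase is None:
            if token == "H2O":
                phase = "liquid-water"
            elif token in _DEFAULT_GAS:
                phase = "gas"
            else:
                phase = "aqueous"
        return cls(token, phase, composition, charge)


@dataclass(frozen=True)
class Reaction:
    """A named reaction: signed stoichiometry plus standard-Gibbs anchors.

    ``stoichiometry`` maps species tokens to signed coefficients (negative =
    reactant, positive = product).  ``anchors`` is a list of
    ``(temperature_K, dG0_kJ_per_mol)`` pairs with strictly increasing
    temperatures.
    """

    name: str
    stoichiometry: Mapping[str, float]
    anchors: Sequence[tuple[float, float]]
    species: Mapping[str, ChemicalSpecies] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError("empty stoichiometry")
        if not self.anchors:
            raise ValueError("at least one Gibbs anchor is required")
        temps = [t for t, _ in self.anchors]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("anchor temperatures must be strictly increasing")
        if self.species is None:
            parsed = {tok: ChemicalSpecies.from_token(tok) for tok in self.stoichiometry}
            object.__setattr__(self, "species", parsed)

    @property
    def proton_consumption(self) -> float:
        """Net protons consumed (reactant-side minus product-side)."""
        return -self.stoichiometry.get("H+", 0.0)

    def coefficient(self, token: str) -> float:
        return self.stoichiometry.get(token, 0.0)


@dataclass(frozen=True)
class ReactionConditions:
    """Temperature, pH and activity map under which dG' is evaluated.

    Activities: mol/L for aqueous solutes, atm for gas partial pressures,
    1 (implicit) for liquid water.
    """

    temperature_k: float
    ph: float
    activities: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (K)")
        if not (0 < self.ph < 14):
            raise ValueError("pH must lie in (0, 14)")
        for tok, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {tok!r} must be positive, got {a}")

    def with_activity(self, token: str, value: float) -> "ReactionConditions":
        acts = dict(self.activities)
        acts[token] = value
        return ReactionConditions(self.temperature_k, self.ph, acts)


@dataclass(frozen=True)
class GibbsResult:
    """Standard, pH-transformed and concentration-corrected Gibbs energies."""

    reaction_name: str
    standard: float  # dG0_T, kJ/mol
    transformed: float  # dG0'_T, kJ/mol
    actual: float  # dG'_T, kJ/mol

    @property
    def exergonic(self) -> bool:
        return self.actual < 0


@dataclass(frozen=True)
class ValidationReport:
    reaction_name: str
    element_imbalance: Mapping[str, float]  # element -> signed atom sum
    charge_imbalance: float

    @property
    def balanced(self) -> bool:
        return (
            all(abs(v) < 1e-9 for v in self.element_imbalance.values())
            and abs(self.charge_imbalance) < 1e-9
        )


def validate_reaction(reaction: Reaction) -> ValidationReport:
    """Check element and charge balance of a reaction.

    Every element appearing in any participating species is checked; the
    report lists the signed atom sum per element (zero means balanced).
    """
    elements: set[str] = set()
    for sp in reaction.species.values():
        elements.update(sp.composition)
    imbalance = {
        el: sum(
            coeff * reaction.species[tok].composition.get(el, 0)
            for tok, coeff in reaction.stoichiometry.items()
        )
        for el in sorted(elements)
    }
    charge = sum(
        coeff * reaction.species[tok].charge for tok, coeff in reaction.stoichiometry.items()
    )
    return ValidationReport(reaction.name, imbalance, charge)


def standard_gibbs_at_temperature(reaction: Reaction, temperature_k: float) -> float:
    """dG0 at ``temperature_k`` by linear interpolation between anchors.

    Exactly reproduces anchor values at anchor temperatures.  Outside the
    anchor range the nearest segment is extrapolated linearly and a warning
    is logged; more than 20 K outside raises ``ValueError``.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (K)")
    temps = [t for t, _ in reaction.anchors]
    values = [g for _, g in reaction.anchors]
    if temperature_k < temps[0] - 20 or temperature_k > temps[-1] + 20:
        raise ValueError(
            f"T={temperature_k} K is more than 20 K outside the anchor range "
            f"[{temps[0]}, {temps[-1]}] of reaction {reaction.name!r}"
        )
    for t_a, g_a in reaction.anchors:  # anchor values are returned bit-for-bit
        if temperature_k == t_a:
            return g_a
    if len(temps) == 1:
        if temperature_k != temps[0]:
            logger.warning(
                "single-anchor reaction %s: returning anchor value for T=%s",
                reaction.name,
                temperature_k,
            )
        return values[0]
    if temperature_k < temps[0] or temperature_k > temps[-1]:
        logger.warning(
            "T=%s K outside anchors of %s; extrapolating linearly",
            temperature_k,
            reaction.name,
        )
    # piecewise-linear; np.interp would clamp at the ends, so do it by hand
    i = max(0, min(len(temps) - 2, _segment_index(temps, temperature_k)))
    t0, t1 = temps[i], temps[i + 1]
    g0, g1 = values[i], values[i + 1]
    return g0 + (g1 - g0) * (temperature_k - t0) / (t1 - t0)


def _segment_index(temps: Sequence[float], t: float) -> int:
    for i in range(len(temps) - 1):
        if t <= temps[i + 1]:
            return i
    return len(temps) - 2


def transformed_standard_gibbs(reaction: Reaction, temperature_k: float, ph: float) -> float:
    """pH-transformed standard Gibbs energy dG0'(T) in kJ/mol.

    dG0' = dG0(T) + nu_H+ * R * T * ln(10) * pH, where nu_H+ is the net
    number of protons consumed (reactant side minus product side).  A
    reaction with no net protons is returned unchanged.
    """
    g0 = standard_gibbs_at_temperature(reaction, temperature_k)
    nu = reaction.proton_consumption
    return g0 + nu * GAS_CONSTANT_KJ * temperature_k * math.log(10.0) * ph


def reaction_quotient(reaction: Reaction, conditions: ReactionConditions) -> float:
    """Reaction quotient Q = prod(products) / prod(reactants).

    H+ is excluded (its contribution lives in the pH transform) and liquid
    water has activity 1.  Raises ``KeyError`` naming any species whose
    activity is missing from the conditions.
    """
    log_q = 0.0
    for tok, coeff in reaction.stoichiometry.items():
        sp = reaction.species[tok]
        if tok == "H+" or sp.phase == "liquid-water":
            continue
        if tok not in conditions.activities:
            raise KeyError(
                f"no activity given for species {tok!r} of reaction {reaction.name!r}"
            )
        log_q += coeff * math.log(conditions.activities[tok])
    return math.exp(log_q)


def actual_gibbs(reaction: Reaction, conditions: ReactionConditions) -> GibbsResult:
    """Concentration-corrected Gibbs energy dG' = dG0' + R*T*ln(Q)."""
    t = conditions.temperature_k
    standard = standard_gibbs_at_temperature(reaction, t)
    transformed = transformed_standard_gibbs(reaction, t, conditions.ph)
    q = reaction_quotient(reaction, conditions)
    actual = transformed + GAS_CONSTANT_KJ * t * math.log(q)
    return GibbsResult(reaction.name, standard, transformed, actual)


def _floored(values: Iterable[float], floor: float) -> list[float]:
    out = []
    for v in values:
        if v < floor:
            logger.warning("concentration %g below floor; using %g mol/L", v, floor)
            out.append(floor)
        else:
            out.append(v)
    return out


def bicarbonate_sweep(
    reaction: Reaction,
    conditions: ReactionConditions,
    hco3_values: Sequence[float],
    species: str = "HCO3-",
    floor: float = CONCENTRATION_FLOOR,
) -> pd.DataFrame:
    """Evaluate dG' across a range of bicarbonate concentrations.

    Returns a DataFrame with columns
    ``reaction, temperature_K, pH, hco3_mol_per_L, dG_prime_kJ_per_mol``.
    Values below ``floor`` (default 1e-6 mol/L, covering a nominal 0 mM
    treatment) are raised to the floor with a logged warning.
    """
    if len(hco3_values) == 0:
        raise ValueError("hco3_values must be nonempty")
    rows = []
    for c in _floored(hco3_values, floor):
        res = actual_gibbs(reaction, conditions.with_activity(species, c))
        rows.append(
            {
                "reaction": reaction.name,
                "temperature_K": conditions.temperature_k,
                "pH": conditions.ph,
                "hco3_mol_per_L": c,
                "dG_prime_kJ_per_mol": res.actual,
            }
        )
    return pd.DataFrame(rows)


def threshold_concentration(
    reaction: Reaction, conditions: ReactionConditions, free_species: str
) -> float:
    """Activity of ``free_species`` at which dG' = 0, all else fixed.

    dG' is monotone in the log-activity of a single species, so the zero
    crossing has the closed form
    ``a* = current * exp(-dG'_current / (nu * R * T))``.
    """
    nu = reaction.coefficient(free_species)
    if nu == 0:
        raise ValueError(
            f"species {free_species!r} has zero coefficient in {reaction.name!r}"
        )
    res = actual_gibbs(reaction, conditions)
    current = conditions.activities[free_species]
    rt = GAS_CONSTANT_KJ * conditions.temperature_k
    return current * math.exp(-res.actual / (nu * rt))


def load_reaction_library(path: str | None = None) -> dict[str, Reaction]:
    """Load the shipped reaction library (or a user YAML of the same shape)."""
    if path is None:
        text = (
            resources.files("thermotrace.data").joinpath("reactions.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    library: dict[str, Reaction] = {}
    for name, spec in raw["reactions"].items():
        library[name] = Reaction(
            name=name,
            stoichiometry={k: float(v) for k, v in spec["stoichiometry"].items()},
            anchors=[(float(t), float(g)) for t, g in spec["anchors"]],
        )
    return library
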