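"""Gibbs-energy engine: balance checks, anchors, transforms, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotrace.thermo import (
    CONCENTRATION_FLOOR,
    GAS_CONSTANT_KJ,
    ChemicalSpecies,
    Reaction,
    ReactionConditions,
    SpeciesParseError,
    actual_gibbs,
    bicarbonate_sweep,
    parse_species_token,
    reaction_quotient,
    standard_gibbs_at_temperature,
    threshold_concentration,
    transformed_standard_gibbs,
    validate_reaction,
)

RT55 = GAS_CONSTANT_KJ * 328.15

ANCHORS = {
    "co2_reduction": (-175.32, -168.56, -124.58),
    "acetate_formation": (-139.69, -137.64, -93.66),
    "formate_methanogenesis": (-170.84, -172.51, -128.53),
    "formate_oxidation": (1.12, -0.92, -0.92),
}


class TestSpeciesParsing:
    @pytest.mark.parametrize(
        "token, composition, charge",
        [
            ("HCO3-", {"H": 1, "C": 1, "O": 3}, -1),
            ("CH3COO-", {"C": 2, "H": 3, "O": 2}, -1),
            ("H+", {"H": 1}, 1),
            ("H2O", {"H": 2, "O": 1}, 0),
            ("CO3--", {"C": 1, "O": 3}, -2),
        ],
    )
    def test_token_parsing(self, token, composition, charge):
        comp, q = parse_species_token(token)
        assert comp == composition and q == charge

    @pytest.mark.parametrize("bad", ["", "h2o", "X!", "-HCO3", "123"])
    def test_malformed_tokens_name_the_token(self, bad):
        with pytest.raises(SpeciesParseError):
            parse_species_token(bad)

    def test_water_phase_reserved(self):
        with pytest.raises(ValueError):
            ChemicalSpecies.from_token("CH4", phase="liquid-water")


class TestValidation:
    def test_all_library_reactions_balanced(self, library):
        for reaction in library.values():
            report = validate_reaction(reaction)
            assert report.balanced, (reaction.name, report)

    def test_identity_reaction_balanced(self):
        r = Reaction("identity", {"H2": 0.0}, [(298.15, 0.0)])
        # zero net stoichiometry is trivially balanced
        assert validate_reaction(r).balanced

    def test_unbalanced_reduction_without_reductant(self):
        r = Reaction("broken", {"HCO3-": -1.0, "CH4": 1.0}, [(298.15, 0.0)])
        report = validate_reaction(r)
        assert not report.balanced
        assert report.element_imbalance["H"] != 0
        assert report.element_imbalance["O"] != 0


class TestStandardGibbs:
    @pytest.mark.parametrize("name", list(ANCHORS))
    def test_exact_at_both_anchors(self, library, name):
        g25, g55, _ = ANCHORS[name]
        assert standard_gibbs_at_temperature(library[name], 298.15) == g25
        assert standard_gibbs_at_temperature(library[name], 328.15) == g55

    def test_linear_midpoint(self, library):
        mid = standard_gibbs_at_temperature(library["co2_reduction"], 313.15)
        assert mid == pytest.approx(-171.94, abs=1e-9)

    def test_domain_errors(self, library):
        with pytest.raises(ValueError):
            standard_gibbs_at_temperature(library["co2_reduction"], -5.0)
        with pytest.raises(ValueError):
            standard_gibbs_at_temperature(library["co2_reduction"], 400.0)


class TestTransformedGibbs:
    @pytest.mark.parametrize("name", list(ANCHORS))
    def test_matches_tabulated_ph7_column(self, library, name):
        expected = ANCHORS[name][2]
        got = transformed_standard_gibbs(library[name], 328.15, 7.0)
        assert got == pytest.approx(expected, abs=0.005)

    def test_no_proton_reaction_unchanged(self, library):
        r = library["formate_oxidation"]
        assert transformed_standard_gibbs(r, 328.15, 7.0) == standard_gibbs_at_temperature(r, 328.15)

    @pytest.mark.parametrize("name", list(ANCHORS))
    def test_ph0_recovers_standard_value(self, library, name):
        r = library[name]
        # pH -> 0 limit removes the proton term entirely
        assert transformed_standard_gibbs(r, 328.15, 1e-12) == pytest.approx(
            standard_gibbs_at_temperature(r, 328.15), abs=1e-9
        )

    def test_proton_transform_identity(self, library):
        for r in library.values():
            delta = transformed_standard_gibbs(r, 328.15, 7.2) - standard_gibbs_at_temperature(r, 328.15)
            assert delta == pytest.approx(
                r.proton_consumption * RT55 * math.log(10) * 7.2, abs=1e-12
            )


class TestReactionQuotient:
    def test_unit_activities_give_unity(self, library, conditions_55):
        for r in library.values():
            assert reaction_quotient(r, conditions_55) == pytest.approx(1.0)

    def test_formate_methanogenesis_hand_value(self, library, conditions_55):
        c = conditions_55.with_activity("HCO3-", 0.03).with_activity("HCOO-", 0.01).with_activity("CH4", 0.5)
        q = reaction_quotient(library["formate_methanogenesis"], c)
        assert q == pytest.approx((0.03**3 * 0.5) / 0.01**4, rel=1e-12)
        assert q == pytest.approx(1350.0, rel=1e-12)

    def test_doubling_product_doubles_q(self, library, conditions_55):
        r = library["formate_oxidation"]
        q1 = reaction_quotient(r, conditions_55)
        q2 = reaction_quotient(r, conditions_55.with_activity("HCO3-", 2.0))
        assert q2 == pytest.approx(2.0 * q1)

    def test_missing_species_names_it(self, library):
        c = ReactionConditions(328.15, 7.2, {"HCO3-": 0.03})
        with pytest.raises(KeyError, match="H2"):
            reaction_quotient(library["co2_reduction"], c)


class TestActualGibbs:
    def test_q_unity_equals_transformed(self, library, conditions_55):
        for r in library.values():
            res = actual_gibbs(r, conditions_55)
            assert res.actual == pytest.approx(res.transformed, abs=1e-12)
            assert res.exergonic == (res.actual < 0)

    def test_doubling_bicarbonate_shifts_by_rtln2(self, library, conditions_55):
        shift = RT55 * math.log(2)
        assert shift == pytest.approx(1.891, abs=5e-4)
        for name, sign in [("formate_oxidation", +1), ("co2_reduction", -1)]:
            base = actual_gibbs(library[name], conditions_55).actual
            bumped = actual_gibbs(
                library[name], conditions_55.with_activity("HCO3-", 2.0)
            ).actual
            assert bumped - base == pytest.approx(sign * shift, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        k1=st.floats(0.1, 10.0, allow_nan=False),
        k2=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_perturbation_additivity(self, library, k1, k2):
        """dG' responds additively in RT ln Q to factorable perturbations."""
        unit = ReactionConditions(
            328.15, 7.2, {"HCO3-": 1.0, "H2": 1.0, "CH4": 1.0, "HCOO-": 1.0, "CH3COO-": 1.0}
        )
        r = library["formate_methanogenesis"]
        base = actual_gibbs(r, unit).actual
        c = unit.with_activity("HCO3-", k1).with_activity("CH4", k2)
        expected = base + RT55 * (3 * math.log(k1) + math.log(k2))
        assert actual_gibbs(r, c).actual == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestBicarbonateSweep:
    def test_monotone_directions(self, library, conditions_55):
        grid = np.geomspace(1e-3, 0.09, 40)
        for name, increasing in [
            ("co2_reduction", False),
            ("acetate_formation", True),
            ("formate_methanogenesis", True),
            ("formate_oxidation", True),
        ]:
            dg = bicarbonate_sweep(library[name], conditions_55, grid)["dG_prime_kJ_per_mol"]
            diffs = np.diff(dg)
            assert np.all(diffs > 0) if increasing else np.all(diffs < 0), name

    def test_ln_space_slope_equals_nu_rt(self, library, conditions_55):
        grid = np.geomspace(1e-3, 0.09, 25)
        for name in ANCHORS:
            r = library[name]
            out = bicarbonate_sweep(r, conditions_55, grid)
            slopes = np.diff(out["dG_prime_kJ_per_mol"]) / np.diff(np.log(out["hco3_mol_per_L"]))
            nu = r.coefficient("HCO3-")
            assert np.allclose(slopes, nu * RT55, rtol=1e-9), name

    def test_methanogenesis_slope_triple_of_oxidation(self, library, conditions_55):
        grid = [0.001, 0.09]
        slope = lambda name: np.diff(
            bicarbonate_sweep(library[name], conditions_55, grid)["dG_prime_kJ_per_mol"]
        )[0] / math.log(90.0)
        assert slope("formate_methanogenesis") == pytest.approx(3 * slope("formate_oxidation"), rel=1e-9)

    def test_degenerate_single_value_matches_actual_gibbs(self, library, conditions_55):
        out = bicarbonate_sweep(library["co2_reduction"], conditions_55, [0.03])
        expected = actual_gibbs(
            library["co2_reduction"], conditions_55.with_activity("HCO3-", 0.03)
        ).actual
        assert len(out) == 1 and out["dG_prime_kJ_per_mol"].iloc[0] == expected

    def test_zero_concentration_floored(self, library, conditions_55):
        out = bicarbonate_sweep(library["co2_reduction"], conditions_55, [0.0])
        assert out["hco3_mol_per_L"].iloc[0] == CONCENTRATION_FLOOR


class TestThresholdConcentration:
    def test_fixed_point_when_already_at_zero(self, library, conditions_55):
        r = library["formate_oxidation"]
        h2_star = threshold_concentration(r, conditions_55, "H2")
        at_star = conditions_55.with_activity("H2", h2_star)
        assert abs(actual_gibbs(r, at_star).actual) < 1e-6
        assert threshold_concentration(r, at_star, "H2") == pytest.approx(h2_star, rel=1e-12)

    def test_h2_threshold_closed_form(self, library, conditions_55):
        """With [HCO3-]=[HCOO-], the H2 feasibility ceiling is exp(-dG0'/RT)."""
        r = library["formate_oxidation"]
        h2_star = threshold_concentration(r, conditions_55, "H2")
        assert h2_star == pytest.approx(math.exp(0.92 / RT55), rel=1e-9)
        assert h2_star == pytest.approx(1.40, abs=0.005)

    def test_doubling_bicarbonate_halves_h2_threshold(self, library, conditions_55):
        r = library["formate_oxidation"]
        h1 = threshold_concentration(r, conditions_55, "H2")
        h2 = threshold_concentration(r, conditions_55.with_activity("HCO3-", 2.0), "H2")
        assert h2 == pytest.approx(h1 / 2, rel=1e-12)

    def test_zero_coefficient_rejected(self, library, conditions_55):
        with pytest.raises(ValueError):
            threshold_concentration(library["formate_oxidation"], conditions_55, "CH4")


class TestReactionConstruction:
    def test_anchor_ordering_enforced(self):
        with pytest.raises(ValueError):
            Reaction("bad", {"H2": -1.0}, [(328.15, 0.0), (298.15, 1.0)])

    def test_conditions_domain(self):
        with pytest.raises(ValueError):
            ReactionConditions(-1.0, 7.0, {})
        with pytest.raises(ValueError):
            ReactionConditions(328.15, 15.0, {})
        with pytest.raises(ValueError):
            ReactionConditions(328.15, 7.0, {"H2": -0.1})
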