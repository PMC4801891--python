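import pytest

from thermotrace.isotopes import TreatmentConfig
from thermotrace.simulate import SimulationParams, simulate_microcosm
from thermotrace.thermo import ReactionConditions, load_reaction_library


@pytest.fixture(scope="session")
def library():
    return load_reaction_library()


@pytest.fixture
def conditions_55():
    """Experimental-state conditions: 55 C, pH 7.2, unit activities."""
    return ReactionConditions(
        328.15,
        7.2,
        {"HCO3-": 1.0, "H2": 1.0, "CH4": 1.0, "HCOO-": 1.0, "CH3COO-": 1.0},
    )


@pytest.fixture(scope="session")
def s30_noiseless():
    """Deterministic noise-free S30-analogue simulation (shared, read-only)."""
    params = SimulationParams(
        treatment=TreatmentConfig("S30", 30.0),
        noise_cv=0.0,
        delta_noise_permil=0.0,
        seed=7,
    )
    return simulate_microcosm(params)
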