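# thermotrace

Bioenergetics and ¹³C-tracer accounting for formate-driven methanogenic
microcosms.

High-temperature oil reservoirs flooded with CO₂ become strongly
bicarbonate-buffered, and whether the resident microbial community can
convert that inorganic carbon to methane hinges on two questions: which of
the candidate reactions are thermodynamically feasible at the in-situ
bicarbonate level, and where does labeled bicarbonate carbon actually end
up after a long incubation. `thermotrace` implements the quantitative
analysis for serum-bottle microcosms fed formate (the electron donor) under
0–90 mM bicarbonate at 55 °C: Gibbs-energy feasibility, δ¹³C bookkeeping,
gas-production kinetics, and a synthetic-bottle simulator so every stage of
the pipeline is testable without instrument data.

It is aimed at geomicrobiologists and biogeochemists analysing anaerobic
incubation experiments with stable-isotope labels.

## The model

Four reactions connect formate, H₂, inorganic carbon and methane:

| reaction | net equation |
|---|---|
| CO₂ reduction | HCO₃⁻ + 4 H₂ + H⁺ → CH₄ + 3 H₂O |
| acetate formation | 4 HCOO⁻ + H⁺ → CH₃COO⁻ + 2 HCO₃⁻ |
| formate methanogenesis | 4 HCOO⁻ + H₂O + H⁺ → CH₄ + 3 HCO₃⁻ |
| syntrophic formate oxidation | HCOO⁻ + H₂O → HCO₃⁻ + H₂ |

For each reaction the package evaluates

* ΔG°(T): standard Gibbs energy, linear in T between tabulated anchors at
  298.15 K and 328.15 K;
* ΔG°′(T) = ΔG°(T) + ν_H⁺ · R·T·ln 10 · pH, the pH-transformed standard
  value (ν_H⁺ = protons consumed);
* ΔG′ = ΔG°′ + R·T·ln Q under stated concentrations (mol/L) and partial
  pressures (atm), with H⁺ excluded from Q and water at unit activity.

Isotope measurements in δ-notation (‰ vs VPDB, with instrument-reference
chaining) are converted to absolute ¹³C atom fractions
F = R/(1+R), R = R_VPDB·(1+δ/1000), so that pool sizes × atom fractions
give μmol of ¹³C directly. The fate of an injected ¹³C-bicarbonate dose is
partitioned into CH₄, headspace CO₂ and residual dissolved inorganic
carbon, with closure (detected = Σ pools) exact by construction and
recovery = detected/injected.

The simulator integrates the three carbon-transforming reactions with a
bicarbonate-dependent lag, first-order formate turnover, Monod H₂ uptake
and full ¹³C propagation; carbon and ¹³C are conserved to machine
precision in the noiseless tracks.

## Worked example

Feasibility of syntrophic formate oxidation under culture-like conditions
(10 mM formate, 30 mM bicarbonate, H₂ at 10⁻⁴ atm, 55 °C, pH 7.2):

```sh
$ thermotrace thermo --reaction formate_oxidation --temp-c 55 --ph 7.2 \
    --conc HCOO-=0.01 --conc HCO3-=0.03 --conc H2=0.0001
reaction:    formate_oxidation
dG0  (55 C):  -0.92 kJ/mol
dG0' (pH 7.2): -0.92 kJ/mol
dG'          : -23.05 kJ/mol
exergonic    : True
```

The standard value sits at the thermodynamic threshold (−0.92 kJ/mol), but
keeping H₂ low — the methanogen partner's job — pulls the reaction to
−23 kJ/mol and makes syntrophic oxidation viable.

Simulating a 30 mM-labeled bottle and recovering the methanogenic pathway
split from its δ¹³C tracks:

```python
from thermotrace.simulate import (SimulationParams, simulate_microcosm,
                                  recover_pathway_fraction)
from thermotrace.isotopes import TreatmentConfig

sim = simulate_microcosm(SimulationParams(treatment=TreatmentConfig("S30", 30.0),
                                          seed=42))
print(sim.latent["ch4_umol"].iloc[-1])   # 135.6  umol CH4 at 180 d
print(sim.realized_dic_fraction)         # 0.540  CH4-C truly drawn from DIC
print(recover_pathway_fraction(sim))     # 0.539  estimated from noisy deltas
```

The bottle plateaus near 136 μmol CH₄ from its 500 μmol formate dose, and
the two-endmember mixing estimator recovers the CO₂-reduction share of
methane to within the measurement noise.

The full pipeline (simulate or read series → rates/lags → ¹³C fate table →
feasibility sweep) runs as `thermotrace run --config cfg.yaml --out-dir out/`.

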