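# Reaction library: the four feasible formate/H2 reactions of a thermophilic
# methanogenic enrichment, with standard Gibbs energies (kJ/mol) tabulated at
# two anchor temperatures (25 C and 55 C).
# Stoichiometric coefficients are signed: negative = reactant, positive = product.
reactions:
  co2_reduction:
    description: hydrogenotrophic (CO2-reducing) methanogenesis
    stoichiometry:
      HCO3-: -1
      H2: -4
      H+: -1
      CH4: 1
      H2O: 3
    anchors:
      - [298.15, -175.32]
      - [328.15, -168.56]
  acetate_formation:
    description: homoacetogenesis from formate
    stoichiometry:
      HCOO-: -4
      H+: -1
      CH3COO-: 1
      HCO3-: 2
    anchors:
      - [298.15, -139.69]
      - [328.15, -137.64]
  formate_methanogenesis:
    description: direct methanogenesis from formate (net reaction)
    stoichiometry:
      HCOO-: -4
      H2O: -1
      H+: -1
      CH4: 1
      HCO3-: 3
    anchors:
      - [298.15, -170.84]
      - [328.15, -172.51]
  formate_oxidation:
    description: syntrophic formate oxidation to bicarbonate and H2
    stoichiometry:
      HCOO-: -1
      H2O: -1
      HCO3-: 1
      H2: 1
    anchors:
      - [298.15, 1.12]
      - [328.15, -0.92]
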