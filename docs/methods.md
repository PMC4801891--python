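# Methods

## Thermodynamics

Each reaction carries tabulated standard Gibbs energies at two anchor
temperatures (298.15 K and 328.15 K). Between (and, with a warning, up to
20 K beyond) the anchors, ΔG°(T) is linear in T — the constant-ΔH°/ΔS°
approximation that two anchors determine; no heat-capacity correction is
attempted. Anchor values are returned bit-for-bit at anchor temperatures.

The pH transform moves H⁺ out of the reaction quotient:
ΔG°′(T) = ΔG°(T) + ν_H⁺·R·T·ln(10)·pH, with ν_H⁺ the net protons consumed
(reactant side minus product side) and R = 8.314462 × 10⁻³ kJ mol⁻¹ K⁻¹.
Because H⁺ never appears in Q, pH dependence is not double-counted, and the
transform reproduces the tabulated ΔG°′(55 °C, pH 7) column of the shipped
library to better than 0.005 kJ/mol.

Activity conventions: molar concentration for aqueous solutes, partial
pressure in atm for gases, unit activity for liquid water. No
ionic-strength or fugacity corrections are applied; the
`ReactionConditions` activity map is the hook for callers who want to
supply corrected activities themselves. Whether H₂ is better represented
as a dissolved concentration or a partial pressure is a genuine modelling
choice; the package declares the partial-pressure convention and applies it
uniformly.

A nominally bicarbonate-free treatment cannot be evaluated at exactly
0 mol/L, so sweep and ΔG′ evaluations floor aqueous activities at
10⁻⁶ mol/L (configurable) with a logged warning.

`threshold_concentration` exploits that ΔG′ is monotone in the
log-activity of any single species: the ΔG′ = 0 crossing has the closed
form a* = a·exp(−ΔG′/(ν·R·T)), which back-substitutes to |ΔG′| < 10⁻⁶
kJ/mol. For syntrophic formate oxidation this is the H₂ ceiling below
which the partner methanogen must hold the headspace.

Reported energies are rounded half-even to 2 decimals in CSV/CLI output;
full precision is kept internally.

## Isotope accounting

δ-values chain exactly: δ_s/VPDB = δ_s/ref + δ_ref/VPDB + δ_s/ref·δ_ref/VPDB/1000,
with the instrument reference gas at −23.73 ‰ vs VPDB by default. The
absolute twin of δ is the ¹³C atom fraction F = R/(1+R) with
R = R_VPDB·(1+δ/1000); R_VPDB defaults to 0.0111802 (the alternative
0.011237 can be passed to the converters). The δ↔F round trip is exact to
10⁻⁹ ‰, which is what makes mixing calculations in F-space safe.

Two-endmember apportionment is computed in atom-fraction space, where
mixing is linear in amounts of ¹³C; the ‰-linear formula is a close
approximation only near natural abundance. Fractions outside [0, 1] warn
rather than error, since measurement noise legitimately produces slight
overshoots.

Headspace gas amounts use the ideal-gas law at the configured headspace
pressure (default 1 atm; pressure buildup from produced gas is ignored — a
known simplification). The carbonate system uses two pKa values
(defaults 6.30 and 10.3) and a Henry constant of 0.0182 mol L⁻¹ atm⁻¹,
round-number values appropriate near 55 °C; all are overridable and the
values used are logged by the pipeline. In the fate budget, the "CO₂" pool
is gas-phase CO₂ only and the "bicarbonate" pool is all aqueous DIC
(CO₂(aq) + HCO₃⁻ + CO₃²⁻), both sharing the measured CO₂ δ; no
equilibrium isotope fractionation between DIC species is applied.

Tracer accounting reports total ¹³C per pool by default, because an
injected label at purity 1.0 dominates every pool; the `excess` mode
subtracts a natural-abundance baseline for low-enrichment work. A
consequence of total-mode accounting is that a lossless bottle shows
recovery slightly above 1 — the formate carbon carries its own
natural-abundance ¹³C into the measured pools; recoveries above 1 warn
rather than error. Percentages of the detected total are rounded half-even
to 2 decimals.

## Kinetics

Windowed rates default to the endpoint estimator
(x(t₁)−x(t₀))/((t₁−t₀)·V), with endpoint values linearly interpolated onto
the window edges; a least-squares slope estimator is available and agrees
exactly on linear tracks. Rates are reported in nmol d⁻¹ mL⁻¹ with the
unit embedded in the output header — rate figures quoted for such
incubations are notoriously unit-fragile, so the unit is never implicit.
Lag time is the linearly interpolated first crossing of a threshold
fraction (default 5 %) of the final amount, non-decreasing in the
threshold by construction.

## Synthetic microcosm

The generator's defaults emulate a 120 mL serum bottle with 50 mL medium at
55 °C and pH 7.2, 10 mM formate (500 μmol/bottle) and 0/30/60/90 mM
bicarbonate, the labeled treatments at label purity 1.0. The dynamics are:

* lag before any turnover, default lag = 30 d + 0.15 d/mM bicarbonate, so
  the most buffered bottle starts latest;
* first-order formate decay (k = 0.04 d⁻¹) split between direct
  methanogenesis (fraction `f_direct`, default 0.5) and syntrophic
  oxidation to HCO₃⁻ + H₂;
* Monod H₂ uptake by CO₂-reducing methanogenesis (vmax = 60 μmol d⁻¹,
  Km = 5 μmol), which keeps H₂ in a rise-then-fall transient rather than
  letting it accumulate;
* a small endogenous electron-donor pool (H₂-equivalents, released
  first-order alongside formate) sized by `dic_reduction_allowance`
  (default 0.022 × the formate dose). This lets the methane plateau sit
  near 136 μmol — just above the strict 125 μmol = formate/4 cap — as raw
  subsurface-fluid incubations tend to, without asserting a mechanism;
* 50 μmol of unlabeled background DIC from the medium, so the unamended
  bottle still has an inorganic-carbon pool.

These rate laws are modelling choices: the real cultures' kinetics were
not measured mechanistically, and the constants were calibrated once so
the unamended bottle plateaus near its observed total between the lag and
day 180. ¹³C propagates by pool bookkeeping: CH₄ formed by CO₂ reduction
carries the DIC pool's current atom fraction, CH₄ formed directly carries
formate's (natural abundance, δ = −30 ‰ by default, a typical organic
substrate value), and DIC receives whatever formate ¹³C does not leave as
CH₄ — so total ¹³C is conserved identically, even with a nonzero kinetic
fractionation ε (applied in ratio space; default 0).

Integration is fixed-step explicit Euler (dt = 0.25 d, horizon 180 d),
sub-stepped so that dt·vmax/Km stays below half the stability bound of the
Monod sink, with step halving whenever a pool would go negative (error on
underflow). Noiseless tracks conserve carbon and ¹³C to ~10⁻¹⁵ relative.

Measurement emulation: sampling every 5 d; multiplicative lognormal noise
(mean 1, CV default 0.05) on amount tracks; additive Gaussian noise
(σ = 0.3 ‰) on δ tracks; headspace CO₂ mole fraction derived from the DIC
pool through the carbonate split at a 1 atm headspace. Per-treatment seeds
derive deterministically from the master seed, so treatment sets are
bit-reproducible.

An optional thermodynamic gate evaluates ΔG′ of the three fluxes at each
substep under the current simulated concentrations (all DIC counted as
bicarbonate) and zeroes any flux that is no longer exergonic. It is off by
default — under the default parameters H₂ never reaches the oxidation
ceiling — but with the H₂ sink disabled it holds the H₂ partial pressure
at the feasibility threshold, the mechanism that keeps H₂ from
accumulating in strongly buffered bottles.

What the generator does *not* emulate: population dynamics, sulfate
reduction or acetogenesis (the acetate track is carried but stays at
zero), pressure buildup, DIC-species isotope equilibria, and
instrument-level drift. Tests passing on simulator output therefore
validate the analysis arithmetic and estimator logic, not the biology of
any particular culture.

## Pathway recovery

`recover_pathway_fraction` estimates the fraction of CH₄ carbon drawn from
the DIC pool using only measurable tracks (CH₄ amount, δ¹³CH₄, δ¹³CO₂).
Because the DIC endmember dilutes over time while CH₄ accumulates, mixing
against the *final* DIC δ is biased; the estimator instead applies
two-endmember mixing per sampling interval — increments of ¹³CH₄ and CH₄
against the trapezoid-averaged DIC atom fraction for that interval — and
sums with production weights. The incremental sums largely telescope, so
per-timepoint noise cancels rather than accumulates: noiseless recovery
matches the simulator's own source tally to ~10⁻⁵, and at 5 % amount noise
the mean absolute error over 100 seeds is ~0.003. An unlabeled bottle has
isotopically indistinguishable endmembers and raises an error rather than
returning a meaningless fraction.

## Pipeline

The `run` pipeline is deterministic for a fixed config and seed: CSV
bodies are byte-identical across reruns, every output carries a
provenance header (package version, seed, constants), and the run log
records the constants and defaults in effect. Problem sizes throughout
(180-day horizon at 0.25 d steps, 50-point sweeps, 100-seed Monte-Carlo
checks) were chosen as the smallest that exercise the full dynamic range
of the system.

## Known limitations

* Activity = concentration: at 30–90 mM bicarbonate plus medium salts,
  ionic-strength corrections would shift ΔG′ by a few kJ/mol; supply
  corrected activities if that matters.
* The fate budget assigns one δ to the whole carbonate system; CO₂(g) vs
  HCO₃⁻ equilibrium fractionation (~−8 ‰ at these temperatures) is below
  the label-scale signal but would matter at natural abundance.
* The endpoint rate estimator is sensitive to endpoint noise; use the
  slope method for noisy series.
* The simulator's lag is a hard switch, not a growth model; fitted lag
  estimates from real optical-density-style gradual onsets will differ.
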