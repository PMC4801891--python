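"""File I/O, pipeline configuration and the end-to-end pipeline.

The pipeline binds the analysis stages together: simulate (or read) one
series per treatment, estimate windowed rates and lags, partition the
injected 13C label into its fate pools, and sweep bicarbonate for the
thermodynamic feasibility report.  All CSV outputs carry a provenance
header (version, seed, constants) and are byte-identical across reruns
with the same inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .isotopes import (
    CarbonateSystem,
    IsotopeFateRow,
    TreatmentConfig,
    carbonate_speciation,
    delta_to_atom_fraction,
    fate_frame,
    fate_table,
    headspace_amount,
    total_injected_13c,
)
from .kinetics import MicrocosmSeries, lag_time, window_rate
from .simulate import SimOutput, SimulationParams, simulate_microcosm
from .thermo import ReactionConditions, bicarbonate_sweep, load_reaction_library

__all__ = [
    "SCHEMA_COLUMNS",
    "PipelineConfig",
    "read_series",
    "write_series",
    "fate_from_series",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Canonical on-disk schema for a per-treatment series file.
SCHEMA_COLUMNS = (
    "time_d",
    "ch4_umol",
    "h2_umol",
    "co2_mole_fraction",
    "formate_mM",
    "acetate_mM",
    "d13c_ch4_permil",
    "d13c_co2_permil",
)
_MANDATORY = ("time_d", "ch4_umol", "h2_umol", "formate_mM")

#: Default activities used for the feasibility sweep when the user supplies
#: none: formate at its dose, trace H2 and product CH4 at mid-incubation
#: levels, acetate at a trace level (none accumulates in these cultures).
DEFAULT_SWEEP_ACTIVITIES = {
    "HCOO-": 0.01,
    "H2": 1e-4,
    "CH4": 0.5,
    "CH3COO-": 1e-3,
    "HCO3-": 0.03,
}


class SchemaError(ValueError):
    """A series file does not match the expected schema."""


def read_series(
    path: str | Path, label: str | None = None, liquid_volume_mL: float = 50.0
) -> MicrocosmSeries:
    """Read a per-treatment CSV into a :class:`MicrocosmSeries`.

    Headers are matched case-insensitively and in any order.  Missing
    optional columns are tolerated (and logged); missing mandatory columns
    raise :class:`SchemaError` listing the expected header.  Non-numeric
    cells and duplicate timepoints are rejected with their line numbers
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    canonical = {c.lower(): c for c in SCHEMA_COLUMNS}
    df.columns = [canonical.get(c.strip().lower(), c.strip()) for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"expected header {','.join(SCHEMA_COLUMNS)}"
        )
    for c in SCHEMA_COLUMNS:
        if c not in df.columns:
            logger.info("%s: optional column %r absent", path.name, c)
    unknown = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, unknown)

    numeric = {}
    for c in [c for c in SCHEMA_COLUMNS if c in df.columns]:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna() & (df[c].str.strip() != "")
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]
            raise SchemaError(f"{path.name}: non-numeric value in column {c!r} at line(s) {lines}")
        numeric[c] = col.to_numpy(float)

    t = numeric["time_d"]
    dup = np.nonzero(np.diff(np.sort(t)) == 0)[0]
    if len(dup):
        order = np.argsort(t, kind="stable")
        lines = sorted({int(order[i + 1]) + 2 for i in dup})
        raise SchemaError(f"{path.name}: duplicate timepoint(s) at line(s) {lines}")

    def opt(c: str) -> np.ndarray | None:
        return numeric.get(c)

    return MicrocosmSeries(
        label=label or path.stem,
        time_d=t,
        ch4_umol=numeric["ch4_umol"],
        h2_umol=numeric["h2_umol"],
        formate_umol=numeric["formate_mM"] * liquid_volume_mL,
        acetate_umol=(
            opt("acetate_mM") * liquid_volume_mL if opt("acetate_mM") is not None else None
        ),
        co2_mole_fraction=opt("co2_mole_fraction"),
        d13c_ch4_permil=opt("d13c_ch4_permil"),
        d13c_co2_permil=opt("d13c_co2_permil"),
    )


def _provenance_lines(seed: int | None, constants: dict) -> list[str]:
    items = " ".join(f"{k}={v}" for k, v in constants.items())
    return [
        f"# thermotrace {__version__}",
        f"# seed={seed} {items}".rstrip(),
    ]


def write_series(
    series: MicrocosmSeries,
    path: str | Path,
    liquid_volume_mL: float = 50.0,
    seed: int | None = None,
) -> None:
    """Write a series in the canonical CSV schema with a provenance header."""
    df = series.to_dataframe()
    out = pd.DataFrame({"time_d": df["time_d"]})
    out["ch4_umol"] = df["ch4_umol"]
    out["h2_umol"] = df["h2_umol"]
    if "co2_mole_fraction" in df:
        out["co2_mole_fraction"] = df["co2_mole_fraction"]
    out["formate_mM"] = df["formate_umol"] / liquid_volume_mL
    if "acetate_umol" in df:
        out["acetate_mM"] = df["acetate_umol"] / liquid_volume_mL
    for c in ("d13c_ch4_permil", "d13c_co2_permil"):
        if c in df:
            out[c] = df[c]
    _write_csv(out, path, seed, {"liquid_volume_mL": liquid_volume_mL})


def _write_csv(df: pd.DataFrame, path: str | Path, seed: int | None, constants: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _provenance_lines(seed, constants):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def fate_from_series(
    series: MicrocosmSeries,
    config: TreatmentConfig,
    system: CarbonateSystem | None = None,
    excess_natural_delta: float | None = None,
) -> IsotopeFateRow:
    """Partition the injected 13C label from a measured series (final state).

    CH4-13C comes from the final CH4 amount and its delta; the headspace CO2
    mole fraction gives gas-phase CO2, which the carbonate equilibria extend
    to the dissolved DIC pool sharing the CO2 delta.  The "bicarbonate" pool
    of the budget is all aqueous DIC; the "CO2" pool is gas-phase only.
    With ``excess_natural_delta`` set, natural-abundance 13C at that delta is
    subtracted from every pool (excess mode).
    """
    if system is None:
        system = CarbonateSystem(temperature_C=config.temperature_C, pH=config.pH)
    if series.co2_mole_fraction is None or series.d13c_co2_permil is None:
        raise ValueError("series lacks CO2 mole-fraction or delta tracks")
    if series.d13c_ch4_permil is None:
        raise ValueError("series lacks a d13c_ch4 track")

    def last_finite(arr: np.ndarray) -> float:
        ok = np.isfinite(arr)
        if not ok.any():
            raise ValueError("no finite values in required track")
        return float(arr[ok][-1])

    ch4 = float(series.ch4_umol[-1])
    f_ch4 = delta_to_atom_fraction(last_finite(series.d13c_ch4_permil))
    f_co2 = delta_to_atom_fraction(last_finite(series.d13c_co2_permil))
    x_co2 = float(series.co2_mole_fraction[-1])

    spec = carbonate_speciation(system, config.liquid_volume_mL, config.headspace_volume_mL)
    gas_co2 = headspace_amount(config, x_co2)
    aqueous_dic = gas_co2 * (1.0 - spec.gas_fraction) / spec.gas_fraction

    f_base = 0.0
    if excess_natural_delta is not None:
        f_base = delta_to_atom_fraction(excess_natural_delta)
    pools = (
        ch4 * max(f_ch4 - f_base, 0.0),
        gas_co2 * max(f_co2 - f_base, 0.0),
        aqueous_dic * max(f_co2 - f_base, 0.0),
    )
    return fate_table(pools, total_injected_13c(config), label=series.label)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs for one run."""

    treatments: list[TreatmentConfig]
    seed: int = 0
    series_paths: dict[str, str] = field(default_factory=dict)  # label -> CSV; else simulate
    sim_overrides: dict = field(default_factory=dict)  # SimulationParams field overrides
    carbonate: CarbonateSystem = field(default_factory=CarbonateSystem)
    rate_window: tuple[float, float] = (35.0, 80.0)
    rate_method: str = "endpoint"
    lag_threshold: float = 0.05
    sweep_from: float = 1e-3
    sweep_to: float = 0.09
    sweep_points: int = 50

    def __post_init__(self) -> None:
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        treatments = [TreatmentConfig(**t) for t in raw.get("treatments", [])]
        kwargs = {}
        for key in (
            "seed", "series_paths", "sim_overrides", "rate_window", "rate_method",
            "lag_threshold", "sweep_from", "sweep_to", "sweep_points",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "rate_window" in kwargs:
            kwargs["rate_window"] = tuple(kwargs["rate_window"])
        if "carbonate" in raw:
            kwargs["carbonate"] = CarbonateSystem(**raw["carbonate"])
        return cls(treatments=treatments, **kwargs)


def _simulate_treatment(config: PipelineConfig, treatment: TreatmentConfig, child_seed: int) -> SimOutput:
    params = SimulationParams(
        treatment=treatment, seed=child_seed, **config.sim_overrides
    )
    return simulate_microcosm(params)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Run simulate/read -> rates -> fate -> thermodynamic sweep.

    Writes ``fate.csv``, ``rates.csv``, ``thermo_sweep.csv``, per-treatment
    series CSVs and ``run.log`` under ``out_dir``; returns the tables.
    Reruns with the same config and seed produce byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = _provenance_lines(config.seed, {})
    log_lines.append(f"carbonate: {config.carbonate}")
    log_lines.append(f"rate_window={config.rate_window} method={config.rate_method}")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        max(len(config.treatments), 1)
    )

    series_by_label: dict[str, MicrocosmSeries] = {}
    for treatment, child in zip(config.treatments, child_seeds):
        if treatment.label in config.series_paths:
            s = read_series(
                config.series_paths[treatment.label],
                label=treatment.label,
                liquid_volume_mL=treatment.liquid_volume_mL,
            )
            log_lines.append(f"{treatment.label}: read from file")
        else:
            sim = _simulate_treatment(config, treatment, int(child) & 0x7FFFFFFF)
            s = sim.series
            log_lines.append(f"{treatment.label}: simulated (seed={sim.params.seed})")
        series_by_label[treatment.label] = s
        write_series(
            s,
            out_dir / f"series_{treatment.label}.csv",
            liquid_volume_mL=treatment.liquid_volume_mL,
            seed=config.seed,
        )

    rate_rows = []
    for treatment in config.treatments:
        s = series_by_label[treatment.label]
        t0, t1 = config.rate_window
        t0 = max(t0, float(s.time_d[0]))
        t1 = min(t1, float(s.time_d[-1]))
        est = window_rate(
            s, "ch4", t0, t1, treatment.liquid_volume_mL, method=config.rate_method
        )
        lag = lag_time(s, "ch4", config.lag_threshold)
        rate_rows.append(
            {
                "label": treatment.label,
                "analyte": "ch4",
                "t0_d": est.window[0],
                "t1_d": est.window[1],
                "rate": est.rate,
                "units": est.units,
                "method": est.method,
                "lag_d": np.nan if lag is None else lag,
            }
        )
    rates_df = pd.DataFrame(
        rate_rows,
        columns=["label", "analyte", "t0_d", "t1_d", "rate", "units", "method", "lag_d"],
    )

    fate_rows = []
    for treatment in config.treatments:
        if total_injected_13c(treatment) <= 0:
            log_lines.append(f"{treatment.label}: unlabeled, no fate row")
            continue
        row = fate_from_series(
            series_by_label[treatment.label], treatment, config.carbonate
        )
        fate_rows.append(row)
    fate_df = fate_frame(fate_rows)

    library = load_reaction_library()
    grid = np.geomspace(config.sweep_from, config.sweep_to, config.sweep_points)
    base = config.treatments[0] if config.treatments else TreatmentConfig("base", 30.0)
    conditions = ReactionConditions(
        base.temperature_K, base.pH, dict(DEFAULT_SWEEP_ACTIVITIES)
    )
    sweep_df = pd.concat(
        [bicarbonate_sweep(r, conditions, grid) for r in library.values()],
        ignore_index=True,
    )
    log_lines.append(f"sweep activities: {DEFAULT_SWEEP_ACTIVITIES}")

    constants = {"pK1": config.carbonate.pK1, "pK2": config.carbonate.pK2,
                 "henry": config.carbonate.henry_constant}
    _write_csv(fate_df, out_dir / "fate.csv", config.seed, constants)
    _write_csv(rates_df, out_dir / "rates.csv", config.seed, {})
    _write_csv(sweep_df, out_dir / "thermo_sweep.csv", config.seed, {})
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {"fate": fate_df, "rates": rates_df, "sweep": sweep_df}
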