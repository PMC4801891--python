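"""Windowed production rates, lag periods and stoichiometric yields.

Operates on :class:`MicrocosmSeries` — the time-indexed record of one
incubation bottle (gas amounts, solutes, optional delta-13C tracks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MicrocosmSeries",
    "RateEstimate",
    "window_rate",
    "lag_time",
    "stoichiometric_yield",
]

_TRACKS = (
    "ch4_umol",
    "h2_umol",
    "formate_umol",
    "acetate_umol",
    "co2_mole_fraction",
    "d13c_ch4_permil",
    "d13c_co2_permil",
)
_NONNEGATIVE = ("ch4_umol", "h2_umol", "formate_umol", "acetate_umol", "co2_mole_fraction")


@dataclass
class MicrocosmSeries:
    """Time series for one bottle: per-bottle amounts plus optional isotopes.

    ``time_d`` must be strictly increasing; amount tracks are nonnegative.
    delta-13C tracks (permil vs VPDB) and the headspace CO2 mole fraction are
    optional.
    """

    label: str
    time_d: np.ndarray
    ch4_umol: np.ndarray
    h2_umol: np.ndarray
    formate_umol: np.ndarray
    acetate_umol: np.ndarray | None = None
    co2_mole_fraction: np.ndarray | None = None
    d13c_ch4_permil: np.ndarray | None = None
    d13c_co2_permil: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_d = np.asarray(self.time_d, dtype=float)
        if self.time_d.ndim != 1 or len(self.time_d) < 1:
            raise ValueError("time_d must be a nonempty 1-D array")
        if np.any(np.diff(self.time_d) <= 0):
            raise ValueError("time_d must be strictly increasing")
        n = len(self.time_d)
        for name in _TRACKS:
            arr = getattr(self, name, None)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise ValueError(f"track {name!r} length {len(arr)} != {n}")
            if name in _NONNEGATIVE and np.any(arr < -1e-12):
                raise ValueError(f"track {name!r} contains negative amounts")
            setattr(self, name, arr)

    def track(self, analyte: str) -> np.ndarray:
        """Return a track by short name ('ch4') or full column name."""
        name = analyte if analyte in _TRACKS else f"{analyte}_umol"
        arr = getattr(self, name, None)
        if arr is None:
            raise KeyError(f"series {self.label!r} has no track {analyte!r}")
        return arr

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_d": self.time_d}
        for name in _TRACKS:
            arr = getattr(self, name, None)
            if arr is not None:
                data[name] = arr
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str) -> "MicrocosmSeries":
        kwargs = {name: df[name].to_numpy(float) for name in _TRACKS if name in df}
        return cls(label=label, time_d=df["time_d"].to_numpy(float), **kwargs)


@dataclass(frozen=True)
class RateEstimate:
    """A volumetric production/consumption rate over a time window."""

    label: str
    analyte: str
    window: tuple[float, float]
    rate: float
    units: str
    method: str

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed window start")


def window_rate(
    series: MicrocosmSeries,
    analyte: str,
    t0: float,
    t1: float,
    liquid_volume_mL: float,
    method: str = "endpoint",
    units: str = "nmol/d/mL",
) -> RateEstimate:
    """Volumetric rate of an analyte over [t0, t1].

    ``endpoint``: (x(t1) - x(t0)) / ((t1 - t0) * V), with the endpoint values
    linearly interpolated onto t0 and t1.  ``slope``: least-squares slope of
    the points inside the window divided by V.  Units default to
    nmol d^-1 mL^-1 ("umol/d/mL" is also accepted).
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    t = series.time_d
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(f"window [{t0}, {t1}] outside series span [{t[0]}, {t[-1]}]")
    x = series.track(analyte)
    mask = (t >= t0) & (t <= t1)
    inside = int(mask.sum())
    if inside < 2 and method == "slope":
        raise ValueError("need at least 2 points inside the window for 'slope'")
    if method == "endpoint":
        x0 = float(np.interp(t0, t, x))
        x1 = float(np.interp(t1, t, x))
        per_bottle = (x1 - x0) / (t1 - t0)
    elif method == "slope":
        per_bottle = float(np.polyfit(t[mask], x[mask], 1)[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    rate = per_bottle / liquid_volume_mL  # umol d^-1 mL^-1
    if units == "nmol/d/mL":
        rate *= 1000.0
    elif units != "umol/d/mL":
        raise ValueError(f"unknown units {units!r}")
    return RateEstimate(series.label, analyte, (t0, t1), rate, units, method)


def lag_time(
    series: MicrocosmSeries, analyte: str, threshold_fraction: float = 0.05
) -> float | None:
    """Time at which a track first reaches a fraction of its final amount.

    Linear interpolation between samples; non-decreasing in the threshold.
    Returns the first timepoint if the series starts above the threshold and
    ``None`` (with a warning) if the track never reaches it.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    x = series.track(analyte)
    t = series.time_d
    final = x[-1]
    if final <= 0:
        raise ValueError("final amount must be positive to define a lag")
    threshold = threshold_fraction * final
    if x[0] >= threshold:
        return float(t[0])
    idx = np.nonzero(x >= threshold)[0]
    if len(idx) == 0:
        warnings.warn(
            f"{series.label}/{analyte}: track never reaches "
            f"{threshold_fraction:.0%} of its final amount",
            stacklevel=2,
        )
        return None
    i = idx[0]
    # linear interpolation across the crossing segment
    frac = (threshold - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


_PATHWAYS = {"formate_methanogenesis", "syntrophic"}


def stoichiometric_yield(formate_consumed_umol: float, pathway: str) -> dict[str, float]:
    """Expected CH4 and bicarbonate from consumed formate (4:1 net reaction).

    Direct formate methanogenesis (4 HCOO- + H2O + H+ -> CH4 + 3 HCO3-) and
    syntrophic oxidation followed by CO2 reduction share the same net
    stoichiometry: CH4 = formate/4, HCO3- = 3*formate/4.
    """
    if pathway not in _PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {sorted(_PATHWAYS)}")
    if formate_consumed_umol < 0:
        raise ValueError("formate consumed must be nonnegative")
    return {
        "ch4_umol": formate_consumed_umol / 4.0,
        "hco3_umol": 3.0 * formate_consumed_umol / 4.0,
    }
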