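"""Kuwait Air Quality Index: piecewise-linear sub-index per pollutant over
the national breakpoint grid, with category labels.

Within the segment holding a concentration C_p, the sub-index is the
linear interpolation

    I_p = (I_high - I_low) / (C_high - C_low) * (C_p - C_low) + I_low

and the day's overall AQI is the maximum sub-index over the pollutants
available that day.  The printed grid has reporting-resolution gaps
between adjacent segments (e.g. NO2 0.03 -> 0.04); concentrations falling
in a gap are interpolated linearly between the two adjacent knots, which
keeps the scale continuous and monotone while every printed knot maps to
exactly its printed index.  Category labels inside a gap come from the
nearer knot, boundaries resolving to the lower segment.

Gas concentrations are in ppm, PM10 in ug/m3.  A helper converts mg/m3
(the monitoring network's reporting unit) to ppm at 25 degC / 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AQIBreakpointTable", "AQIResult", "load_breakpoints",
    "concentration_to_aqi", "panel_aqi", "mgm3_to_ppm",
]

#: molecular weights for the ppm conversion (g/mol)
_MW = {"CO": 28.01, "NO2": 46.01, "O3": 48.0, "SO2": 64.07}
_MOLAR_VOLUME = 24.45  # L/mol at 25 degC, 1 atm


@dataclass(frozen=True)
class Segment:
    c_low: float
    c_high: float
    i_low: float
    i_high: float
    category: str


@dataclass
class AQIResult:
    index: float
    index_rounded: int
    category: str


@dataclass
class AQIBreakpointTable:
    pollutants: dict[str, list[Segment]]
    units: dict[str, str]
    window_hours: dict[str, int]

    def __post_init__(self):
        for name, segs in self.pollutants.items():
            for a, b in zip(segs, segs[1:]):
                if not (a.c_low <= a.c_high < b.c_low and a.i_high <= b.i_low):
                    raise ValueError(f"{name}: segments overlap or are unordered")

    def segment_for(self, pollutant: str, c: float) -> Segment:
        segs = self.pollutants[pollutant]
        if c < segs[0].c_low:
            raise ValueError(f"concentration {c} below table range")
        if c > segs[-1].c_high:
            raise ValueError(
                f"{pollutant} concentration {c} beyond Hazardous scale"
            )
        for a, b in zip(segs, segs[1:]):
            if c <= a.c_high:
                return a
            if c < b.c_low:
                # reporting-resolution gap: bridge the adjacent knots with
                # their own linear segment, so the scale stays continuous
                # and monotone; label from the nearer knot (ties lower)
                mid = 0.5 * (a.c_high + b.c_low)
                label = a.category if c <= mid else b.category
                return Segment(a.c_high, b.c_low, a.i_high, b.i_low, label)
        return segs[-1]


@lru_cache(maxsize=1)
def load_breakpoints() -> AQIBreakpointTable:
    """The Kuwait grid shipped with the package (editable YAML)."""
    text = (resources.files("airimpute") / "data" / "kuwait_aqi.yaml").read_text()
    raw = yaml.safe_load(text)
    pollutants, units, windows = {}, {}, {}
    for name, entry in raw["pollutants"].items():
        pollutants[name] = [Segment(*row) for row in entry["segments"]]
        units[name] = entry["units"]
        windows[name] = entry["window_hours"]
    return AQIBreakpointTable(pollutants, units, windows)


def concentration_to_aqi(
    pollutant: str, c_p: float, table: AQIBreakpointTable | None = None
) -> AQIResult:
    """Sub-index and category for one concentration (table units)."""
    table = table or load_breakpoints()
    if pollutant not in table.pollutants:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    if not np.isfinite(c_p) or c_p < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {c_p}")
    s = table.segment_for(pollutant, c_p)
    ip = (s.i_high - s.i_low) / (s.c_high - s.c_low) * (c_p - s.c_low) + s.i_low
    return AQIResult(float(ip), int(round(ip)), s.category)


def mgm3_to_ppm(pollutant: str, mgm3) -> np.ndarray | float:
    """Convert a gas concentration from mg/m3 to ppm (25 degC, 1 atm)."""
    if pollutant not in _MW:
        raise ValueError(f"no molecular weight for {pollutant!r}")
    return np.asarray(mgm3, dtype=float) * _MOLAR_VOLUME / _MW[pollutant]


def panel_aqi(
    daily: pd.DataFrame, table: AQIBreakpointTable | None = None
) -> pd.DataFrame:
    """Per-day sub-indices and overall AQI (max sub-index) for a daily panel.

    Expects concentrations already in table units; pollutants absent from
    the table are ignored, missing cells are skipped (never treated as 0);
    a day with no valid pollutant gets a missing overall AQI.
    """
    table = table or load_breakpoints()
    cols = [c for c in daily.columns if c in table.pollutants]
    out = pd.DataFrame(index=daily.index)
    for c in cols:
        vals = daily[c]
        sub = np.full(len(vals), np.nan)
        for i, v in enumerate(vals.to_numpy(dtype=float)):
            if np.isnan(v):
                continue
            sub[i] = concentration_to_aqi(c, v, table).index
        out[f"I_{c}"] = sub
    out["AQI"] = out.max(axis=1) if cols else np.nan
    return out
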