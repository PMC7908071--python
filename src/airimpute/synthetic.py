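"""Synthetic multi-station air-quality panels.

The study's raw monitoring data are not public, so every downstream stage
(amputation, imputation, benchmarking) is exercised on synthetic panels that
emulate the structure of a five-station Kuwaiti network: positively skewed
(log-normal) pollutant marginals with prescribed means/SDs on the original
scale, a prescribed cross-variable Pearson correlation structure applied on
the Gaussian (log) scale, an annual temperature cycle, bounded relative
humidity, and wind direction as a plain numeric 0-360 covariate.

Generation is a Gaussian copula: draw correlated standard normals, then push
each column through its marginal transform.  Days are i.i.d. by default; an
optional AR(1) coefficient induces within-series autocorrelation while
preserving the marginals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MarginalSpec",
    "PanelConfig",
    "StationPanel",
    "default_config",
    "generate_panel",
    "generate_study",
    "write_station_csv",
    "read_station_csv",
    "POLLUTANTS",
    "VARIABLES",
    "DEFAULT_STATIONS",
]

#: canonical column order of the station CSV dialect
VARIABLES = ["PM10", "CO", "NO2", "O3", "SO2", "temp", "rh", "ws", "wd"]
POLLUTANTS = ["PM10", "CO", "NO2", "O3", "SO2"]
DEFAULT_STATIONS = ["FAH", "JAH", "MAN", "RUM", "ASA"]

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one variable on its original scale.

    kind:
      ``lognormal`` — moment-matched log-normal (pollutants; strictly > 0)
      ``normal``    — Gaussian, optionally with an additive annual sinusoid
      ``clipped``   — Gaussian clipped to [lower, upper] (relative humidity)
      ``wrapped``   — probability-integral transform onto [lower, upper)
                      (wind direction; uniform margin)
    """

    name: str
    kind: str
    mean: float = 0.0
    sd: float = 1.0
    lower: float = 0.0
    upper: float | None = None
    seasonal: bool = False

    def __post_init__(self):
        if self.kind not in {"lognormal", "normal", "clipped", "wrapped"}:
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "lognormal" and self.mean <= 0:
            raise ValueError(f"{self.name}: log-normal target mean must be > 0")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")


@dataclass
class PanelConfig:
    """Full specification of a synthetic study.

    ``correlation`` is the target Pearson matrix on the Gaussian (copula)
    scale, in the order of ``marginals``; it must be symmetric with unit
    diagonal and is repaired by eigenvalue clipping when slightly indefinite.
    """

    marginals: list[MarginalSpec]
    correlation: np.ndarray
    n_stations: int = 5
    n_days: int = 2192
    seasonal_amplitude: float = 6.0   # degrees C, annual temperature cycle
    ar1: float = 0.0                  # within-series autocorrelation of the copula
    seed: int = 0
    start_date: str = "2012-01-01"
    stations: list[str] = field(default_factory=lambda: list(DEFAULT_STATIONS))

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, dtype=float)
        p = len(self.marginals)
        if self.correlation.shape != (p, p):
            raise ValueError(
                f"correlation matrix is {self.correlation.shape}, need ({p}, {p})"
            )
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")

    @property
    def variable_names(self) -> list[str]:
        return [m.name for m in self.marginals]


@dataclass
class StationPanel:
    """One station's date x variable table; NaN marks a missing cell."""

    station: str
    data: pd.DataFrame  # DatetimeIndex (daily, strictly increasing), float columns

    def __post_init__(self):
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("StationPanel.data must have a DatetimeIndex")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing without duplicates")

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask, True where a value is present."""
        return self.data.notna()

    @property
    def n_days(self) -> int:
        return len(self.data)

    def copy(self) -> "StationPanel":
        return StationPanel(self.station, self.data.copy())


# ---------------------------------------------------------------------------
# default study configuration
# ---------------------------------------------------------------------------

# Overall pollutant means/SDs (original scale) of the emulated network, and
# field-realistic Kuwait meteorology.  Pollutant units follow the source
# network's convention (mg/m3 for gases and PM10).
_DEFAULT_MARGINALS = [
    MarginalSpec("PM10", "lognormal", mean=0.23, sd=1.07),
    MarginalSpec("CO", "lognormal", mean=0.91, sd=0.90),
    MarginalSpec("NO2", "lognormal", mean=0.04, sd=0.02),
    MarginalSpec("O3", "lognormal", mean=0.02, sd=0.01),
    MarginalSpec("SO2", "lognormal", mean=0.01, sd=0.01),
    # noise sd dominates the annual cycle so observed cross-correlations
    # stay close to the copula targets (the cycle dilutes them by ~12%)
    MarginalSpec("temp", "normal", mean=27.0, sd=8.0, seasonal=True),
    MarginalSpec("rh", "clipped", mean=35.0, sd=18.0, lower=0.0, upper=100.0),
    MarginalSpec("ws", "lognormal", mean=3.5, sd=1.8),
    MarginalSpec("wd", "wrapped", lower=0.0, upper=360.0),
]

# Target correlations on the Gaussian scale, order = VARIABLES.
# Entries reported as non-significant in the emulated network (CO-PM10,
# Hum-NO2, Hum-PM10) are set to 0.
_R = np.eye(9)


def _set(name_a, name_b, r):
    i, j = VARIABLES.index(name_a), VARIABLES.index(name_b)
    _R[i, j] = _R[j, i] = r


_set("NO2", "O3", -0.35)
_set("NO2", "SO2", 0.40)
_set("NO2", "CO", 0.35)
_set("NO2", "PM10", -0.06)
_set("NO2", "temp", -0.09)
_set("NO2", "ws", -0.20)
_set("NO2", "wd", -0.25)
_set("O3", "SO2", -0.09)
_set("O3", "CO", -0.26)
_set("O3", "PM10", 0.05)
_set("O3", "temp", 0.45)
_set("O3", "rh", -0.25)
_set("O3", "ws", 0.30)
_set("O3", "wd", 0.13)
_set("SO2", "CO", 0.22)
_set("SO2", "PM10", -0.03)
_set("SO2", "temp", -0.06)
_set("SO2", "rh", -0.08)
_set("SO2", "ws", 0.13)
_set("SO2", "wd", -0.15)
_set("CO", "temp", -0.14)
_set("CO", "rh", 0.29)
_set("CO", "ws", -0.22)
_set("CO", "wd", -0.27)
_set("PM10", "temp", 0.05)
_set("PM10", "ws", 0.10)
_set("PM10", "wd", 0.06)
_set("temp", "rh", -0.61)
_set("temp", "ws", 0.24)
_set("temp", "wd", 0.14)
_set("rh", "ws", -0.32)
_set("rh", "wd", -0.28)
_set("ws", "wd", 0.31)

DEFAULT_CORRELATION = _R.copy()
del _R


def default_config(**overrides) -> PanelConfig:
    """The study's default configuration: 5 stations x 2192 days, 9 variables."""
    cfg = PanelConfig(
        marginals=list(_DEFAULT_MARGINALS),
        correlation=DEFAULT_CORRELATION.copy(),
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _repair_psd(R: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues and rescale to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R
    if w.min() < -1e-4:
        raise ValueError(
            f"correlation matrix is not positive semi-definite: "
            f"smallest eigenvalue {w.min():.3e}"
        )
    w = np.clip(w, _PSD_TOL, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def _station_rng(seed: int, station: str) -> np.random.Generator:
    # stable per-station stream: mix the config seed with a CRC of the label
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(station.encode("utf8"))])
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given original-scale moments."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_panel(config: PanelConfig, station: str) -> StationPanel:
    """Draw one fully observed station panel (Gaussian copula).

    Deterministic given ``(config.seed, station)``.
    """
    p = len(config.marginals)
    n = config.n_days
    R = _repair_psd(config.correlation)
    L = np.linalg.cholesky(R + _PSD_TOL * np.eye(p))
    rng = _station_rng(config.seed, station)

    eps = rng.standard_normal((n, p))
    if config.ar1:
        phi = config.ar1
        z = np.empty_like(eps)
        z[0] = eps[0]
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + scale * eps[t]
        eps = z
    Z = eps @ L.T

    dates = pd.date_range(config.start_date, periods=n, freq="D")
    day_of_year = dates.dayofyear.to_numpy()

    cols = {}
    for j, m in enumerate(config.marginals):
        z = Z[:, j]
        if m.kind == "lognormal":
            mu, sigma = _lognormal_params(m.mean, m.sd)
            x = np.exp(mu + sigma * z)
        elif m.kind == "normal":
            x = m.mean + m.sd * z
            if m.seasonal:
                x = x + config.seasonal_amplitude * np.sin(
                    2.0 * np.pi * day_of_year / 365.25
                )
        elif m.kind == "clipped":
            upper = np.inf if m.upper is None else m.upper
            x = np.clip(m.mean + m.sd * z, m.lower, upper)
        else:  # wrapped
            width = (m.upper if m.upper is not None else 360.0) - m.lower
            x = m.lower + width * norm.cdf(z)
        cols[m.name] = x

    df = pd.DataFrame(cols, index=dates)
    return StationPanel(station, df)


def generate_study(config: PanelConfig) -> list[StationPanel]:
    """One panel per station, each on its own reproducible sub-stream."""
    stations = config.stations[: config.n_stations]
    if len(stations) < config.n_stations:
        stations = stations + [
            f"S{i:02d}" for i in range(len(stations), config.n_stations)
        ]
    return [generate_panel(config, s) for s in stations]


# ---------------------------------------------------------------------------
# station CSV dialect
# ---------------------------------------------------------------------------

def write_station_csv(panel: StationPanel, path) -> None:
    """Write ``date,PM10,CO,...`` with ISO dates; empty field = missing."""
    out = panel.data.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, na_rep="")


def read_station_csv(path, station: str | None = None) -> StationPanel:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    df.index.name = None
    name = station if station is not None else str(path)
    return StationPanel(name, df.astype(float))
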