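"""Controlled amputation: impose MCAR, MAR or MNAR missingness on complete
panels while keeping the removed truth in a vault for scoring.

Counts are exact: every target variable loses exactly ``round(rate * n)``
cells, so realized rates are identical across mechanisms and replicates.

Mechanisms
----------
MCAR  cells chosen uniformly at random without replacement.
MAR   cell-deletion probability is logistic in the standardized rank of a
      fully observed conditioning covariate (default: temperature), so the
      mechanism depends on observed data only.
MNAR  the largest (side="high"), smallest ("low"), or both extremes
      ("both") of the target variable itself are removed; deterministic
      given the data, ties broken by row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .synthetic import StationPanel

__all__ = ["MissingnessSpec", "AmputedPanel", "ampute",
           "ampute_mcar", "ampute_mar", "ampute_mnar", "STUDY_RATES"]

#: missingness rates of the benchmark design
STUDY_RATES = (0.05, 0.10, 0.20, 0.30, 0.40)

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass(frozen=True)
class MissingnessSpec:
    """Fully determines one amputation."""

    mechanism: str
    rate: float
    targets: tuple[str, ...] = ("CO", "NO2", "O3", "SO2")
    conditioning: str = "temp"     # MAR only; must be fully observed
    side: str = "high"             # MNAR only: high | low | both
    mar_strength: float = 1.5      # log-odds slope on the standardized rank
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.rate < 1.0:
            raise ValueError("rate must lie in (0, 1)")
        if self.side not in ("high", "low", "both"):
            raise ValueError("side must be high, low or both")
        if self.conditioning in self.targets:
            raise ValueError("conditioning variable cannot be a target")


@dataclass
class AmputedPanel:
    """A blanked panel, the amputation mask, and the vault of true values."""

    panel: StationPanel
    mask: pd.DataFrame   # True where a cell was amputed
    vault: pd.DataFrame  # true values at masked cells, NaN elsewhere
    spec: MissingnessSpec = field(default=None)  # type: ignore[assignment]

    def restore(self) -> StationPanel:
        """Un-mask: reproduces the original panel bit-exactly."""
        data = self.panel.data.copy()
        for c in self.mask.columns:
            m = self.mask[c].to_numpy()
            data.loc[m, c] = self.vault[c].to_numpy()[m]
        return StationPanel(self.panel.station, data)


def _check_targets(panel: StationPanel, spec: MissingnessSpec) -> list[str]:
    targets = [t for t in spec.targets if t in panel.data.columns]
    if not targets:
        raise ValueError("no target variable present in panel")
    for t in targets:
        if panel.data[t].isna().any():
            raise ValueError(f"target {t!r} must be complete before amputation")
    return targets


def _build(panel, spec, rows_per_target) -> AmputedPanel:
    data = panel.data.copy()
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    vault = pd.DataFrame(np.nan, index=data.index, columns=data.columns)
    for t, rows in rows_per_target.items():
        col = data[t].to_numpy(copy=True)
        vault.iloc[rows, vault.columns.get_loc(t)] = col[rows]
        mask.iloc[rows, mask.columns.get_loc(t)] = True
        col[rows] = np.nan
        data[t] = col
    return AmputedPanel(StationPanel(panel.station, data), mask, vault, spec)


def _n_cells(spec: MissingnessSpec, n: int) -> int:
    # round-half-away-from-zero would not matter here; numpy round-half-even
    # is avoided to keep e.g. 0.05*2190 = 109.5 -> 110 stable
    return int(np.floor(spec.rate * n + 0.5))


def ampute_mcar(panel: StationPanel, spec: MissingnessSpec) -> AmputedPanel:
    """Uniform cell deletion, exactly round(rate*n) per target variable."""
    targets = _check_targets(panel, spec)
    n = panel.n_days
    k = _n_cells(spec, n)
    rng = np.random.default_rng(spec.seed)
    rows = {t: np.sort(rng.choice(n, size=k, replace=False)) for t in targets}
    return _build(panel, spec, rows)


def ampute_mar(panel: StationPanel, spec: MissingnessSpec) -> AmputedPanel:
    """Deletion probability logistic in the conditioning covariate's rank."""
    targets = _check_targets(panel, spec)
    if spec.conditioning not in panel.data.columns:
        raise ValueError(f"conditioning variable {spec.conditioning!r} not in panel")
    cond = panel.data[spec.conditioning]
    if cond.isna().any():
        raise ValueError("conditioning variable must be fully observed")
    n = panel.n_days
    k = _n_cells(spec, n)
    z = rankdata(cond.to_numpy())
    z = (z - z.mean()) / z.std()
    w = expit(spec.mar_strength * z)
    w = w / w.sum()
    rng = np.random.default_rng(spec.seed)
    rows = {
        t: np.sort(rng.choice(n, size=k, replace=False, p=w)) for t in targets
    }
    return _build(panel, spec, rows)


def ampute_mnar(panel: StationPanel, spec: MissingnessSpec) -> AmputedPanel:
    """Remove the extreme order statistics of each target variable."""
    targets = _check_targets(panel, spec)
    n = panel.n_days
    k = _n_cells(spec, n)
    rows = {}
    for t in targets:
        v = panel.data[t].to_numpy()
        order = np.argsort(v, kind="stable")  # ties resolved by row order
        if np.unique(v).size < v.size:
            warnings.warn(f"{t}: ties present; resolved by row order")
        if spec.side == "high":
            sel = order[n - k:]
        elif spec.side == "low":
            sel = order[:k]
        else:
            k_low = k // 2
            sel = np.concatenate([order[:k_low], order[n - (k - k_low):]])
        rows[t] = np.sort(sel)
    return _build(panel, spec, rows)


_DISPATCH = {"MCAR": ampute_mcar, "MAR": ampute_mar, "MNAR": ampute_mnar}


def ampute(panel: StationPanel, spec: MissingnessSpec) -> AmputedPanel:
    """Apply the mechanism named in ``spec``."""
    return _DISPATCH[spec.mechanism](panel, spec)
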