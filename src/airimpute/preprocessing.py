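"""Data preparation: temporal aggregation, log transform, descriptive and
missingness summaries, pairwise correlation analysis, exclusion rule.

Conventions adopted throughout the pipeline:

* the 75% completeness rule for temporal aggregates is inclusive (exactly
  75% observed is enough);
* 8-hour concentration times use the daily maximum of rolling 8-h means
  (standard AQI practice), each window valid iff >= completeness of its 8
  hourly slots are observed;
* log transform is the natural log of pollutant columns only; an exact zero
  is shifted by half the smallest positive observed value of its column;
* quartiles use linear interpolation, SD uses the n-1 denominator;
* pollutants whose pooled missing fraction strictly exceeds the exclusion
  threshold (default 50%) are dropped from imputation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import POLLUTANTS, StationPanel

__all__ = [
    "aggregate_daily",
    "log_transform",
    "summarize",
    "correlation_table",
    "missingness_by_site",
    "exclusion_filter",
]


# ---------------------------------------------------------------------------
# temporal aggregation
# ---------------------------------------------------------------------------

def aggregate_daily(
    hourly: pd.Series, window_hours: int, completeness: float = 0.75
) -> pd.Series:
    """Collapse an hourly series to daily values under a completeness rule.

    window_hours=24: calendar-day mean, valid iff the fraction of the 24
    hourly slots observed is >= ``completeness`` (inclusive).

    window_hours=8: for every 8-h window starting within the day, the window
    mean is valid iff >= ``completeness`` of its 8 slots are observed; the
    daily value is the maximum valid window mean.  Days with no valid window
    are missing.
    """
    if window_hours not in (24, 8):
        raise ValueError("window_hours must be 24 or 8")
    if not 0.0 < completeness <= 1.0:
        raise ValueError("completeness must lie in (0, 1]")
    if len(hourly) == 0:
        return pd.Series(dtype=float)
    if not isinstance(hourly.index, pd.DatetimeIndex):
        raise TypeError("hourly series must have a DatetimeIndex")

    idx = hourly.index
    if len(idx) > 1:
        deltas = np.diff(idx.asi8)
        if not np.all(deltas == 3_600_000_000_000):
            raise ValueError("input is not on a regular hourly grid")

    # pad to whole calendar days so every day has a 24-slot denominator
    full = pd.date_range(
        idx[0].normalize(), idx[-1].normalize() + pd.Timedelta(hours=23), freq="h"
    )
    x = hourly.reindex(full)

    if window_hours == 24:
        grouped = x.groupby(x.index.normalize())
        means = grouped.mean()
        frac = grouped.count() / 24.0
        means[frac < completeness] = np.nan
        return means

    # 8-h rolling means labelled at the window START hour
    roll = x[::-1].rolling(window=8, min_periods=1)
    rmean = roll.mean()[::-1]
    rcount = roll.count()[::-1]
    need = completeness * 8.0
    rmean[rcount < need] = np.nan
    # windows that run past the end of the series have < 8 slots by
    # construction; the count rule already handles them
    grouped = rmean.groupby(rmean.index.normalize())
    return grouped.max()


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform(
    panel: StationPanel, pollutants: list[str] | None = None
) -> StationPanel:
    """Natural log of the pollutant columns; meteorology untouched.

    Zeros are shifted by eps = half the smallest positive observed value of
    the column (scale-aware, order-preserving).  Negative pollutant values
    are an error.
    """
    cols = [c for c in (pollutants or POLLUTANTS) if c in panel.data.columns]
    out = panel.data.copy()
    for c in cols:
        v = out[c].to_numpy(dtype=float, copy=True)
        obs = ~np.isnan(v)
        neg = obs & (v < 0)
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            raise ValueError(
                f"negative pollutant value {v[i]!r} in column {c!r} "
                f"at {panel.data.index[i].date()}"
            )
        pos = v[obs & (v > 0)]
        if (obs & (v == 0)).any():
            if pos.size == 0:
                raise ValueError(f"column {c!r} has no positive values to set eps")
            v[obs & (v == 0)] = pos.min() / 2.0
        v[obs] = np.log(v[obs])
        out[c] = v
    return StationPanel(panel.station, out)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _one_summary(s: pd.Series, n_frame: int) -> dict:
    obs = s.dropna()
    row = dict.fromkeys(
        ["min", "q25", "median", "q75", "max", "mean", "sd"], np.nan
    )
    if len(obs) > 0:
        row.update(
            min=obs.min(),
            q25=obs.quantile(0.25),  # linear interpolation
            median=obs.quantile(0.50),
            q75=obs.quantile(0.75),
            max=obs.max(),
            mean=obs.mean(),
            sd=obs.std(ddof=1) if len(obs) > 1 else 0.0,
        )
    row["n_obs"] = len(obs)
    row["pct_missing"] = 100.0 * (n_frame - len(obs)) / n_frame
    return row


def summarize(
    panels: list[StationPanel], variables: list[str] | None = None
) -> pd.DataFrame:
    """Per station x variable descriptive table plus a pooled ``All`` block.

    %missing uses the full date frame of each station as denominator.
    """
    rows = []
    for p in panels:
        cols = variables or list(p.data.columns)
        for c in cols:
            rows.append(
                {"station": p.station, "variable": c,
                 **_one_summary(p.data[c], len(p.data))}
            )
    first_cols = variables or list(panels[0].data.columns)
    for c in first_cols:
        pooled = pd.concat([p.data[c] for p in panels if c in p.data.columns])
        n_frame = sum(len(p.data) for p in panels if c in p.data.columns)
        rows.append({"station": "All", "variable": c, **_one_summary(pooled, n_frame)})
    out = pd.DataFrame(rows).set_index(["station", "variable"])
    ok = out.dropna(subset=["min"])
    ordered = (
        (ok["min"] <= ok["q25"]) & (ok["q25"] <= ok["median"])
        & (ok["median"] <= ok["q75"]) & (ok["q75"] <= ok["max"])
    )
    assert ordered.all(), "quantile ordering violated"
    return out


def correlation_table(
    data: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided p and stars.

    Stars: ``*`` p<0.1, ``**`` p<0.05, ``***`` p<0.01, ``****`` p<0.001.
    Pairs with fewer than ``min_pairs`` complete observations are missing.
    """
    cols = list(data.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            pair = data[[cols[i], cols[j]]].dropna()
            if len(pair) < min_pairs:
                continue
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue

    def star(pv):
        if np.isnan(pv):
            return ""
        if pv < 0.001:
            return "****"
        if pv < 0.01:
            return "***"
        if pv < 0.05:
            return "**"
        if pv < 0.1:
            return "*"
        return ""

    stars = pd.DataFrame(
        [[star(p[i, j]) for j in range(k)] for i in range(k)],
        index=cols, columns=cols,
    )
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        stars,
    )


def missingness_by_site(
    panels: list[StationPanel], pollutants: list[str] | None = None
) -> pd.DataFrame:
    """Missing count/percent per station x pollutant with a chi-square
    homogeneity p-value per pollutant.

    Percent = 100 * count / station frame length, rounded to one decimal.
    The test is Pearson chi-square (no continuity correction) on the
    station x (missing, observed) contingency table.
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 stations for a homogeneity test")
    cols = pollutants or [c for c in POLLUTANTS if c in panels[0].data.columns]
    rows = []
    for c in cols:
        rec: dict = {"pollutant": c}
        table = []
        for p in panels:
            n = len(p.data)
            miss = int(p.data[c].isna().sum())
            rec[f"{p.station}_missing"] = miss
            rec[f"{p.station}_pct"] = round(100.0 * miss / n, 1)
            table.append([miss, n - miss])
        table = np.asarray(table)
        if (table.sum(axis=0) == 0).any():
            warnings.warn(
                f"{c}: zero expected count in homogeneity table; p not computed"
            )
            rec["p_value"] = np.nan
        elif (table == table[0]).all():
            rec["p_value"] = 1.0  # identical rows: statistic exactly 0
        else:
            chi2, pval, _, _ = stats.chi2_contingency(table, correction=False)
            rec["p_value"] = pval
        rows.append(rec)
    return pd.DataFrame(rows).set_index("pollutant")


def exclusion_filter(
    panels: list[StationPanel],
    threshold: float = 0.5,
    pollutants: list[str] | None = None,
) -> list[str]:
    """Pollutants whose pooled missing fraction strictly exceeds ``threshold``."""
    cols = pollutants or [c for c in POLLUTANTS if c in panels[0].data.columns]
    drop = []
    for c in cols:
        n = sum(len(p.data) for p in panels)
        miss = sum(int(p.data[c].isna().sum()) for p in panels)
        if miss / n > threshold:
            drop.append(c)
    return drop
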