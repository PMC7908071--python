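"""Scoring of imputations against the vault, and the full
method x mechanism x rate benchmark grid.

Scores are computed on the pipeline's working (log) scale, over vault
cells only.  NRMSE uses the population (1/n) variance of the true masked
values so that imputing the masked-cell mean gives exactly 1.0 — the
no-skill yardstick.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .amputation import MissingnessSpec, ampute
from .baselines import ImputerSpec, impute
from .synthetic import StationPanel

__all__ = [
    "rmse", "mae", "nrmse", "correlation_R",
    "score_imputation", "BenchmarkTable", "benchmark_grid",
]


def rmse(true: np.ndarray, imputed: np.ndarray) -> float:
    true, imputed = np.asarray(true, float), np.asarray(imputed, float)
    if true.size == 0:
        raise ValueError("empty input")
    if true.shape != imputed.shape:
        raise ValueError("inputs must share a shape")
    return float(np.sqrt(np.mean((true - imputed) ** 2)))


def mae(true: np.ndarray, imputed: np.ndarray) -> float:
    true, imputed = np.asarray(true, float), np.asarray(imputed, float)
    if true.size == 0:
        raise ValueError("empty input")
    if true.shape != imputed.shape:
        raise ValueError("inputs must share a shape")
    return float(np.mean(np.abs(true - imputed)))


def nrmse(
    true: pd.DataFrame | np.ndarray,
    imputed: pd.DataFrame | np.ndarray,
    mask: pd.DataFrame | np.ndarray,
) -> float:
    """sqrt( mean sq. error over masked cells / population variance of the
    true masked values )."""
    t = np.asarray(true, float)[np.asarray(mask, bool)]
    x = np.asarray(imputed, float)[np.asarray(mask, bool)]
    if t.size == 0:
        raise ValueError("mask selects no cells")
    var = float(np.var(t))  # population (1/n) variance
    if var == 0.0:
        raise ValueError("true masked values have zero variance")
    return float(np.sqrt(np.mean((t - x) ** 2) / var))


def correlation_R(true: np.ndarray, imputed: np.ndarray) -> float:
    """Pearson r between vault truths and their imputations."""
    true, imputed = np.asarray(true, float), np.asarray(imputed, float)
    if true.size < 3:
        raise ValueError("need at least 3 vault cells")
    if np.var(true) == 0.0 or np.var(imputed) == 0.0:
        warnings.warn("zero variance; correlation undefined")
        return np.nan
    return float(stats.pearsonr(true, imputed).statistic)


def score_imputation(amputed, imputed: pd.DataFrame) -> dict[str, float]:
    """RMSE/MAE/R/NRMSE of an AmputedPanel's completion, averaged over the
    amputed variables (macro average, so no variable's scale dominates).
    Each variable is scored on its own vault cells."""
    mask = amputed.mask
    cols = [c for c in mask.columns if mask[c].any()]
    per = {"rmse": [], "mae": [], "r": [], "nrmse": []}
    for c in cols:
        m = mask[c].to_numpy()
        t = amputed.vault[c].to_numpy()[m]
        x = imputed[c].to_numpy()[m]
        per["rmse"].append(rmse(t, x))
        per["mae"].append(mae(t, x))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per["r"].append(
                correlation_R(t, x)
                if t.size >= 3 and np.var(x) > 0 and np.var(t) > 0
                else np.nan
            )
        per["nrmse"].append(float(np.sqrt(np.mean((t - x) ** 2) / np.var(t))))
    return {k: float(np.nanmean(v)) for k, v in per.items()}


@dataclass
class BenchmarkTable:
    """Long-format results keyed by (method, mechanism, rate, replicate)."""

    results: pd.DataFrame
    master_seed: int
    n_replicates: int

    def aggregate(self) -> pd.DataFrame:
        """Mean over replicates per (method, mechanism, rate)."""
        ok = self.results[self.results["status"] == "ok"]
        return (
            ok.groupby(["method", "mechanism", "rate"])[["rmse", "mae", "r", "nrmse"]]
            .mean()
            .reset_index()
        )

    def pivot(self, metric: str = "rmse") -> pd.DataFrame:
        """Method x (mechanism within rate block) layout of one metric."""
        agg = self.aggregate()
        return agg.pivot_table(
            index="method", columns=["rate", "mechanism"], values=metric
        )

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def _sub_seed(master: int, *parts) -> int:
    h = zlib.crc32(("|".join(map(str, parts))).encode())
    return (int(master) * 2_654_435_761 + h) % (2**31)


def benchmark_grid(
    panels: list[StationPanel],
    methods: list[ImputerSpec | str],
    mechanisms: list[str] = ("MCAR", "MAR", "MNAR"),
    rates: list[float] = (0.05, 0.10, 0.20, 0.30, 0.40),
    replicates: int = 10,
    master_seed: int = 0,
    targets: tuple[str, ...] = ("CO", "NO2", "O3", "SO2"),
    resume_from: pd.DataFrame | None = None,
) -> BenchmarkTable:
    """Full factorial benchmark on complete, preprocessed panels.

    Panels must already be on the working (log) scale with over-missing
    pollutants dropped.  Replicate r runs on panel r mod len(panels), so
    every station participates.  The amputation sub-seed depends only on
    (mechanism, rate, replicate): all methods score identical amputations.
    An imputer failure marks the cell failed and the grid continues.
    """
    specs = [ImputerSpec(m) if isinstance(m, str) else m for m in methods]
    done = set()
    rows = []
    if resume_from is not None:
        rows = resume_from.to_dict("records")
        done = {
            (r["method"], r["mechanism"], float(r["rate"]), int(r["replicate"]))
            for r in rows
        }

    for mech in mechanisms:
        for rate in rates:
            for rep in range(replicates):
                panel = panels[rep % len(panels)]
                amp_seed = _sub_seed(master_seed, "amp", mech, rate, rep)
                amputed = ampute(
                    panel,
                    MissingnessSpec(
                        mechanism=mech, rate=rate, targets=targets, seed=amp_seed
                    ),
                )
                for spec in specs:
                    key = (spec.method, mech, float(rate), rep)
                    if key in done:
                        continue
                    imp_seed = _sub_seed(master_seed, spec.method, mech, rate, rep)
                    row = {
                        "method": spec.method, "mechanism": mech,
                        "rate": float(rate), "replicate": rep,
                        "station": panel.station,
                    }
                    try:
                        completed = impute(
                            amputed.panel.data, replace(spec, seed=imp_seed)
                        )
                        row.update(score_imputation(amputed, completed))
                        row["status"] = "ok"
                    except Exception as exc:  # cell fails, grid continues
                        warnings.warn(f"{key}: imputer failed: {exc}")
                        row.update(rmse=np.nan, mae=np.nan, r=np.nan,
                                   nrmse=np.nan, status="failed")
                    rows.append(row)
    return BenchmarkTable(pd.DataFrame(rows), master_seed, replicates)
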