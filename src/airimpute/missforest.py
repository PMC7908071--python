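"""Iterative random-forest imputation (missForest-style), written from
scratch on top of sklearn regression forests.

The algorithm: start from a mean (or median) initial fill; visit variables
in order of missing count; for each variable s, fit a random forest of the
observed part y_obs(s) on the other columns at their current imputed values
and replace the missing part y_mis(s) with forest predictions.  After each
full sweep compute the matrix difference

    delta_N = sum((X_new - X_old)^2) / sum(X_new^2)      (continuous columns)
    delta_F = (# disagreeing entries) / (# NA)            (categorical columns)

and stop the first time the difference increases, returning the previous
sweep's matrix (the last one before the increase).  All variables in this
pipeline are continuous, so the stopping rule uses delta_N alone; one
warm-up sweep always runs before the rule can fire.

Per-variable out-of-bag (OOB) NRMSE is recorded at every sweep; the result
carries the values belonging to the returned matrix, giving an estimate of
imputation error that needs no ground truth.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ImputerParams",
    "ImputationResult",
    "initial_guess",
    "delta_continuous",
    "delta_categorical",
    "missforest_impute",
    "oob_error_gap",
]


@dataclass(frozen=True)
class ImputerParams:
    n_trees: int = 100
    m_try: int | str = "sqrt"       # features per split
    max_iterations: int = 10
    initial: str = "mean"           # mean | median
    column_order: str = "ascending"  # by missing count; or "descending"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.initial not in ("mean", "median"):
            raise ValueError("initial must be 'mean' or 'median'")
        if self.column_order not in ("ascending", "descending"):
            raise ValueError("column_order must be 'ascending' or 'descending'")


@dataclass
class ImputationResult:
    X_imp: pd.DataFrame
    iterations: int
    delta_trace: list[tuple[float, float | None]]
    oob_nrmse: dict[str, float]
    stopped_by: str  # "criterion" | "max_iterations"


def initial_guess(X: pd.DataFrame, strategy: str = "mean") -> pd.DataFrame:
    """Column-wise mean/median fill; observed cells untouched."""
    out = X.copy()
    for c in X.columns:
        col = out[c]
        if col.isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
        if col.isna().any():
            fill = col.mean() if strategy == "mean" else col.median()
            out[c] = col.fillna(fill)
    return out


def delta_continuous(
    X_new: pd.DataFrame | np.ndarray,
    X_old: pd.DataFrame | np.ndarray,
    continuous: list | None = None,
) -> float:
    """Sum-of-squares matrix difference ratio over the continuous columns."""
    new = pd.DataFrame(X_new)
    old = pd.DataFrame(X_old)
    if continuous is not None:
        new, old = new[continuous], old[continuous]
    a = new.to_numpy(dtype=float)
    b = old.to_numpy(dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ValueError("degenerate all-zero imputation: sum(X_new^2) = 0")
    return float(np.sum((a - b) ** 2)) / denom


def delta_categorical(
    X_new: pd.DataFrame, X_old: pd.DataFrame, categorical: list, n_missing: int
) -> float:
    """Disagreement fraction over categorical columns, per missing cell."""
    if categorical and n_missing <= 0:
        raise ValueError("#NA must be positive when categorical columns exist")
    if not categorical:
        return 0.0
    disagree = int((X_new[categorical] != X_old[categorical]).to_numpy().sum())
    return disagree / n_missing


def _pop_nrmse(err: np.ndarray, truth: np.ndarray) -> float:
    var = float(np.var(truth))  # population variance
    if var == 0.0:
        return np.nan
    return float(np.sqrt(np.mean(err ** 2) / var))


def _forest_seed(base: int, sweep: int, col: str) -> int:
    return (base * 1_000_003 + sweep * 9973 + zlib.crc32(col.encode())) % (2**31)


def missforest_impute(
    X: pd.DataFrame, params: ImputerParams = ImputerParams()
) -> ImputationResult:
    """Impute a numeric matrix with the iterative forest scheme.

    Observed cells are bit-exact invariants of the procedure; the result is
    deterministic given ``params.seed``.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    miss = X.isna()
    n_miss = miss.sum()
    cols_with_missing = [c for c in X.columns if n_miss[c] > 0]

    if not cols_with_missing:
        return ImputationResult(X.copy(), 0, [], {}, "criterion")

    cur = initial_guess(X, params.initial)
    order = sorted(
        cols_with_missing,
        key=lambda c: n_miss[c],
        reverse=(params.column_order == "descending"),
    )

    constant = {}
    for c in list(order):
        obs = X[c].dropna()
        if obs.nunique() <= 1:
            warnings.warn(f"column {c!r} is constant; forest skipped")
            constant[c] = float(obs.iloc[0])
            order.remove(c)
    for c, v in constant.items():
        cur[c] = X[c].fillna(v)
    if not order:
        return ImputationResult(cur, 0, [], dict.fromkeys(constant, np.nan),
                                "criterion")

    trace: list[tuple[float, float | None]] = []
    prev_matrix = cur.copy()
    prev_oob: dict[str, float] = {}
    prev_delta = np.inf
    stopped_by = "max_iterations"
    iterations = 0

    for sweep in range(1, params.max_iterations + 1):
        old = cur.copy()
        oob: dict[str, float] = {}
        for c in order:
            m = miss[c].to_numpy()
            others = [x for x in cur.columns if x != c]
            Xp = cur[others].to_numpy()
            y = X[c].to_numpy()
            rf = RandomForestRegressor(
                n_estimators=params.n_trees,
                max_features=params.m_try,
                oob_score=True,
                bootstrap=True,
                random_state=_forest_seed(params.seed, sweep, c),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                # few trees can leave some samples never OOB; handled below
                warnings.simplefilter("ignore")
                rf.fit(Xp[~m], y[~m])
            pred = rf.predict(Xp[m])
            col = cur[c].to_numpy(copy=True)
            col[m] = pred
            cur[c] = col
            oob_pred = rf.oob_prediction_
            valid = np.isfinite(oob_pred)
            oob[c] = _pop_nrmse(y[~m][valid] - oob_pred[valid], y[~m][valid])

        d = delta_continuous(cur, old)
        trace.append((d, None))
        iterations = sweep

        if sweep >= 2 and d > prev_delta:
            cur = prev_matrix          # return the previous iterate
            oob = prev_oob
            stopped_by = "criterion"
            break
        prev_matrix = cur.copy()
        prev_oob = oob
        prev_delta = d

    oob.update(dict.fromkeys(constant, np.nan))
    # observed cells are untouched by construction; re-impose exactly anyway
    result = cur.where(miss, X)
    return ImputationResult(result, iterations, trace, oob, stopped_by)


def oob_error_gap(
    result: ImputationResult, vault: pd.DataFrame, mask: pd.DataFrame
) -> dict[str, float]:
    """|OOB NRMSE - true NRMSE| per variable; needs the amputation vault."""
    if vault is None:
        raise ValueError("no vault available")
    gaps = {}
    for c, oob in result.oob_nrmse.items():
        m = mask[c].to_numpy()
        if not m.any():
            continue
        truth = vault[c].to_numpy()[m]
        imput = result.X_imp[c].to_numpy()[m]
        true_nrmse = _pop_nrmse(imput - truth, truth)
        gaps[c] = abs(oob - true_nrmse)
    return gaps
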