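"""Multiple-imputation orchestration and Rubin's-rules pooling.

Each station is processed independently: m completions are produced with
distinct sub-seeds (stochastic imputers) or with bootstrap retraining
(deterministic imputers, so the completions still differ), any per-
completion analysis is run, and the m estimates are pooled:

    pooled estimate  = mean of the m estimates
    within variance  W = mean of the m variances
    between variance B = sample variance of the m estimates
    total variance   T = W + (1 + 1/m) B
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import ImputerSpec, impute, knn_impute

__all__ = ["MIEnsemble", "PooledEstimate", "run_mi", "pool"]

#: imputers whose output does not change with the seed
_DETERMINISTIC = {"mean", "knn", "bpca"}


@dataclass
class PooledEstimate:
    estimate: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray


@dataclass
class MIEnsemble:
    m: int
    completions: list[pd.DataFrame]
    master_seed: int

    def analyze(self, statistic) -> list[np.ndarray]:
        """Apply a per-completion statistic (matrix -> vector)."""
        return [np.asarray(statistic(c), dtype=float) for c in self.completions]

    def pool_means(self) -> PooledEstimate:
        """Pool per-variable column means with their sampling variances."""
        ests, vars_ = [], []
        for c in self.completions:
            v = c.to_numpy()
            ests.append(v.mean(axis=0))
            vars_.append(v.var(axis=0, ddof=1) / v.shape[0])
        return pool(ests, vars_)


def pool(estimates: list[np.ndarray], variances: list[np.ndarray]) -> PooledEstimate:
    """Rubin's rules for m >= 2 aligned estimate/variance vectors."""
    est = [np.atleast_1d(np.asarray(e, float)) for e in estimates]
    var = [np.atleast_1d(np.asarray(v, float)) for v in variances]
    m = len(est)
    if m < 2:
        raise ValueError("need m >= 2 estimates")
    if len(var) != m or any(e.shape != est[0].shape for e in est) or any(
        v.shape != est[0].shape for v in var
    ):
        raise ValueError("estimates and variances must align")
    E = np.stack(est)
    V = np.stack(var)
    qbar = E.mean(axis=0)
    W = V.mean(axis=0)
    B = E.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    return PooledEstimate(qbar, W, B, T)


def _bootstrap_deterministic(
    X: pd.DataFrame, spec: ImputerSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One bootstrap completion for a deterministic imputer: retrain on a
    row resample, impute the original matrix."""
    n = len(X)
    boot = X.iloc[rng.integers(0, n, size=n)].reset_index(drop=True)
    if spec.method == "mean":
        fills = boot.mean()
        return X.fillna(fills)
    if spec.method == "knn":
        # donors come from the bootstrap pool: append the original rows,
        # impute, read back the original block
        stack = pd.concat([X.reset_index(drop=True), boot], ignore_index=True)
        completed = knn_impute(stack, spec)
        out = completed.iloc[: n].set_axis(X.index)
        return out
    if spec.method == "bpca":
        mu = boot.mean()
        sd = boot.std(ddof=0).replace(0.0, 1.0)
        bz = ((boot - mu) / sd).fillna(0.0).to_numpy()
        k = spec.n_components if spec.n_components is not None else X.shape[1] - 1
        _, _, Vt = np.linalg.svd(bz, full_matrices=False)
        Wk = Vt[:k].T                                # subspace from the resample
        Z = ((X - mu) / sd).to_numpy()
        out = X.to_numpy(copy=True)
        for i in range(n):
            mrow = np.isnan(Z[i])
            if not mrow.any():
                continue
            o = ~mrow
            Wo = Wk[o]
            z, *_ = np.linalg.lstsq(Wo, Z[i, o], rcond=None)
            rec = Wk @ z
            out[i, mrow] = (rec * sd.to_numpy() + mu.to_numpy())[mrow]
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    raise ValueError(f"no bootstrap path for method {spec.method!r}")


def run_mi(
    amputed,
    spec: ImputerSpec,
    m: int = 20,
    seed: int = 0,
    bootstrap: bool | None = None,
) -> MIEnsemble:
    """Produce an m-completion ensemble for one station's amputed panel.

    Stochastic imputers get distinct sub-seeds.  Deterministic imputers
    need ``bootstrap=True`` (retrain on row resamples) — requesting them
    without it is an error, since the m completions would be identical.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    X = amputed.panel.data
    deterministic = spec.method in _DETERMINISTIC
    if deterministic and not bootstrap:
        raise ValueError(
            f"{spec.method!r} is deterministic: pass bootstrap=True so the "
            "m completions differ"
        )
    ss = np.random.SeedSequence([seed, 0x4D49])  # per-ensemble stream
    child_seeds = ss.generate_state(m) % (2**31)
    completions = []
    for j in range(m):
        if deterministic:
            rng = np.random.default_rng(int(child_seeds[j]))
            completions.append(_bootstrap_deterministic(X, spec, rng))
        else:
            completions.append(impute(X, replace(spec, seed=int(child_seeds[j]))))
    return MIEnsemble(m, completions, seed)
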