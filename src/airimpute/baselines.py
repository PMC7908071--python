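"""Baseline imputers behind a single contract: k-nearest-neighbour,
predictive mean matching, multivariate-normal EM with bootstrapping,
iterative low-rank reconstruction (BPCA-style), chained random-forest
draws, and column-mean imputation as the no-skill null.

Each is a simplified but faithful form of the published algorithm it stands
for; exact numeric parity with the R packages that popularized them (VIM,
mice, Amelia, pcaMethods) is a non-goal.  All imputers leave observed cells
untouched, return a complete matrix, and are deterministic under a fixed
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .missforest import ImputerParams, initial_guess, missforest_impute

__all__ = [
    "ImputerSpec",
    "mean_impute",
    "knn_impute",
    "pmm_impute",
    "em_impute",
    "em_fit",
    "conditional_mean",
    "bpca_impute",
    "chained_rf_impute",
    "impute",
    "METHODS",
]

METHODS = ("missforest", "knn", "pmm", "em", "bpca", "chained_rf", "mean")


@dataclass(frozen=True)
class ImputerSpec:
    method: str = "missforest"
    k: int = 5                 # knn neighbours
    donors: int = 5            # pmm donor pool
    n_components: int | None = None  # bpca; default p-1
    max_iterations: int = 10
    n_trees: int = 100         # missforest; chained_rf uses rf_trees
    rf_trees: int = 10         # chained_rf forest size (mice 'rf' convention)
    em_draw: bool = True       # draw from the conditional normal (EMB-style)
    n_bootstrap: int = 1       # em: bootstrap resamples of rows before EM
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.k < 1 or self.donors < 1:
            raise ValueError("k and donors must be >= 1")


# ---------------------------------------------------------------------------
# mean (null)
# ---------------------------------------------------------------------------

def mean_impute(X: pd.DataFrame, spec: ImputerSpec | None = None) -> pd.DataFrame:
    return initial_guess(X, "mean")


# ---------------------------------------------------------------------------
# k-nearest neighbours
# ---------------------------------------------------------------------------

def knn_impute(X: pd.DataFrame, spec: ImputerSpec = ImputerSpec("knn")) -> pd.DataFrame:
    """Distance = Euclidean over mutually observed standardized coordinates,
    rescaled by sqrt(p / #shared); missing cell <- mean of the k nearest
    rows observed in that variable.
    """
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    if np.isnan(V).all(axis=1).any():
        raise ValueError("every row must have at least one observed value")
    mu = np.nanmean(V, axis=0)
    sd = np.nanstd(V, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (V - mu) / sd
    obs = ~np.isnan(Z)
    Z0 = np.where(obs, Z, 0.0)

    out = V.copy()
    for j in range(p):
        mis_rows = np.flatnonzero(np.isnan(V[:, j]))
        if mis_rows.size == 0:
            continue
        feat = [c for c in range(p) if c != j]
        A, Ao = Z0[:, feat], obs[:, feat]
        donors_ok = obs[:, j]
        for i in mis_rows:
            shared = Ao[i] & Ao              # (n, p-1)
            cnt = shared.sum(axis=1)
            diff = (A[i] - A) * shared
            with np.errstate(divide="ignore", invalid="ignore"):
                d2 = (diff ** 2).sum(axis=1) * (len(feat) / cnt)
            d2[cnt == 0] = np.inf
            d2[i] = np.inf
            d2[~donors_ok] = np.inf
            finite = np.isfinite(d2)
            if not finite.any():
                warnings.warn(f"no donor for cell ({i}, {X.columns[j]!r}); "
                              "column mean used")
                out[i, j] = mu[j]
                continue
            k = min(spec.k, int(finite.sum()))
            nearest = np.argpartition(d2, k - 1)[:k]
            out[i, j] = V[nearest, j].mean()
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# predictive mean matching
# ---------------------------------------------------------------------------

def pmm_impute(X: pd.DataFrame, spec: ImputerSpec = ImputerSpec("pmm")) -> pd.DataFrame:
    """Type-1 PMM: Bayesian draw of regression coefficients; each missing
    cell takes the observed value of a donor sampled from the ``donors``
    closest predicted means.
    """
    rng = np.random.default_rng(spec.seed)
    filled = initial_guess(X, "mean").to_numpy(dtype=float)
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    out = V.copy()
    for j in range(p):
        mis = np.isnan(V[:, j])
        if not mis.any():
            continue
        obs = ~mis
        D = np.column_stack([np.ones(n), np.delete(filled, j, axis=1)])
        y = V[obs, j]
        Do, Dm = D[obs], D[mis]
        q = D.shape[1]
        XtX = Do.T @ Do
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            warnings.warn("singular design; ridge fallback")
            XtX_inv = np.linalg.inv(XtX + 1e-6 * np.eye(q))
        beta_hat = XtX_inv @ Do.T @ y
        resid = y - Do @ beta_hat
        dof = max(len(y) - q, 1)
        sigma2_draw = resid @ resid / rng.chisquare(dof)
        L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(q))
        beta_draw = beta_hat + np.sqrt(sigma2_draw) * (L @ rng.standard_normal(q))

        pred_obs = Do @ beta_hat        # type-1: OLS means for the donors
        pred_mis = Dm @ beta_draw       # drawn coefficients for the targets
        for row, pm in zip(np.flatnonzero(mis), pred_mis):
            dist = np.abs(pred_obs - pm)
            kk = min(spec.donors, len(y))
            pool = np.argpartition(dist, kk - 1)[:kk]
            out[row, j] = y[rng.choice(pool)]
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# EM for the multivariate normal (+ bootstrap, EMB-style)
# ---------------------------------------------------------------------------

class EMConvergenceError(RuntimeError):
    def __init__(self, msg, loglik_trace):
        super().__init__(msg)
        self.loglik_trace = loglik_trace


def _loglik(V, mu, Sigma):
    ll = 0.0
    for i in range(V.shape[0]):
        o = ~np.isnan(V[i])
        if not o.any():
            continue
        x = V[i, o] - mu[o]
        S = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(S)
        ll += -0.5 * (o.sum() * np.log(2 * np.pi) + logdet
                      + x @ np.linalg.solve(S, x))
    return ll


def em_fit(
    X: pd.DataFrame | np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """EM estimates (mu, Sigma) of a multivariate normal with missing data.

    Returns the log-likelihood trace; raises ``EMConvergenceError`` if the
    relative parameter change has not fallen below ``tol`` in ``max_iter``
    steps.  With complete data the first M-step already equals the sample
    moments.
    """
    V = np.asarray(X, dtype=float)
    n, p = V.shape
    miss = np.isnan(V)
    mu = np.nanmean(V, axis=0)
    filled = np.where(miss, mu, V)
    Sigma = np.cov(filled, rowvar=False, ddof=0) + 1e-6 * np.eye(p)
    trace: list[float] = []

    if not miss.any():
        Sigma = np.cov(V, rowvar=False, ddof=0)
        return mu, Sigma, [_loglik(V, mu, Sigma + 1e-12 * np.eye(p))]

    patterns = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)

    for _ in range(max_iter):
        EX = V.copy()
        C = np.zeros((p, p))  # sum of conditional covariance corrections
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            rows = np.asarray(rows)
            if o.any():
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                B = np.linalg.solve(Soo, Smo.T).T       # regression coefs
                cond = mu[m] + (V[np.ix_(rows, o)] - mu[o]) @ B.T
                cov_corr = Sigma[np.ix_(m, m)] - B @ Smo.T
            else:
                cond = np.broadcast_to(mu[m], (len(rows), int(m.sum())))
                cov_corr = Sigma[np.ix_(m, m)]
            EX[np.ix_(rows, m)] = cond
            C[np.ix_(m, m)] += len(rows) * cov_corr
        mu_new = EX.mean(axis=0)
        diff = EX - mu_new
        Sigma_new = (diff.T @ diff + C) / n
        change = max(
            np.max(np.abs(mu_new - mu)) / (1 + np.max(np.abs(mu))),
            np.max(np.abs(Sigma_new - Sigma)) / (1 + np.max(np.abs(Sigma))),
        )
        mu, Sigma = mu_new, Sigma_new
        trace.append(_loglik(V, mu, Sigma + 1e-12 * np.eye(p)))
        if change < tol:
            return mu, Sigma, trace
    raise EMConvergenceError(
        f"EM did not converge in {max_iter} steps", trace
    )


def conditional_mean(
    mu: np.ndarray, Sigma: np.ndarray, row: np.ndarray
) -> np.ndarray:
    """Closed-form conditional mean of a row's missing block given its
    observed block under N(mu, Sigma).  Returns the completed row."""
    row = np.asarray(row, dtype=float)
    m = np.isnan(row)
    if not m.any():
        return row
    o = ~m
    out = row.copy()
    if not o.any():
        out[m] = mu[m]
        return out
    Soo = Sigma[np.ix_(o, o)]
    Smo = Sigma[np.ix_(m, o)]
    out[m] = mu[m] + Smo @ np.linalg.solve(Soo, row[o] - mu[o])
    return out


def em_impute(
    X: pd.DataFrame,
    spec: ImputerSpec = ImputerSpec("em"),
    n_bootstrap: int | None = None,
    params: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame | list[pd.DataFrame]:
    """EM-with-bootstrapping imputation.

    Parameters are estimated by multivariate-normal EM on a bootstrap
    resample of the rows; each missing block is then imputed from its
    conditional normal given the observed block — by a random draw when
    ``spec.em_draw`` (the cited algorithm's behaviour, which propagates
    residual uncertainty), or by the conditional mean when not.

    ``params=(mu, Sigma)`` skips estimation (used by the closed-form
    oracle checks).  ``n_bootstrap > 1`` returns that many completions.
    """
    nb = spec.n_bootstrap if n_bootstrap is None else n_bootstrap
    rng = np.random.default_rng(spec.seed)
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    miss = np.isnan(V)

    completions = []
    for _ in range(max(nb, 1)):
        if params is not None:
            mu, Sigma = params
        else:
            boot = V[rng.integers(0, n, size=n)] if nb >= 1 else V
            # a bootstrap may lose all observations of a cell pattern; EM
            # handles any pattern, only all-NaN columns are fatal
            mu, Sigma, _ = em_fit(boot, max_iter=200)
        out = V.copy()
        for i in range(n):
            m = miss[i]
            if not m.any():
                continue
            o = ~m
            if o.any():
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                B = np.linalg.solve(Soo, Smo.T).T
                cm = mu[m] + B @ (V[i, o] - mu[o])
                cv = Sigma[np.ix_(m, m)] - B @ Smo.T
            else:
                cm = mu[m]
                cv = Sigma[np.ix_(m, m)]
            if spec.em_draw:
                L = np.linalg.cholesky(cv + 1e-10 * np.eye(int(m.sum())))
                out[i, m] = cm + L @ rng.standard_normal(int(m.sum()))
            else:
                out[i, m] = cm
        completions.append(pd.DataFrame(out, index=X.index, columns=X.columns))
    return completions[0] if nb <= 1 else completions


# ---------------------------------------------------------------------------
# BPCA-style iterative low-rank reconstruction
# ---------------------------------------------------------------------------

def bpca_impute(
    X: pd.DataFrame,
    spec: ImputerSpec = ImputerSpec("bpca"),
    return_trace: bool = False,
):
    """Alternate truncated-SVD reconstruction of the missing cells and
    refit on standardized columns until the change at missing cells falls
    below 1e-8 (or ``max_iterations * 10`` sweeps; non-convergence returns
    the last iterate with a warning).  ``return_trace`` additionally yields
    the per-sweep low-rank reconstruction error (Frobenius), which is
    non-increasing for this alternating scheme."""
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    k = spec.n_components if spec.n_components is not None else p - 1
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k > min(n, p):
        raise ValueError("n_components cannot exceed min(n_rows, n_cols)")
    miss = np.isnan(V)
    C = np.where(miss, np.broadcast_to(np.nanmean(V, axis=0), V.shape), V)

    max_sweeps = spec.max_iterations * 10
    converged = False
    trace: list[float] = []
    for _ in range(max_sweeps):
        # re-estimate location/scale from the current completion (EM-PCA)
        mu = C.mean(axis=0)
        sd = C.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (C - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k]
        trace.append(float(np.linalg.norm(Z - recon)))
        delta = np.max(np.abs(recon[miss] - Z[miss])) if miss.any() else 0.0
        C[miss] = (recon * sd + mu)[miss]
        if delta < 1e-8:
            converged = True
            break
    if not converged:
        warnings.warn("low-rank reconstruction did not converge; "
                      "returning last iterate")
    result = pd.DataFrame(C, index=X.index, columns=X.columns)
    return (result, trace) if return_trace else result


# ---------------------------------------------------------------------------
# chained random forest (MICE-RF analog)
# ---------------------------------------------------------------------------

def chained_rf_impute(
    X: pd.DataFrame, spec: ImputerSpec = ImputerSpec("chained_rf")
) -> pd.DataFrame:
    """Like the iterative-forest imputer but each missing cell takes the
    prediction of ONE tree sampled at random (a stochastic draw, chained-
    equations style), for a fixed number of cycles."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    rng = np.random.default_rng(spec.seed)
    miss = X.isna()
    n_miss = miss.sum()
    order = sorted([c for c in X.columns if n_miss[c] > 0], key=lambda c: n_miss[c])
    if not order:
        return X.copy()
    cur = initial_guess(X, "mean")
    for cycle in range(spec.max_iterations):
        for c in order:
            m = miss[c].to_numpy()
            others = [x for x in cur.columns if x != c]
            Xp = cur[others].to_numpy()
            y = X[c].to_numpy()
            rf = RandomForestRegressor(
                n_estimators=spec.rf_trees,
                max_features="sqrt",
                bootstrap=True,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(Xp[~m], y[~m])
            per_tree = np.stack([t.predict(Xp[m]) for t in rf.estimators_])
            pick = rng.integers(0, spec.rf_trees, size=int(m.sum()))
            col = cur[c].to_numpy(copy=True)
            col[m] = per_tree[pick, np.arange(int(m.sum()))]
            cur[c] = col
    return cur.where(miss, X)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def impute(X: pd.DataFrame, spec: ImputerSpec) -> pd.DataFrame:
    """Run the imputer named in ``spec``; returns a complete matrix."""
    if spec.method == "missforest":
        params = ImputerParams(
            n_trees=spec.n_trees, max_iterations=spec.max_iterations,
            seed=spec.seed,
        )
        return missforest_impute(X, params).X_imp
    if spec.method == "knn":
        return knn_impute(X, spec)
    if spec.method == "pmm":
        return pmm_impute(X, spec)
    if spec.method == "em":
        return em_impute(X, spec)
    if spec.method == "bpca":
        return bpca_impute(X, spec)
    if spec.method == "chained_rf":
        return chained_rf_impute(X, spec)
    return mean_impute(X, spec)


def with_seed(spec: ImputerSpec, seed: int) -> ImputerSpec:
    return replace(spec, seed=seed)
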