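"""Baseline imputers: contracts, hand-traceable fixtures, oracles."""

import numpy as np
import pandas as pd
import pytest

import airimpute as ai
from airimpute.baselines import ImputerSpec, conditional_mean, em_fit


def _mcar_frame(n=200, p=4, frac=0.2, seed=0):
    rng = np.random.default_rng(seed)
    L = rng.normal(size=(p, p))
    V = rng.normal(size=(n, p)) @ L.T
    df = pd.DataFrame(V, columns=[f"v{i}" for i in range(p)])
    out = df.copy()
    for j in range(p):
        idx = rng.choice(n, int(frac * n / p), replace=False)
        out.iloc[idx, j] = np.nan
    # guarantee no all-missing row
    out.iloc[0] = df.iloc[0]
    return df, out


ALL_METHODS = ["mean", "knn", "pmm", "em", "bpca", "chained_rf"]


class TestCommonContract:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_complete_output_observed_unchanged(self, method):
        _, dfm = _mcar_frame(seed=3)
        spec = ImputerSpec(method, seed=5, rf_trees=5, max_iterations=3)
        out = ai.impute(dfm, spec)
        assert out.notna().all().all()
        for c in dfm.columns:
            obs = dfm[c].notna().to_numpy()
            assert np.array_equal(out[c].to_numpy()[obs], dfm[c].to_numpy()[obs])

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_deterministic_under_fixed_seed(self, method):
        _, dfm = _mcar_frame(seed=4)
        spec = ImputerSpec(method, seed=11, rf_trees=5, max_iterations=3)
        a = ai.impute(dfm, spec)
        b = ai.impute(dfm, spec)
        pd.testing.assert_frame_equal(a, b)


class TestKNN:
    def test_equidistant_symmetric_fixture(self):
        # rows 1 and 2 are mirror images around row 0 in the feature column:
        # with k=2 the imputed value is the mean of both donors
        df = pd.DataFrame({"x": [0.0, 1.0, -1.0], "y": [np.nan, 3.0, 5.0]})
        out = ai.knn_impute(df, ImputerSpec("knn", k=2))
        assert out["y"].iloc[0] == pytest.approx(4.0)

    def test_duplicate_row_donor(self):
        df = pd.DataFrame(
            {"x": [1.0, 1.0, 9.0], "z": [2.0, 2.0, 7.0],
             "y": [np.nan, 42.0, 0.0]}
        )
        out = ai.knn_impute(df, ImputerSpec("knn", k=1))
        assert out["y"].iloc[0] == 42.0

    def test_matches_exhaustive_oracle(self):
        # 20x3 random matrix vs a brute-force all-pairs nearest-neighbour
        # search written independently of the implementation
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        dfm = df.copy()
        miss = [(2, "a"), (5, "b"), (11, "c"), (17, "a")]
        for i, c in miss:
            dfm.loc[i, c] = np.nan
        out = ai.knn_impute(dfm, ImputerSpec("knn", k=3))

        V = dfm.to_numpy()
        mu = np.nanmean(V, axis=0)
        sd = np.nanstd(V, axis=0)
        Z = (V - mu) / sd
        for i, c in miss:
            j = dfm.columns.get_loc(c)
            feats = [f for f in range(3) if f != j]
            dists = []
            for r in range(20):
                if r == i or np.isnan(V[r, j]):
                    dists.append(np.inf)
                    continue
                shared = [
                    f for f in feats
                    if not np.isnan(Z[i, f]) and not np.isnan(Z[r, f])
                ]
                if not shared:
                    dists.append(np.inf)
                    continue
                d2 = sum((Z[i, f] - Z[r, f]) ** 2 for f in shared)
                dists.append(np.sqrt(d2 * len(feats) / len(shared)))
            nearest = np.argsort(dists)[:3]
            assert out.loc[i, c] == pytest.approx(V[nearest, j].mean())


class TestPMM:
    def test_imputed_values_are_observed_donors(self):
        _, dfm = _mcar_frame(seed=9)
        out = ai.pmm_impute(dfm, ImputerSpec("pmm", seed=2))
        for c in dfm.columns:
            mis = dfm[c].isna()
            observed = set(dfm[c].dropna())
            assert set(out[c][mis]).issubset(observed)

    def test_single_donor_collinear_data(self):
        # y = 2x exactly: with donors=1 the imputed y is the observed y of
        # the row whose predicted mean (hence x) is nearest
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 2.2])
        y = 2 * x
        df = pd.DataFrame({"x": x, "y": y})
        df.loc[6, "y"] = np.nan
        out = ai.pmm_impute(df, ImputerSpec("pmm", donors=1, seed=0))
        assert out["y"].iloc[6] == 4.0  # donor row x=2.0

    def test_preserves_spread_unlike_mean_fill(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=2000)
        y = x + rng.normal(scale=1.0, size=2000)
        df = pd.DataFrame({"x": x, "y": y})
        dfm = df.copy()
        idx = rng.choice(2000, 400, replace=False)
        dfm.iloc[idx, 1] = np.nan
        out = ai.pmm_impute(dfm, ImputerSpec("pmm", seed=3))
        v_imp = out["y"].to_numpy()[idx].var()
        v_obs = dfm["y"].dropna().var()
        assert 0.75 * v_obs <= v_imp <= 1.25 * v_obs


class TestEM:
    def test_complete_data_equals_sample_moments(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(200, 3))
        mu, Sigma, trace = em_fit(V)
        assert np.allclose(mu, V.mean(axis=0))
        assert np.allclose(Sigma, np.cov(V, rowvar=False, ddof=0))

    def test_loglik_nondecreasing(self):
        _, dfm = _mcar_frame(seed=6)
        _, _, trace = em_fit(dfm.to_numpy())
        diffs = np.diff(trace)
        assert (diffs >= -1e-6).all()

    def test_conditional_mean_matches_closed_form(self):
        # bivariate normal: E[y|x] = mu_y + s_xy/s_xx (x - mu_x)
        mu = np.array([1.0, -2.0])
        Sigma = np.array([[2.0, 0.8], [0.8, 1.5]])
        row = np.array([3.0, np.nan])
        out = conditional_mean(mu, Sigma, row)
        expected = -2.0 + 0.8 / 2.0 * (3.0 - 1.0)
        assert abs(out[1] - expected) < 1e-6

    def test_impute_with_true_params_gives_conditional_mean(self):
        mu = np.array([0.0, 0.0])
        Sigma = np.array([[1.0, 0.6], [0.6, 1.0]])
        df = pd.DataFrame({"x": [1.5, 0.2], "y": [np.nan, 0.1]})
        out = ai.em_impute(df, ImputerSpec("em", em_draw=False),
                           params=(mu, Sigma))
        assert abs(out["y"].iloc[0] - 0.6 * 1.5) < 1e-6

    def test_draws_vary_but_center_on_conditional_mean(self):
        df, dfm = _mcar_frame(n=300, seed=8)
        a = ai.em_impute(dfm, ImputerSpec("em", seed=1))
        b = ai.em_impute(dfm, ImputerSpec("em", seed=2))
        assert not a.equals(b)  # stochastic draws

    def test_bootstrap_set_of_completions(self):
        _, dfm = _mcar_frame(seed=10)
        outs = ai.em_impute(dfm, ImputerSpec("em", seed=4), n_bootstrap=3)
        assert isinstance(outs, list) and len(outs) == 3


class TestBPCA:
    def test_rank_one_exact_recovery(self):
        u = np.arange(1.0, 9.0)
        v = np.array([2.0, -1.0, 0.5])
        M = np.outer(u, v)
        df = pd.DataFrame(M.copy(), columns=list("abc"))
        df.loc[3, "b"] = np.nan
        out = ai.bpca_impute(df, ImputerSpec("bpca", n_components=1))
        assert abs(out.loc[3, "b"] - M[3, 1]) < 1e-6

    def test_zero_components_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, np.nan]})
        with pytest.raises(ValueError):
            ai.bpca_impute(df, ImputerSpec("bpca", n_components=0))

    def test_reconstruction_error_decreases(self):
        _, dfm = _mcar_frame(seed=13)
        out, trace = ai.bpca_impute(
            dfm, ImputerSpec("bpca", n_components=2), return_trace=True
        )
        t = np.asarray(trace)
        assert len(t) >= 2 and (np.diff(t) <= 1e-9).all()


class TestChainedRF:
    def test_zero_missing_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(
            ai.chained_rf_impute(df, ImputerSpec("chained_rf")), df
        )

    def test_draws_within_observed_range(self):
        _, dfm = _mcar_frame(seed=14)
        out = ai.chained_rf_impute(
            dfm, ImputerSpec("chained_rf", rf_trees=5, max_iterations=3, seed=1)
        )
        for c in dfm.columns:
            mis = dfm[c].isna()
            obs = dfm[c].dropna()
            assert out[c][mis].between(obs.min(), obs.max()).all()

    def test_stochastic_across_seeds(self):
        _, dfm = _mcar_frame(seed=15)
        a = ai.chained_rf_impute(dfm, ImputerSpec("chained_rf", rf_trees=5,
                                                  max_iterations=2, seed=1))
        b = ai.chained_rf_impute(dfm, ImputerSpec("chained_rf", rf_trees=5,
                                                  max_iterations=2, seed=2))
        assert not a.equals(b)


class TestNullCalibration:
    def test_mean_imputation_nrmse_near_one_under_mcar(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        dfm = df.copy()
        idx = rng.choice(1000, 200, replace=False)
        dfm.iloc[idx, 0] = np.nan
        out = ai.mean_impute(dfm)
        truth = df["a"].to_numpy()[idx]
        imp = out["a"].to_numpy()[idx]
        nrmse = np.sqrt(np.mean((imp - truth) ** 2) / np.var(truth))
        assert abs(nrmse - 1.0) < 0.1
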