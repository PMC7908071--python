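"""Data preparation: completeness-ruled aggregation, log transform,
summary/missingness tables, correlation analysis, exclusion rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import airimpute as ai
from airimpute.synthetic import StationPanel


def _hourly(values, start="2013-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return pd.Series(values, index=idx, dtype=float)


class TestAggregateDaily:
    def test_full_day_mean(self):
        s = _hourly([5.0] * 24)
        out = ai.aggregate_daily(s, 24)
        assert out.iloc[0] == 5.0 and len(out) == 1

    def test_17_of_24_is_missing(self):
        # 17/24 = 0.7083 < 0.75
        vals = [1.0] * 17 + [np.nan] * 7
        out = ai.aggregate_daily(_hourly(vals), 24)
        assert np.isnan(out.iloc[0])

    def test_exactly_75_percent_is_valid(self):
        vals = [2.0] * 18 + [np.nan] * 6
        out = ai.aggregate_daily(_hourly(vals), 24)
        assert out.iloc[0] == 2.0

    def test_mean_preserving_when_complete(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=48)
        out = ai.aggregate_daily(_hourly(vals), 24)
        assert np.allclose(out.to_numpy(),
                           [vals[:24].mean(), vals[24:].mean()])

    def test_8h_is_daily_max_of_rolling_means(self):
        # one clean peak: hours 8..15 hold 10s, rest 1s
        vals = np.ones(24)
        vals[8:16] = 10.0
        out = ai.aggregate_daily(_hourly(vals), 8)
        assert out.iloc[0] == 10.0

    def test_8h_window_completeness(self):
        # every 8-h window has at most 5 of 8 observed -> whole day missing
        vals = np.array([1.0, np.nan, 1.0, np.nan] * 6)
        out = ai.aggregate_daily(_hourly(vals), 8)
        assert np.isnan(out.iloc[0])

    def test_empty_input(self):
        out = ai.aggregate_daily(pd.Series(dtype=float), 24)
        assert out.empty

    def test_non_hourly_spacing_rejected(self):
        idx = pd.date_range("2013-01-01", periods=10, freq="2h")
        with pytest.raises(ValueError, match="hourly"):
            ai.aggregate_daily(pd.Series(1.0, index=idx), 24)


class TestLogTransform:
    def _panel(self, co):
        idx = pd.date_range("2013-01-01", periods=len(co), freq="D")
        df = pd.DataFrame({"CO": co, "temp": np.full(len(co), 25.0)}, index=idx)
        return StationPanel("X", df)

    def test_unit_and_e(self):
        out = ai.log_transform(self._panel([1.0, np.e, 4.0]))
        assert out.data["CO"].iloc[0] == pytest.approx(0.0)
        assert out.data["CO"].iloc[1] == pytest.approx(1.0)

    def test_meteorology_untouched_missing_stays_missing(self):
        out = ai.log_transform(self._panel([1.0, np.nan, 4.0]))
        assert (out.data["temp"] == 25.0).all()
        assert np.isnan(out.data["CO"].iloc[1])

    def test_zero_gets_half_min_positive_offset(self):
        out = ai.log_transform(self._panel([0.0, 0.4, 2.0]))
        assert out.data["CO"].iloc[0] == pytest.approx(np.log(0.2))
        # ordering preserved
        assert out.data["CO"].is_monotonic_increasing

    def test_negative_value_names_cell(self):
        with pytest.raises(ValueError, match="CO"):
            ai.log_transform(self._panel([1.0, -0.1, 4.0]))


class TestSummarize:
    def _panel(self, values, name="CO"):
        idx = pd.date_range("2013-01-01", periods=len(values), freq="D")
        return StationPanel("X", pd.DataFrame({name: values}, index=idx))

    def test_linear_interpolation_quartiles(self):
        out = ai.summarize([self._panel([1.0, 2.0, 3.0, 4.0])])
        row = out.loc[("X", "CO")]
        assert row["median"] == pytest.approx(2.5)
        assert row["q25"] == pytest.approx(1.75)

    def test_constant_column_sd_zero(self):
        out = ai.summarize([self._panel([7.0] * 10)])
        assert out.loc[("X", "CO"), "sd"] == 0.0

    def test_761_of_2192_missing_is_34_7_percent(self):
        vals = np.ones(2192)
        vals[:761] = np.nan
        out = ai.summarize([self._panel(vals)])
        assert round(out.loc[("X", "CO"), "pct_missing"], 1) == 34.7

    def test_row_permutation_invariant(self, small_panels):
        p = small_panels[0]
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(p.data))
        shuffled = StationPanel(
            p.station, p.data.iloc[perm].sort_index()
        )
        a = ai.summarize([p])
        b = ai.summarize([shuffled])
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_column(self):
        out = ai.summarize([self._panel([np.nan] * 5)])
        row = out.loc[("X", "CO")]
        assert np.isnan(row["mean"]) and row["pct_missing"] == 100.0


class TestCorrelationTable:
    def test_self_and_anti_correlation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": -x})
        r, p, stars = ai.correlation_table(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([2.1, 3.4, 1.2, 5.6, 4.4, 2.2, 3.3, 0.9, 4.1, 2.8])
        y = np.array([1.0, 2.2, 0.8, 4.1, 3.9, 1.4, 2.0, 0.5, 3.6, 2.1])
        r, _, _ = ai.correlation_table(pd.DataFrame({"x": x, "y": y}))
        # independent oracle: raw covariance formula
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert abs(r.loc["x", "y"] - oracle) < 1e-12

    def test_too_few_pairs_is_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan],
                           "b": [1.0, np.nan, 2.0, 3.0]})
        r, _, _ = ai.correlation_table(df)
        assert np.isnan(r.loc["a", "b"])

    def test_star_thresholds(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(scale=0.5, size=200)})
        _, p, stars = ai.correlation_table(df)
        assert p.loc["x", "y"] < 0.001 and stars.loc["x", "y"] == "****"


class TestMissingnessBySite:
    def _panels(self, counts, n=2192, var="NO2"):
        panels = []
        for i, k in enumerate(counts):
            vals = np.ones(n)
            vals[:k] = np.nan
            idx = pd.date_range("2013-01-01", periods=n, freq="D")
            panels.append(
                StationPanel(f"S{i}", pd.DataFrame({var: vals}, index=idx))
            )
        return panels

    def test_percent_arithmetic(self):
        counts = (454, 379, 454, 761, 382)
        out = ai.missingness_by_site(self._panels(counts), pollutants=["NO2"])
        pcts = [out.loc["NO2", f"S{i}_pct"] for i in range(5)]
        assert pcts == [20.7, 17.3, 20.7, 34.7, 17.4]
        assert out.loc["NO2", "p_value"] < 0.001

    def test_identical_counts_give_p_one(self):
        out = ai.missingness_by_site(self._panels((100, 100, 100)),
                                     pollutants=["NO2"])
        assert out.loc["NO2", "p_value"] == 1.0

    def test_chi_square_equals_hand_formula(self):
        # 2x2 table (10,90 / 20,80): hand-computed sum (O-E)^2/E
        out = ai.missingness_by_site(self._panels((10, 20), n=100),
                                     pollutants=["NO2"])
        obs = np.array([[10, 90], [20, 80]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - exp) ** 2 / exp).sum()
        assert out.loc["NO2", "p_value"] == pytest.approx(
            stats.chi2.sf(hand, df=1)
        )

    def test_homogeneity_p_matches_permutation_estimate(self):
        # small table: compare the chi-square p to a Monte-Carlo permutation p
        counts, n = (6, 14), 40
        out = ai.missingness_by_site(self._panels(counts, n=n),
                                     pollutants=["NO2"])
        labels = np.repeat([0, 1], n)
        miss = np.concatenate([
            np.r_[np.ones(c), np.zeros(n - c)] for c in counts
        ])
        obs = np.array([[c, n - c] for c in counts])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat_obs = ((obs - exp) ** 2 / exp).sum()
        rng = np.random.default_rng(0)
        hits = 0
        trials = 2000
        for _ in range(trials):
            perm = rng.permutation(miss)
            a = perm[labels == 0].sum()
            b = perm[labels == 1].sum()
            t = np.array([[a, n - a], [b, n - b]])
            stat = ((t - exp) ** 2 / exp).sum()
            hits += stat >= stat_obs - 1e-12
        mc_p = hits / trials
        assert abs(out.loc["NO2", "p_value"] - mc_p) < 0.05

    def test_single_station_rejected(self):
        with pytest.raises(ValueError):
            ai.missingness_by_site(self._panels((5,))[:1])


class TestExclusionFilter:
    def _panel(self, frac_missing, var="PM10", n=1000):
        vals = np.ones(n)
        vals[: int(frac_missing * n)] = np.nan
        idx = pd.date_range("2013-01-01", periods=n, freq="D")
        return StationPanel("X", pd.DataFrame({var: vals}, index=idx))

    def test_over_half_missing_dropped(self):
        assert ai.exclusion_filter([self._panel(0.5216)]) == ["PM10"]

    def test_exactly_half_retained(self):
        assert ai.exclusion_filter([self._panel(0.50)]) == []

    def test_nothing_above_threshold(self):
        assert ai.exclusion_filter([self._panel(0.10)]) == []
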