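"""Skill metrics and temporal aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prolai import aggregate, evaluate


def daily_series(values, start="2001-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestAggregate:
    def test_constant_series_constant_everywhere(self):
        s = daily_series([3.0] * 730)
        for level in ("7day", "monthly", "annual"):
            agg = aggregate(s, level)
            assert np.allclose(agg.to_numpy(), 3.0)

    def test_365_days_make_53_weekly_blocks(self):
        s = daily_series(np.arange(365.0))
        agg = aggregate(s, "7day")
        assert len(agg) == 53  # 52 full blocks + 1 single-day block
        assert agg.iloc[0] == pytest.approx(np.mean(np.arange(7.0)))
        assert agg.iloc[-1] == 364.0

    def test_monthly_means_match_direct_average(self):
        doy = np.arange(730)
        s = daily_series(2.0 + np.sin(2 * np.pi * doy / 365))
        agg = aggregate(s, "monthly")
        assert len(agg) == 12
        jan = s[s.index.month == 1]
        assert agg.loc[1] == pytest.approx(float(jan.mean()), rel=1e-12)

    def test_annual_means(self):
        s = daily_series(np.r_[np.full(365, 1.0), np.full(365, 3.0)])
        agg = aggregate(s, "annual")
        assert list(agg.index) == [2001, 2002]
        assert np.allclose(agg.to_numpy(), [1.0, 3.0])

    def test_spatial_mean_by_site(self):
        s = daily_series(np.r_[np.full(10, 1.0), np.full(10, 5.0)])
        site = pd.Series(["a"] * 10 + ["b"] * 10, index=s.index)
        agg = aggregate(s, "spatial", site=site)
        assert agg.loc["a"] == 1.0 and agg.loc["b"] == 5.0

    def test_empty_and_unknown_level(self):
        with pytest.raises(ValueError):
            aggregate(daily_series([]), "7day")
        with pytest.raises(ValueError):
            aggregate(daily_series([1.0] * 10), "fortnight")


class TestEvaluate:
    def test_perfect_agreement(self):
        s = daily_series(np.sin(np.arange(100.0)) + 2)
        rep = evaluate(s, s.copy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.bias == pytest.approx(0.0, abs=1e-12)
        assert rep.slope == pytest.approx(1.0)

    def test_constant_offset(self):
        obs = daily_series(np.sin(np.arange(100.0)) + 2)
        rep = evaluate(obs + 0.5, obs)
        assert rep.bias == pytest.approx(0.5)
        assert rep.rmse == pytest.approx(0.5)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_metrics_match_independent_recomputation(self):
        """Every reported metric recomputed formula by formula on random
        pairs."""
        rng = np.random.default_rng(21)
        obs = daily_series(rng.uniform(0.5, 6.0, 10000))
        sim = obs * 0.8 + rng.normal(0, 0.5, 10000)
        rep = evaluate(sim, obs)
        x, y = obs.to_numpy(), sim.to_numpy()
        assert rep.rmse == pytest.approx(
            float(np.sqrt(np.mean((y - x) ** 2))), rel=1e-12)
        assert rep.bias == pytest.approx(float(np.mean(y - x)), rel=1e-9)
        assert rep.rrmse_percent == pytest.approx(
            100.0 * rep.rmse / float(np.mean(x)), rel=1e-12)
        r_expected = float(stats.pearsonr(x, y).statistic)
        assert rep.pearson_r == pytest.approx(r_expected, rel=1e-12)
        assert rep.r2 == pytest.approx(r_expected**2, rel=1e-12)
        slope_expected = float(np.cov(x, y, ddof=1)[0, 1] /
                               np.var(x, ddof=1))
        assert rep.slope == pytest.approx(slope_expected, rel=1e-9)

    def test_unit_change_invariance(self):
        rng = np.random.default_rng(2)
        obs = daily_series(rng.uniform(1, 5, 500))
        sim = daily_series(rng.uniform(1, 5, 500))
        r1 = evaluate(sim, obs)
        r2 = evaluate(10 * sim, 10 * obs)
        assert r2.pearson_r == pytest.approx(r1.pearson_r, rel=1e-12)
        assert r2.r2 == pytest.approx(r1.r2, rel=1e-12)
        assert r2.rrmse_percent == pytest.approx(r1.rrmse_percent,
                                                 rel=1e-12)
        assert r2.rmse == pytest.approx(10 * r1.rmse, rel=1e-12)
        assert r2.bias == pytest.approx(10 * r1.bias, rel=1e-9)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(8)
        obs = daily_series(rng.uniform(1, 5, 200))
        sim = daily_series(rng.uniform(1, 5, 200))
        shuffled = rng.permutation(200)
        r1 = evaluate(sim, obs)
        r2 = evaluate(sim.iloc[shuffled], obs)
        assert r2.rmse == pytest.approx(r1.rmse, rel=1e-12)
        assert r2.pearson_r == pytest.approx(r1.pearson_r, rel=1e-12)

    def test_zero_variance_flags_correlation_undefined(self):
        obs = daily_series([2.0] * 50)
        sim = daily_series(np.linspace(1, 3, 50))
        rep = evaluate(sim, obs)
        assert rep.pearson_r is None and rep.r2 is None and rep.slope is None
        assert rep.rmse > 0
        assert rep.bias == pytest.approx(0.0, abs=1e-12)

    def test_aggregated_levels_run(self):
        # three non-leap years: 2001-01-01 .. 2003-12-31
        rng = np.random.default_rng(4)
        obs = daily_series(2 + np.sin(np.arange(1095) / 58.0))
        sim = obs + rng.normal(0, 0.1, 1095)
        expected_n = {"7day": 3 * 53, "monthly": 12, "annual": 3}
        for level, n in expected_n.items():
            rep = evaluate(sim, obs, level=level)
            assert rep.level == level
            assert rep.n == n

    def test_too_few_points_rejected(self):
        s = daily_series([1.0, 2.0])
        with pytest.raises(ValueError):
            evaluate(s, s)
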