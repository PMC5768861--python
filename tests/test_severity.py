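import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import disturbkit as dk
from disturbkit import IntervalStatus
from disturbkit.severity import _bc_interval

from conftest import make_abundance, make_growth_series


class TestAnnualize:
    def test_post_event_season_selected(self):
        # spring and autumn censuses; the first post-event census is autumn
        years = np.repeat(np.arange(2000, 2006), 2)
        seasons = ["spring", "autumn"] * 6
        ab = dk.AbundanceSeries(
            data=pd.DataFrame(
                {"year": years, "season": seasons, "abundance": np.arange(12) + 1.0}
            ),
            species_id="s",
            event_year=2003,
            post_event_season="autumn",
        )
        annual = dk.annualize(ab)
        assert len(annual.data) == 6
        # autumn values are the even-indexed + 1 entries: 2, 4, 6, ...
        assert list(annual.data["abundance"]) == [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]

    def test_season_inferred_from_first_post_event_census(self):
        years = [2000, 2000, 2001, 2001, 2002, 2002]
        seasons = ["spring", "autumn"] * 3
        ab = dk.AbundanceSeries(
            data=pd.DataFrame({"year": years, "season": seasons, "abundance": 1.0}),
            species_id="s",
            event_year=2001,
        )
        annual = dk.annualize(ab)
        assert len(annual.data) == 3  # first record of 2001 is spring

    def test_single_census_per_year_unchanged(self):
        ab = make_abundance([10.0, 20.0, 30.0], event_year=2001)
        annual = dk.annualize(ab)
        assert list(annual.data["abundance"]) == [10.0, 20.0, 30.0]

    def test_zero_abundance_becomes_missing(self):
        ab = make_abundance([10.0, 20.0, 0.0, 30.0, 40.0], event_year=2001)
        annual = dk.annualize(ab)
        assert np.isnan(annual.data["abundance"].iloc[2])


class TestGrowthRates:
    def test_constant_abundance_gives_zero_rate(self):
        g = dk.growth_rates(make_abundance([100.0, 100.0, 100.0], event_year=2001))
        assert g.r_pd == 0.0

    def test_doubling_gives_log_two(self):
        g = dk.growth_rates(make_abundance([100.0, 200.0, 200.0, 200.0], event_year=2001))
        assert g.r_pd == pytest.approx(math.log(2))

    def test_zero_year_makes_both_intervals_missing(self):
        ab = make_abundance([100.0, 50.0, 100.0, 0.0, 50.0, 60.0], event_year=2001)
        g = dk.growth_rates(dk.annualize(ab))
        statuses = dict(zip(g.intervals["start_year"], g.intervals["status"]))
        assert statuses[2002] is IntervalStatus.MISSING
        assert statuses[2003] is IntervalStatus.MISSING

    def test_missing_bracketing_census_is_an_error(self):
        ab = make_abundance([100.0, 0.0, 50.0, 60.0], event_year=2001)
        with pytest.raises(ValueError, match="disturbance-year growth rate undefined"):
            dk.growth_rates(dk.annualize(ab))


class TestTrendFilter:
    def test_flat_series_fully_retained(self):
        points = [(2000 + i, 5.0) for i in range(8)]
        retained, removals = dk.trend_filter(points)
        assert retained == points
        assert removals == []

    def test_strict_linear_trend_exhausts_to_untested_remainder(self):
        # near-noiseless increasing trend: the regression stays significant
        # until fewer than 3 points remain
        rng = np.random.default_rng(0)
        points = [(2000 + i, 100.0 + 10.0 * i + rng.normal(0, 1e-6)) for i in range(10)]
        # independent oracle: iterate OLS by hand
        expected = list(points)
        while len(expected) >= 3:
            yrs = np.array([p[0] for p in expected], dtype=float)
            ab = np.array([p[1] for p in expected])
            if stats.linregress(yrs, ab).pvalue >= 0.05:
                break
            expected.pop(0)
        with pytest.warns(UserWarning, match="untested"):
            retained, removals = dk.trend_filter(points)
        assert retained == expected
        assert len(retained) == 2
        assert len(removals) == 8

    def test_two_points_returned_untested(self):
        points = [(2000, 1.0), (2001, 100.0)]
        retained, removals = dk.trend_filter(points)
        assert retained == points and removals == []

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        points = [(2000 + i, 50.0 + 3.0 * i + rng.normal(0, 2)) for i in range(12)]
        retained, _ = dk.trend_filter(points)
        again, removals = dk.trend_filter(retained)
        assert again == retained and removals == []


class TestSelectNormalYears:
    def _series(self, abundances, event_year=2005, **kw):
        return make_abundance(abundances, event_year=event_year, **kw)

    def test_no_exclusions_all_intervals_normal(self):
        rng = np.random.default_rng(2)
        ab = self._series(np.exp(rng.normal(5, 0.1, 12)))
        g = dk.select_normal_years(dk.growth_rates(ab), ab)
        statuses = g.intervals["status"].value_counts()
        assert statuses[IntervalStatus.NORMAL] == 10
        assert statuses[IntervalStatus.DISTURBANCE_YEAR] == 1

    def test_other_stress_period_excluded(self):
        rng = np.random.default_rng(3)
        ab = self._series(
            np.exp(rng.normal(5, 0.1, 14)),
            excluded_periods=[(2010, 2012)],
        )
        g = dk.select_normal_years(dk.growth_rates(ab), ab)
        sub = g.intervals.set_index("start_year")["status"]
        for year in (2009, 2010, 2011, 2012):
            assert sub[year] is IntervalStatus.EXCLUDED_OTHER_STRESS

    def test_post_event_recovery_trend_excluded(self):
        # crash at the event, then strong exponential recovery
        pre = [100.0] * 6
        crash = [20.0]
        recovery = [20 * 1.6**k for k in range(1, 7)]
        ab = self._series(pre + crash + recovery, event_year=2006)
        g = dk.select_normal_years(dk.growth_rates(ab), ab)
        sub = g.intervals.set_index("start_year")["status"]
        assert (sub == IntervalStatus.EXCLUDED_TREND).sum() >= 3
        # pre-event intervals survive as normal
        assert sub[2000] is IntervalStatus.NORMAL

    def test_too_few_normal_rates_is_an_error(self):
        ab = self._series([100.0, 90.0, 50.0, 55.0], event_year=2002)
        g = dk.growth_rates(ab)
        ab_excluded = self._series(
            [100.0, 90.0, 50.0, 55.0],
            event_year=2002,
            excluded_periods=[(2003, 2003)],
        )
        with pytest.raises(ValueError, match="insufficient normal-condition data"):
            dk.select_normal_years(g, ab_excluded)


class TestEffectSize:
    def test_disturbance_rate_at_normal_mean_gives_zero(self):
        g = make_growth_series([0.2, 0.0, -0.2], r_pd=0.0)
        assert dk.effect_size(g).es == pytest.approx(0.0)

    def test_two_sd_below_mean_gives_minus_two(self):
        rates = [0.1, -0.1, 0.2, -0.2, 0.0]
        sd = np.std(rates, ddof=1)
        g = make_growth_series(rates, r_pd=-2 * sd)
        assert dk.effect_size(g).es == pytest.approx(-2.0)

    def test_worked_example(self, worked_growth_series):
        """Five normal rates with mean 0 and sd 0.15811; r_pd = -0.3."""
        res = dk.effect_size(worked_growth_series)
        assert res.es == pytest.approx(-0.3 / math.sqrt(0.025), rel=1e-9)
        assert res.es == pytest.approx(-1.8974, abs=1e-4)

    def test_zero_normal_variability_rejected(self):
        g = make_growth_series([0.1, 0.1, 0.1], r_pd=-0.5)
        with pytest.raises(ValueError, match="zero variability"):
            dk.effect_size(g)


def _exact_bc_interval(rates, r_pd, level=0.95):
    """BC interval from exhaustive enumeration of all n^n resamples.

    Degenerate (zero-sd) resamples are excluded, mirroring the redraw
    policy, which conditions the bootstrap law on non-degeneracy.
    """
    n = len(rates)
    es_all = []
    for combo in itertools.product(rates, repeat=n):
        if len(set(combo)) == 1:  # degenerate: all-equal resample
            continue
        arr = np.array(combo)
        es_all.append((r_pd - arr.mean()) / arr.std(ddof=1))
    es_all = np.sort(es_all)
    point = (r_pd - np.mean(rates)) / np.std(rates, ddof=1)
    prop_less = np.mean(es_all < point)
    z0 = stats.norm.ppf(prop_less)
    z_lo, z_hi = stats.norm.ppf([(1 - level) / 2, (1 + level) / 2])
    a_lo, a_hi = stats.norm.cdf(2 * z0 + z_lo), stats.norm.cdf(2 * z0 + z_hi)
    return np.quantile(es_all, a_lo), np.quantile(es_all, a_hi)


class TestBootstrapCI:
    def test_identical_rates_propagate_zero_sd_error(self):
        g = make_growth_series([0.1, 0.1, 0.1], r_pd=-0.5)
        with pytest.raises(ValueError, match="zero variability"):
            dk.bootstrap_ci(g, seed=0)

    def test_three_rate_interval_matches_exhaustive_enumeration(self):
        rates = [0.05, -0.12, 0.2]
        r_pd = -0.4
        g = make_growth_series(rates, r_pd=r_pd)
        exact_lo, exact_hi = _exact_bc_interval(rates, r_pd)
        with pytest.warns(UserWarning, match="degenerate"):
            res = dk.bootstrap_ci(g, n_boot=10_000, seed=123)
        assert res.ci_low == pytest.approx(exact_lo, abs=0.05)
        assert res.ci_high == pytest.approx(exact_hi, abs=0.05)

    def test_symmetric_bootstrap_reduces_to_percentile_interval(self):
        # when the bootstrap distribution is symmetric about the point
        # estimate the bias-correction term vanishes and the BC interval
        # coincides with the plain percentile interval
        rng = np.random.default_rng(9)
        point = -2.0
        boot = point + np.concatenate([(d := rng.normal(0, 0.5, 25_000)), -d])
        lo, hi = _bc_interval(boot, point)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.01)
        assert hi == pytest.approx(phi, abs=0.01)

    def test_ci_width_shrinks_with_more_normal_rates(self):
        rng = np.random.default_rng(21)
        widths = []
        for n in (8, 60):
            per_seed = []
            for seed in range(5):
                rates = rng.normal(0, 0.2, size=n)
                g = make_growth_series(list(rates), r_pd=-0.4)
                res = dk.bootstrap_ci(g, n_boot=4000, seed=seed)
                per_seed.append(res.ci_high - res.ci_low)
            widths.append(np.mean(per_seed))
        assert widths[1] < widths[0]

    def test_small_n_boot_rejected(self):
        g = make_growth_series([0.1, -0.1, 0.2], r_pd=-0.3)
        with pytest.raises(ValueError, match="n_boot"):
            dk.bootstrap_ci(g, n_boot=100, seed=0)


class TestSeverityReturnPeriod:
    def test_zero_effect_size_gives_two_years(self):
        sev = dk.severity_return_period(0.0)
        assert sev.return_period == pytest.approx(2.0)
        assert sev.no_decline

    @pytest.mark.parametrize(
        "es,expected", [(-1.6449, 20.0), (-2.3263, 100.0)]
    )
    def test_standard_normal_quantile_oracle(self, es, expected):
        sev = dk.severity_return_period(es)
        assert sev.return_period == pytest.approx(expected, rel=1e-3)

    @given(st.floats(-6.0, 3.0))
    def test_inverse_roundtrip(self, es):
        sev = dk.severity_return_period(es)
        assert dk.es_from_return_period(sev.return_period) == pytest.approx(es, abs=1e-9)

    def test_strictly_decreasing_in_effect_size(self):
        es = np.linspace(-5, 2, 40)
        rps = [dk.severity_return_period(e).return_period for e in es]
        assert np.all(np.diff(rps) < 0)

    def test_ci_maps_order_reversed(self, worked_growth_series):
        res = dk.bootstrap_ci(worked_growth_series, seed=3)
        sev = dk.severity_return_period(res)
        assert sev.ci_low == pytest.approx(1 / stats.norm.cdf(res.ci_high))
        assert sev.ci_high == pytest.approx(1 / stats.norm.cdf(res.ci_low))
        assert sev.ci_low <= sev.return_period <= sev.ci_high

    def test_small_sample_mode_is_more_conservative(self):
        # t tail with inflation gives a shorter return period for a decline
        g = make_growth_series([0.1, -0.1, 0.2, -0.2, 0.0], r_pd=-0.4)
        res = dk.effect_size(g)
        plain = dk.severity_return_period(res)
        t_mode = dk.severity_return_period(res, small_sample=True)
        assert t_mode.return_period < plain.return_period


class TestScaleInvariance:
    @given(st.floats(0.01, 1000.0))
    def test_rescaled_abundance_preserves_es_and_severity(self, factor):
        base = make_abundance(
            [100.0, 110.0, 95.0, 105.0, 100.0, 40.0, 42.0, 41.0, 43.0, 40.0],
            event_year=2005,
        )
        scaled = make_abundance(
            [factor * a for a in [100.0, 110.0, 95.0, 105.0, 100.0, 40.0, 42.0, 41.0, 43.0, 40.0]],
            event_year=2005,
        )
        g1 = dk.select_normal_years(dk.growth_rates(base), base)
        g2 = dk.select_normal_years(dk.growth_rates(scaled), scaled)
        es1, es2 = dk.effect_size(g1), dk.effect_size(g2)
        assert es1.es == pytest.approx(es2.es, rel=1e-9)
        s1 = dk.severity_return_period(es1)
        s2 = dk.severity_return_period(es2)
        assert s1.return_period == pytest.approx(s2.return_period, rel=1e-9)


class TestEstimatorRecovery:
    def test_injected_effect_size_recovered_on_average(self):
        """Mean estimated ES over seeded replicates is close to the truth."""
        ests = []
        for seed in range(120):
            ab = dk.simulate_abundance(
                30, 0.0, 0.2, 1995, true_es=-2.0, obs_noise_sd=0.0, n0=1000.0, seed=seed
            )
            g = dk.select_normal_years(dk.growth_rates(ab), ab)
            ests.append(dk.effect_size(g).es)
        assert np.mean(ests) == pytest.approx(-2.0, abs=0.12)

    def test_sampling_sd_shrinks_with_longer_series(self):
        sds = []
        for n_years in (12, 40):
            ests = [
                dk.effect_size(
                    dk.select_normal_years(
                        g := dk.growth_rates(
                            ab := dk.simulate_abundance(
                                n_years, 0.0, 0.2, 1980 + n_years // 2, -2.0, 0.0, 1000.0, seed=s
                            )
                        ),
                        ab,
                    )
                ).es
                for s in range(60)
            ]
            sds.append(np.std(ests))
        assert sds[1] < sds[0]
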