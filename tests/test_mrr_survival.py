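"""Removal adjustment, smoothing, log-linear fitting and longevity metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitfield.mrr_survival import (
    CohortSeries,
    SurvivalEstimate,
    adjust_recaptures,
    aggregate_replicates,
    cohort_series_from_logs,
    derive_metrics,
    estimate_cohort_survival,
    fit_log_decline,
    moving_average_3,
)
from sitfield.synthetic_field import simulate_cohort


def make_cohort(raw, release_size=1000, colour="yellow"):
    return CohortSeries(
        colour=colour,
        release_size=release_size,
        day_index=tuple(range(1, len(raw) + 1)),
        raw_counts=tuple(raw),
    )


def make_estimate(ale=4.5, pds=0.8, significant=True):
    slope = math.log10(pds)
    return SurvivalEstimate(
        slope=slope,
        pds=pds,
        half_life_days=math.log(0.5) / math.log(pds),
        ale_days=ale,
        fit_p_value=0.001 if significant else 0.4,
        r_squared=0.95,
        significant=significant,
        n_days_fit=12,
    )


class TestAdjustRecaptures:
    def test_worked_two_day_example(self):
        adj = adjust_recaptures(make_cohort([100, 90], release_size=1000))
        assert adj.adjusted_counts == (100.0, pytest.approx(100.0))

    def test_half_then_half_of_remainder(self):
        adj = adjust_recaptures(make_cohort([50, 25], release_size=100))
        assert adj.adjusted_counts == (50.0, pytest.approx(50.0))

    def test_identity_on_zero_series(self):
        adj = adjust_recaptures(make_cohort([0, 0, 0], release_size=500))
        assert adj.adjusted_counts == (0.0, 0.0, 0.0)

    def test_day_one_always_unadjusted(self):
        adj = adjust_recaptures(make_cohort([37, 10, 5], release_size=200))
        assert adj.adjusted_counts[0] == 37.0

    def test_exhausted_release_rejected(self):
        with pytest.raises(ValueError, match="cumulative"):
            adjust_recaptures(make_cohort([100, 1], release_size=100))

    @given(
        st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=14),
        st.integers(min_value=500, max_value=5000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_never_below_raw(self, raw, release_size):
        adj = adjust_recaptures(make_cohort(raw, release_size=release_size))
        assert all(a >= r for a, r in zip(adj.adjusted_counts, raw))


class TestMovingAverage:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([3, 6, 9], [6.0]),
            ([5, 5, 5, 5], [5.0, 5.0]),
            ([0, 3, 6, 9, 0], [3.0, 6.0, 5.0]),
        ],
    )
    def test_centred_window(self, series, expected):
        assert moving_average_3(series) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            moving_average_3([1, 2])


class TestFitLogDecline:
    def test_exact_decade_decline(self):
        smoothed = [10 * 10 ** (-0.1 * t) for t in range(10)]
        est = fit_log_decline(smoothed)
        assert est.slope == pytest.approx(-0.1, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.significant

    def test_flat_series_not_significant(self):
        est = fit_log_decline([7.0] * 8)
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert not est.significant

    def test_all_zero_is_no_signal(self):
        with pytest.raises(ValueError, match="no signal"):
            fit_log_decline([0.0, 0.0, 0.0, 0.0])

    def test_zero_days_dropped_not_imputed(self):
        # zeros interleaved with an exact decline must not bend the fit
        smoothed = [10.0, 0.0, 10 ** (1 - 0.2), 0.0, 10 ** (1 - 0.4)]
        est = fit_log_decline(smoothed, day_index=[1, 2, 3, 4, 5])
        assert est.slope == pytest.approx(-0.1, abs=1e-12)

    def test_rising_series_has_undefined_longevity(self):
        est = fit_log_decline([1.0, 2.0, 4.0, 8.0])
        assert est.slope > 0
        assert not est.significant
        assert math.isnan(est.half_life_days) and math.isnan(est.ale_days)


class TestDeriveMetrics:
    def test_half_life_of_coin_flip_survival(self):
        pds, hl, _ = derive_metrics(math.log10(0.5))
        assert pds == pytest.approx(0.5)
        assert hl == pytest.approx(1.0)

    def test_ale_of_inverse_e_survival(self):
        _, _, ale = derive_metrics(math.log10(math.exp(-1)))
        assert ale == pytest.approx(1.0)

    def test_reference_slope(self):
        pds, hl, ale = derive_metrics(-0.1)
        assert pds == pytest.approx(0.7943282347242815, rel=1e-12)
        assert hl == pytest.approx(3.0102999566398116, rel=1e-12)
        assert ale == pytest.approx(4.342944819032518, rel=1e-12)

    def test_non_declining_slope_rejected(self):
        with pytest.raises(ValueError):
            derive_metrics(0.0)

    @given(st.floats(min_value=-0.5, max_value=-0.01))
    @settings(max_examples=50, derandomize=True)
    def test_metrics_monotone_in_slope(self, slope):
        pds_a, hl_a, ale_a = derive_metrics(slope)
        pds_b, hl_b, ale_b = derive_metrics(slope - 0.05)
        assert pds_a > pds_b and hl_a > hl_b and ale_a > ale_b


class TestPipeline:
    def test_noiseless_geometric_recovered_to_machine_precision(self):
        """MA3 of a geometric series is a constant multiple of it, so the
        fitted slope equals log10(PDS) exactly (no removal, no noise)."""
        pds = 0.8
        counts = [100 * pds ** (t - 1) for t in range(1, 15)]
        est = fit_log_decline(moving_average_3(counts))
        assert est.slope == pytest.approx(math.log10(pds), abs=1e-12)
        assert est.pds == pytest.approx(pds, abs=1e-12)

    def test_simulated_cohort_recovers_pds(self):
        counts = simulate_cohort(5000, 0.80, 0.02, 14, rng_seed=3)
        cohort = make_cohort([int(c) for c in counts], release_size=5000)
        est = estimate_cohort_survival(cohort)
        assert est.pds == pytest.approx(0.80, abs=0.05)

    def test_cohort_series_from_logs_pools_included_traps(self, release_pair):
        import datetime as dt

        from conftest import make_trap

        day0 = dt.date(2021, 4, 13)
        traps = [
            make_trap("T01", date=day0, sterile={"yellow": 3}),
            make_trap("T02", date=day0, sterile={"yellow": 2}),
            make_trap("T03", date=day0, sterile={"yellow": 9}, included=False),
            make_trap("T01", date=day0 + dt.timedelta(days=1), sterile={"yellow": 4}),
        ]
        cohort = cohort_series_from_logs(traps, release_pair, "yellow", n_days=5)
        assert cohort.raw_counts == (5, 4, 0, 0, 0)
        assert cohort.release_size == 950_739


class TestAggregateReplicates:
    def test_table_of_three_replicates(self):
        """Three replicate ALEs of 4.87, 4.55 and 4.37 days average to 4.60."""
        ests = [make_estimate(ale=a) for a in (4.87, 4.55, 4.37)]
        agg = aggregate_replicates(ests)
        assert round(agg.ale_mean, 2) == 4.60
        assert round(agg.ale_sd, 2) == 0.25

    def test_pds_mean_rounds_to_point_eight(self):
        ests = [make_estimate(pds=p) for p in (0.81, 0.80, 0.80)]
        agg = aggregate_replicates(ests)
        assert round(agg.pds_mean, 2) == 0.80

    def test_non_significant_replicates_excluded(self):
        ests = [make_estimate(ale=4.0), make_estimate(ale=100.0, significant=False)]
        agg = aggregate_replicates(ests)
        assert agg.n_total == 2
        assert agg.n_significant == 1
        assert agg.ale_mean == pytest.approx(4.0)

    def test_single_replicate_sd_not_applicable(self):
        agg = aggregate_replicates([make_estimate(ale=4.2)])
        assert agg.ale_mean == pytest.approx(4.2)
        assert math.isnan(agg.ale_sd)

    def test_no_significant_replicates_is_error(self):
        with pytest.raises(ValueError, match="significant"):
            aggregate_replicates([make_estimate(significant=False)])
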