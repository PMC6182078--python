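"""Marker-decline fits, threshold solving, and derived epoch events."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from devtempo import (
    DeclineFit,
    EpochThresholds,
    MarkerSeries,
    SimConfig,
    average_replicates,
    derive_epoch_events,
    estimate_event_day_from_bracket,
    fit_decline,
    gen_marker_series,
    solve_threshold,
)


def power_law_series(species="mouse", marker="Ki67", scale=100.0, exponent=-1.0,
                     ages=(50, 100, 150, 200, 300, 400)):
    ages = np.asarray(ages, float)
    return MarkerSeries(species, marker, ages, scale * ages**exponent)


class TestAverageReplicates:
    def test_duplicate_ages_averaged(self):
        s = MarkerSeries("mouse", "Ki67", np.array([100.0, 100.0, 150.0]),
                         np.array([2.0, 4.0, 1.0]))
        out = average_replicates(s)
        np.testing.assert_allclose(out.age_pc, [100.0, 150.0])
        np.testing.assert_allclose(out.pct, [3.0, 1.0])

    def test_no_duplicates_identity(self):
        s = power_law_series()
        out = average_replicates(s)
        np.testing.assert_array_equal(out.age_pc, s.age_pc)
        np.testing.assert_array_equal(out.pct, s.pct)

    def test_disabled_for_marmoset_keeps_points(self):
        s = MarkerSeries("marmoset", "DCX", np.array([100.0, 100.0, 150.0]),
                         np.array([2.0, 4.0, 1.0]))
        out = average_replicates(s, enabled=False)
        assert len(out) == 3

    def test_idempotent(self):
        s = MarkerSeries("rat", "Ki67", np.array([50.0, 50.0, 80.0, 80.0, 120.0]),
                         np.array([5.0, 7.0, 3.0, 1.0, 0.5]))
        once = average_replicates(s)
        twice = average_replicates(once)
        np.testing.assert_array_equal(once.age_pc, twice.age_pc)
        np.testing.assert_array_equal(once.pct, twice.pct)

    def test_zero_fractions_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="cannot be log-transformed"):
            s = MarkerSeries("mouse", "Ki67", np.array([50.0, 100.0, 150.0, 200.0]),
                             np.array([2.0, 0.0, 1.0, 0.5]))
        assert len(s) == 3


class TestFitDecline:
    def test_exact_power_law(self):
        fit = fit_decline(power_law_series())
        assert fit.alpha == pytest.approx(math.log(100), abs=1e-10)
        assert fit.beta == pytest.approx(-1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_slope_within_3_se(self):
        series, truth = gen_marker_series(SimConfig(seed=5))
        fit = fit_decline(series)
        assert abs(fit.beta - truth["beta"]) < 3 * fit.beta_se
        # independent closed-form OLS on ln-ln values
        b_hat = np.polyfit(np.log(series.age_pc), np.log(series.pct), 1)[0]
        assert fit.beta == pytest.approx(b_hat, rel=1e-10)

    def test_window_restriction(self):
        s = power_law_series(ages=(10, 50, 100, 200, 400, 800))
        fit = fit_decline(s, window=(50, 400))
        assert fit.n == 4
        assert fit.window == (50, 400)

    def test_too_few_points_rejected(self):
        s = power_law_series(ages=(50, 100, 150))
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_decline(s, window=(50, 60))

    def test_rising_fit_warns(self):
        s = MarkerSeries("mouse", "Ki67", np.array([50.0, 100.0, 200.0]),
                         np.array([1.0, 2.0, 4.0]))
        with pytest.warns(UserWarning, match="no decline"):
            fit_decline(s)


class TestSolveThreshold:
    def fit_100_over_age(self):
        return DeclineFit("mouse", "Ki67", alpha=math.log(100), beta=-1.0,
                          alpha_se=0.0, beta_se=0.0, r2=1.0, window=(50, 400), n=6)

    def test_closed_form(self):
        assert solve_threshold(self.fit_100_over_age(), 0.5) == pytest.approx(200.0)

    def test_monotone_decreasing_in_pct(self):
        fit = self.fit_100_over_age()
        ages = [solve_threshold(fit, p) for p in (2.0, 1.0, 0.5)]
        assert ages == pytest.approx([50.0, 100.0, 200.0])
        assert ages[0] < ages[1] < ages[2]

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolated"):
            solve_threshold(self.fit_100_over_age(), 0.1)  # age 1000 > window

    def test_rising_fit_unsolvable(self):
        fit = DeclineFit("m", "Ki67", 1.0, 0.5, 0, 0, 1, (1, 10), 4)
        with pytest.raises(ValueError, match="rising"):
            solve_threshold(fit, 1.0)

    @given(st.floats(0.05, 5.0), st.floats(1.1, 20.0))
    @settings(deadline=None)
    def test_round_trip_and_scale_equivariance(self, pct, k):
        fit = self.fit_100_over_age()
        age = solve_threshold(fit, pct)
        assert fit.predict_pct(age) == pytest.approx(pct, rel=1e-9)
        # multiplying ages by k shifts alpha by -beta*ln(k): solved age scales by k
        fit_k = DeclineFit("m", "Ki67", fit.alpha - fit.beta * math.log(k), fit.beta,
                           0, 0, 1, (fit.window[0] * k, fit.window[1] * k), 6)
        assert solve_threshold(fit_k, pct) == pytest.approx(k * age, rel=1e-9)


class TestDeriveEpochEvents:
    def test_two_species_solution(self):
        fits = {
            ("mouse", "Ki67"): fit_decline(power_law_series("mouse", scale=100)),
            ("macaque", "Ki67"): fit_decline(
                power_law_series("macaque", scale=400, ages=(100, 200, 400, 800, 1600))),
        }
        events = derive_epoch_events(fits, EpochThresholds(ki67=(0.5,), dcx=(3.0,)))
        by_species = {e.species: e.day_pc for e in events}
        assert by_species["mouse"] == pytest.approx(200.0)
        assert by_species["macaque"] == pytest.approx(800.0)
        assert all(e.event == "Ki67_0.5pct" for e in events)

    def test_single_species_threshold_dropped(self):
        fits = {("macaque", "Ki67"): fit_decline(power_law_series("macaque"))}
        with pytest.warns(UserWarning, match="dropped"):
            events = derive_epoch_events(fits, EpochThresholds(ki67=(0.5,), dcx=(3.0,)))
        assert events == []

    def test_default_thresholds_full_grid(self):
        species = ["mouse", "rat", "marmoset", "macaque"]
        fits = {}
        for i, sp in enumerate(species):
            for marker in ("Ki67", "DCX"):
                fits[(sp, marker)] = fit_decline(
                    power_law_series(sp, marker, scale=100 * (i + 1)))
        events = derive_epoch_events(fits)
        # 6 Ki67 + 6 DCX thresholds per species
        assert len(events) == 4 * 12
        names = {e.event for e in events}
        assert "Ki67_0.5pct" in names and "DCX_2.5pct" in names
        # solved ages increase as thresholds decrease within a species/marker
        for sp in species:
            ki = sorted(
                (float(e.event.split("_")[1][:-3]), e.day_pc)
                for e in events if e.species == sp and e.event.startswith("Ki67"))
            days = [d for _, d in ki]
            assert days == sorted(days, reverse=True)


class TestThresholdDefaults:
    def test_defaults_match_published_lists(self):
        t = EpochThresholds()
        assert t.ki67 == (2.0, 0.7, 0.5, 0.3, 0.2, 0.1)
        assert t.dcx == (3.0, 2.5, 2.0, 1.5, 1.0, 0.5)

    def test_non_decreasing_rejected(self):
        with pytest.raises(ValueError):
            EpochThresholds(ki67=(0.5, 0.5, 0.3))


class TestBracketEstimate:
    @pytest.mark.parametrize("occurred,not_yet,expected",
                             [(12.0, 10.0, 11.0), (90.0, 80.0, 85.0)])
    def test_arithmetic_midpoint(self, occurred, not_yet, expected):
        assert estimate_event_day_from_bracket(occurred, not_yet) == expected

    def test_geometric_option(self):
        assert estimate_event_day_from_bracket(90.0, 40.0, rule="geometric") == pytest.approx(60.0)

    def test_inverted_bracket_rejected(self):
        with pytest.raises(ValueError, match="inverted bracket"):
            estimate_event_day_from_bracket(10.0, 12.0)

    @given(st.floats(0.1, 1e4), st.floats(1.01, 10.0))
    @settings(deadline=None)
    def test_midpoint_strictly_inside(self, lo, ratio):
        hi = lo * ratio
        mid = estimate_event_day_from_bracket(hi, lo)
        assert lo < mid < hi
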