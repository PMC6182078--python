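"""Latent event-scale fitting, translation and prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devtempo import (
    EventScale,
    EventTimingTable,
    SpeciesRegression,
    extend_model,
    fit_event_scale,
    fit_species_regression,
    predict_day,
    rescale_scale,
    score_new_event,
    translate_time,
)
from devtempo.events import COLUMNS

from _oracles import grid_search_scale, profile_sse
from conftest import make_table


class TestRescale:
    def test_affine_map_to_unit_interval(self):
        out = rescale_scale(EventScale({"a": 2.0, "b": 4.0, "c": 6.0}))
        assert out.scores == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_identity_when_already_spanning(self):
        scores = {"a": 0.0, "b": 0.3, "c": 1.0}
        out = rescale_scale(EventScale(scores))
        assert out.scores == scores

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError, match="degenerate scale"):
            rescale_scale(EventScale({"a": 1.0, "b": 1.0}))

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20, unique=True))
    @settings(deadline=None)
    def test_order_preserved_and_idempotent(self, vals):
        scale = EventScale({f"e{i}": v for i, v in enumerate(vals)})
        out = rescale_scale(scale)
        v_in = scale.values()
        v_out = out.values()
        assert v_out.min() == 0.0 and v_out.max() == 1.0
        # order preserved (ties may appear when inputs collapse in float)
        assert np.all(np.diff(v_out[np.argsort(v_in, kind="stable")]) >= 0)
        again = rescale_scale(out)
        assert np.allclose(again.values(), v_out)


class TestSpeciesRegression:
    def test_collinear_input_recovered_exactly(self):
        scale = EventScale({"a": 0.0, "b": 0.5, "c": 1.0})
        table = EventTimingTable(
            pd.DataFrame(
                [("sp", e, 10.0**d, False, False, "") for e, d in
                 zip("abc", [1.5, 2.7, 3.9])],
                columns=COLUMNS,
            )
        )
        reg = fit_species_regression(table, scale, "sp")
        assert reg.slope == pytest.approx(2.4)
        assert reg.intercept == pytest.approx(1.5)
        assert reg.r2 == pytest.approx(1.0)

    def test_noisy_slope_within_3_se_of_truth(self):
        rng = np.random.default_rng(42)
        n = 100
        x = rng.uniform(0, 1, n)
        y = 1.53 + 2.44 * x + rng.normal(0, 0.05, n)
        scale = EventScale({f"e{i}": xi for i, xi in enumerate(x)})
        table = EventTimingTable(
            pd.DataFrame(
                [("human", f"e{i}", 10.0 ** y[i], False, False, "") for i in range(n)],
                columns=COLUMNS,
            )
        )
        reg = fit_species_regression(table, scale, "human")
        assert abs(reg.slope - 2.44) < 3 * reg.slope_se
        # closed-form OLS on the same sample must agree
        b_hat = np.polyfit(x, y, 1)[0]
        assert reg.slope == pytest.approx(b_hat, rel=1e-10)

    def test_zero_variance_predictor_rejected(self):
        scale = EventScale({"a": 0.5, "b": 0.5})
        table = EventTimingTable(
            pd.DataFrame(
                [("sp", "a", 10.0, False, False, ""), ("sp", "b", 20.0, False, False, "")],
                columns=COLUMNS,
            )
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_species_regression(table, scale, "sp")


class TestFitEventScale:
    def test_noise_free_generative_inverse(self, two_species_exact):
        table, scores, params = two_species_exact
        model = fit_event_scale(table)
        assert model.converged
        assert model.sse == pytest.approx(0.0, abs=1e-20)
        for e, x in scores.items():
            assert model.scale[e] == pytest.approx(x, abs=1e-12)
        for sp, (a, b) in params.items():
            assert model.regressions[sp].intercept == pytest.approx(a, abs=1e-9)
            assert model.regressions[sp].slope == pytest.approx(b, abs=1e-9)

    def test_sse_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        scores = {f"e{i}": s for i, s in enumerate(rng.uniform(0, 1, 6))}
        params = {"mouse": (1.0, 1.0), "rat": (1.1, 1.3), "human": (1.5, 2.4)}
        table = make_table(scores, params, noise_sd=0.02, rng=rng)
        model = fit_event_scale(table)

        frame = table.frame
        species = sorted(frame["species"].unique())
        events = sorted(frame["event"].unique())
        s_idx = frame["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
        e_idx = frame["event"].map({e: i for i, e in enumerate(events)}).to_numpy()
        y = np.log10(frame["day_pc"].to_numpy())
        x0 = np.array([model.scale[e] for e in events])
        _, sse_grid = grid_search_scale(s_idx, e_idx, y, len(species), len(events))
        # start the grid from scratch; the fit must be within 1% of its minimum
        assert model.sse <= sse_grid * 1.01 + 1e-12

    def test_insufficient_events_rejected(self):
        frame = pd.DataFrame(
            [("mouse", "a", 10, False, False, ""),
             ("mouse", "b", 20, False, False, ""),
             ("mouse", "c", 40, False, False, ""),
             ("rat", "a", 12, False, False, ""),
             ("rat", "b", 25, False, False, "")],
            columns=COLUMNS,
        )
        with pytest.raises(ValueError, match="insufficient events"):
            fit_event_scale(EventTimingTable(frame))

    def test_disconnected_graph_rejected(self):
        rows = [("mouse", e, d, False, False, "") for e, d in
                [("a", 10), ("b", 20), ("c", 40)]]
        rows += [("rat", e, d, False, False, "") for e, d in
                 [("x", 11), ("y", 22), ("z", 44)]]
        with pytest.raises(ValueError, match="unidentifiable scale"):
            fit_event_scale(EventTimingTable(pd.DataFrame(rows, columns=COLUMNS)))


class TestScoreNewEvent:
    def test_single_species_inversion(self, two_species_exact):
        table, *_ = two_species_exact
        model = fit_event_scale(table)
        model.regressions["mouse"] = SpeciesRegression("mouse", slope=2.0, intercept=1.0)
        assert score_new_event(model, {"mouse": 100.0}) == pytest.approx(0.5)

    def test_consistent_observations_agree(self, two_species_exact):
        table, *_ = two_species_exact
        model = fit_event_scale(table)
        model.regressions = {
            "mouse": SpeciesRegression("mouse", slope=1.0, intercept=1.0),
            "human": SpeciesRegression("human", slope=2.0, intercept=1.5),
        }
        x = score_new_event(model, {"mouse": 100.0, "human": 10**3.5})
        assert x == pytest.approx(1.0)

    def test_conflicting_observations_slope_squared_weighted(self, two_species_exact):
        table, *_ = two_species_exact
        model = fit_event_scale(table)
        # inversions land at x=0.4 (slope 1) and x=0.6 (slope 3)
        model.regressions = {
            "mouse": SpeciesRegression("mouse", slope=1.0, intercept=0.0),
            "human": SpeciesRegression("human", slope=3.0, intercept=0.0),
        }
        x = score_new_event(model, {"mouse": 10**0.4, "human": 10**1.8})
        assert x == pytest.approx(0.58)

    def test_unscorable_event(self, two_species_exact):
        table, *_ = two_species_exact
        model = fit_event_scale(table)
        with pytest.raises(ValueError, match="unscorable"):
            score_new_event(model, {"alien": 50.0})


class TestPredictTranslate:
    def test_human_day_at_scale_end(self, human_reg):
        # 10**(1.53 + 2.44) = 10**3.97, inside the 3000-10000 day plateau window
        day = predict_day(human_reg, 1.0)
        assert day == pytest.approx(10**3.97)
        assert 3000 < day < 10000

    def test_day_at_score_zero_is_intercept(self, mouse_reg):
        assert predict_day(mouse_reg, 0.0) == pytest.approx(10.0)

    def test_monotone_in_score(self, human_reg):
        scores = np.linspace(0, 1, 50)
        days = [predict_day(human_reg, s) for s in scores]
        assert np.all(np.diff(days) > 0)

    def test_identity_translation(self, mouse_reg):
        assert translate_time(123.0, mouse_reg, mouse_reg) == pytest.approx(123.0)

    def test_mouse_to_human_closed_form(self, mouse_reg, human_reg):
        # mouse day 100 -> x = 1.0 -> human 10**3.97
        assert translate_time(100.0, mouse_reg, human_reg) == pytest.approx(10**3.97)

    @given(
        st.floats(1e-3, 1e6),
        st.floats(0.1, 5.0), st.floats(-1.0, 3.0),
        st.floats(0.1, 5.0), st.floats(-1.0, 3.0),
    )
    @settings(deadline=None)
    def test_round_trip(self, day, b1, a1, b2, a2):
        r1 = SpeciesRegression("s1", slope=b1, intercept=a1)
        r2 = SpeciesRegression("s2", slope=b2, intercept=a2)
        back = translate_time(translate_time(day, r1, r2), r2, r1)
        assert back == pytest.approx(day, rel=1e-9)

    def test_invalid_day_rejected(self, mouse_reg, human_reg):
        with pytest.raises(ValueError, match="invalid day"):
            translate_time(-1.0, mouse_reg, human_reg)


class TestExtendModel:
    def test_extrapolate_places_new_events_and_refits(self, two_species_exact):
        table, scores, params = two_species_exact
        model = fit_event_scale(table)
        # a new event beyond the current scale end, consistent across species
        x_new = 1.2
        rows = [
            (sp, "late_event", 10.0 ** (a + b * x_new), True, True, "")
            for sp, (a, b) in params.items()
        ]
        new = EventTimingTable(pd.DataFrame(rows, columns=COLUMNS))
        ext = extend_model(model, table, new, mode="extrapolate")
        assert "late_event" in ext.scale.scores
        assert ext.scale.values().max() == pytest.approx(1.0)
        assert ext.scale["late_event"] == pytest.approx(1.0)  # now the latest event
        assert ext.sse == pytest.approx(0.0, abs=1e-18)

    def test_refit_mode_matches_full_fit(self, two_species_exact):
        table, scores, params = two_species_exact
        model = fit_event_scale(table)
        rows = [
            (sp, "late_event", 10.0 ** (a + b * 1.2), True, True, "")
            for sp, (a, b) in params.items()
        ]
        new = EventTimingTable(pd.DataFrame(rows, columns=COLUMNS))
        ext = extend_model(model, table, new, mode="refit")
        direct = fit_event_scale(table.extended(new))
        assert ext.sse == pytest.approx(direct.sse, abs=1e-15)
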