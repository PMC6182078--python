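"""Latent event-scale model of cross-species developmental timing.

Every developmental event *i* is assigned a latent score ``x_i`` on a
common 0-1 "event scale", and each species *j* traverses that scale at
its own log-linear rate:

    log10(day_pc of event i in species j) = a_j + b_j * x_i + noise

The intercept ``a_j`` locates the onset of neurodevelopment relative to
conception (precocial species start late), and the slope ``b_j`` is the
species' stretch of developmental time: steeper means slower absolute
progress through the same maturational states.  Scores and per-species
regressions are fit jointly by alternating least squares, then the scale
is affinely rescaled so the earliest event sits at 0 and the latest at 1.

Once fitted, the model translates ages between species (invert one
species' regression, evaluate the other's) and predicts the timing of
events far beyond the data — e.g. the age window over which the human
hippocampal neurogenesis markers are expected to plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .events import EventTimingTable

__all__ = [
    "EventScale",
    "SpeciesRegression",
    "FittedModel",
    "rescale_scale",
    "fit_species_regression",
    "fit_event_scale",
    "score_new_event",
    "predict_day",
    "translate_time",
    "extend_model",
]


@dataclass(frozen=True)
class EventScale:
    """Map from event name to latent score, nominally on [0, 1]."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.scores.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("event scores must be finite")

    def values(self) -> np.ndarray:
        return np.asarray(list(self.scores.values()), dtype=float)

    def __getitem__(self, event: str) -> float:
        return self.scores[event]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class SpeciesRegression:
    """OLS of log10(PC day) on event score for one species.

    ``slope`` is in log10-days per event-scale unit; ``intercept`` is the
    log10 PC day at score 0 (onset of the modelled span).
    """

    species: str
    slope: float
    intercept: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    r2: float = float("nan")
    n: int = 0


@dataclass
class FittedModel:
    scale: EventScale
    regressions: dict[str, SpeciesRegression]
    converged: bool
    n_iter: int
    sse: float

    def to_dict(self) -> dict:
        return {
            "scores": dict(self.scale.scores),
            "regressions": {
                s: {
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "slope_se": r.slope_se,
                    "intercept_se": r.intercept_se,
                    "r2": r.r2,
                    "n": r.n,
                }
                for s, r in self.regressions.items()
            },
            "converged": self.converged,
            "n_iter": self.n_iter,
            "sse": self.sse,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        regs = {
            s: SpeciesRegression(species=s, **v) for s, v in d["regressions"].items()
        }
        return cls(
            scale=EventScale({k: float(v) for k, v in d["scores"].items()}),
            regressions=regs,
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            sse=float(d["sse"]),
        )


# ---------------------------------------------------------------------------
# elementary operations


def rescale_scale(scale: EventScale) -> EventScale:
    """Affinely map scores onto [0, 1], preserving order.

    The earliest event is subtracted from every score and the result is
    divided by the span between latest and earliest.
    """
    if len(scale) < 2:
        raise ValueError("degenerate scale: need at least 2 scores")
    vals = scale.values()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("degenerate scale: all scores equal")
    return EventScale({e: (v - lo) / (hi - lo) for e, v in scale.scores.items()})


def fit_species_regression(
    table: EventTimingTable, scale: EventScale, species: str
) -> SpeciesRegression:
    """OLS of log10(day_pc) on event score for one species."""
    sub = table.subset_species(species)
    sub = sub[sub["event"].isin(scale.scores)]
    if len(sub) < 2:
        raise ValueError(f"insufficient events: species {species!r} has {len(sub)} scored events")
    x = np.array([scale[e] for e in sub["event"]])
    y = np.log10(sub["day_pc"].to_numpy())
    if np.ptp(x) == 0:
        raise ValueError("zero variance predictor: all event scores identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SpeciesRegression(
        species=species,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        r2=float(res.rsquared),
        n=len(sub),
    )


def predict_day(reg: SpeciesRegression, score: float) -> float:
    """Predicted PC day at a given event-scale score: 10**(a + b*score).

    Extrapolation outside [0, 1] is allowed but flagged with a warning.
    """
    if not 0.0 <= score <= 1.0:
        warnings.warn(
            f"score {score} outside [0, 1]: extrapolating beyond the fitted scale",
            stacklevel=2,
        )
    return float(10.0 ** (reg.intercept + reg.slope * score))


def translate_time(
    day_pc: float, from_reg: SpeciesRegression, to_reg: SpeciesRegression
) -> float:
    """Express a PC age of one species in the time frame of another.

    Inverts the source regression to a scale position, then evaluates the
    target regression there.  Exact round trips by construction.
    """
    if not np.isfinite(day_pc) or day_pc <= 0:
        raise ValueError(f"invalid day: {day_pc!r}")
    if from_reg.slope <= 0:
        raise ValueError("degenerate species regression: non-positive slope")
    x = (np.log10(day_pc) - from_reg.intercept) / from_reg.slope
    return float(10.0 ** (to_reg.intercept + to_reg.slope * x))


def score_new_event(
    model: FittedModel, observations: Mapping[str, float]
) -> float:
    """Place a new event on the fitted scale from its observed ages.

    Each observing species' regression is inverted,
    ``x_j = (log10 day - a_j) / b_j``, and the inversions are combined as a
    slope^2-weighted mean: the steeper a species' regression, the more a
    fixed error in log-day moves the implied score, so weighting by b^2
    weights by information about x.  The result may fall outside [0, 1];
    rescaling is the caller's decision.
    """
    xs, ws = [], []
    for species, day in observations.items():
        reg = model.regressions.get(species)
        if reg is None or reg.slope <= 0:
            continue
        if not np.isfinite(day) or day <= 0:
            raise ValueError(f"invalid day: {day!r} for species {species!r}")
        xs.append((np.log10(day) - reg.intercept) / reg.slope)
        ws.append(reg.slope**2)
    if not xs:
        raise ValueError("unscorable event: no observing species with a positive-slope regression")
    return float(np.average(xs, weights=ws))


# ---------------------------------------------------------------------------
# joint fit


def _prepare_arrays(table: EventTimingTable):
    frame = table.frame
    species = sorted(frame["species"].unique())
    events = sorted(frame["event"].unique())
    s_idx = frame["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    e_idx = frame["event"].map({e: i for i, e in enumerate(events)}).to_numpy()
    y = np.log10(frame["day_pc"].to_numpy())
    return species, events, s_idx, e_idx, y


def _species_ols(
    x: np.ndarray, y: np.ndarray, s_idx: np.ndarray, e_idx: np.ndarray, n_species: int
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-species OLS of y on x[e_idx], vectorised with bincount."""
    xe = x[e_idx]
    n = np.bincount(s_idx, minlength=n_species).astype(float)
    sx = np.bincount(s_idx, weights=xe, minlength=n_species)
    sy = np.bincount(s_idx, weights=y, minlength=n_species)
    sxx = np.bincount(s_idx, weights=xe * xe, minlength=n_species)
    sxy = np.bincount(s_idx, weights=xe * y, minlength=n_species)
    denom = sxx - sx * sx / n
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (sxy - sx * sy / n) / denom
    b = np.where(denom > 0, b, np.nan)
    a = (sy - b * sx) / n
    return a, b


def _initial_scores(
    y: np.ndarray, s_idx: np.ndarray, e_idx: np.ndarray, n_species: int, n_events: int
) -> np.ndarray:
    """Mean over observing species of the within-species min-max-normalised log day."""
    lo = np.full(n_species, np.inf)
    hi = np.full(n_species, -np.inf)
    np.minimum.at(lo, s_idx, y)
    np.maximum.at(hi, s_idx, y)
    span = np.where(hi > lo, hi - lo, 1.0)
    z = (y - lo[s_idx]) / span[s_idx]
    num = np.bincount(e_idx, weights=z, minlength=n_events)
    cnt = np.bincount(e_idx, minlength=n_events)
    return num / cnt


def fit_event_scale(
    table: EventTimingTable, tol: float = 1e-8, max_iter: int = 500
) -> FittedModel:
    """Fit the latent event scale and species regressions jointly.

    Alternating least squares: given scores, each species' (a_j, b_j) is an
    OLS fit; given regressions, each event's score is the weighted
    projection ``x_i = sum_j b_j (y_ij - a_j) / sum_j b_j^2`` over its
    observing species.  The scale is rescaled to [0, 1] each round and
    iteration stops when no score moves by more than ``tol``.

    Requires every species to contribute at least 3 events and the
    species-event graph to be connected (otherwise the scale has
    independently shiftable blocks and is unidentifiable).
    """
    per_species = table.events_per_species()
    thin = per_species[per_species < 3]
    if len(thin):
        raise ValueError(
            "insufficient events: species "
            + ", ".join(f"{s} ({n})" for s, n in thin.items())
            + " have fewer than 3 events"
        )
    if not table.is_connected():
        raise ValueError("unidentifiable scale: disconnected event/species graph")

    species, events, s_idx, e_idx, y = _prepare_arrays(table)
    n_species, n_events = len(species), len(events)

    x = _initial_scores(y, s_idx, e_idx, n_species, n_events)
    x = (x - x.min()) / (x.max() - x.min())

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a, b = _species_ols(x, y, s_idx, e_idx, n_species)
        if np.any(~np.isfinite(b)):
            raise ValueError("degenerate species regression: zero-variance scores within a species")
        # per-event weighted projection onto the current regressions
        resid = y - a[s_idx]
        num = np.bincount(e_idx, weights=b[s_idx] * resid, minlength=n_events)
        den = np.bincount(e_idx, weights=b[s_idx] ** 2, minlength=n_events)
        x_new = num / den
        x_new = (x_new - x_new.min()) / (x_new.max() - x_new.min())
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if delta < tol:
            converged = True
            break

    scale = EventScale(dict(zip(events, x.tolist())))
    regressions: dict[str, SpeciesRegression] = {}
    for sp in species:
        reg = fit_species_regression(table, scale, sp)
        if reg.slope <= 0:
            raise ValueError(f"degenerate species regression: non-positive slope for {sp!r}")
        regressions[sp] = reg

    a_fin = np.array([regressions[sp].intercept for sp in species])
    b_fin = np.array([regressions[sp].slope for sp in species])
    sse = float(np.sum((y - (a_fin[s_idx] + b_fin[s_idx] * x[e_idx])) ** 2))
    return FittedModel(scale=scale, regressions=regressions, converged=converged, n_iter=n_iter, sse=sse)


def extend_model(
    model: FittedModel,
    base_table: EventTimingTable,
    new_table: EventTimingTable,
    mode: str = "extrapolate",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedModel:
    """Add new events (e.g. derived neurogenesis epochs) to a fitted model.

    ``mode="extrapolate"`` scores each new event against the frozen
    regressions via :func:`score_new_event`, rescales the union of old and
    new scores to [0, 1], and refits the per-species regressions once —
    the timetable is extended, not recomputed.  ``mode="refit"`` reruns the
    full alternating fit on the combined table.
    """
    combined = base_table.extended(new_table)
    if mode == "refit":
        return fit_event_scale(combined, tol=tol, max_iter=max_iter)
    if mode != "extrapolate":
        raise ValueError(f"unknown mode {mode!r}")

    scores = dict(model.scale.scores)
    new_frame = new_table.frame
    for event, grp in new_frame.groupby("event"):
        if event in scores:
            continue
        obs = dict(zip(grp["species"], grp["day_pc"]))
        scores[event] = score_new_event(model, obs)
    scale = rescale_scale(EventScale(scores))

    regressions = {
        sp: fit_species_regression(combined, scale, sp) for sp in combined.species
    }
    for sp, reg in regressions.items():
        if reg.slope <= 0:
            raise ValueError(f"degenerate species regression: non-positive slope for {sp!r}")
    frame = combined.frame
    y = np.log10(frame["day_pc"].to_numpy())
    pred = np.array(
        [
            regressions[s].intercept + regressions[s].slope * scale[e]
            for s, e in zip(frame["species"], frame["event"])
        ]
    )
    sse = float(np.sum((y - pred) ** 2))
    return FittedModel(scale=scale, regressions=regressions, converged=True, n_iter=1, sse=sse)
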