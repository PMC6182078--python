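"""Hippocampal neurogenesis epochs from Ki67+/DCX+ marker declines.

The fraction of proliferating (Ki67+) and immature (DCX+) cells among
dentate granule cells falls off with age roughly as a power law.  On
natural-log axes the decline is linear, so a regression of ln(percent)
on ln(PC age) over a window of sharp decline summarises it with two
numbers, and solving the line for a given percentage yields the age at
which the marker fraction crosses that threshold.  Each threshold
crossing ("epoch") is a derived developmental event that can be fed back
into the cross-species event-scale model.

Marker fractions are handled as percent of total granule cells
throughout; data normalised per mm^2 of tissue are not comparable and
must not be used here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .events import DEFAULT_RODENT_SPECIES, EventRecord

__all__ = [
    "MarkerSeries",
    "DeclineFit",
    "EpochThresholds",
    "DerivedEvent",
    "average_replicates",
    "fit_decline",
    "solve_threshold",
    "derive_epoch_events",
    "estimate_event_day_from_bracket",
]

#: Default epoch thresholds, in percent of total granule cells.
DEFAULT_KI67_THRESHOLDS = (2.0, 0.7, 0.5, 0.3, 0.2, 0.1)
DEFAULT_DCX_THRESHOLDS = (3.0, 2.5, 2.0, 1.5, 1.0, 0.5)


@dataclass(frozen=True)
class MarkerSeries:
    """Marker-positive fraction (percent of granule cells) versus PC age."""

    species: str
    marker: str
    age_pc: np.ndarray
    pct: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age_pc, dtype=float)
        pct = np.asarray(self.pct, dtype=float)
        if age.shape != pct.shape or age.ndim != 1:
            raise ValueError("age_pc and pct must be 1-D arrays of equal length")
        if np.any(age <= 0):
            raise ValueError("ages must be positive PC days")
        keep = pct > 0
        if not keep.all():
            warnings.warn(
                f"{(~keep).sum()} non-positive marker fractions dropped "
                f"({self.species}/{self.marker}): zero fractions cannot be log-transformed",
                stacklevel=3,
            )
            age, pct = age[keep], pct[keep]
        object.__setattr__(self, "age_pc", age)
        object.__setattr__(self, "pct", pct)

    def __len__(self) -> int:
        return len(self.age_pc)


@dataclass(frozen=True)
class DeclineFit:
    """ln(pct) = alpha + beta * ln(age_pc), fitted inside ``window``."""

    species: str
    marker: str
    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    r2: float
    window: tuple[float, float]
    n: int

    def predict_pct(self, age_pc: float) -> float:
        return float(np.exp(self.alpha + self.beta * np.log(age_pc)))


@dataclass(frozen=True)
class EpochThresholds:
    """Percent thresholds defining neurogenesis epochs, strictly decreasing."""

    ki67: tuple[float, ...] = DEFAULT_KI67_THRESHOLDS
    dcx: tuple[float, ...] = DEFAULT_DCX_THRESHOLDS

    def __post_init__(self) -> None:
        for name, seq in (("ki67", self.ki67), ("dcx", self.dcx)):
            arr = np.asarray(seq, dtype=float)
            if np.any(arr <= 0) or np.any(np.diff(arr) >= 0):
                raise ValueError(f"{name} thresholds must be positive and strictly decreasing")

    def for_marker(self, marker: str) -> tuple[float, ...]:
        key = marker.lower()
        if key == "ki67":
            return self.ki67
        if key == "dcx":
            return self.dcx
        raise KeyError(f"unknown marker {marker!r}")


@dataclass(frozen=True)
class DerivedEvent:
    """A threshold-crossing epoch expressed as a developmental event."""

    species: str
    event: str
    day_pc: float
    limbic: bool = True
    neurogenetic: bool = True
    source: str = "derived epoch"

    def to_record(self) -> EventRecord:
        return EventRecord(
            species=self.species,
            event=self.event,
            day_pc=self.day_pc,
            limbic=self.limbic,
            neurogenetic=self.neurogenetic,
            source=self.source,
        )


def average_replicates(series: MarkerSeries, enabled: bool = True) -> MarkerSeries:
    """Average marker fractions sharing an age (arithmetic mean of pct).

    Some series (e.g. the marmoset) are kept as individual animals, so the
    averaging can be disabled per species via ``enabled=False``, which
    returns the series unchanged.
    """
    if not enabled or len(series) == 0:
        return series
    ages, inv = np.unique(series.age_pc, return_inverse=True)
    sums = np.bincount(inv, weights=series.pct)
    counts = np.bincount(inv)
    return MarkerSeries(series.species, series.marker, ages, sums / counts)


def fit_decline(
    series: MarkerSeries, window: tuple[float, float] | None = None
) -> DeclineFit:
    """OLS of ln(pct) on ln(age_pc) restricted to an age window.

    The window should cover the span of sharp, monotone decline; a
    non-negative slope inside the window triggers a warning, since a
    rising fit cannot be solved for threshold-crossing ages.
    """
    if window is None:
        window = (float(series.age_pc.min()), float(series.age_pc.max()))
    lo, hi = window
    mask = (series.age_pc >= lo) & (series.age_pc <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points in window [{lo}, {hi}], got {int(mask.sum())}"
        )
    x = np.log(series.age_pc[mask])
    y = np.log(series.pct[mask])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    beta = float(res.params[1])
    if beta >= 0:
        warnings.warn(
            f"no decline in window for {series.species}/{series.marker}: slope {beta:.3g} >= 0",
            stacklevel=2,
        )
    return DeclineFit(
        species=series.species,
        marker=series.marker,
        alpha=float(res.params[0]),
        beta=beta,
        alpha_se=float(res.bse[0]),
        beta_se=float(res.bse[1]),
        r2=float(res.rsquared),
        window=(lo, hi),
        n=int(mask.sum()),
    )


def solve_threshold(fit: DeclineFit, pct: float) -> float:
    """Age (PC days) at which the fitted decline crosses ``pct``.

    Inverts the power law: age = exp((ln pct - alpha) / beta).  Warns when
    the solution lies outside the fitted window (extrapolation).
    """
    if fit.beta >= 0:
        raise ValueError("cannot solve rising fit: beta >= 0")
    if pct <= 0:
        raise ValueError("threshold percent must be positive")
    age = float(math.exp((math.log(pct) - fit.alpha) / fit.beta))
    if not (fit.window[0] <= age <= fit.window[1]):
        warnings.warn(
            f"threshold {pct}% solved at {age:.1f} PC days, "
            f"extrapolated outside fitted window {fit.window}",
            stacklevel=2,
        )
    return age


def _event_name(marker: str, pct: float) -> str:
    return f"{marker}_{pct:g}pct"


def derive_epoch_events(
    fits: Mapping[tuple[str, str], DeclineFit],
    thresholds: EpochThresholds = EpochThresholds(),
    rodent_species: Iterable[str] = DEFAULT_RODENT_SPECIES,
    min_species: int = 2,
) -> list[DerivedEvent]:
    """Solve every (species, marker, threshold) crossing and apply retention.

    A threshold is retained as a model event only when it is solvable in at
    least ``min_species`` species including at least one rodent, mirroring
    the table-wide retention rule; others are dropped with a warning.
    """
    rodents = set(rodent_species)
    candidates: dict[str, list[DerivedEvent]] = {}
    for (species, marker), fit in fits.items():
        if fit.beta >= 0:
            raise ValueError(f"fit for ({species}, {marker}) has beta >= 0")
        for pct in thresholds.for_marker(marker):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                day = solve_threshold(fit, pct)
            candidates.setdefault(_event_name(marker, pct), []).append(
                DerivedEvent(species=species, event=_event_name(marker, pct), day_pc=day)
            )
    events: list[DerivedEvent] = []
    for name in sorted(candidates):
        group = candidates[name]
        n_sp = len({ev.species for ev in group})
        has_rodent = any(ev.species in rodents for ev in group)
        if n_sp >= min_species and has_rodent:
            events.extend(sorted(group, key=lambda ev: ev.species))
        else:
            warnings.warn(
                f"epoch event {name} dropped: observed in {n_sp} species "
                f"(rodent: {has_rodent})",
                stacklevel=2,
            )
    return events


def estimate_event_day_from_bracket(
    earliest_occurred: float, latest_not_occurred: float, rule: str = "midpoint"
) -> float:
    """Estimate an event's day from an occurrence bracket.

    Staged observations (e.g. structural MRI) give the earliest age at
    which an event has occurred and the latest age at which it had not;
    the event day is taken as the midpoint (arithmetic by default,
    geometric via ``rule="geometric"``).
    """
    if earliest_occurred <= 0 or latest_not_occurred <= 0:
        raise ValueError("bracket ages must be positive")
    if latest_not_occurred >= earliest_occurred:
        raise ValueError(
            "inverted bracket: latest_not_occurred must precede earliest_occurred"
        )
    if rule == "midpoint":
        return (earliest_occurred + latest_not_occurred) / 2.0
    if rule == "geometric":
        return math.sqrt(earliest_occurred * latest_not_occurred)
    raise ValueError(f"unknown rule {rule!r}")
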