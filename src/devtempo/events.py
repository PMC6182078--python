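"""Event-timing tables: the observational unit of the cross-species model.

A record is one developmental event observed in one species at a
post-conception (PC) age in days.  Events are things like "onset of
cerebellar neurogenesis" or a derived epoch such as "Ki67+ fraction
crosses 0.5% of granule cells".  The comparative model only retains
events observed in at least two species, at least one of them a rodent,
so that every event anchors a cross-species comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "EventTimingTable",
    "DEFAULT_RODENT_SPECIES",
]

#: Species treated as rodents by the two-species / one-rodent retention rule.
DEFAULT_RODENT_SPECIES = frozenset({"mouse", "rat", "spiny_mouse", "guinea_pig", "rabbit"})

COLUMNS = ["species", "event", "day_pc", "limbic", "neurogenetic", "source"]


@dataclass(frozen=True)
class EventRecord:
    """One (species, event) observation at a positive post-conception day."""

    species: str
    event: str
    day_pc: float
    limbic: bool = False
    neurogenetic: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.day_pc) or self.day_pc <= 0:
            raise ValueError(
                f"day_pc must be a positive finite number, got {self.day_pc!r} "
                f"for ({self.species!r}, {self.event!r})"
            )


class EventTimingTable:
    """Long-format table of event-timing records.

    Wraps a :class:`pandas.DataFrame` with columns
    ``species, event, day_pc, limbic, neurogenetic, source`` and enforces
    positivity of days and uniqueness of (species, event) keys.  Duplicate
    keys are an error, never silently averaged.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        frame = frame[COLUMNS].reset_index(drop=True)
        frame["species"] = frame["species"].astype(str)
        frame["event"] = frame["event"].astype(str)
        frame["day_pc"] = frame["day_pc"].astype(float)
        frame["limbic"] = frame["limbic"].astype(bool)
        frame["neurogenetic"] = frame["neurogenetic"].astype(bool)
        frame["source"] = frame["source"].fillna("").astype(str)
        if len(frame) == 0:
            raise ValueError("event table is empty")
        bad = frame.index[~np.isfinite(frame["day_pc"]) | (frame["day_pc"] <= 0)]
        if len(bad) > 0:
            raise ValueError(f"non-positive day_pc at rows {list(bad)}")
        dup = frame.duplicated(subset=["species", "event"], keep=False)
        if dup.any():
            keys = frame.loc[dup, ["species", "event"]].drop_duplicates()
            raise ValueError(
                "duplicate (species, event) rows: "
                + ", ".join(f"({s}, {e})" for s, e in keys.itertuples(index=False))
            )
        self._frame = frame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[EventRecord]) -> "EventTimingTable":
        rows = [
            (r.species, r.event, r.day_pc, r.limbic, r.neurogenetic, r.source)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (copy-on-write: do not mutate)."""
        return self._frame

    @property
    def species(self) -> list[str]:
        return sorted(self._frame["species"].unique())

    @property
    def events(self) -> list[str]:
        return sorted(self._frame["event"].unique())

    def __len__(self) -> int:
        return len(self._frame)

    def records(self) -> list[EventRecord]:
        return [
            EventRecord(r.species, r.event, r.day_pc, bool(r.limbic), bool(r.neurogenetic), r.source)
            for r in self._frame.itertuples(index=False)
        ]

    def subset_species(self, species: str) -> pd.DataFrame:
        return self._frame[self._frame["species"] == species]

    def events_per_species(self) -> pd.Series:
        return self._frame.groupby("species")["event"].nunique()

    # -- combination -------------------------------------------------------

    def extended(self, other: "EventTimingTable") -> "EventTimingTable":
        """Concatenate two tables; duplicate keys raise."""
        return EventTimingTable(pd.concat([self._frame, other._frame], ignore_index=True))

    # -- retention rule ----------------------------------------------------

    def filtered(
        self,
        rodent_species: Iterable[str] = DEFAULT_RODENT_SPECIES,
        min_species: int = 2,
        require_rodent: bool = True,
    ) -> tuple["EventTimingTable", int]:
        """Apply the cross-species retention rule.

        Keeps only events observed in at least ``min_species`` species and,
        if ``require_rodent``, in at least one rodent species.  Returns the
        filtered table and the number of events removed.
        """
        rodents = set(rodent_species)
        by_event = self._frame.groupby("event")["species"]
        n_species = by_event.nunique()
        has_rodent = by_event.agg(lambda s: bool(set(s) & rodents))
        keep = n_species >= min_species
        if require_rodent:
            keep &= has_rodent
        kept_events = set(keep.index[keep])
        removed = int((~keep).sum())
        if removed:
            warnings.warn(f"retention rule removed {removed} events", stacklevel=2)
        if not kept_events:
            raise ValueError("no events survive the retention rule")
        out = self._frame[self._frame["event"].isin(kept_events)]
        return EventTimingTable(out), removed

    def is_connected(self) -> bool:
        """True if the species-event bipartite graph has a single component.

        Connectivity is what makes the latent event scale identifiable:
        disjoint blocks of species/events can be shifted independently.
        """
        # union-find over species (prefixed) and events
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for r in self._frame.itertuples(index=False):
            a, b = find("s:" + r.species), find("e:" + r.event)
            if a != b:
                parent[a] = b
        roots = {find("s:" + s) for s in self._frame["species"].unique()}
        roots |= {find("e:" + e) for e in self._frame["event"].unique()}
        return len(roots) == 1
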