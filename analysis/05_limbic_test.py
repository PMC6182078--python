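#!/usr/bin/env python
"""Test whether limbic neurogenetic events terminate early.

Simulates an event table in which limbic events traverse the scale with
a 10% shallower slope, fits the scale, and runs the sequential-ANOVA
interaction test per species: log10(day) ~ scale + limbic +
scale:limbic, F statistics in that order.  A significant interaction
means limbic events progress at a different rate than the rest of the
timetable — the signature of early limbic termination.  A control run
with no limbic effect shows the test stays quiet under the null.
"""

import json
from pathlib import Path

import pandas as pd

from devtempo import (
    EventSimParams,
    SimConfig,
    fit_event_scale,
    fit_limbic_anova,
    gen_event_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921


def run(multiplier: float, label: str) -> list[dict]:
    cfg = SimConfig(seed=SEED + 30, events=EventSimParams(
        n_events=120, limbic_slope_multiplier=multiplier))
    table, _ = gen_event_table(cfg)
    model = fit_event_scale(table)
    rows = []
    for sp in table.species:
        res = fit_limbic_anova(table, model.scale, sp)
        rows.append({"condition": label, **res.to_dict()})
        print(f"  [{label}] {sp:<9} F_model={res.f_model:7.1f} R2={res.r2_model:.3f} "
              f"F_limbic={res.f_limbic:6.2f} (p={res.p_limbic:.3f}) "
              f"F_interaction={res.f_interaction:6.2f} (p={res.p_interaction:.4f})")
    return rows


def main() -> None:
    print("limbic slope 10% shallower (early termination built in):")
    rows = run(0.9, "effect")
    print("no limbic effect (null control):")
    rows += run(1.0, "null")
    pd.DataFrame(rows).to_csv(ROOT / "limbic_tests.tsv", sep="\t", index=False)
    n_sig = sum(r["p_interaction"] < 0.05 for r in rows if r["condition"] == "effect")
    n_null = sum(r["p_interaction"] < 0.05 for r in rows if r["condition"] == "null")
    print(f"limbic terms significant at 0.05: {n_sig}/4 species with the effect, "
          f"{n_null}/4 under the null control")
    print("note: the scale is a cross-species compromise, so a deviation shared by "
          "the three primates surfaces as a relative deviation — often most "
          "visible in the rodent reference species")


if __name__ == "__main__":
    main()
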