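#!/usr/bin/env python
"""Detect expression plateaus and form the shared developmental event.

Each gene's time course is fit with a linear-plateau model (rise then
flat); fits must converge to an interior breakpoint with all three
coefficients significant at 0.05.  Genes passing in both the mouse-like
and human-like datasets (via the ortholog map) contribute their
breakpoint ages, whose per-species means become one developmental event
observed in two species.
"""

import json
from pathlib import Path

import pandas as pd

import devtempo.io as dio
from devtempo import cross_species_plateau_event, detect_plateaus

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main() -> None:
    ds_m = dio.read_expression(SIM / "expr_mouse.tsv", SIM / "meta_mouse.tsv")
    ds_h = dio.read_expression(SIM / "expr_human.tsv", SIM / "meta_human.tsv")
    orth = dio.read_orthologs(SIM / "orthologs.tsv")
    truth = json.loads((SIM / "truth.json").read_text())["plateaus"]

    f_m = detect_plateaus(ds_m, (ds_m[0].age_pc.min(), ds_m[0].age_pc.max()))
    f_h = detect_plateaus(ds_h, (ds_h[0].age_pc.min(), ds_h[0].age_pc.max()))
    print(f"mouse-like: {len(f_m)} plateau genes retained "
          f"({sum(truth['mouse_labels'].values())} simulated)")
    print(f"human-like: {len(f_h)} plateau genes retained "
          f"({sum(truth['human_labels'].values())} simulated)")

    ev_m, ev_h = cross_species_plateau_event(f_m, f_h, orth)
    shared = [g for g, _ in orth.pairs if g in f_m and g in f_h]
    print(f"{len(shared)} genes plateau in both species")
    print(f"shared event '{ev_m.event}': {ev_m.day_pc:.1f} PC days ({ev_m.species}) / "
          f"{ev_h.day_pc:.1f} PC days ({ev_h.species})")

    rows = [{"species": "mouse", "gene": g, "c": f_m[g].c, "a": f_m[g].a, "b": f_m[g].b}
            for g in sorted(f_m)]
    rows += [{"species": "human", "gene": g, "c": f_h[g].c, "a": f_h[g].a, "b": f_h[g].b}
             for g in sorted(f_h)]
    pd.DataFrame(rows).to_csv(ROOT / "plateau_fits.tsv", sep="\t", index=False)
    pd.DataFrame([{"species": e.species, "event": e.event, "day_pc": e.day_pc}
                  for e in (ev_m, ev_h)]).to_csv(
        ROOT / "plateau_event.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
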