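#!/usr/bin/env python
"""Extend the fitted model with the epoch events and predict human ages.

The derived neurogenesis epochs are placed on the fitted scale by
inverting each observing species' regression (no full recomputation),
the union of scores is rescaled to [0, 1], and the species regressions
are refit once.  The human regression then translates each epoch's
scale position into a predicted human post-conception day, and
mouse-range ages are translated into their human equivalents.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import devtempo.io as dio
from devtempo import extend_model, predict_day, translate_time

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    base_table = dio.read_event_table(ROOT / "sim" / "events.tsv")
    new_table = dio.read_event_table(ROOT / "new_events.tsv")
    model = dio.read_model(ROOT / "model.json")

    ext = extend_model(model, base_table, new_table, mode="extrapolate")
    dio.write_model(ext, ROOT / "model_extended.json")

    human = ext.regressions["human"]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for event in sorted(new_table.events):
            score = ext.scale[event]
            rows.append({"event": event, "scale": score,
                         "human_day_pc": predict_day(human, score),
                         "human_years_pc": predict_day(human, score) / 365.25})
    df = pd.DataFrame(rows).sort_values("scale")
    df.to_csv(ROOT / "human_epoch_predictions.tsv", sep="\t", index=False)

    print(f"extended scale spans {len(ext.scale)} events; human regression "
          f"log10(day) = {human.intercept:.3f} + {human.slope:.3f}*scale")
    print("predicted human ages for the derived epochs:")
    for r in df.itertuples(index=False):
        print(f"  {r.event:<16} scale={r.scale:.3f} -> {r.human_day_pc:8.0f} PC days "
              f"({r.human_years_pc:5.1f} yr)")

    mouse = ext.regressions["mouse"]
    trans = [(d, translate_time(d, mouse, human)) for d in (38.0, 45.0, 50.0)]
    pd.DataFrame(trans, columns=["mouse_day_pc", "human_day_pc"]).to_csv(
        ROOT / "mouse_to_human.tsv", sep="\t", index=False)
    for d, h in trans:
        print(f"mouse PC day {d:.0f} translates to human PC day {h:.0f}")


if __name__ == "__main__":
    main()
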