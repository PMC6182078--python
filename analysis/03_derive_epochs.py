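#!/usr/bin/env python
"""Fit marker declines and derive neurogenesis epoch events.

For each simulated species the Ki67+ fraction of granule cells falls as
a power law of post-conception age; a regression of ln(percent) on
ln(age) is solved for the ages at which the fraction crosses the
standard epoch thresholds (2, 0.7, 0.5, 0.3, 0.2, 0.1%).  Thresholds
solvable in at least two species including a rodent become derived
developmental events (new_events.tsv).
"""

from pathlib import Path

import pandas as pd

import devtempo.io as dio
from devtempo import EpochThresholds, average_replicates, derive_epoch_events, fit_decline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fits = {}
    rows = []
    for series in dio.read_marker_table(ROOT / "sim" / "markers.tsv"):
        series = average_replicates(series, enabled=series.species != "marmoset")
        fit = fit_decline(series)
        fits[(series.species, series.marker)] = fit
        rows.append({"species": series.species, "marker": series.marker,
                     "alpha": fit.alpha, "beta": fit.beta, "beta_se": fit.beta_se,
                     "r2": fit.r2, "n": fit.n})
        print(f"{series.species:<9} {series.marker}: ln(pct) = {fit.alpha:.2f} "
              f"{fit.beta:+.2f}*ln(age)  (R2={fit.r2:.3f}, n={fit.n})")

    pd.DataFrame(rows).to_csv(ROOT / "decline_fits.tsv", sep="\t", index=False)

    events = derive_epoch_events(fits, EpochThresholds())
    dio.write_derived_events(events, ROOT / "new_events.tsv")
    n_thresholds = len({e.event for e in events})
    print(f"derived {len(events)} epoch events ({n_thresholds} thresholds x species), "
          f"written to {ROOT / 'new_events.tsv'}")


if __name__ == "__main__":
    main()
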