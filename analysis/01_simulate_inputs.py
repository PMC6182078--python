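#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/sim/: an event-timing table for four species
(published human/macaque/marmoset coefficients plus a mouse-like
rodent), Ki67 marker-decline series for three species, paired
mouse-like and human-like expression time courses, and a clustered
sparse single-cell count matrix — each beside its ground truth.
"""

import json
from pathlib import Path

import devtempo.io as dio
from devtempo import (
    MarkerSimParams,
    PlateauSimParams,
    SimConfig,
    gen_cell_matrix,
    gen_event_table,
    gen_expression_timecourses,
    gen_marker_series,
)
from devtempo.io import write_expression

SEED = 20260921
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth_all = {}

    table, truth = gen_event_table(SimConfig(seed=SEED))
    dio.write_event_table(table, OUT / "events.tsv")
    truth_all["events"] = {k: truth[k] for k in ("species", "noise_sd")}
    print(f"events: {len(table)} records, {len(table.events)} events, "
          f"{len(table.species)} species")

    series = []
    for i, (sp, alpha, beta, lo, hi) in enumerate([
        ("mouse", 6.0, -1.5, 50, 250),
        ("rat", 6.5, -1.4, 55, 280),
        ("macaque", 8.0, -1.2, 150, 3000),
    ]):
        s, t = gen_marker_series(SimConfig(seed=SEED + i, markers=MarkerSimParams(
            species=sp, alpha=alpha, beta=beta, age_min=lo, age_max=hi)))
        series.append(s)
        truth_all.setdefault("markers", {})[sp] = t
    dio.write_marker_table(series, OUT / "markers.tsv")
    print(f"markers: {sum(len(s) for s in series)} points across {len(series)} species")

    ds_m, t_m = gen_expression_timecourses(SimConfig(seed=SEED + 10))
    ds_h, t_h = gen_expression_timecourses(SimConfig(seed=SEED + 11, plateaus=PlateauSimParams(
        species="human", age_min=101, age_max=999, n_samples=10, noise_sd=0.05)))
    write_expression(ds_m, OUT / "expr_mouse.tsv", OUT / "meta_mouse.tsv")
    write_expression(ds_h, OUT / "expr_human.tsv", OUT / "meta_human.tsv")
    (OUT / "orthologs.tsv").write_text(
        "".join(f"{tc.gene}\t{tc.gene}\n" for tc in ds_m))
    truth_all["plateaus"] = {"mouse_labels": t_m["labels"], "human_labels": t_h["labels"]}
    print(f"expression: {len(ds_m)} mouse genes, {len(ds_h)} human genes")

    matrix, annotation, t_c = gen_cell_matrix(SimConfig(seed=SEED + 20))
    dio.write_cell_inputs(matrix, annotation, OUT / "counts.mtx", OUT / "genes.tsv",
                          OUT / "barcodes.tsv", OUT / "clusters.tsv")
    truth_all["cells"] = {"rho": t_c["rho"], "n_anchor_pos": int(t_c["anchor_pos"].sum())}
    print(f"cells: {matrix.counts.shape[0]} cells x {matrix.counts.shape[1]} genes, "
          f"{matrix.counts.nnz} nonzeros")

    (OUT / "truth.json").write_text(json.dumps(truth_all, indent=2))
    print(f"wrote inputs + truth.json to {OUT}")


if __name__ == "__main__":
    main()
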