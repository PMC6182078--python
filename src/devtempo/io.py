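"""Readers and writers for the pipeline's tabular formats.

One tabular dialect everywhere: tab-delimited UTF-8 with '.' decimals.
Event tables, marker series, expression matrices and ortholog maps are
TSV; single-cell counts are MatrixMarket MTX (genes x cells, 1-based)
with companion gene/barcode lists; fitted models and reports are JSON;
pipeline configuration is YAML.  All ages are exchanged as
post-conception days — postnatal ages must be converted with a
per-species gestation length before they enter these files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .epochs import DerivedEvent, MarkerSeries
from .event_model import FittedModel
from .events import COLUMNS, EventTimingTable
from .plateau import ExpressionTimecourse, OrthologMap
from .sc_codetection import CellAnnotation, CellMatrix

__all__ = [
    "read_event_table",
    "write_event_table",
    "write_derived_events",
    "read_marker_table",
    "write_marker_table",
    "read_expression",
    "read_orthologs",
    "read_cell_inputs",
    "write_cell_inputs",
    "read_model",
    "write_model",
    "postnatal_to_pc",
    "GESTATION_DAYS",
]

#: Default gestation lengths (days) for postnatal -> post-conception conversion.
GESTATION_DAYS = {
    "mouse": 19.5,
    "rat": 21.5,
    "marmoset": 144.0,
    "macaque": 165.0,
    "human": 270.0,
}

_BOOL_TOKENS = {"0": False, "1": True}


def postnatal_to_pc(day_postnatal: float, species: str,
                    gestation: Mapping[str, float] = GESTATION_DAYS) -> float:
    """Convert a postnatal age to post-conception days."""
    return float(day_postnatal) + gestation[species]


# -- event tables -----------------------------------------------------------


def read_event_table(path: str | Path) -> EventTimingTable:
    """Read the event-table TSV, reporting offending line numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    # line numbers: header is line 1
    lines = df.index + 2
    try:
        day = df["day_pc"].astype(float)
    except ValueError:
        bad = [int(l) for l, v in zip(lines, df["day_pc"]) if not _is_float(v)]
        raise ValueError(f"{path}: non-numeric day_pc on lines {bad}") from None
    bad_day = [int(l) for l, v in zip(lines, day) if not np.isfinite(v) or v <= 0]
    if bad_day:
        raise ValueError(f"{path}: non-positive day_pc on lines {bad_day}")
    for col in ("limbic", "neurogenetic"):
        unknown = [int(l) for l, v in zip(lines, df[col]) if v not in _BOOL_TOKENS]
        if unknown:
            raise ValueError(f"{path}: unknown boolean token in {col!r} on lines {unknown}")
    dup = df.duplicated(subset=["species", "event"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (species, event) rows on lines {[int(l) for l in lines[dup]]}"
        )
    out = pd.DataFrame(
        {
            "species": df["species"],
            "event": df["event"],
            "day_pc": day,
            "limbic": df["limbic"].map(_BOOL_TOKENS),
            "neurogenetic": df["neurogenetic"].map(_BOOL_TOKENS),
            "source": df["source"],
        }
    )
    return EventTimingTable(out)


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_event_table(table: EventTimingTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["limbic"] = df["limbic"].astype(int)
    df["neurogenetic"] = df["neurogenetic"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_derived_events(events: Sequence[DerivedEvent], path: str | Path) -> None:
    """Write derived epoch events in the event-table dialect."""
    table = EventTimingTable.from_records([e.to_record() for e in events])
    write_event_table(table, path)


# -- marker series ----------------------------------------------------------


def read_marker_table(path: str | Path) -> list[MarkerSeries]:
    """Read `species marker age_pc pct` TSV into one series per (species, marker)."""
    df = pd.read_csv(path, sep="\t")
    required = ["species", "marker", "age_pc", "pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    out = []
    for (species, marker), grp in df.groupby(["species", "marker"], sort=True):
        out.append(
            MarkerSeries(str(species), str(marker),
                         grp["age_pc"].to_numpy(float), grp["pct"].to_numpy(float))
        )
    return out


def write_marker_table(series_list: Iterable[MarkerSeries], path: str | Path) -> None:
    rows = [
        (s.species, s.marker, a, p)
        for s in series_list
        for a, p in zip(s.age_pc, s.pct)
    ]
    pd.DataFrame(rows, columns=["species", "marker", "age_pc", "pct"]).to_csv(
        path, sep="\t", index=False
    )


# -- expression -------------------------------------------------------------


def read_expression(
    expr_path: str | Path, meta_path: str | Path, species: str | None = None
) -> list[ExpressionTimecourse]:
    """Read a genes x samples TSV plus `sample species age_pc` metadata."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("sample", "species", "age_pc"):
        if col not in meta.columns:
            raise ValueError(f"{meta_path}: missing metadata column {col!r}")
    if species is not None:
        meta = meta[meta["species"] == species]
    meta = meta[meta["sample"].isin(expr.columns)]
    if meta.empty:
        raise ValueError("no samples shared between expression matrix and metadata")
    samples = meta["sample"].tolist()
    ages = meta["age_pc"].to_numpy(float)
    sp = meta["species"].iloc[0] if species is None else species
    return [
        ExpressionTimecourse(str(gene), str(sp), ages, expr.loc[gene, samples].to_numpy(float))
        for gene in expr.index
    ]


def write_expression(
    dataset: Sequence[ExpressionTimecourse], expr_path: str | Path, meta_path: str | Path
) -> None:
    ages = dataset[0].age_pc
    samples = [f"s{i:03d}" for i in range(len(ages))]
    mat = pd.DataFrame(
        {s: [tc.expression[i] for tc in dataset] for i, s in enumerate(samples)},
        index=[tc.gene for tc in dataset],
    )
    mat.index.name = "gene"
    mat.to_csv(expr_path, sep="\t")
    pd.DataFrame(
        {"sample": samples, "species": dataset[0].species, "age_pc": ages}
    ).to_csv(meta_path, sep="\t", index=False)


def read_orthologs(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: ortholog map must have exactly two columns")
    return OrthologMap(tuple(df.itertuples(index=False, name=None)))


# -- single-cell ------------------------------------------------------------


def read_cell_inputs(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    clusters_path: str | Path,
    excluded_clusters: Iterable[int] = (),
) -> tuple[CellMatrix, CellAnnotation]:
    """Read MTX counts (genes x cells, 1-based) with companion TSVs."""
    mat = spio.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix is {mat.shape} but gene/cell lists give {(len(genes), len(cells))}"
        )
    data = sparse.coo_matrix(mat)
    if data.nnz and not np.allclose(data.data, np.round(data.data)):
        raise ValueError("non-integer counts in matrix")
    matrix = CellMatrix(sparse.csc_matrix(data.T), cells, genes)
    cl = pd.read_csv(clusters_path, sep="\t", header=None, names=["barcode", "cluster"])
    annotation = CellAnnotation(
        clusters=dict(zip(cl["barcode"].astype(str), cl["cluster"].astype(int))),
        excluded=frozenset(int(c) for c in excluded_clusters),
    )
    annotation.retained_mask(matrix.cell_ids)  # verify every cell is annotated
    return matrix, annotation


def write_cell_inputs(
    matrix: CellMatrix,
    annotation: CellAnnotation,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    clusters_path: str | Path,
) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(matrix.counts.T))
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")
    pd.DataFrame(
        {"barcode": matrix.cell_ids,
         "cluster": [annotation.clusters[c] for c in matrix.cell_ids]}
    ).to_csv(clusters_path, sep="\t", index=False, header=False)


# -- models and config ------------------------------------------------------


def write_model(model: FittedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model(path: str | Path) -> FittedModel:
    return FittedModel.from_dict(json.loads(Path(path).read_text()))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
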