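"""End-to-end orchestration: epochs -> extended model -> predictions -> tests.

The pipeline mirrors the order of the underlying analysis: fit marker
declines and derive epoch events, append them to the base event table,
fit or extend the latent-scale model, predict the human timetable for
the derived epochs, and run the limbic interaction test.  Expression
plateaus and the single-cell co-detection test are optional stages.
Every stage can be skipped; failures carry the stage name.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import io as dio
from .epochs import EpochThresholds, average_replicates, derive_epoch_events, fit_decline
from .event_model import extend_model, fit_event_scale, predict_day
from .events import DEFAULT_RODENT_SPECIES, EventTimingTable
from .limbic import fit_limbic_anova
from .plateau import cross_species_plateau_event, detect_plateaus
from .sc_codetection import permutation_test

logger = logging.getLogger("devtempo")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the umbrella pipeline needs, typically loaded from YAML."""

    events_path: str
    markers_path: str | None = None
    decline_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    average_replicates_except: tuple[str, ...] = ("marmoset",)
    ki67_thresholds: tuple[float, ...] | None = None
    dcx_thresholds: tuple[float, ...] | None = None
    rodent_species: tuple[str, ...] = tuple(sorted(DEFAULT_RODENT_SPECIES))
    mode: str = "extrapolate"            # how epoch events join the model
    tol: float = 1e-8
    max_iter: int = 500
    predict_species: str | None = "human"
    limbic_species: str | None = None
    expression: dict[str, Any] | None = None   # expr/meta/orthologs paths + windows
    single_cell: dict[str, Any] | None = None  # mtx/genes/cells/clusters + test params
    n_perm: int = 1000
    seed: int = 0
    skip: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = dio.load_yaml(path)
        for key in ("decline_windows",):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)


def _stage(name: str, skip: Sequence[str]):
    def deco(fn):
        def wrapped(*args, **kwargs):
            if name in skip:
                logger.info("stage %s skipped", name)
                return None
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return a JSON-serialisable report."""
    report: dict[str, Any] = {"seed": config.seed, "stages": []}
    skip = config.skip

    table = dio.read_event_table(config.events_path)
    report["n_events_input"] = len(table.events)

    # -- epochs ------------------------------------------------------------
    epoch_events = None
    if config.markers_path and "epochs" not in skip:
        @_stage("epochs", skip)
        def do_epochs():
            thresholds = EpochThresholds(
                ki67=config.ki67_thresholds or EpochThresholds().ki67,
                dcx=config.dcx_thresholds or EpochThresholds().dcx,
            )
            fits = {}
            for series in dio.read_marker_table(config.markers_path):
                series = average_replicates(
                    series, enabled=series.species not in config.average_replicates_except
                )
                window = (config.decline_windows.get(f"{series.species}/{series.marker}")
                          or config.decline_windows.get(series.species))
                fits[(series.species, series.marker)] = fit_decline(series, window)
            return derive_epoch_events(
                fits, thresholds, rodent_species=config.rodent_species
            ), fits

        out = do_epochs()
        if out is not None:
            epoch_events, fits = out
            report["stages"].append("epochs")
            report["epochs"] = {
                "n_events": len(epoch_events),
                "declines": {
                    f"{sp}/{mk}": {"alpha": f.alpha, "beta": f.beta, "r2": f.r2}
                    for (sp, mk), f in fits.items()
                },
            }

    # -- expression plateaus ----------------------------------------------
    if config.expression and "plateaus" not in skip:
        @_stage("plateaus", skip)
        def do_plateaus():
            e = config.expression
            ds1 = dio.read_expression(e["expr1"], e["meta1"])
            ds2 = dio.read_expression(e["expr2"], e["meta2"])
            orth = dio.read_orthologs(e["orthologs"])
            f1 = detect_plateaus(ds1, tuple(e["window1"]), e.get("alpha", 0.05))
            f2 = detect_plateaus(ds2, tuple(e["window2"]), e.get("alpha", 0.05))
            return f1, f2, cross_species_plateau_event(f1, f2, orth)

        out = do_plateaus()
        if out is not None:
            f1, f2, (ev1, ev2) = out
            report["stages"].append("plateaus")
            report["plateaus"] = {
                "n_retained_species1": len(f1),
                "n_retained_species2": len(f2),
                "event": {ev1.species: ev1.day_pc, ev2.species: ev2.day_pc},
            }

    # -- model fit / extension --------------------------------------------
    @_stage("model", skip)
    def do_model():
        base = fit_event_scale(table, tol=config.tol, max_iter=config.max_iter)
        if epoch_events:
            new_table = EventTimingTable.from_records(
                [e.to_record() for e in epoch_events]
            )
            return extend_model(base, table, new_table, mode=config.mode,
                                tol=config.tol, max_iter=config.max_iter)
        return base

    model = do_model()
    if model is not None:
        report["stages"].append("model")
        report["model"] = model.to_dict()

    # -- human predictions --------------------------------------------------
    if model is not None and config.predict_species in model.regressions and "predict" not in skip:
        reg = model.regressions[config.predict_species]
        epoch_names = sorted({e.event for e in epoch_events}) if epoch_events else []
        preds = {}
        for name in epoch_names:
            score = model.scale.scores.get(name)
            if score is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    preds[name] = predict_day(reg, score)
        report["stages"].append("predict")
        report["predictions"] = {
            "species": config.predict_species,
            "day_at_scale_end": predict_day(reg, 1.0),
            "epochs": preds,
        }

    # -- limbic test ---------------------------------------------------------
    if model is not None and config.limbic_species and "limbic" not in skip:
        @_stage("limbic", skip)
        def do_limbic():
            return fit_limbic_anova(table, model.scale, config.limbic_species)

        res = do_limbic()
        if res is not None:
            report["stages"].append("limbic")
            report["limbic"] = res.to_dict()

    # -- single-cell co-detection -------------------------------------------
    if config.single_cell and "sc" not in skip:
        @_stage("sc", skip)
        def do_sc():
            s = config.single_cell
            matrix, annotation = dio.read_cell_inputs(
                s["mtx"], s["genes"], s["cells"], s["clusters"],
                excluded_clusters=s.get("excluded_clusters", ()),
            )
            results = {}
            for marker in s.get("markers", ("DCX", "SOX2", "DPYSL3")):
                results[marker] = permutation_test(
                    matrix, marker, s.get("anchor", "PROX1"), annotation,
                    n_perm=config.n_perm, seed=config.seed,
                )
            return results

        res = do_sc()
        if res is not None:
            report["stages"].append("sc")
            report["sc"] = {m: r.to_dict() for m, r in res.items()}

    return report
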