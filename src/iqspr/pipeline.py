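"""End-to-end orchestration: filter → split → select → fit → diagnose →
invert → screen → rank, writing every intermediate artifact.

The stages mirror the iterative discovery loop the package implements: build
a GA-PLS property model, define its applicability domain, invert it toward
reference property values, and rank candidates by descriptor-space distance
to the solution (optionally fused with docking ranks).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import data_model, diagnostics, ga_selection, inversion, preprocess, screening
from .data_model import ReferenceProperties
from .pls_core import NipalsPLS, metrics
from .synthetic import SyntheticSpec, generate

log = logging.getLogger("iqspr")

DEFAULT_CONFIG = {
    "rsd_threshold_pct": 5.0,
    "corr_threshold": 0.8,
    "n_train": 33,
    "alpha": 0.05,
    "seed": 0,
    "ga": {},
    "inverter": {},
    "reference": None,       # {"logkw": float, "logKi": float} or None
    "descriptors": None,     # CSV path, or None -> synthetic
    "properties": None,
    "kinds": None,
    "library": None,         # candidate library CSV (selected descriptors)
    "docking": None,         # docking score CSV
    "synthetic": {},         # SyntheticSpec overrides when no CSVs given
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute every stage; returns the artifact directory.

    Any stage failure aborts with the stage name in the exception; artifacts
    written before the failure are retained.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    chash = config_hash(cfg)
    meta = {"config_hash": chash, "seed": cfg["seed"], "outputs": {},
            "python": sys.version.split()[0]}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        meta["outputs"][name] = {"config_hash": chash, "seed": cfg["seed"]}
        log.info("wrote %s", path)

    stage = "load"
    try:
        if cfg["descriptors"] is not None:
            desc = data_model.read_descriptor_table(cfg["descriptors"], cfg["kinds"])
            props = data_model.read_property_table(cfg["properties"])
        else:
            spec = SyntheticSpec(**{**cfg["synthetic"], "seed": cfg["seed"]})
            desc, props, _ = generate(spec)
            emit("synthetic_descriptors.csv",
                 lambda p: data_model.write_descriptor_table(desc, p))
            emit("synthetic_properties.csv",
                 lambda p: data_model.write_property_table(props, p))
        desc, props = data_model.align(desc, props)

        stage = "filter"
        desc_f, report = preprocess.apply_filters(
            desc, props, cfg["rsd_threshold_pct"], cfg["corr_threshold"])
        fates = ([("removed_by_rsd", n) for n in report.removed_by_rsd]
                 + [("removed_by_correlation", n) for n in report.removed_by_correlation]
                 + [("removed_by_zero", n) for n in report.removed_by_zero]
                 + [("surviving", n) for n in report.surviving])
        emit("filter_report.csv", lambda p: pd.DataFrame(
            fates, columns=["fate", "descriptor"]).to_csv(p, index=False))
        log.info("filters: %d -> %d descriptors", desc.n_descriptors,
                 desc_f.n_descriptors)

        stage = "split"
        split = preprocess.kennard_stone_split(desc_f, cfg["n_train"])
        emit("split.csv", lambda p: pd.DataFrame(
            [("train", c) for c in split.train_ids]
            + [("test", c) for c in split.test_ids],
            columns=["set", "compound_id"]).to_csv(p, index=False))
        train_desc = desc_f.reorder(split.train_ids)
        test_desc = desc_f.reorder(split.test_ids)
        train_props = props.select(split.train_ids)
        test_props = props.select(split.test_ids)

        stage = "select"
        ga_cfg = ga_selection.GAConfig(**{"seed": cfg["seed"], **cfg["ga"]})
        sel = ga_selection.run_ga(train_desc.values, train_props.Y,
                                  test_desc.values, test_props.Y,
                                  desc_f.descriptor_names, ga_cfg)
        emit("selection.json", lambda p: Path(p).write_text(json.dumps({
            "selected_names": sel.selected_names, "eta": sel.eta,
            "eta1": sel.eta1, "eta2": sel.eta2, "A_chosen": sel.A_chosen,
            "rmsee": sel.rmsee, "rmsep": sel.rmsep}, indent=2)))
        emit("selection_history.csv", lambda p: pd.DataFrame(
            {"generation": range(len(sel.history)),
             "best_eta": sel.history}).to_csv(p, index=False))

        stage = "fit"
        train_sel = train_desc.subset(sel.selected_names)
        test_sel = test_desc.subset(sel.selected_names)
        model = NipalsPLS(n_components=sel.A_chosen).fit(train_sel.values,
                                                         train_props.Y)
        emit("model.json", lambda p: Path(p).write_text(model.to_json()))
        m = metrics(model, train_sel.values, train_props.Y,
                    test_sel.values, test_props.Y)
        emit("metrics.json", lambda p: Path(p).write_text(
            json.dumps(dataclasses.asdict(m), indent=2)))

        stage = "diagnose"
        all_sel = desc_f.subset(sel.selected_names).reorder(
            split.train_ids + split.test_ids)
        all_props = props.select(split.train_ids + split.test_ids)
        rep = diagnostics.diagnostics_report(
            model, train_sel.values, train_props.Y, all_sel.values,
            all_props.Y, ids=all_sel.compound_ids, alpha=cfg["alpha"])
        emit("diagnostics.csv", lambda p: rep.table.to_csv(p))

        stage = "invert"
        if cfg["reference"] is not None:
            ref = ReferenceProperties(cfg["reference"]["logkw"],
                                      cfg["reference"]["logKi"])
        else:  # default: first test compound's observed properties
            ref = ReferenceProperties(float(test_props.logkw[0]),
                                      float(test_props.logKi[0]))
            log.info("no reference given; using test compound %s",
                     test_props.compound_ids[0])
        inv_cfg = inversion.InverterConfig(**{"seed": cfg["seed"],
                                              **cfg["inverter"]})
        problem = inversion.build_problem(model, ref, train_sel,
                                          alpha=cfg["alpha"], config=inv_cfg)
        sol = inversion.invert(problem)
        emit("inversion.csv", lambda p: pd.DataFrame(
            {"descriptor": sel.selected_names, "raw": sol.x_star,
             "scaled": sol.x_star_scaled}).to_csv(p, index=False))
        emit("inversion.json", lambda p: Path(p).write_text(json.dumps({
            "objective": sol.objective, "t2": sol.t2_value,
            "recon_residual": sol.recon_residual, "feasible": sol.feasible,
            "predicted_logkw": sol.predicted[0],
            "predicted_logKi": sol.predicted[1],
            "c1": problem.c1, "c2": problem.c2}, indent=2)))

        stage = "screen"
        if cfg["library"] is not None:
            library = data_model.read_descriptor_table(cfg["library"])
            library = library.subset(sel.selected_names)
        else:
            library = test_sel  # screen the held-out compounds
        h_star = diagnostics.leverage_threshold(len(sel.selected_names),
                                                len(split.train_ids))

        stage = "rank"
        docking = None
        if cfg["docking"] is not None:
            docking = pd.read_csv(cfg["docking"], index_col=0)
            docking.index = docking.index.astype(str)
        else:
            log.warning("no docking CSV given; ranking stops at iqspr_rank")
        table = screening.screen(sol.x_star, library, train_sel, h_star,
                                 docking=docking)
        emit("screening.csv", lambda p: table.to_csv(p))

        emit("run_metadata.json", lambda p: Path(p).write_text(
            json.dumps(meta, indent=2)))
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
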