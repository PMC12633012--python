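"""End-to-end orchestration from a single YAML config.

Stages run in dependency order: simulate -> qc -> signatures -> classify ->
composition -> niche -> spatial stats -> maturation.  A single global seed
is split deterministically per stage; the run report echoes the config and
per-stage summaries and is byte-identical across reruns of the same
config+seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, niche, qc, signatures, spatial_stats, synthetic

log = logging.getLogger("alveoniche")

STAGE_SEED_OFFSETS = {
    "simulate": 1,
    "qc": 2,
    "signatures": 3,
    "classify": 4,
    "composition": 5,
    "niche": 6,
    "spatial_stats": 7,
    "maturation": 8,
}

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "outdir": "alveoniche_run",
    "simulate": {
        "cohort": {},  # CohortConfig overrides
        "spatial": {},  # SpatialConfig overrides
        "maturation": {"stages": ["fetal", "birth", "6mo", "2yr"], "program_size": 100,
                       "n_arrest_specimens": 1},
    },
    "qc": {"min_features": 500, "max_features": 7500, "min_molecules": 1000,
           "max_frac_mito": 0.05, "max_frac_ribo": 0.075, "spatial_min_counts": 25},
    "normalize": {"scale": 10000.0},
    "signatures": {"top_n_state": 50, "min_pct": 0.25, "min_logfc": 0.25,
                   "n_bins": 24, "n_controls": 100},
    "classify": {"enrich_threshold": 0.65, "min_at2_cells": 50},
    "niche": {"neighbors_k": 20, "niches_k": 4, "n_init": 10, "standardize": True},
    "spatial_stats": {
        "pairs": [["AT2_FMO5", "AF_c1"], ["AT2_FMO5", "AF_c2"], ["AT2_FMO5", "AF_c3"],
                  ["AT2_CFTR", "AF_c1"], ["AT2_CFTR", "AF_c2"], ["AT2_CFTR", "AF_c3"]],
        "joincount_labels": ["AT2_FMO5", "AT2_CFTR"],
        "radii": [10, 15, 20, 25, 30],
        "null": "analytic",
    },
    "maturation": {"top_n": 100},
    "stages": ["simulate", "qc", "signatures", "classify", "composition",
               "niche", "spatial_stats", "maturation"],
}


def _merge(base: Dict, override: Optional[Dict]) -> Dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str] = None, overrides: Optional[Dict] = None) -> Dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def _stage_seed(cfg: Dict, stage: str) -> int:
    ss = np.random.SeedSequence([int(cfg["seed"]), STAGE_SEED_OFFSETS[stage]])
    return int(ss.generate_state(1)[0])


def run_pipeline(config: Dict, outdir: Optional[str] = None) -> Dict:
    """Execute the configured stages; returns the run report dict."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg)
    report: Dict = {"version": __version__, "config": cfg, "config_hash": chash,
                    "stages": {}, "warnings": []}
    stages = cfg["stages"]

    ctx: Dict = {}
    try:
        if "simulate" in stages:
            _stage_simulate(cfg, out, chash, ctx, report)
        if "qc" in stages:
            _stage_qc(cfg, out, chash, ctx, report)
        if "signatures" in stages:
            _stage_signatures(cfg, out, chash, ctx, report)
        if "classify" in stages:
            _stage_classify(cfg, out, chash, ctx, report)
        if "composition" in stages:
            _stage_composition(cfg, out, chash, ctx, report)
        if "niche" in stages:
            _stage_niche(cfg, out, chash, ctx, report)
        if "spatial_stats" in stages:
            _stage_spatial_stats(cfg, out, chash, ctx, report)
        if "maturation" in stages:
            _stage_maturation(cfg, out, chash, ctx, report)
    except Exception as exc:  # partial report on failure
        report["error"] = f"{type(exc).__name__}: {exc}"
        _write_report(report, out)
        raise
    _write_report(report, out)
    return report


def _write_report(report: Dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    lines = [f"alveoniche {report['version']} run (config {report['config_hash']})"]
    for name, summary in report["stages"].items():
        lines.append(f"[{name}]")
        for k, v in summary.items():
            lines.append(f"  {k}: {v}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def _stage_simulate(cfg, out, chash, ctx, report):
    seed = _stage_seed(cfg, "simulate")
    ccfg = synthetic.CohortConfig(**{"seed": seed, **cfg["simulate"]["cohort"]})
    cm, gt = synthetic.generate_expression_cohort(ccfg)
    io.write_counts(cm, out / "cohort", "simulate", chash)
    io._write_csv(gt.cell_truth, out / "cohort" / "cell_truth.csv", "simulate", chash, index=False)
    io._write_csv(gt.gene_truth, out / "cohort" / "gene_truth.csv", "simulate", chash, index=False)

    scfg_over = dict(cfg["simulate"]["spatial"])
    scfg = synthetic.SpatialConfig(**{"seed": seed, **scfg_over})
    sections, sgt = synthetic.generate_spatial_sections(scfg, ccfg)
    io.write_spatial(sections, out / "spatial", "simulate", chash)
    io._write_csv(sgt.region_truth, out / "spatial" / "region_truth.csv", "simulate", chash, index=False)

    mcfg = cfg["simulate"]["maturation"]
    series, mgt = synthetic.generate_maturation_series(
        ccfg,
        stages=mcfg["stages"],
        program_size=mcfg["program_size"],
        n_arrest_specimens=mcfg["n_arrest_specimens"],
    )
    io.write_counts(series, out / "maturation_series", "simulate", chash)
    io._write_csv(mgt.cell_truth, out / "maturation_series" / "cell_truth.csv",
                  "simulate", chash, index=False)
    ctx.update(cohort=cm, cohort_truth=gt, sections=sections, spatial_truth=sgt,
               series=series, series_truth=mgt, cohort_cfg=ccfg)
    report["stages"]["simulate"] = {
        "cohort_cells": cm.n_cells, "cohort_genes": cm.n_genes,
        "sections": len(sections),
        "spatial_cells": sum(s.n_cells for s in sections),
        "series_cells": series.n_cells,
    }


def _stage_qc(cfg, out, chash, ctx, report):
    t = qc.QCThresholds(**cfg["qc"])
    before = ctx["cohort"].n_cells
    filtered = qc.apply_qc_filters(ctx["cohort"], t)
    norm = qc.normalize_counts(filtered, scale=cfg["normalize"]["scale"])
    ctx.update(filtered=filtered, norm=norm, thresholds=t)
    io.write_counts(filtered, out / "cohort_qc", "qc", chash)
    report["stages"]["qc"] = {"cells_in": before, "cells_out": filtered.n_cells}


def _stage_signatures(cfg, out, chash, ctx, report):
    seed = _stage_seed(cfg, "signatures")
    norm = ctx["norm"]
    truth = ctx["cohort_truth"].cell_truth.set_index("cell_id").loc[list(norm.cells)]
    scfg = cfg["signatures"]
    at2 = truth["cell_type"] == synthetic.AT2_TYPE
    labels = np.where(at2, truth["at2_state"], "other")
    mr = signatures.rank_markers(
        norm, labels, qc.FMO5, qc.CFTR,
        min_pct=scfg["min_pct"], min_logfc=scfg["min_logfc"],
    )
    fmo5_sig = signatures.build_signature(mr, scfg["top_n_state"], "up", name="FMO5_state")
    cftr_sig = signatures.build_signature(mr, scfg["top_n_state"], "down", name="CFTR_state")
    io.write_signatures_csv([fmo5_sig, cftr_sig], out / "state_signatures.csv",
                            "signatures", chash)
    io.write_signatures_gmt([fmo5_sig, cftr_sig], out / "state_signatures.gmt")
    at2_norm = norm.subset_cells(at2.to_numpy())
    scores = signatures.score_modules(
        at2_norm, [fmo5_sig, cftr_sig],
        n_bins=scfg["n_bins"], n_controls=scfg["n_controls"], seed=seed,
    ).scores
    states = signatures.assign_at2_state(None, scores=scores)
    io._write_csv(scores.assign(at2_state=states), out / "at2_state_scores.csv",
                  "signatures", chash, index=True)
    ctx.update(fmo5_sig=fmo5_sig, cftr_sig=cftr_sig, at2_states=states, markers=mr)
    report["stages"]["signatures"] = {
        "markers_tested": len(mr),
        "fmo5_sig": len(fmo5_sig), "cftr_sig": len(cftr_sig),
        "at2_assigned": int((states != qc.UNASSIGNED).sum()),
    }


def _stage_classify(cfg, out, chash, ctx, report):
    norm = ctx["norm"]
    truth = ctx["cohort_truth"].cell_truth.set_index("cell_id").loc[list(norm.cells)]
    at2 = truth[truth["cell_type"] == synthetic.AT2_TYPE].copy()
    at2["at2_state"] = ctx["at2_states"].reindex(at2.index)
    groups = qc.classify_specimens_by_at2_state(
        at2.reset_index(),
        enrich_threshold=cfg["classify"]["enrich_threshold"],
        min_at2_cells=cfg["classify"]["min_at2_cells"],
    )
    df = pd.DataFrame(
        {"specimen": list(groups.classes), "class": list(groups.classes.values())}
    )
    df["fmo5_fraction"] = df["specimen"].map(groups.fmo5_fraction)
    io._write_csv(df, out / "specimen_classes.csv", "classify", chash, index=False)
    ctx["groups"] = groups
    report["stages"]["classify"] = dict(
        pd.Series(list(groups.classes.values())).value_counts()
    )


def _stage_composition(cfg, out, chash, ctx, report):
    norm = ctx["norm"]
    truth = ctx["cohort_truth"].cell_truth.set_index("cell_id").loc[list(norm.cells)]
    wc = qc.weighted_composition(truth.reset_index(), ctx["groups"])
    io._write_csv(wc.class_proportions, out / "composition_by_class.csv",
                  "composition", chash, index=True)
    io._write_csv(wc.class_shares, out / "composition_class_shares.csv",
                  "composition", chash, index=True)
    io._write_csv(wc.overall_proportions.rename("proportion").to_frame(),
                  out / "composition_overall.csv", "composition", chash, index=True)
    ctx["composition"] = wc
    report["stages"]["composition"] = {
        "n_classes": wc.n_classes,
        "n_types": len(wc.overall_proportions),
    }


def _stage_niche(cfg, out, chash, ctx, report):
    seed = _stage_seed(cfg, "niche")
    ncfg = cfg["niche"]
    models = []
    assign_frames = []
    for s in ctx["sections"]:
        prof = niche.neighborhood_profiles(s, k=ncfg["neighbors_k"])
        model = niche.fit_niches(
            prof, K=ncfg["niches_k"], seed=seed, n_init=ncfg["n_init"],
            standardize=ncfg["standardize"],
        )
        models.append(model)
        assign_frames.append(pd.DataFrame(
            {"cell_id": model.cell_ids, "section_id": s.section_id, "niche": model.niche}
        ))
    corr = niche.align_niches_across_sections(models)
    io._write_csv(pd.concat(assign_frames, ignore_index=True),
                  out / "niche_assignments.csv", "niche", chash, index=False)
    flat = corr.correlation.copy()
    flat.index = [f"{s}:{n}" for s, n in flat.index]
    flat.columns = [f"{s}:{n}" for s, n in flat.columns]
    io._write_csv(flat, out / "niche_correlation.csv", "niche", chash, index=True)
    io._write_csv(corr.groups.reset_index(), out / "niche_groups.csv", "niche",
                  chash, index=False)
    ctx.update(niche_models=models, niche_corr=corr)
    report["stages"]["niche"] = {
        "sections": len(models),
        "groups": int(corr.groups.nunique()),
    }


def _stage_spatial_stats(cfg, out, chash, ctx, report):
    seed = _stage_seed(cfg, "spatial_stats")
    scfg = cfg["spatial_stats"]
    pairs = [tuple(p) for p in scfg["pairs"]]
    table = spatial_stats.pair_distance_table(ctx["sections"], pairs)
    io._write_csv(table, out / "pair_distances.csv", "spatial_stats", chash, index=False)
    summary = {}
    if len(table) and table["pair"].nunique() >= 2:
        res = spatial_stats.distance_anova_tukey(table)
        io._write_csv(res.tukey, out / "distance_tukey.csv", "spatial_stats",
                      chash, index=False)
        summary["anova_F"] = round(res.f_statistic, 4)
        summary["anova_p"] = res.p_value
    jc_frames = []
    for label in scfg["joincount_labels"]:
        results = spatial_stats.joincount_profile(
            ctx["sections"], label, radii=scfg["radii"], null=scfg["null"], seed=seed,
        )
        jc_frames.append(spatial_stats.joincount_table(results))
    jc = pd.concat(jc_frames, ignore_index=True)
    io._write_csv(jc, out / "joincount.csv", "spatial_stats", chash, index=False)
    summary["joincount_rows"] = len(jc)
    ctx["joincount"] = jc
    report["stages"]["spatial_stats"] = summary


def _stage_maturation(cfg, out, chash, ctx, report):
    seed = _stage_seed(cfg, "maturation")
    series = ctx["series"]
    truth = ctx["series_truth"].cell_truth.set_index("cell_id").loc[list(series.cells)]
    norm = qc.normalize_counts(series, scale=cfg["normalize"]["scale"])
    normal = ~truth["arrested"].to_numpy()
    ref = norm.subset_cells(normal)
    sets = signatures.build_maturation_sets(
        ref,
        truth.loc[normal, "stage"].to_numpy(),
        truth.loc[normal, "cell_type"].to_numpy(),
        fetal_stage=cfg["simulate"]["maturation"]["stages"][0],
        top_n=cfg["maturation"]["top_n"],
    )
    scores = signatures.score_maturation(
        norm, truth["cell_type"].to_numpy(), sets, seed=seed,
    )
    scores["stage"] = truth["stage"].to_numpy()
    scores["specimen"] = truth["specimen"].to_numpy()
    scores["arrested"] = truth["arrested"].to_numpy()
    io._write_csv(scores, out / "maturation_scores.csv", "maturation", chash, index=True)
    per_stage = scores.groupby("stage", sort=False)["on_score"].mean()
    ctx["maturation_scores"] = scores
    report["stages"]["maturation"] = {
        "types_with_sets": len(sets.sets),
        "mean_on_by_stage": {k: round(float(v), 4) for k, v in per_stage.items()},
    }
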