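"""End-to-end orchestration: simulate → (render/segment) → track →
kinetics → annotate → migration → stats report, plus the qPCR and
clinical branches.

A run is configured by a plain dict (YAML on disk), validated against a
small schema, and writes its tables into a run directory with provenance
headers (version, seed, config hash) and a ``summary.json``.  Rerunning
an identical config reproduces identical deterministic outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as _clinical
from . import expression as _expression
from . import imaging as _imaging
from . import kinetics as _kinetics
from . import migration as _migration
from . import synthetic as _synthetic
from .io import config_hash, read_table, write_table
from .stats import kruskal_wallis, mann_whitney_u

log = logging.getLogger("timing")

__all__ = ["demo_config", "run_pipeline", "report"]

_KNOWN_KEYS = {
    "seed",
    "stages",
    "chip",
    "behavior_weights",
    "imaging_mode",
    "analysis",
    "migration",
    "qpcr",
    "clinical",
}


def demo_config() -> dict:
    """A small configuration that exercises every stage in minutes."""
    return {
        "seed": 11,
        "stages": ["chip", "qpcr", "clinical"],
        "chip": {"wells": 120, "duration_h": 6.0, "frame_interval_min": 5.0},
        "behavior_weights": {
            "migratory_killer": 0.3,
            "serial_killer": 0.2,
            "monofunctional_secretor": 0.2,
            "nonmigratory_nonkiller": 0.3,
        },
        "imaging_mode": "tracks",  # "tracks" or "images"
        "analysis": {"slack_um": 2.0, "min_duration_min": 5.0, "secretion_k": 3.0},
        "migration": {"angle_tol_deg": 45.0},
        "qpcr": {"n_migratory": 48, "n_nonmigratory": 44, "effect_size": 1.0},
        "clinical": {"n": 40, "cutoff": 80.0, "hazard_ratio": 4.0},
    }


def _validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("config must set a seed")
    if config.get("imaging_mode", "tracks") not in ("tracks", "images"):
        raise ValueError("imaging_mode must be 'tracks' or 'images'")


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path."""
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = config_hash(config)
    meta = {"seed": seed, "config_hash": chash}

    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": seed, "config_hash": chash}
    try:
        stages = config.get("stages", ["chip"])
        if "chip" in stages:
            summary["chip"] = _run_chip_branch(config, out, meta, seed)
        if "qpcr" in stages:
            summary["qpcr"] = _run_qpcr_branch(config, out, meta, seed)
        if "clinical" in stages:
            summary["clinical"] = _run_clinical_branch(config, out, meta, seed)
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return out

def _run_chip_branch(config, out, meta, seed) -> dict:
    log.info("stage chip: simulating")
    chip_cfg = _synthetic.AssayConfig(rng_seed=seed, **config.get("chip", {}))
    profiles = _synthetic.default_behaviors()
    weights_cfg = config.get(
        "behavior_weights", {k: 1 / len(profiles) for k in profiles}
    )
    behaviors = [profiles[k] for k in weights_cfg]
    weights = list(weights_cfg.values())
    chip, truth = _synthetic.simulate_chip(chip_cfg, behaviors, weights)
    write_table(chip.tracks, out / "tracks.csv", meta)
    write_table(chip.bead_endpoint, out / "bead_endpoint.csv", meta)
    write_table(truth.labels, out / "ground_truth_labels.csv", meta)

    tracks = chip.tracks
    if config.get("imaging_mode", "tracks") == "images":
        log.info("stage imaging: render + segment + link")
        from .render import render_frames

        stack, sidecar = render_frames(chip, seed=seed)
        detections = _imaging.segment_chip(stack, sidecar)
        tracks = _imaging.link_tracks(detections)
        write_table(tracks, out / "tracks_resegmented.csv", meta)

    log.info("stage kinetics/annotation")
    analysis = _kinetics.analyze_chip(
        tracks, chip.bead_endpoint, **config.get("analysis", {})
    )
    write_table(analysis.conjugations, out / "conjugations.csv", meta)
    write_table(analysis.kinetics, out / "kinetics.csv", meta)
    write_table(analysis.annotations, out / "annotations.csv", meta)

    log.info("stage migration")
    mig = _migration.migration_table(
        tracks,
        analysis.conjugations,
        analysis.selected_wells,
        **config.get("migration", {}),
    )
    write_table(mig, out / "migration.csv", meta)
    return {
        "wells_selected": len(analysis.selected_wells),
        "baseline_effectors": int(len(analysis.annotations)),
        "kills": int(analysis.kinetics["killed"].sum()) if len(analysis.kinetics) else 0,
    }


def _run_qpcr_branch(config, out, meta, seed) -> dict:
    log.info("stage qpcr")
    qcfg = dict(config.get("qpcr", {}))
    matrix, truth = _synthetic.simulate_qpcr_cohort(seed=seed + 1, **qcfg)
    filtered, qc_report = _expression.qc_filter(matrix)
    de = _expression.differential_expression(filtered)
    write_table(de.reset_index(), out / "differential_expression.csv", meta)
    corr = _expression.migration_correlogram(
        filtered, genes=list(de.index[de["significant"]])
    )
    write_table(corr.reset_index(), out / "correlogram.csv", meta)
    return {
        "n_significant": int(de["significant"].sum()),
        "significant_genes": sorted(de.index[de["significant"]]),
        "planted_genes": truth["effect_genes"],
        "qc_removed_cells": len(qc_report["removed_cells"]),
    }


def _run_clinical_branch(config, out, meta, seed) -> dict:
    log.info("stage clinical")
    ccfg = dict(config.get("clinical", {}))
    cutoff = ccfg.pop("cutoff", 80.0)
    cohort = _synthetic.simulate_clinical_cohort(seed=seed + 2, cutoff=cutoff, **ccfg)
    write_table(cohort, out / "cohort.csv", meta)
    strat = _clinical.stratified_pfs(cohort, cutoff=cutoff)
    write_table(strat.summary(), out / "pfs_summary.csv", meta)
    roc = _clinical.roc_cutoff(
        cohort["h_score"], cohort["response"] == "CR", mode="youden"
    )
    return {
        "cutoff": cutoff,
        "median_pfs_high": strat.median_high,
        "median_pfs_low": strat.median_low,
        "logrank_p": strat.logrank_p,
        "roc_youden_cutoff": roc.cutoff,
    }


def report(run_dir, make_plots: bool = False) -> dict:
    """Summarize group contrasts from a finished chip run.

    Per function class: median and quartiles of cumulative contact time
    and out-of-contact migration, pairwise Mann-Whitney p-values and a
    Kruskal-Wallis omnibus p.  Optionally writes violin plots.
    """
    run_dir = Path(run_dir)
    ann_path = run_dir / "annotations.csv"
    mig_path = run_dir / "migration.csv"
    kin_path = run_dir / "kinetics.csv"
    if not ann_path.exists() or not mig_path.exists():
        raise FileNotFoundError(
            f"run directory {run_dir} lacks annotation/migration outputs"
        )
    ann = read_table(ann_path)
    mig = read_table(mig_path)
    kin = read_table(kin_path)

    merged = ann.merge(mig, on=["well_id", "effector_id"], how="left")
    contact = (
        kin.groupby("well_id")["t_contact"].sum().rename("cum_contact_min").reset_index()
    )
    merged = merged.merge(contact, on="well_id", how="left")

    out: dict = {"classes": {}, "contrasts": {}}
    by_class = {
        fc: grp for fc, grp in merged.groupby("function_class") if len(grp) > 0
    }
    for fc, grp in by_class.items():
        out["classes"][fc] = {
            "n": int(len(grp)),
            "median_cum_contact_min": float(grp["cum_contact_min"].median()),
            "contact_quartiles": [
                float(q) for q in grp["cum_contact_min"].quantile([0.25, 0.75])
            ],
            "median_out_rate": float(grp["out_of_contact_rate"].median()),
        }
    classes = sorted(by_class)
    if len(classes) < 2:
        out["note"] = "fewer than 2 function classes present; contrasts skipped"
    else:
        for metric in ("cum_contact_min", "out_of_contact_rate"):
            groups = [
                by_class[c][metric].dropna().to_numpy() for c in classes
            ]
            groups = [g for g in groups if g.size > 0]
            if len(groups) >= 2:
                out["contrasts"][f"kruskal_{metric}"] = kruskal_wallis(
                    groups
                ).p_two_sided
            pw = {}
            for i, a in enumerate(classes):
                for b in classes[i + 1 :]:
                    ga = by_class[a][metric].dropna()
                    gb = by_class[b][metric].dropna()
                    if len(ga) and len(gb):
                        pw[f"{a}|{b}"] = mann_whitney_u(ga, gb).p_two_sided
            out["contrasts"][f"pairwise_{metric}"] = pw
    if make_plots:
        _violin_plots(merged, classes, run_dir)
        out["plots"] = ["report_contact.png", "report_migration.png"]
    with open(run_dir / "report.json", "w") as fh:
        json.dump(out, fh, indent=1, default=float)
    return out


def _violin_plots(merged: pd.DataFrame, classes, run_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, fname in (
        ("cum_contact_min", "report_contact.png"),
        ("out_of_contact_rate", "report_migration.png"),
    ):
        data = [
            merged.loc[merged["function_class"] == c, metric].dropna().to_numpy()
            for c in classes
        ]
        keep = [(c, d) for c, d in zip(classes, data) if d.size > 0]
        if not keep:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.violinplot([d for _, d in keep], showmedians=True)
        ax.set_xticks(range(1, len(keep) + 1))
        ax.set_xticklabels([c for c, _ in keep], rotation=20, fontsize=8)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(run_dir / fname, dpi=120)
        plt.close(fig)
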