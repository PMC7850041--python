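"""End-to-end driver: simulate a two-group study and run every stage.

All randomness flows from the single root seed in :class:`RunConfig`,
split per stage with :class:`numpy.random.SeedSequence`; every output
is stamped with the config hash and the root seed so a rerun with the
same config is bit-identical (timestamps aside).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, classify, cohort, connectivity, spectral
from .io import RunConfig, write_table
from .simulate import (
    COHORT_DESIGN_COLUMNS,
    EffectTruth,
    SimConfig,
    generate_cohort_table,
    generate_subject_dataset,
)

__all__ = ["run_pipeline", "write_report"]


def _truth_from_config(cfg: RunConfig) -> EffectTruth:
    sync_pairs = ((0, 1),) if cfg.n_channels >= 2 else ()
    return EffectTruth(
        temporal_clustering_strength=cfg.temporal_clustering_strength,
        semantic_clustering_strength=cfg.semantic_clustering_strength,
        theta_power_delta=cfg.theta_power_delta,
        hfa_power_delta=cfg.hfa_power_delta,
        sync_pairs=sync_pairs,
        sync_plv_delta=cfg.sync_plv_delta,
    )


def _simulate_groups(cfg: RunConfig, seeds) -> tuple[list, pd.Series]:
    sim = SimConfig(
        n_subjects_per_group=cfg.n_subjects_per_group,
        n_sessions=cfg.n_sessions,
        n_lists=cfg.n_lists,
        n_channels=cfg.n_channels,
        task_variant=cfg.task_variant,
        fs=cfg.fs,
    )
    truth = _truth_from_config(cfg)
    datasets, labels = [], {}
    i = 0
    for group in ("case", "control"):
        for _ in range(cfg.n_subjects_per_group):
            subj = f"S{i:03d}"
            datasets.append(
                generate_subject_dataset(sim, truth, int(seeds[i]), subject=subj)
            )
            labels[subj] = group
            i += 1
    return datasets, pd.Series(labels, name="group")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; write artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "rng_seed": cfg.rng_seed}
    ss = np.random.SeedSequence(cfg.rng_seed)
    subject_seeds = ss.generate_state(2 * cfg.n_subjects_per_group)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("connectivity", "classify", "cohort"),
            np.random.SeedSequence((cfg.rng_seed, 1)).generate_state(3),
        )
    }
    datasets, groups = _simulate_groups(cfg, subject_seeds)
    all_events = pd.concat([d.events for d in datasets], ignore_index=True)
    bundle: dict = {"stamp": stamp}

    if "behavior" in cfg.stages:
        curve = behavior.serial_position_curve(all_events)
        temporal = behavior.temporal_clustering_score(all_events)
        out = {
            **stamp,
            "serial_position_curve": {
                str(s): curve.loc[s].tolist() for s in curve.index
            },
            "temporal_score": temporal.dropna().to_dict(),
            "temporal_group_test": behavior.clustering_group_comparison(
                temporal, groups
            ),
            "recall_lr_test": behavior.recall_group_lr_test(all_events, groups),
        }
        if cfg.task_variant == "categorized":
            arc = behavior.semantic_arc_score(all_events)
            out["arc_score"] = arc.dropna().to_dict()
            out["arc_group_test"] = behavior.clustering_group_comparison(arc, groups)
        (outdir / "behavior.json").write_text(json.dumps(out, indent=1, default=float))
        bundle["behavior"] = out

    if "sme" in cfg.stages:
        cells = {}
        t_rows = []
        for d in datasets:
            ep, elec = spectral.preprocess(d.epochs, d.electrodes)
            power, times = spectral.morlet_power(ep, spectral.DEFAULT_SME_FREQS)
            feats = spectral.encoding_power_features(
                power, times, d.events["session"].to_numpy(), window=cfg.sme_window
            )
            t = spectral.power_sme(feats, d.events["recalled"].to_numpy())
            cells[d.subject] = spectral.band_region_sme(
                t, spectral.DEFAULT_SME_FREQS, elec
            )
            for ci, chan in enumerate(elec["channel"]):
                for fi, f in enumerate(spectral.DEFAULT_SME_FREQS):
                    t_rows.append(
                        {"subject": d.subject, "channel": chan,
                         "freq": float(f), "t": float(t[ci, fi])}
                    )
        contrast = spectral.group_sme_contrast(cells, groups)
        out = {
            **stamp,
            "band_region_cells": {s: cells[s].to_dict() for s in cells},
            "group_contrast": contrast.to_dict(orient="records"),
        }
        (outdir / "sme.json").write_text(json.dumps(out, indent=1, default=float))
        write_table(pd.DataFrame(t_rows), outdir / "sme_tstats.tsv")
        bundle["sme"] = {"cells": cells, "contrast": contrast}

    if "connectivity" in cfg.stages:
        edge_tables = {}
        for k, d in enumerate(datasets):
            pair_z = connectivity.connectivity_sme_z(
                d.epochs,
                d.electrodes,
                d.events["recalled"].to_numpy(),
                n_perm=cfg.n_perm_connectivity,
                rng_seed=stage_seeds["connectivity"] + k,
            )
            edge_tables[d.subject] = connectivity.roi_edges(pair_z)
        tests = connectivity.group_network_tests(edge_tables, groups)
        mean_edges = (
            pd.concat(edge_tables.values())
            .groupby(["roi_a", "roi_b"])["mean_z"].mean().reset_index()
        )
        out = {
            **stamp,
            "subject_mean_edge": tests["subject_mean_edge"].to_dict(),
            "group_tests": {k: v for k, v in tests.items()
                            if k != "subject_mean_edge"},
            "mean_roi_edges": mean_edges.to_dict(orient="records"),
        }
        (outdir / "net.json").write_text(json.dumps(out, indent=1, default=float))
        write_table(mean_edges, outdir / "roi_edges.tsv")
        bundle["connectivity"] = {"edges": edge_tables, "tests": tests}

    if "classify" in cfg.stages:
        aucs = {}
        for d in datasets:
            X = classify.build_feature_matrix(d.epochs, d.electrodes, d.events)
            res = classify.cross_validated_auc(
                X,
                d.events["recalled"].to_numpy(dtype=int),
                d.events["session"].to_numpy(),
                d.events["list"].to_numpy(),
                C=cfg.C,
            )
            aucs[d.subject] = res.auc
        auc_series = pd.Series(aucs)
        by_group = {
            g: float(auc_series[groups.reindex(auc_series.index) == g].mean())
            for g in ("case", "control")
        }
        out = {**stamp, "auc": aucs, "group_mean_auc": by_group,
               "fold_scheme": res.fold_scheme, "C": cfg.C}
        (outdir / "clf.json").write_text(json.dumps(out, indent=1, default=float))
        bundle["classifier"] = out

    if "match" in cfg.stages:
        table = generate_cohort_table(
            n_total=200,
            coefficients=np.concatenate(
                [[-1.6], np.zeros(len(COHORT_DESIGN_COLUMNS))]
            ),
            rng_seed=stage_seeds["cohort"],
        )
        matched = cohort.match_controls(table, match_ratio=cfg.match_ratio)
        balance = cohort.balance_table(matched)
        write_table(matched, outdir / "matched.tsv")
        (outdir / "balance.json").write_text(
            json.dumps({**stamp,
                        "balance": balance.to_dict(orient="records")},
                       indent=1, default=float)
        )
        bundle["matching"] = {"matched": matched, "balance": balance}

    (outdir / "report.md").write_text(write_report(bundle))
    return bundle


def write_report(bundle: dict) -> str:
    """Human-readable markdown summary of a results bundle."""
    lines = ["# memsme run report", ""]
    stamp = bundle.get("stamp", {})
    if stamp:
        lines += [f"config hash: `{stamp.get('config_hash')}`, "
                  f"seed: {stamp.get('rng_seed')}", ""]
    if "behavior" in bundle:
        b = bundle["behavior"]
        lines += ["## Recall behaviour", ""]
        t = b.get("temporal_group_test", {})
        lines += [f"- temporal clustering group Welch t = {t.get('t', float('nan')):.3f} "
                  f"(p = {t.get('p', float('nan')):.3f})"]
        lr = b.get("recall_lr_test", {})
        lines += [f"- recall group LR chi2 = {lr.get('chi2_group', float('nan')):.2f} "
                  f"(p = {lr.get('p_group', float('nan')):.3f})", ""]
    if "sme" in bundle:
        lines += ["## Spectral SME (region x band mean t, averaged over subjects)", ""]
        cells = bundle["sme"]["cells"]
        mean_cells = sum(cells.values()) / len(cells)
        lines += [mean_cells.round(3).to_markdown(), ""]
    if "connectivity" in bundle:
        lines += ["## Theta connectivity network", ""]
        tests = bundle["connectivity"]["tests"]
        for key, val in tests.items():
            if key == "subject_mean_edge":
                continue
            lines += [f"- {key}: t = {val['t']:.3f}, p = {val['p']:.3f}"]
        lines += [""]
    if "classifier" in bundle:
        c = bundle["classifier"]
        lines += ["## Recall classifier", ""]
        for g, v in c.get("group_mean_auc", {}).items():
            lines += [f"- mean AUC ({g}): {v:.3f}"]
        lines += [""]
    if "matching" in bundle:
        bal = bundle["matching"]["balance"]
        lines += ["## Cohort matching balance", "",
                  bal.round(3).to_markdown(index=False), ""]
    return "\n".join(lines) + "\n"
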