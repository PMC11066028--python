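"""End-to-end orchestration: simulate -> preprocess -> train -> extract ->
analyse, driven by a single config mapping.

Stages communicate through in-memory objects and, when an output directory
is configured, through on-disk CSV/TSV/TIFF artifacts whose first line is a
provenance comment (config hash + seed). Ground-truth standards for the
synthetic screen (archetype annotations, planted complexes, planted
heterogeneity verdicts) are derived from the panel and threaded through the
benchmark, hierarchy, localization, heterogeneity and complex stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmarks, complexes, heterogeneity, hierarchy, locmap, prep, synth
from .network import (
    ProteinIdentityNetwork,
    average_profiles,
    extract_scfps,
    feature_matrix,
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": None,
    "stages": {
        "simulate": True, "prep": True, "train": True, "benchmark": True,
        "hierarchy": True, "locmap": True, "heterogeneity": True,
        "cellcycle": True, "complexes": True,
    },
    "synthio": {
        "n_proteins": 12,
        "n_complexes": 2,
        "het_fractions": {"AND": 1 / 6, "OR": 1 / 6},
        "n_archetypes": 4,
        "n_cellcycle": 1,
        "cells_per_protein": 100,
        "replicates": 2,
        "fields_per_replicate": 4,
        "noise_sd": 0.05,
        "field_size": 256,
    },
    "prep": {
        "crop_size": 64, "boundary_margin": 10, "intensity_percentile": 5.0,
        "min_cells_per_protein": 10, "split_ratios": [8, 1, 1],
        "variance_floor": 1e-4,
    },
    "network": {
        "n_conv_blocks": 2, "base_channels": 8, "fc1_units": 64,
        "feature_dim": 16, "dropout": 0.05, "lr": 1e-3, "epochs": 30,
        "batch_size": 128,
    },
    # the head's published protocol is 5 epochs at ~1.1e4 steps/epoch; at this
    # problem size that is a few dozen Adam updates, so the demo scales the
    # epoch count (and shrinks batches) to give the optimizer a comparable
    # update budget; early stopping on validation accuracy is unchanged
    "locmap": {"epochs": 60, "lr": 1e-3, "batch_size": 32},
    "heterogeneity": {"alpha_conf": 0.5, "beta": 0.5, "or_threshold": 0.08,
                       "undetermined_fraction": 0.5},
    "cellcycle": {"n_members": 3, "n_conv_blocks": 2, "base_channels": 6,
                   "feature_dim": 24, "epochs": 40, "lr": 5e-4,
                   "max_per_class": 200},
    "complexes": {"step": 0.05, "plateau_tolerance": 0.95, "score_cutoff": 0.6,
                   "run_baselines": True},
}

_SCHEMA_TYPES = {
    "seed": int,
    "stages": dict,
    "synthio": dict,
    "prep": dict,
    "network": dict,
    "locmap": dict,
    "heterogeneity": dict,
    "cellcycle": dict,
    "complexes": dict,
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge over defaults and validate types before any stage runs."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key == "out_dir":
            merged[key] = value
            continue
        if key not in _SCHEMA_TYPES:
            raise ConfigError(f"unknown config section {key!r}")
        if not isinstance(value, _SCHEMA_TYPES[key]):
            raise ConfigError(f"config section {key!r} must be {_SCHEMA_TYPES[key].__name__}")
        if isinstance(value, dict):
            unknown = set(value) - set(merged[key]) if key != "stages" else set()
            if unknown:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    syn = merged["synthio"]
    if syn["n_proteins"] < 2 * syn["n_complexes"]:
        raise ConfigError("n_proteins must be at least twice n_complexes")
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, config: dict, index=True):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cellfp config_hash={config_hash(config)} seed={config['seed']}\n")
        df.to_csv(fh, index=index, sep="\t" if path.suffix == ".tsv" else ",")


# ------------------------------------------------------------------
# ground-truth standards from the panel


def archetype_standard(panel) -> benchmarks.AnnotationStandard:
    """Protein -> localization archetype label set (both archetypes for
    heterogeneous proteins)."""
    mapping = {}
    for spec in panel:
        labels = {spec.archetype}
        if spec.secondary_archetype:
            labels.add(spec.secondary_archetype)
        mapping[spec.protein_id] = frozenset(labels)
    return benchmarks.AnnotationStandard(name="archetype", mapping=mapping,
                                         overlap_rule="exact")


def complex_standard(panel, min_members=3) -> complexes.ComplexStandard:
    mapping: dict[str, set] = {}
    for spec in panel:
        if spec.complex_id:
            mapping.setdefault(spec.complex_id, set()).add(spec.protein_id)
    return complexes.ComplexStandard(
        mapping={k: frozenset(v) for k, v in mapping.items()}, min_members=min_members
    )


def planted_verdicts(panel) -> pd.Series:
    """Ground-truth heterogeneity verdict per protein ("single"/"AND"/"OR")."""
    return pd.Series({s.protein_id: s.heterogeneity for s in panel}, name="verdict")


# ------------------------------------------------------------------


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages; returns a report with per-stage
    metrics and the principal in-memory artifacts under ``"artifacts"``."""
    config = validate_config(config or {})
    seed = config["seed"]
    stages = config["stages"]
    out_dir = Path(config["out_dir"]) if config.get("out_dir") else None
    report: dict = {"seed": seed, "config_hash": config_hash(config), "stages": {}}
    artifacts: dict = {}
    t_start = time.time()

    # -- simulate ----------------------------------------------------
    syn_cfg = config["synthio"]
    panel = synth.make_protein_panel(
        n_proteins=syn_cfg["n_proteins"],
        n_complexes=syn_cfg["n_complexes"],
        het_fractions=syn_cfg["het_fractions"],
        seed=seed,
        n_archetypes=syn_cfg["n_archetypes"],
        n_cellcycle=syn_cfg["n_cellcycle"],
    )
    artifacts["panel"] = panel
    if stages.get("simulate", True):
        dataset = synth.generate_dataset(
            panel,
            cells_per_protein=syn_cfg["cells_per_protein"],
            replicates=syn_cfg["replicates"],
            fields_per_replicate=syn_cfg["fields_per_replicate"],
            seed=seed,
            noise_sd=syn_cfg["noise_sd"],
            field_size=syn_cfg["field_size"],
        )
        artifacts["dataset"] = dataset
        report["stages"]["simulate"] = {
            "n_fields": len(dataset.fields), "n_cells": len(dataset.manifest),
        }
        if out_dir:
            dataset.write(out_dir / "data")
    else:
        return _finish(report, artifacts, t_start)

    # -- prep --------------------------------------------------------
    if not stages.get("prep", True):
        return _finish(report, artifacts, t_start)
    prep_cfg = prep.PreprocessConfig(
        crop_size=config["prep"]["crop_size"],
        boundary_margin=config["prep"]["boundary_margin"],
        intensity_percentile=config["prep"]["intensity_percentile"],
        min_cells_per_protein=config["prep"]["min_cells_per_protein"],
        split_ratios=tuple(config["prep"]["split_ratios"]),
        variance_floor=config["prep"]["variance_floor"],
        seed=seed,
    )
    crops = prep.prepare_dataset(dataset, prep_cfg)
    artifacts["crops"] = crops
    split_counts = pd.Series([c.split for c in crops]).value_counts().to_dict()
    report["stages"]["prep"] = {"n_crops": len(crops), "splits": split_counts}

    # -- train -------------------------------------------------------
    if not stages.get("train", True):
        return _finish(report, artifacts, t_start)
    net_cfg = config["network"]
    model = ProteinIdentityNetwork(random_state=seed, **net_cfg)
    Xtr, ytr, _ = prep.crops_to_arrays(crops, "train")
    Xva, yva, _ = prep.crops_to_arrays(crops, "val")
    Xte, yte, _ = prep.crops_to_arrays(crops, "test")
    model.fit(Xtr, ytr, X_val=Xva, y_val=yva, X_test=Xte, y_test=yte)
    artifacts["model"] = model
    test_acc = model.score(Xte, yte)
    report["stages"]["train"] = {
        "best_epoch": int(model.best_epoch_),
        "test_accuracy": test_acc,
        "chance": 1.0 / len(model.classes_),
    }

    X_all, pid_all, cid_all = prep.crops_to_arrays(crops)
    scfps_all = extract_scfps(model, X_all, cid_all, pid_all)
    scfps_all["split"] = [c.split for c in crops]
    scfps_test = scfps_all[scfps_all.split == "test"].drop(columns="split")
    # aFPs over all of a protein's crops: per-protein averages need many more
    # cells than a tenth of this dataset provides to be stable
    afps = average_profiles(scfps_all.drop(columns="split"))
    artifacts["scfps"] = scfps_all
    artifacts["afps"] = afps
    if out_dir:
        _write(scfps_all, out_dir / "scfps.csv", config)
        _write(afps, out_dir / "afps.csv", config)

    std = archetype_standard(panel)
    single_labels = std.single_label()

    # -- benchmark ---------------------------------------------------
    if stages.get("benchmark", True):
        scores = benchmarks.score_profiles(afps, [std])
        report["stages"]["benchmark"] = scores.to_dict("records")
        artifacts["benchmark"] = scores
        if out_dir:
            _write(scores, out_dir / "benchmark.csv", config, index=False)

    # -- hierarchy ---------------------------------------------------
    if stages.get("hierarchy", True):
        dend = hierarchy.build_dendrogram(afps)
        cutoff = hierarchy.select_cutoff(dend, single_labels, standard_name=std.name)
        truth = {p: single_labels[p] for p in cutoff.clusters.index if p in single_labels}
        ami = benchmarks.ami_score(
            [truth[p] for p in truth], [cutoff.clusters[p] for p in truth]
        )
        report["stages"]["hierarchy"] = {
            "threshold": cutoff.threshold, "archetype_ami": ami,
            "n_clusters": int(cutoff.clusters.nunique()),
        }
        artifacts["cutoff"] = cutoff
        if out_dir:
            _write(cutoff.clusters.to_frame("cluster_id"), out_dir / "clusters.tsv", config)
            _write(cutoff.curve, out_dir / "ami_curve.csv", config, index=False)
            # scFP embedding with archetype annotation
            n = len(scfps_test)
            perplexity = min(200.0, max(5.0, (n - 1) / 3.0))
            coords, _ = hierarchy.embed_annotate(
                scfps_test, None, perplexity=perplexity, kde=False,
                random_state=seed,
            )
            coords["label"] = [
                single_labels.get(p, "heterogeneous") for p in scfps_test.protein_id
            ]
            _write(coords, out_dir / "embedding.csv", config)
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(5, 5))
                for lab, grp in coords.groupby("label"):
                    ax.scatter(grp.tsne1, grp.tsne2, s=6, label=lab, alpha=0.6)
                ax.legend(fontsize=6, markerscale=2)
                ax.set_xlabel("tSNE 1"); ax.set_ylabel("tSNE 2")
                fig.savefig(out_dir / "embedding.png", dpi=120,
                            bbox_inches="tight")
                plt.close(fig)
            except Exception:  # plotting must never fail the run
                pass

    # -- locmap ------------------------------------------------------
    head = None
    if stages.get("locmap", True):
        single_ids = set(single_labels)
        tr = scfps_all[(scfps_all.split == "train") & scfps_all.protein_id.isin(single_ids)]
        va = scfps_all[(scfps_all.split == "val") & scfps_all.protein_id.isin(single_ids)]
        te = scfps_all[(scfps_all.split == "test") & scfps_all.protein_id.isin(single_ids)]
        head = locmap.LocalizationHead(random_state=seed, **config["locmap"])
        head.fit(
            feature_matrix(tr), tr.protein_id.map(single_labels).to_numpy(),
            feature_matrix(va), va.protein_id.map(single_labels).to_numpy(),
        )
        loc_acc = head.score(feature_matrix(te), te.protein_id.map(single_labels).to_numpy())
        report["stages"]["locmap"] = {
            "val_best_epoch": int(head.best_epoch_),
            "test_accuracy": loc_acc,
            "n_classes": int(len(head.classes_)),
        }
        artifacts["head"] = head
        if out_dir:
            _write(locmap.feature_importance(head), out_dir / "feature_importance.tsv",
                   config, index=False)
            locmap.save_head(head, out_dir / "localization_head.csv",
                             out_dir / "localization_head.json")

    # -- heterogeneity -----------------------------------------------
    if stages.get("heterogeneity", True) and head is not None:
        params = heterogeneity.HeterogeneityParams(**config["heterogeneity"])
        # all splits: per-protein category fractions need stable estimates at
        # this problem size
        scfps_het = scfps_all.drop(columns="split")
        probs = pd.DataFrame(
            head.predict_proba(feature_matrix(scfps_het)), columns=head.classes_
        )
        calls = heterogeneity.call_heterogeneity(probs, scfps_het.protein_id.to_numpy(),
                                                 params)
        truth = planted_verdicts(panel)
        calls["planted"] = calls.protein_id.map(truth)
        acc = float((calls.verdict == calls.planted).mean())
        report["stages"]["heterogeneity"] = {
            "verdict_accuracy": acc,
            "verdicts": calls.verdict.value_counts().to_dict(),
        }
        artifacts["heterogeneity_calls"] = calls
        artifacts["heterogeneity_params"] = params
        if out_dir:
            _write(calls, out_dir / "heterogeneity.tsv", config, index=False)

    # -- cell cycle --------------------------------------------------
    if stages.get("cellcycle", True) and head is not None:
        cc_cfg = dict(config["cellcycle"])
        max_per_class = cc_cfg.pop("max_per_class", 200)
        labelled = [c for c in crops if c.stage in heterogeneity.STAGE_CLASSES]
        rng = np.random.default_rng(seed)
        chosen = []
        for stage in heterogeneity.STAGE_CLASSES:
            pool = [c for c in labelled if c.stage == stage]
            take = min(len(pool), max_per_class)
            chosen += [pool[i] for i in rng.choice(len(pool), take, replace=False)]
        Xcc = np.stack([c.pixels[..., 1:3].transpose(2, 0, 1) for c in chosen])
        ycc = np.array([c.stage for c in chosen])
        ensemble = heterogeneity.CellCycleEnsemble(random_state=seed, **cc_cfg)
        ensemble.fit(Xcc, ycc)
        merged_truth = {"G1": "T/G1", "T": "T/G1", "S": "S/G2", "MA": "M/A"}
        pred = ensemble.predict_proba_merged(Xcc).to_numpy().argmax(1)
        truth3 = np.array(
            [list(heterogeneity.MERGED_CLASSES).index(merged_truth[s]) for s in ycc]
        )
        merged_acc = float(np.mean(pred == truth3))
        report["stages"]["cellcycle"] = {"merged_accuracy_train_pool": merged_acc}
        artifacts["cellcycle_ensemble"] = ensemble

        # stage-localization links for heterogeneous proteins (all splits)
        links = []
        params = artifacts.get("heterogeneity_params", heterogeneity.HeterogeneityParams())
        het_specs = [s for s in panel if s.heterogeneity in ("AND", "OR")]
        for spec in het_specs:
            rows = scfps_all[scfps_all.protein_id == spec.protein_id]
            crop_sel = [c for c in crops if c.protein_id == spec.protein_id]
            probs = pd.DataFrame(
                head.predict_proba(feature_matrix(rows)), columns=head.classes_
            )
            loc1, loc2, pairs = heterogeneity.top2_localizations(probs)
            Xst = np.stack([c.pixels[..., 1:3].transpose(2, 0, 1) for c in crop_sel])
            stage_probs = ensemble.predict_proba_merged(Xst)
            links.append(
                heterogeneity.cellcycle_association(
                    pairs, stage_probs, params,
                    protein_id=spec.protein_id, loc1=str(loc1), loc2=str(loc2),
                )
            )
        links = (
            pd.concat([l for l in links if not l.empty] or
                      [pd.DataFrame(columns=["protein_id", "stage", "localization",
                                             "U", "p"])],
                      ignore_index=True) if links
            else pd.DataFrame(columns=["protein_id", "stage", "localization", "U", "p"])
        )
        cc_proteins = {s.protein_id for s in het_specs if s.cellcycle_dependence}
        planted_links = links[links.protein_id.isin(cc_proteins)]
        report["stages"]["cellcycle"]["n_links"] = int(len(links))
        report["stages"]["cellcycle"]["planted_protein_links"] = int(len(planted_links))
        artifacts["cellcycle_links"] = links
        if out_dir:
            _write(links, out_dir / "cellcycle_links.tsv", config, index=False)

    # -- complexes ---------------------------------------------------
    if stages.get("complexes", True):
        cx_cfg = dict(config["complexes"])
        run_baselines = cx_cfg.pop("run_baselines", True)
        cstd = complex_standard(panel)
        Xs = feature_matrix(scfps_test)
        pids = scfps_test.protein_id.to_numpy()
        clus = complexes.AdaptiveThresholdClustering(**cx_cfg).fit(Xs, pids)
        f1, precision, recall = complexes.pairwise_f1(clus.labels_, pids, cstd)
        med = complexes.per_cluster_f1(clus.labels_, pids, cstd)
        rec = {
            "n_roots": len(clus.roots_),
            "n_high_confidence": len(clus.high_confidence_),
            "pairwise_f1": f1, "precision": precision, "recall": recall,
            "median_cluster_f1": float(med.median()) if len(med) else 0.0,
            "recovered_complexes": _recovered(clus, cstd),
        }
        if run_baselines:
            table = complexes.baseline_grid(Xs, pids, cstd)
            rec["baselines"] = table.to_dict("records")
            rec["best_baseline_median_f1"] = float(table.median_f1.max())
            artifacts["baseline_table"] = table
        report["stages"]["complexes"] = rec
        artifacts["complex_clustering"] = clus
        if out_dir:
            _write(clus.to_frame(), out_dir / "complexes.tsv", config, index=False)

    return _finish(report, artifacts, t_start)


def _recovered(clus, cstd) -> int:
    """Number of planted complexes matched by a high-confidence cluster
    (cluster's protein set contains a majority of the complex)."""
    hit = 0
    for cid, members in cstd.mapping.items():
        for root in clus.high_confidence_:
            if len(root.proteins & members) >= max(2, len(members) // 2 + 1):
                hit += 1
                break
    return hit


def _finish(report, artifacts, t_start):
    report["runtime_s"] = round(time.time() - t_start, 2)
    report["artifacts"] = artifacts
    return report


def export_profiles(model, crops, out_dir=None, config=None):
    """Out-of-the-box feature extraction for unseen crops.

    Applies per-image standardization to each crop's protein channel, runs
    the network, and returns (scfps, afps); writes them as CSV when
    ``out_dir`` is given.
    """
    norm = [prep.normalize_crop(c) for c in crops]
    X, pids, cids = prep.crops_to_arrays(norm)
    scfps = extract_scfps(model, X, cids, pids)
    afps = average_profiles(scfps)
    if out_dir is not None:
        cfg = config or {"seed": "NA"}
        _write(scfps, Path(out_dir) / "scfps.csv", cfg)
        _write(afps, Path(out_dir) / "afps.csv", cfg)
    return scfps, afps
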