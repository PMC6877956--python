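"""End-to-end orchestration: label -> featurize -> window -> CV -> report -> analyze.

A run is described by one flat key/value config (every key has a default and
a CLI flag). All randomness flows from the single ``seed`` key; per-stage
seeds are derived by hashing the stage name with the master seed, so a rerun
from a saved manifest reproduces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (aa_class_distribution, mean_decrease_accuracy,
                       physchem_distribution, tree_feature_importance)
from .evaluation import aggregate_report
from .features import PhysChemScales, chain_feature_rows, read_pssm
from .model import TrainConfig, cross_validate, derive_seed, train
from .structure_labeling import LabelConfig, label_binding_residues, parse_structure
from .synthetic_data import SynthBundle, generate_bundle, preset_config, write_bundle
from .windows import FeatureMatrix, WindowConfig, extract_windows

logger = logging.getLogger("smopsi")

DEFAULT_CONFIG: dict = {
    "preset": "strong",
    "n_chains": 50,
    "seed": 0,
    "window_width": 15,
    "distance_threshold": 3.5,
    "atom_mode": "central_atom",
    "n_downsample_repeats": 5,
    "neg_pos_ratio": 1.0,
    "n_estimators": 100,
    "learning_rate": 0.1,
    "max_depth": 4,
    "subsample": 0.8,
    "decision_threshold": 0.5,
    "cv_folds": 10,
    "cv_grouping": "chain",
    "eval_on_full": False,
    "analyze": True,
    "importance_repeats": 5,
}


def resolve_config(config: dict | None = None) -> dict:
    """Materialize all defaults and fail fast on any constraint violation."""
    resolved = {**DEFAULT_CONFIG, **(config or {})}
    unknown = set(resolved) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # constructing the typed configs runs every invariant check
    WindowConfig(width=int(resolved["window_width"]))
    LabelConfig(distance_threshold=float(resolved["distance_threshold"]),
                atom_mode=resolved["atom_mode"])
    _train_config(resolved)
    return resolved


def _train_config(cfg: dict, seed_tag: str = "train") -> TrainConfig:
    return TrainConfig(
        n_downsample_repeats=int(cfg["n_downsample_repeats"]),
        neg_pos_ratio=float(cfg["neg_pos_ratio"]),
        n_estimators=int(cfg["n_estimators"]),
        learning_rate=float(cfg["learning_rate"]),
        max_depth=int(cfg["max_depth"]),
        subsample=float(cfg["subsample"]),
        random_seed=derive_seed(int(cfg["seed"]), seed_tag),
        decision_threshold=float(cfg["decision_threshold"]),
        cv_folds=int(cfg["cv_folds"]),
        cv_grouping=cfg["cv_grouping"],
        eval_on_full=bool(cfg["eval_on_full"]),
    )


def featurize_bundle(bundle: SynthBundle, window_config: WindowConfig = WindowConfig(),
                     label_config: LabelConfig = LabelConfig(),
                     scales: PhysChemScales | None = None):
    """Run the real parsers over a bundle and window the features.

    Labels are re-derived from the PDB geometry via the contact rule (never
    copied from the generator's ground truth). Returns ``(matrix,
    chain_features, chain_labels)`` — the per-residue pieces are kept for the
    window sweep and the distribution analyses.
    """
    if scales is None:
        scales = PhysChemScales()
    parts, chain_features, chain_labels = [], {}, {}
    for cid in bundle.chain_ids():
        chains, ligands = parse_structure(bundle.pdb_texts[cid],
                                          het_codes={bundle.config.het_code},
                                          structure_id=cid)
        chain = chains[0]
        labels = label_binding_residues(chain, ligands, label_config)
        pssm = read_pssm(bundle.pssm_texts[cid], chain_id=cid)
        rows = chain_feature_rows(chain.sequence, pssm, scales)
        parts.append(extract_windows(rows, labels.labels, chain_id=cid,
                                     config=window_config))
        chain_features[cid] = rows
        chain_labels[cid] = labels.labels
    return FeatureMatrix.concat(parts), chain_features, chain_labels


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_end_to_end(config: dict | None = None, out_dir="smopsi_run") -> dict:
    """Execute the full workflow on a simulated preset; returns the manifest.

    Writes ``bundle/`` (inputs), ``report.json`` (CV metrics), the analysis
    tables and ``manifest.json`` to ``out_dir``. ``report.json`` contains no
    timestamps, so a rerun from the manifest's config is byte-identical.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stage_log: list[dict] = []

    def stage(name):
        logger.info("stage %s", name)
        stage_log.append({"stage": name, "t": round(time.time() - started, 3)})

    try:
        stage("simulate")
        synth = preset_config(cfg["preset"], seed=derive_seed(int(cfg["seed"]), "simulate"),
                              n_chains=int(cfg["n_chains"]))
        bundle = generate_bundle(synth)
        write_bundle(bundle, out / "bundle")

        stage("label+featurize+window")
        window_config = WindowConfig(width=int(cfg["window_width"]))
        label_config = LabelConfig(distance_threshold=float(cfg["distance_threshold"]),
                                   atom_mode=cfg["atom_mode"])
        matrix, _, chain_labels = featurize_bundle(bundle, window_config, label_config)

        stage("cv")
        result = cross_validate(matrix, _train_config(cfg))
        report = result.to_json_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        aggregate_report(result.folds if result.folds else [result.pooled]) \
            .to_dataframe(rounded=True) \
            .to_csv(out / "report.tsv", sep="\t", index=False)

        if cfg["analyze"]:
            stage("analyze")
            pairs = [(bundle.sequences[cid], chain_labels[cid]) for cid in bundle.chain_ids()]
            aa_class_distribution(pairs).table.to_csv(out / "aa_distribution.tsv",
                                                      sep="\t", index=False)
            physchem_distribution(pairs).to_csv(out / "physchem_distribution.tsv",
                                                sep="\t", index=False)
            ensemble = train(matrix, _train_config(cfg, seed_tag="importance-train"))
            mda = mean_decrease_accuracy(ensemble, matrix,
                                         n_repeats=int(cfg["importance_repeats"]),
                                         seed=derive_seed(int(cfg["seed"]), "mda"))
            tree = tree_feature_importance(matrix,
                                           seed=derive_seed(int(cfg["seed"]), "tree-imp"))
            (out / "importance.json").write_text(json.dumps(
                {"mean_decrease_accuracy": mda.as_dict(),
                 "tree_importance": tree.as_dict()}, indent=2, sort_keys=True))
    except Exception as exc:
        failed = stage_log[-1]["stage"] if stage_log else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest = {
        "tool_version": __version__,
        "config": cfg,
        "master_seed": int(cfg["seed"]),
        "input_checksums": {f"{cid}.pdb": _sha256(bundle.pdb_texts[cid])
                            for cid in bundle.chain_ids()},
        "started_unix": started,
        "elapsed_s": round(time.time() - started, 3),
        "stages": stage_log,
        "pooled_auc": report["pooled"]["AUC"],
        "pooled_acc": report["pooled"]["ACC"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
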