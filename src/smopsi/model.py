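"""Downsample-balanced gradient-boosted classification with grouped CV.

Binding residues are heavily outnumbered by nonbinding ones, so training
repeatedly draws random balanced subsets: every positive window is kept and
the negatives are sampled down to ``neg_pos_ratio`` times the positive count.
One boosted-tree model is fitted per draw and prediction averages the
per-model positive-class probabilities.

All randomness flows from a single master seed: per-repeat and per-fold seeds
are derived by hashing ``(tag, master_seed)``, so identical configs reproduce
identical models and scores.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .evaluation import MetricsRecord, compute_metrics
from .windows import FeatureMatrix, WindowConfig


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31 from (tag, master seed)."""
    digest = hashlib.sha256(f"{tag}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TrainConfig:
    n_downsample_repeats: int = 5
    neg_pos_ratio: float = 1.0
    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 4
    subsample: float = 0.8
    random_seed: int = 0
    decision_threshold: float = 0.5
    cv_folds: int = 10
    cv_grouping: str = "chain"  # or "residue"
    eval_on_full: bool = False  # score the unbalanced test stream instead

    def __post_init__(self):
        if self.n_downsample_repeats < 1:
            raise ValueError("n_downsample_repeats must be >= 1")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_grouping not in ("chain", "residue"):
            raise ValueError("cv_grouping must be 'chain' or 'residue'")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass
class TrainedEnsemble:
    """Boosted-tree models fitted on repeated downsampled draws."""

    models: list
    config: TrainConfig
    n_features: int
    window_config: WindowConfig | None = None

    def __post_init__(self):
        if len(self.models) != self.config.n_downsample_repeats:
            raise ValueError("model count must equal n_downsample_repeats")


def downsample(matrix: FeatureMatrix, seed: int,
               neg_pos_ratio: float = 1.0) -> FeatureMatrix:
    """Keep all positives; sample negatives without replacement down to
    ``ceil(neg_pos_ratio * n_pos)`` (or all, if fewer). Reproducible by seed."""
    pos_idx = np.flatnonzero(matrix.labels == 1)
    neg_idx = np.flatnonzero(matrix.labels == 0)
    if pos_idx.size == 0:
        raise ValueError("cannot balance a matrix with no positive rows")
    n_neg = min(neg_idx.size, math.ceil(neg_pos_ratio * pos_idx.size))
    rng = np.random.default_rng(seed)
    chosen_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.sort(np.concatenate([pos_idx, chosen_neg]))
    return matrix.subset(keep)


def _new_booster(config: TrainConfig, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        subsample=config.subsample,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


def train(matrix: FeatureMatrix, config: TrainConfig = TrainConfig()) -> TrainedEnsemble:
    """Fit one booster per downsample repeat; repeat seeds derive from the
    master seed."""
    if matrix.n_positive == 0 or matrix.n_positive == len(matrix):
        raise ValueError("training data must contain both classes")
    models = []
    for r in range(config.n_downsample_repeats):
        seed_r = derive_seed(config.random_seed, f"downsample-{r}")
        balanced = downsample(matrix, seed=seed_r, neg_pos_ratio=config.neg_pos_ratio)
        booster = _new_booster(config, derive_seed(config.random_seed, f"booster-{r}"))
        booster.fit(balanced.rows, balanced.labels)
        models.append(booster)
    return TrainedEnsemble(models=models, config=config,
                           n_features=matrix.rows.shape[1],
                           window_config=matrix.window_config)


def predict_scores(ensemble: TrainedEnsemble, matrix) -> np.ndarray:
    """Mean positive-class probability across the ensemble's models."""
    rows = matrix.rows if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if rows.ndim != 2 or rows.shape[1] != ensemble.n_features:
        raise ValueError(
            f"feature width {rows.shape[-1]} does not match the ensemble's "
            f"{ensemble.n_features}"
        )
    scores = np.mean([m.predict_proba(rows)[:, 1] for m in ensemble.models], axis=0)
    return scores.astype(float)


@dataclass
class CVResult:
    folds: list[MetricsRecord]
    pooled: MetricsRecord
    config: TrainConfig
    grouping: str
    eval_mode: str  # "balanced" or "full"

    def to_json_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "eval_mode": self.eval_mode,
            "config": asdict(self.config),
            "folds": [
                {**r.as_dict(),
                 "counts": None if r.counts is None else
                 {"TP": r.counts.tp, "FP": r.counts.fp,
                  "TN": r.counts.tn, "FN": r.counts.fn}}
                for r in self.folds
            ],
            "pooled": self.pooled.as_dict(),
        }


def _fold_iterator(matrix: FeatureMatrix, config: TrainConfig):
    """Yield (train_idx, test_idx) pairs.

    Chain grouping shuffles the chain ids once (seeded) and splits them into
    folds whose group counts differ by at most one; every row of a chain
    lands in that chain's fold. Residue grouping stratifies plain rows.
    """
    if config.cv_grouping == "chain":
        groups = matrix.chain_ids.astype(str)
        unique = np.unique(groups)
        if unique.size < config.cv_folds:
            raise ValueError(
                f"only {unique.size} chains for {config.cv_folds} folds; use "
                "cv_grouping='residue' or fewer folds"
            )
        rng = np.random.default_rng(derive_seed(config.random_seed, "cv-groups"))
        shuffled = rng.permutation(unique)
        all_idx = np.arange(len(matrix))
        for fold_chains in np.array_split(shuffled, config.cv_folds):
            mask = np.isin(groups, fold_chains)
            yield all_idx[~mask], all_idx[mask]
        return
    splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=derive_seed(config.random_seed, "cv-shuffle"))
    yield from splitter.split(matrix.rows, matrix.labels)


def cross_validate(matrix: FeatureMatrix, config: TrainConfig = TrainConfig()) -> CVResult:
    """Grouped k-fold cross-validation of the downsample-balanced ensemble.

    Under chain grouping no chain contributes rows to more than one test
    fold, preventing same-protein leakage between train and test. By default
    each test fold is itself downsample-balanced before scoring (metrics on
    the balanced stream); ``eval_on_full`` scores the natural class ratio
    instead. The pooled record concatenates all out-of-fold scores.
    """
    fold_records: list[MetricsRecord] = []
    all_true: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    for k, (train_idx, test_idx) in enumerate(_fold_iterator(matrix, config)):
        train_cfg = TrainConfig(**{**asdict(config),
                                   "random_seed": derive_seed(config.random_seed, f"fold-{k}")})
        ensemble = train(matrix.subset(train_idx), train_cfg)
        test = matrix.subset(test_idx)
        if not config.eval_on_full and test.n_positive > 0:
            test = downsample(test, seed=derive_seed(config.random_seed, f"eval-{k}"),
                              neg_pos_ratio=config.neg_pos_ratio)
        scores = predict_scores(ensemble, test)
        if 0 < test.n_positive < len(test):
            fold_records.append(compute_metrics(test.labels, scores,
                                                threshold=config.decision_threshold,
                                                unit=f"fold{k}"))
        all_true.append(test.labels)
        all_scores.append(scores)
    pooled = compute_metrics(np.concatenate(all_true), np.concatenate(all_scores),
                             threshold=config.decision_threshold, unit="pooled")
    return CVResult(folds=fold_records, pooled=pooled, config=config,
                    grouping=config.cv_grouping,
                    eval_mode="full" if config.eval_on_full else "balanced")


def save_ensemble(ensemble: TrainedEnsemble, directory) -> None:
    """Persist the boosters in their native JSON format plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, model in enumerate(ensemble.models):
        # persist the raw booster; the sklearn wrapper is rebuilt on load
        model.get_booster().save_model(directory / f"booster_{i:02d}.json")
    manifest = {
        "n_models": len(ensemble.models),
        "n_features": ensemble.n_features,
        "config": asdict(ensemble.config),
        "window_width": None if ensemble.window_config is None
        else ensemble.window_config.width,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_ensemble(directory) -> TrainedEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = TrainConfig(**manifest["config"])
    models = []
    for i in range(manifest["n_models"]):
        booster = _new_booster(config, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            booster.load_model(directory / f"booster_{i:02d}.json")
        models.append(booster)
    width = manifest.get("window_width")
    return TrainedEnsemble(
        models=models, config=config, n_features=manifest["n_features"],
        window_config=None if width is None else WindowConfig(width=width),
    )
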