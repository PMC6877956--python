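"""Descriptive analyses: residue-class and physicochemical distributions
between binding and nonbinding residues, and feature-group importance.

Importance is scored two ways, both aggregated over the feature groups of
:data:`smopsi.features.FEATURE_GROUPS` replicated across window positions:

* *mean decrease accuracy* — how much held-out accuracy drops when a group's
  columns are corrupted at prediction time (within-column permutation by
  default, which preserves marginals; uniform random substitution available);
* *tree importance* — normalized impurity-based importance summed per group
  from a random forest fitted on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_GROUPS, PSSM_ALPHABET, PhysChemScales, ROW_WIDTH
from .model import TrainedEnsemble, predict_scores
from .windows import FeatureMatrix


@dataclass
class ClassDistribution:
    """Per-letter composition of the binding and nonbinding residue classes."""

    table: pd.DataFrame  # letter, binding_count, nonbinding_count, freqs, p, q

    def __post_init__(self):
        for col in ("binding_freq", "nonbinding_freq"):
            total = self.table[col].sum()
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{col} must sum to 1, got {total}")


def _stack_residues(sequences_labels):
    letters, labels = [], []
    for seq, lab in sequences_labels:
        lab = np.asarray(getattr(lab, "labels", lab))
        if len(seq) != len(lab):
            raise ValueError("sequence and label lengths differ")
        letters.extend(seq)
        labels.extend(int(v) for v in lab)
    return np.array(letters), np.array(labels)


def aa_class_distribution(sequences_labels) -> ClassDistribution:
    """Letter frequencies within each class, with a per-letter two-proportion
    z-test and Benjamini-Hochberg q-values across the 20 letters."""
    letters, labels = _stack_residues(sequences_labels)
    n_bind = int((labels == 1).sum())
    n_non = int((labels == 0).sum())
    if n_bind == 0 or n_non == 0:
        raise ValueError("both classes must contain at least one residue")
    rows = []
    for aa in PSSM_ALPHABET:
        b = int(np.sum((letters == aa) & (labels == 1)))
        n = int(np.sum((letters == aa) & (labels == 0)))
        p1, p2 = b / n_bind, n / n_non
        pooled = (b + n) / (n_bind + n_non)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n_bind + 1 / n_non))
        if se == 0:
            pval = 1.0
        else:
            z = (p1 - p2) / se
            pval = float(2 * stats.norm.sf(abs(z)))
        rows.append({"letter": aa, "binding_count": b, "nonbinding_count": n,
                     "binding_freq": p1, "nonbinding_freq": p2, "p": pval})
    df = pd.DataFrame(rows)
    df["q"] = stats.false_discovery_control(df["p"].to_numpy())
    return ClassDistribution(table=df)


def physchem_distribution(sequences_labels, scales: PhysChemScales | None = None) -> pd.DataFrame:
    """Class means, standard deviations and Mann-Whitney p-value for each of
    the four physicochemical properties."""
    if scales is None:
        scales = PhysChemScales()
    letters, labels = _stack_residues(sequences_labels)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must contain at least one residue")
    rows = []
    for prop in ("hydrophilicity", "hydrophobicity", "charge", "hbond"):
        mapping = getattr(scales, prop)
        values = np.array([mapping[aa] for aa in letters])
        bind, non = values[labels == 1], values[labels == 0]
        if np.ptp(values) == 0:
            pval = 1.0
        else:
            pval = float(stats.mannwhitneyu(bind, non, alternative="two-sided").pvalue)
        rows.append({
            "property": prop,
            "binding_mean": float(bind.mean()), "binding_sd": float(bind.std()),
            "nonbinding_mean": float(non.mean()), "nonbinding_sd": float(non.std()),
            "p": pval,
        })
    return pd.DataFrame(rows)


@dataclass
class ImportanceReport:
    method: str  # "mean_decrease_accuracy" or "tree_importance"
    scores: dict[str, float]
    n_repeats: int
    seed: int
    baseline_acc: float | None = None

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not all(np.isfinite(v) for v in self.scores.values()):
            raise ValueError("importance scores must be finite")

    def ranking(self) -> list[str]:
        return sorted(self.scores, key=self.scores.get, reverse=True)

    def as_dict(self) -> dict:
        return {"method": self.method, "scores": self.scores,
                "n_repeats": self.n_repeats, "seed": self.seed,
                "baseline_acc": self.baseline_acc,
                "ranking": self.ranking()}


def group_columns(width: int, group: str) -> np.ndarray:
    """Column indices of one feature group replicated across a window of
    ``width`` positions."""
    if group not in FEATURE_GROUPS:
        raise KeyError(f"unknown feature group {group!r}; "
                       f"choose from {sorted(FEATURE_GROUPS)}")
    base = FEATURE_GROUPS[group]
    return np.concatenate([base + k * ROW_WIDTH for k in range(width)])


def _accuracy(ensemble: TrainedEnsemble, rows, labels, threshold: float) -> float:
    scores = predict_scores(ensemble, rows)
    return float(np.mean((scores >= threshold) == (np.asarray(labels) == 1)))


def mean_decrease_accuracy(ensemble: TrainedEnsemble, matrix: FeatureMatrix,
                           groups=None, n_repeats: int = 10, seed: int = 0,
                           corrupt: str = "permute") -> ImportanceReport:
    """Drop in held-out accuracy when one feature group is corrupted.

    ``corrupt="permute"`` shuffles each of the group's columns independently
    across rows; ``corrupt="random-uniform"`` replaces them with uniform draws
    over each column's observed range.
    """
    if corrupt not in ("permute", "random-uniform"):
        raise ValueError("corrupt must be 'permute' or 'random-uniform'")
    if matrix.n_positive in (0, len(matrix)):
        raise ValueError("held-out set must contain both classes")
    groups = list(groups) if groups is not None else list(FEATURE_GROUPS)
    width = matrix.window_config.width
    threshold = ensemble.config.decision_threshold
    baseline = _accuracy(ensemble, matrix.rows, matrix.labels, threshold)
    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    for group in groups:
        cols = group_columns(width, group)
        drops = []
        for _ in range(n_repeats):
            corrupted = matrix.rows.copy()
            if corrupt == "permute":
                for c in cols:
                    corrupted[:, c] = rng.permutation(corrupted[:, c])
            else:
                lo = corrupted[:, cols].min(axis=0)
                hi = corrupted[:, cols].max(axis=0)
                corrupted[:, cols] = rng.uniform(lo, hi, size=(len(matrix), cols.size))
            drops.append(baseline - _accuracy(ensemble, corrupted, matrix.labels, threshold))
        scores[group] = float(np.mean(drops))
    return ImportanceReport(method="mean_decrease_accuracy", scores=scores,
                            n_repeats=n_repeats, seed=seed, baseline_acc=baseline)


def tree_feature_importance(matrix: FeatureMatrix, seed: int = 0,
                            n_trees: int = 200, groups=None) -> ImportanceReport:
    """Impurity-based random-forest importance summed per feature group and
    normalized to sum to 1 over the groups."""
    labels = np.asarray(matrix.labels)
    if labels.sum() in (0, len(labels)):
        raise ValueError("training data must contain both classes")
    groups = list(groups) if groups is not None else list(FEATURE_GROUPS)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(matrix.rows, labels)
    width = matrix.window_config.width
    raw = {g: float(forest.feature_importances_[group_columns(width, g)].sum())
           for g in groups}
    total = sum(raw.values())
    if total > 0:
        raw = {g: v / total for g, v in raw.items()}
    return ImportanceReport(method="tree_importance", scores=raw,
                            n_repeats=1, seed=seed)
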