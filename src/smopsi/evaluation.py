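"""Classification metrics (ACC, precision, recall, F1, AUC) and report tables.

AUC follows the Mann-Whitney convention: the probability that a random
positive is scored above a random negative, with half credit for ties,
computed from midranks. Thresholded predictions call a row positive when
its score is >= the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsRecord:
    """ACC/precision/recall/F1/AUC for one evaluation unit (ligand class or fold)."""

    unit: str
    acc: float
    precision: float
    recall: float
    f1: float
    auc: float
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"unit": self.unit, "ACC": self.acc, "precision": self.precision,
                "recall": self.recall, "F1": self.f1, "AUC": self.auc}


METRIC_COLUMNS = ("ACC", "precision", "recall", "F1", "AUC")


def _validate_vectors(y_true, y_score):
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_score must be equal-length 1-D vectors")
    if y_true.size == 0:
        raise ValueError("empty input")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be binary")
    return y_true.astype(int), y_score


def confusion(y_true, y_score, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN at a decision threshold (score >= threshold -> positive)."""
    y_true, y_score = _validate_vectors(y_true, y_score)
    pred = y_score >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def roc_auc(y_true, y_score) -> float:
    """Midrank (Mann-Whitney) area under the ROC curve.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all positive-negative
    pairs; exact with ties.
    """
    y_true, y_score = _validate_vectors(y_true, y_score)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(y_score)  # midranks
    rank_sum_pos = ranks[y_true == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(y_true, y_score, threshold: float = 0.5,
                    unit: str = "") -> MetricsRecord:
    """Full metrics record for one evaluation unit.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``record.undefined``.
    """
    counts = confusion(y_true, y_score, threshold)
    undefined = []
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision = 0.0
        undefined.append("precision")
    if counts.tp + counts.fn:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall = 0.0
        undefined.append("recall")
    auc = roc_auc(y_true, y_score)
    return MetricsRecord(
        unit=unit, acc=acc, precision=precision, recall=recall,
        f1=f1_score(precision, recall), auc=auc, counts=counts,
        undefined=tuple(undefined),
    )


@dataclass
class LigandReport:
    """Per-unit metric records plus an unweighted Average row."""

    records: list[MetricsRecord]
    average: MetricsRecord = field(init=False)

    def __post_init__(self):
        if not self.records:
            raise ValueError("report needs at least one record")
        self.average = MetricsRecord(
            unit="Average",
            acc=float(np.mean([r.acc for r in self.records])),
            precision=float(np.mean([r.precision for r in self.records])),
            recall=float(np.mean([r.recall for r in self.records])),
            f1=float(np.mean([r.f1 for r in self.records])),
            auc=float(np.mean([r.auc for r in self.records])),
        )

    def to_dataframe(self, rounded: bool = False) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.records + [self.average]])
        if rounded:
            df[list(METRIC_COLUMNS)] = df[list(METRIC_COLUMNS)].round(3)
        return df

    def to_tsv(self, handle, rounded: bool = True) -> None:
        self.to_dataframe(rounded=rounded).to_csv(handle, sep="\t", index=False)


def aggregate_report(records) -> LigandReport:
    """Aggregate per-unit records; the Average row is the unweighted
    arithmetic mean of each metric column (display rounding only)."""
    return LigandReport(records=list(records))


def load_reference_metrics() -> list[MetricsRecord]:
    """Published per-ligand 10-fold CV metrics for the 14 sc-PDB ligand
    classes, shipped as package data (used for aggregate-arithmetic checks
    and comparison tables)."""
    text = resources.files("smopsi.data").joinpath("scpdb_reference_metrics.tsv").read_text()
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", comment="#")
    return [
        MetricsRecord(unit=row["ligand"], acc=row["ACC"], precision=row["precision"],
                      recall=row["recall"], f1=row["F1"], auc=row["AUC"])
        for _, row in df.iterrows()
    ]


def window_sweep(chain_features: dict, chain_labels: dict, widths,
                 train_config=None) -> pd.DataFrame:
    """Re-window, downsample and cross-validate at each candidate width.

    ``chain_features`` maps chain id -> (L, 44) per-residue feature array and
    ``chain_labels`` maps chain id -> binary label vector. Returns a table of
    pooled (width, ACC, AUC); the best width is the argmax-AUC row.
    """
    from .model import TrainConfig, cross_validate
    from .windows import FeatureMatrix, WindowConfig, extract_windows

    if train_config is None:
        train_config = TrainConfig()
    records = []
    for w in widths:
        cfg = WindowConfig(width=int(w))
        matrix = FeatureMatrix.concat([
            extract_windows(chain_features[cid], chain_labels[cid], chain_id=cid, config=cfg)
            for cid in chain_features
        ])
        result = cross_validate(matrix, train_config)
        records.append({"width": int(w), "ACC": result.pooled.acc, "AUC": result.pooled.auc})
    df = pd.DataFrame(records)
    df.attrs["best_width"] = int(df.loc[df["AUC"].idxmax(), "width"])
    return df
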