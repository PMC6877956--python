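"""Sliding-window assembly of per-residue features into training vectors.

Every residue of a chain becomes the center of one window of odd width ``w``:
the center's 44 feature values flanked by the features of the ``(w - 1) / 2``
residues on each side. Positions past either terminus are filled with all-zero
44-blocks (the one-hot block summing to 0 marks padding). The window's label
is the binding label of its center residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import ROW_WIDTH


@dataclass(frozen=True)
class WindowConfig:
    width: int = 15
    padding_policy: str = "zero"

    def __post_init__(self):
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"window width must be odd and >= 1, got {self.width}")
        if self.padding_policy != "zero":
            raise ValueError("only zero padding is shipped")


@dataclass
class FeatureMatrix:
    """N windowed feature rows with labels and (chain, position) provenance."""

    rows: np.ndarray          # (N, w * 44)
    labels: np.ndarray        # (N,) of {0, 1}
    chain_ids: np.ndarray     # (N,) str
    positions: np.ndarray     # (N,) 1-based center positions
    window_config: WindowConfig = field(default_factory=WindowConfig)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=int)
        n = self.rows.shape[0]
        if not (len(self.labels) == len(self.chain_ids) == len(self.positions) == n):
            raise ValueError("rows/labels/provenance lengths disagree")
        expected = self.window_config.width * ROW_WIDTH
        if n and self.rows.shape[1] != expected:
            raise ValueError(
                f"row width {self.rows.shape[1]} != w*44 = {expected}"
            )

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices)
        return FeatureMatrix(
            rows=self.rows[indices],
            labels=self.labels[indices],
            chain_ids=self.chain_ids[indices],
            positions=self.positions[indices],
            window_config=self.window_config,
        )

    @classmethod
    def concat(cls, matrices) -> "FeatureMatrix":
        matrices = list(matrices)
        if not matrices:
            raise ValueError("nothing to concatenate")
        cfg = matrices[0].window_config
        if any(m.window_config != cfg for m in matrices):
            raise ValueError("window configs differ between matrices")
        return cls(
            rows=np.vstack([m.rows for m in matrices]),
            labels=np.concatenate([m.labels for m in matrices]),
            chain_ids=np.concatenate([m.chain_ids for m in matrices]),
            positions=np.concatenate([m.positions for m in matrices]),
            window_config=cfg,
        )

    def save(self, path) -> None:
        """Portable container: npz arrays + a JSON sidecar with the config."""
        np.savez(
            path,
            rows=self.rows,
            labels=self.labels,
            chain_ids=self.chain_ids.astype(str),
            positions=self.positions,
        )
        sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"width": self.window_config.width,
                       "padding_policy": self.window_config.padding_policy}, fh)

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        data = np.load(path, allow_pickle=False)
        with open(path[:-4] + ".json") as fh:
            cfg = json.load(fh)
        return cls(
            rows=data["rows"],
            labels=data["labels"],
            chain_ids=data["chain_ids"].astype(object),
            positions=data["positions"],
            window_config=WindowConfig(**cfg),
        )

    def to_tsv(self, handle) -> None:
        for cid, pos, label, row in zip(self.chain_ids, self.positions, self.labels, self.rows):
            values = "\t".join(f"{v:g}" for v in row)
            handle.write(f"{cid}\t{pos}\t{int(label)}\t{values}\n")


def extract_windows(chain_features: np.ndarray, labels, chain_id: str = "",
                    config: WindowConfig = WindowConfig()) -> FeatureMatrix:
    """Window an (L, 44) per-residue feature array into an (L, w*44) matrix."""
    chain_features = np.asarray(chain_features, dtype=float)
    label_values = np.asarray(getattr(labels, "labels", labels), dtype=np.int8)
    cid = getattr(labels, "chain_id", None) or chain_id
    L = chain_features.shape[0]
    if L == 0:
        return FeatureMatrix(
            rows=np.empty((0, config.width * ROW_WIDTH)),
            labels=np.empty(0, dtype=np.int8),
            chain_ids=np.empty(0, dtype=object),
            positions=np.empty(0, dtype=int),
            window_config=config,
        )
    if chain_features.shape[1] != ROW_WIDTH:
        raise ValueError(f"chain features must be (L, {ROW_WIDTH})")
    if len(label_values) != L:
        raise ValueError("feature list and label lengths differ")
    half = (config.width - 1) // 2
    padded = np.vstack([
        np.zeros((half, ROW_WIDTH)),
        chain_features,
        np.zeros((half, ROW_WIDTH)),
    ])
    rows = np.stack([padded[i:i + config.width].ravel() for i in range(L)])
    return FeatureMatrix(
        rows=rows,
        labels=label_values,
        chain_ids=np.array([cid] * L, dtype=object),
        positions=np.arange(1, L + 1),
        window_config=config,
    )


def center_block(matrix: FeatureMatrix) -> np.ndarray:
    """The (N, 44) center-residue block of each window row."""
    half = (matrix.window_config.width - 1) // 2
    start = half * ROW_WIDTH
    return matrix.rows[:, start:start + ROW_WIDTH]
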