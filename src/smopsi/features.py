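"""Per-residue feature values: PSSM rows, physicochemical scales, one-hot identity.

Each residue is described by 44 numbers in a fixed order:

* columns 0-19  — the residue's PSSM row, in PSI-BLAST column order
  (``ARNDCQEGHILKMFPSTWYV``);
* columns 20-23 — four physicochemical values: hydrophilicity (Hopp-Woods,
  AAindex HOPT810101), hydrophobicity (Kyte-Doolittle hydropathy, AAindex
  KYTJ820101, overridable), electrostatic charge (+1 for R/H/K, -1 for D/E,
  0 otherwise) and side-chain hydrogen-bond donor count (AAindex FAUJ880109);
* columns 24-43 — one-hot residue identity, same alphabet order as the PSSM
  block.

The block layout is exposed as :data:`FEATURE_GROUPS` so downstream code
(feature-importance scoring, masking experiments) can address whole groups.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: PSI-BLAST PSSM column order; also the one-hot alphabet order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

STANDARD_AA = frozenset(PSSM_ALPHABET)

#: Width of one residue's feature row.
ROW_WIDTH = 44

#: Column indices of each feature group within a 44-wide residue row.
FEATURE_GROUPS: dict[str, np.ndarray] = {
    "pssm": np.arange(0, 20),
    "hydrophilicity": np.array([20]),
    "hydrophobicity": np.array([21]),
    "charge": np.array([22]),
    "hbond": np.array([23]),
    "onehot": np.arange(24, 44),
}

POSITIVE_AA = frozenset("RHK")
NEGATIVE_AA = frozenset("DE")


class PssmParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""


@dataclass(frozen=True)
class Pssm:
    """An L x 20 position-specific scoring matrix for one chain."""

    chain_id: str
    matrix: np.ndarray  # (L, 20) float
    sequence: str  # residue letters as read from the file
    column_alphabet: str = PSSM_ALPHABET

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got {m.shape}")
        if m.shape[0] != len(self.sequence):
            raise ValueError("PSSM row count does not match sequence length")
        if sorted(self.column_alphabet) != sorted(PSSM_ALPHABET):
            raise ValueError("column alphabet is not a permutation of the 20 letters")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PssmConfig:
    """Parameters for the external profile-search tool (metadata for provenance)."""

    e_value: float = 0.001
    iterations: int = 3
    database: str = "nr"

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def read_pssm(pssm_text: str, chain_id: str = "") -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM.

    Accepts both the full 40-column dialect (20 substitution scores followed
    by 20 weighted percentages) and a minimal 20-column dialect; only the
    first 20 score columns are kept.
    """
    if not pssm_text.strip():
        raise PssmParseError("empty PSSM file")
    letters: list[str] = []
    rows: list[list[float]] = []
    alphabet: str | None = None
    for lineno, line in enumerate(pssm_text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if alphabet is None:
            # header line: 20 (or 40) single residue letters
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                alphabet = "".join(tokens[:20])
            continue
        if not tokens[0].lstrip("-").isdigit():
            continue  # trailing statistics block
        if len(tokens) < 2 or len(tokens[1]) != 1:
            continue
        scores = tokens[2:22]
        if len(scores) != 20:
            raise PssmParseError(
                f"line {lineno}: expected 20 score fields, got {len(scores)}"
            )
        try:
            rows.append([float(s) for s in scores])
        except ValueError as exc:
            raise PssmParseError(f"line {lineno}: non-numeric score field") from exc
        letters.append(tokens[1])
    if alphabet is None or not rows:
        raise PssmParseError("no PSSM header/data rows found")
    return Pssm(chain_id=chain_id, matrix=np.array(rows), sequence="".join(letters),
                column_alphabet=alphabet)


def write_pssm(pssm: Pssm) -> str:
    """Render a :class:`Pssm` in the ASCII dialect :func:`read_pssm` reads."""
    lines = ["", "Last position-specific scoring matrix computed", ""]
    lines.append("            " + "   ".join(pssm.column_alphabet))
    for i, (letter, row) in enumerate(zip(pssm.sequence, pssm.matrix), start=1):
        scores = " ".join(f"{int(round(v)):>3d}" for v in row)
        lines.append(f"{i:>5d} {letter}   {scores}")
    lines.append("")
    return "\n".join(lines)


def run_pssm_tool(fasta_path, out_path, config: PssmConfig = PssmConfig(),
                  executable: str = "psiblast", dry_run: bool = False):
    """Build (and optionally run) the external profile-search command.

    Returns the argument list when ``dry_run`` is true; otherwise runs the
    tool and returns the output PSSM path. Tests never execute the tool.
    """
    args = [
        executable,
        "-query", str(fasta_path),
        "-db", config.database,
        "-evalue", str(config.e_value),
        "-num_iterations", str(config.iterations),
        "-out_ascii_pssm", str(out_path),
    ]
    if dry_run:
        return args
    if shutil.which(executable) is None:
        raise FileNotFoundError(
            f"{executable!r} not found on PATH; supply precomputed ASCII PSSM "
            "files (one per chain) instead of running the search tool"
        )
    import subprocess

    subprocess.run(args, check=True)
    return str(out_path)


def charge_value(residue_letter: str) -> int:
    """Electrostatic charge of a residue: R/H/K -> +1, D/E -> -1, else 0."""
    if residue_letter not in STANDARD_AA:
        raise ValueError(f"unknown residue letter {residue_letter!r}")
    if residue_letter in POSITIVE_AA:
        return 1
    if residue_letter in NEGATIVE_AA:
        return -1
    return 0


def parse_aaindex(text: str) -> dict[str, float]:
    """Parse one AAindex flat-file entry into a letter -> value map.

    The ``I`` line names the residues in two rows of ten (``A/L R/K ...``);
    the two following numeric lines carry the values.
    """
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if line.startswith("I "):
            pairs = line[1:].split()
            first = [p.split("/")[0] for p in pairs]
            second = [p.split("/")[1] for p in pairs]
            row1 = [float(v) for v in lines[i + 1].split()]
            row2 = [float(v) for v in lines[i + 2].split()]
            if len(row1) != 10 or len(row2) != 10:
                raise ValueError("AAindex entry does not have 2 x 10 values")
            values = dict(zip(first + second, row1 + row2))
            if set(values) != STANDARD_AA:
                raise ValueError("AAindex entry does not cover the 20 standard letters")
            return values
    raise ValueError("no 'I' line found in AAindex entry")


def _load_packaged_scale(filename: str) -> dict[str, float]:
    text = resources.files("smopsi.data").joinpath(filename).read_text()
    return parse_aaindex(text)


@dataclass(frozen=True)
class PhysChemScales:
    """The four physicochemical property maps used in the feature rows."""

    hydrophilicity: dict = field(default_factory=lambda: _load_packaged_scale("hopt810101.txt"))
    hydrophobicity: dict = field(default_factory=lambda: _load_packaged_scale("kytj820101.txt"))
    hbond: dict = field(default_factory=lambda: _load_packaged_scale("fauj880109.txt"))
    charge: dict = field(default_factory=lambda: {a: float(charge_value(a)) for a in PSSM_ALPHABET})

    def __post_init__(self):
        for name in ("hydrophilicity", "hydrophobicity", "hbond", "charge"):
            m = getattr(self, name)
            if set(m) != STANDARD_AA:
                raise ValueError(f"{name} scale does not cover the 20 standard letters")

    @classmethod
    def with_hydrophobicity_file(cls, path) -> "PhysChemScales":
        """Use an alternative AAindex-format hydrophobicity entry."""
        with open(path) as fh:
            return cls(hydrophobicity=parse_aaindex(fh.read()))


def logistic(x):
    """Optional squashing 1 / (1 + e^-x) for raw PSSM scores."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def residue_feature_row(residue_letter: str, pssm_row, scales: PhysChemScales,
                        squash_pssm: bool = False) -> np.ndarray:
    """Assemble one residue's 44-value feature row (PSSM, physchem, one-hot)."""
    pssm_row = np.asarray(pssm_row, dtype=float)
    if pssm_row.shape != (20,):
        raise ValueError(f"PSSM row must have 20 values, got {pssm_row.shape}")
    if residue_letter not in STANDARD_AA:
        raise ValueError(f"unknown residue letter {residue_letter!r}")
    row = np.zeros(ROW_WIDTH)
    row[0:20] = logistic(pssm_row) if squash_pssm else pssm_row
    row[20] = scales.hydrophilicity[residue_letter]
    row[21] = scales.hydrophobicity[residue_letter]
    row[22] = scales.charge[residue_letter]
    row[23] = scales.hbond[residue_letter]
    row[24 + PSSM_ALPHABET.index(residue_letter)] = 1.0
    return row


def chain_feature_rows(sequence: str, pssm: Pssm, scales: PhysChemScales | None = None,
                       squash_pssm: bool = False) -> np.ndarray:
    """Stack :func:`residue_feature_row` over a chain; returns an (L, 44) array.

    The chain sequence is cross-checked against the letters read from the
    PSSM file.
    """
    if scales is None:
        scales = PhysChemScales()
    if len(sequence) != len(pssm):
        raise ValueError(
            f"sequence length {len(sequence)} != PSSM rows {len(pssm)}"
        )
    if pssm.sequence and pssm.sequence != sequence:
        raise ValueError("PSSM residue letters disagree with the chain sequence")
    return np.vstack([
        residue_feature_row(letter, row, scales, squash_pssm=squash_pssm)
        for letter, row in zip(sequence, pssm.matrix)
    ])
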