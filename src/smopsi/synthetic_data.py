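"""Synthetic benchmark generator with planted, controllable signal.

Produces a self-consistent bundle of toy inputs — PDB-format structures,
PSI-BLAST-dialect PSSM files, FASTA and ground-truth labels — so the whole
pipeline is testable without downloads:

* Geometry: C-alpha atoms on a straight 3.8-Angstrom-spaced trace. Each
  planted binding residue gets one ligand atom 3.3 A above its C-alpha, so
  the 3.5 A contact rule recovers the planted labels exactly, while the
  nearest nonbinding C-alpha is sqrt(3.8^2 + 3.3^2) ~ 5.03 A away.
* PSSM signal: scores are discretized normals (sd 2); rows at binding
  positions (and ``spatial_extent`` flanking positions) are mean-shifted by
  ``signal_strength`` on a fixed subset of columns, confining the learnable
  signal to the PSSM feature block.
* Composition: letters at binding positions are drawn with excess probability
  ``composition_bias`` from the hydrophilic/charged set ``RKHDESTNQ``.

Everything is deterministic given the seed; identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .features import PSSM_ALPHABET, Pssm, write_pssm

AA_1TO3 = {one: three.upper() for one, three in protein_letters_1to3.items()}

HYDROPHILIC_SET = "RKHDESTNQ"

#: PSSM columns carrying the planted class signal.
SIGNAL_COLUMNS = tuple(range(8))

CA_SPACING = 3.8       # Angstrom between consecutive C-alpha atoms
LIGAND_OFFSET = 3.3    # Angstrom above a binding residue's C-alpha (< 3.5)
PSSM_SD = 2.0
PSSM_CLIP = 12


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_chains: int = 50
    chain_length: tuple[int, int] = (80, 160)
    binding_fraction: float = 0.10
    signal_strength: float = 0.0    # PSSM mean shift, score units
    composition_bias: float = 0.0   # excess hydrophilic probability at sites
    spatial_extent: int = 0         # flanking residues sharing the PSSM signal
    het_code: str = "ATP"

    def __post_init__(self):
        if not 0 < self.binding_fraction < 1:
            raise ValueError("binding_fraction must be in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0 <= self.composition_bias <= 1:
            raise ValueError("composition_bias must be in [0, 1]")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        lo, hi = self.chain_length
        if lo < 3 or hi < lo:
            raise ValueError("chain_length must satisfy 3 <= lo <= hi")


#: Named presets used throughout the tests: identical study conditions except
#: for the planted effect sizes.
PRESETS = {
    "null": dict(signal_strength=0.0, composition_bias=0.0),
    "weak": dict(signal_strength=1.0, composition_bias=0.10),
    "strong": dict(signal_strength=4.0, composition_bias=0.40),
}


def preset_config(name: str, seed: int, n_chains: int = 50, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SynthConfig(seed=seed, n_chains=n_chains, **{**PRESETS[name], **overrides})


@dataclass
class SynthBundle:
    """All generated inputs plus the planted ground truth, keyed by chain id."""

    config: SynthConfig
    fasta_text: str
    pdb_texts: dict[str, str]
    pssm_texts: dict[str, str]
    labels: dict[str, np.ndarray]
    sequences: dict[str, str] = field(default_factory=dict)

    def chain_ids(self) -> list[str]:
        return list(self.pdb_texts)


def _sample_sequence(rng, length: int, binding: np.ndarray, bias: float) -> str:
    letters = []
    hydrophilic = list(HYDROPHILIC_SET)
    for i in range(length):
        if binding[i] and rng.random() < bias:
            letters.append(hydrophilic[rng.integers(len(hydrophilic))])
        else:
            letters.append(PSSM_ALPHABET[rng.integers(20)])
    return "".join(letters)


def _sample_pssm(rng, length: int, signal_rows: np.ndarray, strength: float) -> np.ndarray:
    scores = rng.normal(0.0, PSSM_SD, size=(length, 20))
    scores[np.ix_(np.flatnonzero(signal_rows), np.array(SIGNAL_COLUMNS))] += strength
    return np.clip(np.rint(scores), -PSSM_CLIP, PSSM_CLIP)


def _pdb_text(chain_id_label: str, sequence: str, binding: np.ndarray,
              het_code: str) -> str:
    """Fixed-width PDB records: one CA per residue on a straight trace, one
    ligand atom above each binding residue."""
    lines = [f"HEADER    SYNTHETIC CHAIN {chain_id_label}"]
    serial = 1
    for i, letter in enumerate(sequence):
        resname = AA_1TO3[letter]
        x = CA_SPACING * i
        lines.append(
            f"ATOM  {serial:>5d}  CA  {resname:>3s} A{i + 1:>4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{'C':>2s}"
        )
        serial += 1
    lines.append(f"TER   {serial:>5d}      "
                 f"{AA_1TO3[sequence[-1]]:>3s} A{len(sequence):>4d}")
    serial += 1
    for j, pos in enumerate(np.flatnonzero(binding), start=1):
        x = CA_SPACING * int(pos)
        lines.append(
            f"HETATM{serial:>5d}  P{j % 10}  {het_code:>3s} A{900 + j:>4d}    "
            f"{x:8.3f}{0.0:8.3f}{LIGAND_OFFSET:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{'P':>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_bundle(config: SynthConfig) -> SynthBundle:
    """Deterministically generate the full fixture bundle for one config."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.chain_length
    fasta_lines: list[str] = []
    pdb_texts: dict[str, str] = {}
    pssm_texts: dict[str, str] = {}
    labels: dict[str, np.ndarray] = {}
    sequences: dict[str, str] = {}
    for c in range(config.n_chains):
        cid = f"syn{c:04d}"
        length = int(rng.integers(lo, hi + 1))
        n_bind = max(1, round(config.binding_fraction * length))
        if n_bind >= length:
            raise ValueError("binding_fraction too high for this chain length")
        binding = np.zeros(length, dtype=np.int8)
        binding[rng.choice(length, size=n_bind, replace=False)] = 1

        sequence = _sample_sequence(rng, length, binding, config.composition_bias)
        signal_rows = binding.astype(bool).copy()
        for k in range(1, config.spatial_extent + 1):
            signal_rows[k:] |= binding[:-k].astype(bool)
            signal_rows[:-k] |= binding[k:].astype(bool)
        matrix = _sample_pssm(rng, length, signal_rows, config.signal_strength)

        fasta_lines.append(f">{cid}\n{sequence}")
        pdb_texts[cid] = _pdb_text(cid, sequence, binding, config.het_code)
        pssm_texts[cid] = write_pssm(Pssm(chain_id=cid, matrix=matrix, sequence=sequence))
        labels[cid] = binding
        sequences[cid] = sequence
    return SynthBundle(config=config, fasta_text="\n".join(fasta_lines) + "\n",
                       pdb_texts=pdb_texts, pssm_texts=pssm_texts,
                       labels=labels, sequences=sequences)


def write_bundle(bundle: SynthBundle, directory) -> Path:
    """Lay the bundle out on disk the way the CLI expects.

    ``<id>.pdb`` and ``<id>.pssm`` per chain, plus ``sequences.fasta``,
    ``labels.tsv`` and a JSON manifest. Round-trips through the real parsers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid in bundle.chain_ids():
        (directory / f"{cid}.pdb").write_text(bundle.pdb_texts[cid])
        (directory / f"{cid}.pssm").write_text(bundle.pssm_texts[cid])
    (directory / "sequences.fasta").write_text(bundle.fasta_text)
    with open(directory / "labels.tsv", "w") as fh:
        for cid in bundle.chain_ids():
            seq = bundle.sequences[cid]
            for pos, (letter, lab) in enumerate(zip(seq, bundle.labels[cid]), start=1):
                fh.write(f"{cid}\t{pos}\t{letter}\t{int(lab)}\n")
    manifest = {
        "n_chains": bundle.config.n_chains,
        "seed": bundle.config.seed,
        "het_code": bundle.config.het_code,
        "signal_strength": bundle.config.signal_strength,
        "composition_bias": bundle.config.composition_bias,
        "binding_fraction": bundle.config.binding_fraction,
        "spatial_extent": bundle.config.spatial_extent,
        "chain_ids": bundle.chain_ids(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return directory


def load_bundle(directory) -> SynthBundle:
    """Re-read a written bundle (texts only; config partially reconstructed)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = SynthConfig(
        seed=manifest["seed"], n_chains=manifest["n_chains"],
        binding_fraction=manifest["binding_fraction"],
        signal_strength=manifest["signal_strength"],
        composition_bias=manifest["composition_bias"],
        spatial_extent=manifest["spatial_extent"],
        het_code=manifest["het_code"],
    )
    pdb_texts, pssm_texts, labels, sequences = {}, {}, {}, {}
    for cid in manifest["chain_ids"]:
        pdb_texts[cid] = (directory / f"{cid}.pdb").read_text()
        pssm_texts[cid] = (directory / f"{cid}.pssm").read_text()
    for line in (directory / "labels.tsv").read_text().splitlines():
        cid, pos, letter, lab = line.split("\t")
        labels.setdefault(cid, []).append(int(lab))
        sequences[cid] = sequences.get(cid, "") + letter
    labels = {cid: np.array(v, dtype=np.int8) for cid, v in labels.items()}
    fasta = (directory / "sequences.fasta").read_text()
    return SynthBundle(config=config, fasta_text=fasta, pdb_texts=pdb_texts,
                       pssm_texts=pssm_texts, labels=labels, sequences=sequences)
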