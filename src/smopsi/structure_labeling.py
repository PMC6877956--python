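"""PDB parsing, ligand extraction, contact-based binding labels, dataset curation.

A residue is a *binding residue* when its reference atom lies strictly within
a distance threshold (default 3.5 Angstrom) of any atom of a co-resolved
small-molecule ligand; otherwise it is a nonbinding residue. The reference
atom is the C-alpha by default (``central_atom`` mode); ``any_heavy_atom``
mode takes the minimum over all of the residue's heavy atoms instead, which
is the more permissive reading and yields a superset of the C-alpha labels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

from .features import STANDARD_AA

#: Common nonstandard residues mapped onto a standard parent; anything else
#: is dropped from the chain (with a warning) so sequence and coordinates
#: stay aligned.
NONSTANDARD_MAP = {
    "MSE": "M", "SEC": "C", "HYP": "P", "SEP": "S", "TPO": "T",
    "PTR": "Y", "MLY": "K", "CSO": "C", "PCA": "E",
}


class StructureParseError(ValueError):
    """Raised for malformed PDB input."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Residue:
    position: int  # 1-based index within the chain
    letter: str
    atoms: tuple[Atom, ...]


@dataclass
class StructureChain:
    """One polymer chain: sequence plus per-residue atom coordinates."""

    chain_id: str
    sequence: str
    residues: list[Residue]

    def __post_init__(self):
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence and residue list lengths differ")
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("residue positions must be strictly increasing")
        if any(not r.atoms for r in self.residues):
            raise ValueError("every residue must retain at least one atom")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LigandRecord:
    het_code: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("ligand record must contain at least one atom")


@dataclass(frozen=True)
class LabelConfig:
    """Contact rule: strictly-less-than distance to any ligand atom."""

    distance_threshold: float = 3.5
    atom_mode: str = "central_atom"  # or "any_heavy_atom"

    def __post_init__(self):
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if self.atom_mode not in ("central_atom", "any_heavy_atom"):
            raise ValueError(f"unknown atom_mode {self.atom_mode!r}")


@dataclass
class BindingLabels:
    chain_id: str
    labels: np.ndarray  # (L,) of {0, 1}
    config_used: LabelConfig = field(default_factory=LabelConfig)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass(frozen=True)
class CurationConfig:
    max_identity: float = 0.30
    min_length: int = 40

    def __post_init__(self):
        if not 0 < self.max_identity <= 1:
            raise ValueError("max_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def parse_structure(pdb_text: str, het_codes=(), structure_id: str = "struct"):
    """Parse PDB-format text into chains and requested ligand records.

    Waters are always excluded; alternate locations resolve to the conformer
    Biopython selects (first/highest occupancy). Returns
    ``(chains, ligands)``.
    """
    het_codes = {c.upper() for c in het_codes}
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"malformed PDB input: {exc}") from exc
    model = next(structure.get_models(), None)
    if model is None:
        raise StructureParseError("no model found in PDB input")

    chains: list[StructureChain] = []
    ligands: list[LigandRecord] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, _, _ = bio_res.id
            resname = bio_res.get_resname().strip()
            if hetflag.strip():  # HETATM group
                if resname == "HOH" or resname not in het_codes:
                    continue
                atoms = tuple(
                    Atom(a.get_name(), (a.element or "").strip(), *map(float, a.coord))
                    for a in bio_res.get_atoms()
                )
                ligands.append(LigandRecord(het_code=resname, atoms=atoms))
                continue
            letter = protein_letters_3to1.get(resname, NONSTANDARD_MAP.get(resname))
            if letter is None or letter not in STANDARD_AA:
                warnings.warn(
                    f"dropping nonstandard residue {resname} in chain {bio_chain.id}"
                )
                continue
            atoms = tuple(
                Atom(a.get_name(), (a.element or "").strip(), *map(float, a.coord))
                for a in bio_res.get_atoms()
            )
            if not atoms:
                continue
            residues.append(Residue(position=len(residues) + 1, letter=letter, atoms=atoms))
        if residues:
            chains.append(StructureChain(
                chain_id=str(bio_chain.id),
                sequence="".join(r.letter for r in residues),
                residues=residues,
            ))
    if not chains:
        raise StructureParseError("no polymer chain with standard residues found")
    return chains, ligands


def _reference_coords(residue: Residue, atom_mode: str) -> np.ndarray | None:
    """Coordinates the contact rule measures from; None if unavailable."""
    if atom_mode == "central_atom":
        for atom in residue.atoms:
            if atom.name.strip() == "CA":
                return atom.coord[None, :]
        return None
    heavy = [a.coord for a in residue.atoms if a.element.upper() != "H"]
    return np.array(heavy) if heavy else None


def label_binding_residues(chain: StructureChain, ligands,
                           config: LabelConfig = LabelConfig(),
                           missing_reference: str = "warn") -> BindingLabels:
    """Label each residue 1 iff its reference atom(s) lie < threshold from any
    ligand atom (union over all ligand copies).

    ``missing_reference`` controls what happens when a residue lacks its
    reference atom (e.g. no C-alpha in ``central_atom`` mode): ``"warn"``
    labels it 0 with a warning, ``"error"`` raises.
    """
    if not len(chain):
        raise ValueError("chain is empty")
    ligand_coords = np.array([a.coord for lig in ligands for a in lig.atoms])
    if ligand_coords.size == 0:
        raise ValueError("no ligand atoms to measure contacts against")
    labels = np.zeros(len(chain), dtype=np.int8)
    for i, residue in enumerate(chain.residues):
        ref = _reference_coords(residue, config.atom_mode)
        if ref is None:
            if missing_reference == "error":
                raise ValueError(
                    f"residue {residue.position} lacks a reference atom "
                    f"for mode {config.atom_mode}"
                )
            warnings.warn(
                f"residue {residue.position} in chain {chain.chain_id} lacks a "
                f"reference atom; labeled nonbinding"
            )
            continue
        if cdist(ref, ligand_coords).min() < config.distance_threshold:
            labels[i] = 1
    return BindingLabels(chain_id=chain.chain_id, labels=labels, config_used=config)


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global alignment identity = matches / alignment length."""
    if not seq_a or not seq_b:
        return 0.0
    alignment = _identity_aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def curate_chains(chains, config: CurationConfig = CurationConfig()) -> list[str]:
    """Greedy redundancy/length filter over ``(id, sequence)`` pairs.

    Chains shorter than ``min_length`` are removed; the survivors are scanned
    longest-first (ties broken lexicographically by id) and a chain is kept
    only if its identity to every already-kept chain is below
    ``max_identity``. Returns the retained ids in input order.
    """
    candidates = [(cid, seq) for cid, seq in chains if len(seq) >= config.min_length]
    order = sorted(candidates, key=lambda item: (-len(item[1]), item[0]))
    kept: list[tuple[str, str]] = []
    for cid, seq in order:
        if all(pairwise_identity(seq, kseq) < config.max_identity for _, kseq in kept):
            kept.append((cid, seq))
    kept_ids = {cid for cid, _ in kept}
    return [cid for cid, _ in chains if cid in kept_ids]


def write_labels_tsv(chain: StructureChain, labels: BindingLabels, handle) -> None:
    """Write ``chain_id, position (1-based), residue letter, label`` rows."""
    for residue, label in zip(chain.residues, labels.labels):
        handle.write(f"{chain.chain_id}\t{residue.position}\t{residue.letter}\t{int(label)}\n")
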