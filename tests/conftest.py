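import numpy as np
import pytest

from smopsi.features import PhysChemScales
from smopsi.model import TrainConfig, cross_validate, train
from smopsi.pipeline import featurize_bundle
from smopsi.synthetic_data import generate_bundle, preset_config
from smopsi.windows import WindowConfig

TOY_PDB = """\
HEADER    TOY COMPLEX
ATOM      1  N   GLY A   1      -1.000   0.500   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  LYS A   3       7.600   0.000   0.000  1.00  0.00           C
TER       5      LYS A   3
HETATM    6  PA  ATP A 901       0.000   0.000   3.000  1.00  0.00           P
HETATM    7  O1  HOH A 902       0.100   0.000   3.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture(scope="session")
def scales():
    return PhysChemScales()


@pytest.fixture(scope="session")
def strong_bundle():
    """Small strong-signal benchmark shared across model/analysis tests."""
    return generate_bundle(preset_config("strong", seed=11, n_chains=25))


@pytest.fixture(scope="session")
def strong_matrix(strong_bundle):
    matrix, _, _ = featurize_bundle(strong_bundle, WindowConfig(width=15))
    return matrix


@pytest.fixture(scope="session")
def strong_ensemble(strong_matrix):
    return train(strong_matrix, TrainConfig(n_downsample_repeats=3, random_seed=5))


@pytest.fixture(scope="session")
def strong_cv(strong_matrix):
    return cross_validate(strong_matrix, TrainConfig(n_downsample_repeats=3,
                                                     random_seed=5, cv_folds=5))


def random_geometry_case(rng):
    """One random chain + ligand coordinate set for labeling oracle tests."""
    from smopsi.structure_labeling import Atom, LigandRecord, Residue, StructureChain

    length = int(rng.integers(3, 15))
    residues = []
    for i in range(length):
        n_atoms = int(rng.integers(1, 4))
        coords = rng.uniform(-8, 8, size=(n_atoms, 3))
        atoms = [Atom("CA" if a == 0 else f"CB{a}", "C", *coords[a])
                 for a in range(n_atoms)]
        residues.append(Residue(position=i + 1, letter="A", atoms=tuple(atoms)))
    chain = StructureChain(chain_id="Z", sequence="A" * length, residues=residues)
    n_lig = int(rng.integers(1, 5))
    lig = LigandRecord(het_code="LIG", atoms=tuple(
        Atom(f"X{a}", "P", *rng.uniform(-8, 8, size=3)) for a in range(n_lig)
    ))
    return chain, [lig]
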