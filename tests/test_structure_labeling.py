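import numpy as np
import pytest

from smopsi.structure_labeling import (
    Atom, BindingLabels, CurationConfig, LabelConfig, LigandRecord, Residue,
    StructureChain, StructureParseError, curate_chains, label_binding_residues,
    pairwise_identity, parse_structure, write_labels_tsv,
)

from conftest import random_geometry_case


def make_ca_chain(coords, letters=None):
    coords = np.asarray(coords, dtype=float)
    letters = letters or "A" * len(coords)
    residues = [
        Residue(position=i + 1, letter=letters[i],
                atoms=(Atom("CA", "C", *coords[i]),))
        for i in range(len(coords))
    ]
    return StructureChain(chain_id="A", sequence="".join(letters), residues=residues)


def single_atom_ligand(x, y, z, het="ATP"):
    return LigandRecord(het_code=het, atoms=(Atom("PA", "P", x, y, z),))


class TestParseStructure:
    def test_toy_fixture_yields_chain_and_ligand(self, toy_pdb_text):
        chains, ligands = parse_structure(toy_pdb_text, het_codes={"ATP"})
        assert len(chains) == 1
        chain = chains[0]
        assert chain.sequence == "GAK"
        assert len(chain) == 3
        assert [r.position for r in chain.residues] == [1, 2, 3]
        # residue 1 keeps both its N and CA atoms
        assert {a.name for a in chain.residues[0].atoms} == {"N", "CA"}
        assert len(ligands) == 1
        assert ligands[0].het_code == "ATP"
        np.testing.assert_allclose(ligands[0].atoms[0].coord, [0.0, 0.0, 3.0])

    def test_water_always_excluded(self, toy_pdb_text):
        _, ligands = parse_structure(toy_pdb_text, het_codes={"ATP", "HOH"})
        assert {l.het_code for l in ligands} == {"ATP"}

    def test_unrequested_het_codes_ignored(self, toy_pdb_text):
        _, ligands = parse_structure(toy_pdb_text, het_codes={"GDP"})
        assert ligands == []

    def test_no_het_codes_gives_empty_ligands(self, toy_pdb_text):
        _, ligands = parse_structure(toy_pdb_text, het_codes=set())
        assert ligands == []

    def test_malformed_coordinates_raise(self, toy_pdb_text):
        broken = toy_pdb_text.replace("       0.000   0.000   0.000",
                                      "       xx.xx   0.000   0.000")
        with pytest.raises(StructureParseError):
            parse_structure(broken, het_codes={"ATP"})

    def test_no_protein_chain_raises(self):
        with pytest.raises(StructureParseError):
            parse_structure("HEADER    EMPTY\nEND\n", het_codes=set())

    def test_nonstandard_mse_mapped_to_met(self, toy_pdb_text):
        text = toy_pdb_text.replace("CA  ALA A   2", "CA  MSE A   2")
        chains, _ = parse_structure(text, het_codes=set())
        assert chains[0].sequence == "GMK"


class TestLabelBindingResidues:
    def test_contact_under_threshold_labels_first_residue(self):
        chain = make_ca_chain([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        labels = label_binding_residues(chain, [single_atom_ligand(0, 0, 3.0)])
        assert labels.labels.tolist() == [1, 0, 0]

    def test_distant_ligand_gives_all_zero(self):
        chain = make_ca_chain([(0, 0, 0), (3.8, 0, 0)])
        labels = label_binding_residues(chain, [single_atom_ligand(500, 0, 0)])
        assert labels.labels.tolist() == [0, 0]

    def test_threshold_is_strict_less_than(self):
        chain = make_ca_chain([(0, 0, 0)])
        at_threshold = label_binding_residues(chain, [single_atom_ligand(0, 0, 3.5)])
        assert at_threshold.labels.tolist() == [0]
        just_inside = label_binding_residues(chain, [single_atom_ligand(0, 0, 3.499)])
        assert just_inside.labels.tolist() == [1]

    def test_union_over_multiple_ligand_copies(self):
        chain = make_ca_chain([(0, 0, 0), (3.8, 0, 0)])
        ligands = [single_atom_ligand(0, 0, 1.0), single_atom_ligand(3.8, 0, 1.0)]
        labels = label_binding_residues(chain, ligands)
        assert labels.labels.tolist() == [1, 1]

    def test_missing_ca_warns_and_labels_zero(self):
        residues = [Residue(position=1, letter="A",
                            atoms=(Atom("CB", "C", 0, 0, 0),))]
        chain = StructureChain(chain_id="A", sequence="A", residues=residues)
        with pytest.warns(UserWarning):
            labels = label_binding_residues(chain, [single_atom_ligand(0, 0, 1.0)])
        assert labels.labels.tolist() == [0]
        with pytest.raises(ValueError):
            label_binding_residues(chain, [single_atom_ligand(0, 0, 1.0)],
                                   missing_reference="error")

    def test_no_ligand_atoms_raises(self):
        chain = make_ca_chain([(0, 0, 0)])
        with pytest.raises(ValueError):
            label_binding_residues(chain, [])


def brute_force_labels(chain, ligands, threshold, atom_mode):
    """Independent double loop over residue reference atoms x ligand atoms."""
    out = []
    for residue in chain.residues:
        if atom_mode == "central_atom":
            ref = [a for a in residue.atoms if a.name == "CA"]
        else:
            ref = [a for a in residue.atoms if a.element != "H"]
        hit = 0
        for atom in ref:
            for lig in ligands:
                for latom in lig.atoms:
                    d = np.sqrt((atom.x - latom.x) ** 2 + (atom.y - latom.y) ** 2
                                + (atom.z - latom.z) ** 2)
                    if d < threshold:
                        hit = 1
        out.append(hit)
    return out


@pytest.mark.parametrize("atom_mode", ["central_atom", "any_heavy_atom"])
def test_labeling_matches_brute_force_oracle(atom_mode):
    """Contact labels agree exactly with an all-pairs distance double loop
    on 120 random coordinate sets."""
    rng = np.random.default_rng(42)
    for _ in range(120):
        chain, ligands = random_geometry_case(rng)
        threshold = float(rng.uniform(1.0, 12.0))
        config = LabelConfig(distance_threshold=threshold, atom_mode=atom_mode)
        got = label_binding_residues(chain, ligands, config).labels.tolist()
        assert got == brute_force_labels(chain, ligands, threshold, atom_mode)


def test_raising_threshold_never_unlabels():
    rng = np.random.default_rng(7)
    for _ in range(50):
        chain, ligands = random_geometry_case(rng)
        t1, t2 = sorted(rng.uniform(1.0, 12.0, size=2))
        low = label_binding_residues(chain, ligands, LabelConfig(distance_threshold=t1))
        high = label_binding_residues(chain, ligands, LabelConfig(distance_threshold=t2))
        assert (high.labels >= low.labels).all()


def test_any_heavy_atom_labels_superset_of_central():
    rng = np.random.default_rng(13)
    for _ in range(50):
        chain, ligands = random_geometry_case(rng)
        central = label_binding_residues(
            chain, ligands, LabelConfig(atom_mode="central_atom"))
        any_heavy = label_binding_residues(
            chain, ligands, LabelConfig(atom_mode="any_heavy_atom"))
        assert (any_heavy.labels >= central.labels).all()


class TestCurateChains:
    def test_identical_sequences_collapse(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        kept = curate_chains([("a", seq), ("b", seq)])
        assert kept == ["a"]

    def test_short_chain_removed(self):
        kept = curate_chains([("short", "A" * 39), ("long", "ACDEFGHIKL" * 5)])
        assert kept == ["long"]

    def test_similar_pair_keeps_longest_plus_distinct(self):
        rng = np.random.default_rng(3)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(alphabet), size=60))
        b = a[:57] + "WWW"  # ~95% identical to a, same length -> tie on id
        c = "".join(rng.choice(list("PG"), size=60))
        assert pairwise_identity(a, b) > 0.9
        assert pairwise_identity(a, c) < 0.30
        kept = curate_chains([("a", a), ("b", b), ("c", c)])
        assert kept == ["a", "c"]

    def test_retained_set_respects_identity_bound(self):
        rng = np.random.default_rng(9)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(alphabet, size=50))
        chains = [("c0", base)]
        for i in range(1, 8):
            seq = list(base)
            for j in rng.choice(50, size=int(rng.integers(1, 50)), replace=False):
                seq[j] = str(rng.choice(alphabet))
            chains.append((f"c{i}", "".join(seq)))
        config = CurationConfig(max_identity=0.5)
        kept = curate_chains(chains, config)
        kept_seqs = [s for cid, s in chains if cid in kept]
        for i in range(len(kept_seqs)):
            for j in range(i + 1, len(kept_seqs)):
                assert pairwise_identity(kept_seqs[i], kept_seqs[j]) < 0.5

    def test_empty_input_gives_empty_output(self):
        assert curate_chains([]) == []


def test_write_labels_tsv_round_trip(tmp_path):
    chain = make_ca_chain([(0, 0, 0), (3.8, 0, 0)], letters="GK")
    labels = label_binding_residues(chain, [single_atom_ligand(0, 0, 1.0)])
    path = tmp_path / "labels.tsv"
    with open(path, "w") as fh:
        write_labels_tsv(chain, labels, fh)
    rows = [line.split("\t") for line in path.read_text().splitlines()]
    assert rows == [["A", "1", "G", "1"], ["A", "2", "K", "0"]]
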