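"""Structure model: PDB parsing/writing, bond perception, MOL2 export."""

from __future__ import annotations

import numpy as np
import pytest

from qmmmprep import FixtureSpec, assign_charges, parse_pdb, write_mol2_charges, \
    write_pdb
from qmmmprep.fixtures import build_fixture_model
from qmmmprep.structure import PDBParseError, brute_force_bonds, build_bond_graph


def test_parse_fixture_identifies_residues_and_ligand(std_files):
    model = parse_pdb(std_files[0])
    protein = [r for r in model.protein_residues if not r.is_cap]
    assert len(protein) == 5
    assert [r.resname for r in protein] == ["ALA", "ARG", "ALA", "ASP", "ALA"]
    assert len(model.ligand_residues) == 1
    assert model.ligand_residues[0].resname == "LIG"
    caps = [r for r in model.protein_residues if r.is_cap]
    assert {r.resname for r in caps} == {"ACE", "NME"}


def test_parse_preserves_atom_order_and_serials(std_files):
    model = parse_pdb(std_files[0])
    serials = [a.serial for r in model.residues for a in r.atoms]
    assert serials == sorted(serials)
    assert len(serials) == len(set(serials))


def test_element_inferred_when_column_missing(tmp_path):
    pdb = tmp_path / "noelem.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00\n"
        "ATOM      3 HB21 ALA A   1       2.000   1.000   0.000  1.00  0.00\n"
        "HETATM    4 CL    CL A   2       8.000   8.000   8.000  1.00  0.00\n"
        "END\n")
    model = parse_pdb(pdb)
    # independently hand-parsed expectation for each record
    expected = {1: "N", 2: "C", 3: "H", 4: "Cl"}
    for serial, element in expected.items():
        assert model.atom(serial).element == element


@pytest.mark.parametrize("content, match", [
    ("", "no ATOM"),
    ("ATOM      1  N   ALA A   1       0.000   bogus   0.000\nEND\n",
     "line 1"),
    ("ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
     "ATOM      1  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
     "END\n", "duplicate"),
])
def test_malformed_pdb_rejected(tmp_path, content, match):
    pdb = tmp_path / "bad.pdb"
    pdb.write_text(content)
    with pytest.raises(PDBParseError, match=match):
        parse_pdb(pdb)


def test_ala_template_bonds(std_model):
    model, _ = std_model
    ala = next(r for r in model.protein_residues if r.resname == "ALA")
    by_name = {a.name: a.serial for a in ala.atoms}
    expected_pairs = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                      ("N", "H"), ("CA", "HA"), ("CB", "HB1"), ("CB", "HB2"),
                      ("CB", "HB3")]
    for a, b in expected_pairs:
        assert by_name[b] in model.bonds.neighbors(by_name[a]), (a, b)


def test_peptide_bond_added_between_consecutive_residues(std_model):
    model, _ = std_model
    protein = [r for r in model.protein_residues if not r.is_cap]
    c1 = protein[0].atom("C")
    n2 = protein[1].atom("N")
    assert abs(np.linalg.norm(c1.coords - n2.coords) - 1.329) < 0.01
    assert n2.serial in model.bonds.neighbors(c1.serial)


def test_ligand_bonds_match_brute_force_oracle(std_model):
    model, _ = std_model
    lig = model.ligand_residues[0]
    serials = {a.serial for a in lig.atoms}
    graph_bonds = {frozenset((a, b)) for a, b in model.bonds.edges()
                   if a in serials and b in serials}
    oracle = {bond for bond in brute_force_bonds(model)
              if bond <= serials}
    assert graph_bonds == oracle
    assert len(graph_bonds) == len(lig.atoms) - 1  # acyclic 6-atom molecule


def test_bond_graph_matches_brute_force_oracle_and_is_symmetric():
    spec = FixtureSpec(n_residues=6, n_waters=3, seed=7)
    model, _ = build_fixture_model(spec)
    assert len(model.atoms) <= 200
    graph = {frozenset(e) for e in model.bonds.edges()}
    assert graph == brute_force_bonds(model)
    adj = model.bonds.adjacency
    for a, nbrs in adj.items():
        assert a not in nbrs
        for b in nbrs:
            assert a in adj[b]


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_pdb_round_trip_lossless(tmp_path, seed):
    spec = FixtureSpec(n_residues=4, n_waters=1, seed=seed)
    model, _ = build_fixture_model(spec)
    path = tmp_path / "rt.pdb"
    write_pdb(model, path)
    back = parse_pdb(path)
    assert len(back.atoms) == len(model.atoms)
    for serial, atom in model.atoms.items():
        b = back.atom(serial)
        assert b.name == atom.name
        assert b.residue_key == atom.residue_key
        np.testing.assert_allclose(b.coords, np.round(atom.coords, 3),
                                   atol=5e-4)
    assert [r.resseq for r in back.residues] == \
        [r.resseq for r in model.residues]


def test_mol2_export_counts_and_charge_conservation(charged_model, tmp_path):
    model = charged_model
    path = tmp_path / "charges.mol2"
    write_mol2_charges(model, path)
    lines = path.read_text().splitlines()
    nonligand = [a for r in model.residues if not r.is_ligand for a in r.atoms]
    header_count = int(lines[lines.index("@<TRIPOS>MOLECULE") + 2].split()[0])
    atom_lines = lines[lines.index("@<TRIPOS>ATOM") + 1:]
    assert header_count == len(nonligand) == len(atom_lines)
    total_written = sum(float(line.split()[-1]) for line in atom_lines)
    total_assigned = sum(a.charge for a in nonligand)
    assert abs(total_written - total_assigned) < 1e-6


def test_mol2_errors(tmp_path, std_model):
    model, charges = std_model
    with pytest.raises(ValueError, match="serials"):
        write_mol2_charges(model, tmp_path / "x.mol2")  # no charges assigned
    lig_only_model, _ = std_model
    lig_only_model.residues = [r for r in lig_only_model.residues
                               if r.is_ligand]
    lig_only_model.reindex()
    with pytest.raises(ValueError, match="no nonligand"):
        write_mol2_charges(lig_only_model, tmp_path / "y.mol2")
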