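"""QM-region carving: selection, cuts, shells, clash absorption, link atoms."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from qmmmprep import (FixtureSpec, LinkAtomParams, SeedSpec, absorb_clashes,
                      count_qm_atoms, place_cuts, place_link_atom,
                      select_residues)
from qmmmprep.fixtures import build_fixture_model
from qmmmprep.region import RegionError
from qmmmprep.structure import Atom

from conftest import build_charged


def bfs_shells_oracle(adjacency: dict[int, set[int]], q1: int,
                      mm_side: set[int]) -> tuple[set, set, set]:
    """Independent breadth-first 1/2/3-bond frontiers restricted to MM atoms."""
    seen = {q1}
    frontier = {q1}
    shells = []
    for _ in range(3):
        nxt = set()
        for s in frontier:
            for n in adjacency.get(s, ()):
                if n in mm_side and n not in seen:
                    nxt.add(n)
        shells.append(nxt)
        seen |= nxt
        frontier = nxt
    return tuple(shells)


def test_selection_matches_construction(charged_model):
    sel = select_residues(charged_model, SeedSpec(mode="whole_ligand"), 5.0)
    protein_keys = {r.key for r in charged_model.protein_residues}
    assert sel & protein_keys == {("A", 3, "")}


def test_tiny_cutoff_raises(charged_model):
    with pytest.raises(RegionError, match="cutoff"):
        select_residues(charged_model, SeedSpec(mode="whole_ligand"), 0.1)


def test_selection_nested_in_larger_cutoff(charged_model):
    """Selection at cutoff c is a subset of selection at c' > c, and both
    match a brute-force distance-matrix oracle."""
    seed = SeedSpec(mode="whole_ligand")
    lig_xyz = np.array([a.coords for r in charged_model.ligand_residues
                        for a in r.atoms])
    prev: set = set()
    for cutoff in (4.1, 5.0, 7.0, 10.0):
        sel = select_residues(charged_model, seed, cutoff)
        assert prev <= sel
        prev = sel
        oracle = set()
        for res in charged_model.residues:
            if res.is_ligand:
                continue
            xyz = np.array([a.coords for a in res.atoms])
            if cdist(xyz, lig_xyz).min() <= cutoff:
                oracle.add(res.key)
        assert sel == oracle


def test_seed_atom_must_belong_to_ligand(charged_model):
    protein_serial = next(a.serial for r in charged_model.protein_residues
                          for a in r.atoms)
    with pytest.raises(RegionError, match="ligand"):
        select_residues(charged_model,
                        SeedSpec(mode="atom", atom_serial=protein_serial), 5.0)


def test_single_residue_run_cut_convention(charged_model):
    """Run {3}: QM = res3 + C2,O2 - C3,O3; cuts CA2-C2 and CA3-C3."""
    asg = place_cuts(charged_model, {("A", 3, "")})
    model = charged_model
    chain = model.chains()["A"]
    res2, res3 = chain[2], chain[3]  # after ACE
    assert res2.resseq == 2 and res3.resseq == 3
    expected_qm = {a.serial for a in res3.atoms if a.name not in ("C", "O")}
    expected_qm |= {res2.atom("C").serial, res2.atom("O").serial}
    assert asg.qm_serials == expected_qm
    cuts = {(model.atom(c.q1_serial).name, model.atom(c.m1_serial).name,
             model.atom(c.q1_serial).residue_key[1]) for c in asg.cut_bonds}
    assert cuts == {("C", "CA", 2), ("CA", "C", 3)}


def test_whole_chain_selection_has_no_cuts(charged_model):
    keys = {r.key for r in charged_model.protein_residues if not r.is_cap}
    asg = place_cuts(charged_model, keys)
    assert asg.cut_bonds == []
    protein_serials = {a.serial for r in charged_model.protein_residues
                       for a in r.atoms}
    assert asg.qm_serials == protein_serials  # caps absorbed


def test_shells_match_bfs_oracle(charged_model):
    asg = place_cuts(charged_model, {("A", 3, "")})
    adjacency = charged_model.bonds.adjacency
    nonligand = {a.serial for r in charged_model.residues if not r.is_ligand
                 for a in r.atoms}
    mm_side = nonligand - asg.qm_serials
    for cut in asg.cut_bonds:
        m1, m2, m3 = bfs_shells_oracle(adjacency, cut.q1_serial, mm_side)
        assert m1 == {cut.m1_serial}
        assert m2 == set(cut.m2_serials)
        assert m3 == set(cut.m3_serials)
    # C-terminal cut: M2 = {O(k), N(k+1)} by name
    c_cut = next(c for c in asg.cut_bonds
                 if charged_model.atom(c.q1_serial).name == "CA")
    names = sorted(charged_model.atom(s).name for s in c_cut.m2_serials)
    assert names == ["N", "O"]


def test_partition_covers_all_nonligand_atoms(charged_model):
    asg = place_cuts(charged_model, {("A", 3, "")})
    nonligand = {a.serial for r in charged_model.residues if not r.is_ligand
                 for a in r.atoms}
    assert set(asg.categories) == nonligand
    q1s = {s for s, c in asg.categories.items() if c == "Q1"}
    assert q1s <= asg.qm_serials
    for label in ("M1", "M2", "M3"):
        shell = {s for s, c in asg.categories.items() if c == label}
        assert shell.isdisjoint(asg.qm_serials)


def _model_6mer():
    return build_charged(FixtureSpec(n_residues=6, seed=21))


def test_gap_of_one_residue_absorbed():
    model = _model_6mer()
    asg = place_cuts(model, {("A", 2, ""), ("A", 4, "")})
    asg = absorb_clashes(model, asg)
    assert {("A", 2, ""), ("A", 3, ""), ("A", 4, "")} <= \
        asg.selected_residue_keys
    assert len(asg.cut_bonds) == 2  # one run, two boundary cuts


def test_gap_of_two_residues_kept():
    model = _model_6mer()
    asg = place_cuts(model, {("A", 2, ""), ("A", 5, "")})
    out = absorb_clashes(model, asg)
    assert out.selected_residue_keys == {("A", 2, ""), ("A", 5, "")}


def test_absorption_is_idempotent():
    model = _model_6mer()
    asg = place_cuts(model, {("A", 2, ""), ("A", 4, "")})
    once = absorb_clashes(model, asg)
    twice = absorb_clashes(model, once)
    assert once.selected_residue_keys == twice.selected_residue_keys
    assert [c.q1_serial for c in once.cut_bonds] == \
        [c.q1_serial for c in twice.cut_bonds]


def _atom(serial, name, coords):
    return Atom(serial=serial, name=name, element=name[0], coords=coords,
                record="ATOM", residue_key=("A", 1, ""))


@pytest.mark.parametrize("r_actual, expected", [
    (1.522, 1.090),  # reference-length identity
    (1.600, 1.600 * 1.090 / 1.522),  # 1.14586... by direct evaluation
])
def test_link_atom_scaled_distance(r_actual, expected):
    q1 = _atom(1, "CA", np.zeros(3))
    m1 = _atom(2, "C", np.array([r_actual, 0.0, 0.0]))
    coords, r_q1_m1, r_q1_h = place_link_atom(q1, m1, LinkAtomParams())
    assert r_q1_m1 == pytest.approx(r_actual, abs=1e-12)
    assert r_q1_h == pytest.approx(expected, abs=1e-9)
    assert np.linalg.norm(coords - q1.coords) == pytest.approx(expected,
                                                               abs=1e-9)


def test_link_atom_collinear():
    q1 = _atom(1, "CA", np.array([1.0, -2.0, 0.5]))
    m1 = _atom(2, "C", np.array([2.2, -1.1, 1.7]))
    coords, _, r = place_link_atom(q1, m1, LinkAtomParams())
    v1 = (m1.coords - q1.coords) / np.linalg.norm(m1.coords - q1.coords)
    v2 = (coords - q1.coords) / np.linalg.norm(coords - q1.coords)
    angle = np.arccos(np.clip(np.dot(v1, v2), -1, 1))
    assert angle < 1e-6


def test_coincident_atoms_rejected():
    q1 = _atom(1, "CA", np.zeros(3))
    m1 = _atom(2, "C", np.zeros(3))
    with pytest.raises(RegionError, match="coincide"):
        place_link_atom(q1, m1, LinkAtomParams())


def test_qm_atom_counts(charged_model):
    asg = place_cuts(charged_model, {("A", 3, "")})
    assert count_qm_atoms(asg) == 12  # 10 (res3) + 2 (C2,O2) - 2 + 2 links
    n_lig = sum(len(r.atoms) for r in charged_model.ligand_residues)
    assert count_qm_atoms(asg, include_ligand=True,
                          model=charged_model) == 12 + n_lig


def test_adding_a_water_adds_three_qm_atoms():
    model = build_charged(FixtureSpec(n_residues=5, n_waters=1, seed=13))
    water_key = next(r.key for r in model.residues if r.is_water)
    base = place_cuts(model, {("A", 3, "")})
    with_water = place_cuts(model, {("A", 3, ""), water_key})
    assert count_qm_atoms(with_water) == count_qm_atoms(base) + 3
    assert len(with_water.cut_bonds) == len(base.cut_bonds)  # waters uncut


def test_every_cut_is_a_ca_c_bond(charged_model):
    for cutoff in (4.1, 5.0, 7.0):
        sel = select_residues(charged_model, SeedSpec(mode="whole_ligand"),
                              cutoff)
        asg = absorb_clashes(charged_model, place_cuts(charged_model, sel))
        for cut in asg.cut_bonds:
            names = {charged_model.atom(cut.q1_serial).name,
                     charged_model.atom(cut.m1_serial).name}
            assert names == {"CA", "C"}
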