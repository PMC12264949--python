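"""Input-file emission: system assembly, three dialects, SAPT, F-SAPT."""

from __future__ import annotations

from collections import Counter

import pytest

from qmmmprep import (FixtureSpec, JobSpec, SeedSpec, absorb_clashes,
                      apply_scheme, build_systems, make_fsapt_partition,
                      place_cuts, select_residues, write_input,
                      write_sapt_input)
from qmmmprep.writers import (WriterError, default_filename, read_back,
                              write_fsapt_files)

from conftest import build_charged


@pytest.fixture()
def state():
    model = build_charged(FixtureSpec(n_residues=6, n_waters=1, seed=6))
    sel = select_residues(model, SeedSpec(mode="whole_ligand"), 5.0)
    asg = absorb_clashes(model, place_cuts(model, sel))
    pcs = apply_scheme(asg, model, "BRC")
    return model, asg, pcs


def test_complex_count_is_ligand_plus_protein(state):
    model, asg, pcs = state
    systems = build_systems(asg, pcs, model, JobSpec())
    lig, prot, comp = (systems[k][0] for k in ("ligand", "protein", "complex"))
    assert len(comp) == len(lig) + len(prot)
    assert len(prot) == len(asg.qm_serials) + len(asg.cut_bonds)


def test_counterpoise_ghost_counts(state):
    model, asg, pcs = state
    systems = build_systems(asg, pcs, model, JobSpec(counterpoise=True))
    lig, prot, comp = (systems[k][0] for k in ("ligand", "protein", "complex"))
    assert len(lig) == len(comp)  # ligand file carries protein ghosts
    assert len(prot) == len(comp)
    assert lig.n_real + prot.n_real == len(comp)


def test_point_charges_shared_between_protein_and_complex(state):
    model, asg, pcs = state
    systems = build_systems(asg, pcs, model, JobSpec())
    assert systems["protein"][1] is systems["complex"][1]
    assert len(systems["ligand"][1]) == 0  # QM-only ligand job


@pytest.mark.parametrize("software", ["psi4_format", "nwchem_format",
                                      "qchem_format"])
def test_write_and_read_back(state, tmp_path, software):
    model, asg, pcs = state
    spec = JobSpec(software=software, scf_convergence=6)
    systems = build_systems(asg, pcs, model, spec)
    system, sys_pcs = systems["protein"]
    path = tmp_path / default_filename("protein", spec)
    write_input(system, sys_pcs, spec, path)
    back = read_back(path)
    assert len(back["atoms"]) == len(system)
    assert len(back["charges"]) == len(sys_pcs)
    assert back["charge_mult"] == [(system.charge, system.multiplicity)]
    text = path.read_text()
    assert any(tok in text for tok in ("e_convergence 6", "thresh 1e-06",
                                       "SCF_CONVERGENCE 6"))


def test_cross_format_semantic_equivalence(state, tmp_path):
    """The (element, coords) and charge-value multisets parsed back from the
    three dialects are identical."""
    model, asg, pcs = state
    parsed = {}
    for software in ("psi4_format", "nwchem_format", "qchem_format"):
        spec = JobSpec(software=software, counterpoise=True)
        systems = build_systems(asg, pcs, model, spec)
        for name in ("ligand", "protein", "complex"):
            system, sys_pcs = systems[name]
            path = tmp_path / f"{name}.{software}"
            write_input(system, sys_pcs, spec, path)
            parsed[(software, name)] = read_back(path)
    for name in ("ligand", "protein", "complex"):
        ref = parsed[("psi4_format", name)]
        for software in ("nwchem_format", "qchem_format"):
            other = parsed[(software, name)]
            assert Counter(ref["atoms"]) == Counter(other["atoms"])
            assert Counter(ref["charges"]) == Counter(other["charges"])
            assert ref["charge_mult"] == other["charge_mult"]


def test_deterministic_output(state, tmp_path):
    model, asg, pcs = state
    spec = JobSpec()
    system, sys_pcs = build_systems(asg, pcs, model, spec)["complex"]
    p1, p2 = tmp_path / "a.in", tmp_path / "b.in"
    write_input(system, sys_pcs, spec, p1)
    write_input(system, sys_pcs, spec, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_extra_keywords_appended_last(state, tmp_path):
    model, asg, pcs = state
    spec = JobSpec(extra_keywords=["set scf_type direct"])
    system, sys_pcs = build_systems(asg, pcs, model, spec)["protein"]
    path = tmp_path / "x.in"
    write_input(system, sys_pcs, spec, path)
    text = path.read_text()
    assert text.index("scf_type df") < text.index("set scf_type direct")


def test_sapt_single_file(state, tmp_path):
    model, asg, pcs = state
    spec = JobSpec(sapt_mode=True, method="sapt0")
    systems = build_systems(asg, pcs, model, spec)
    lig, prot = systems["ligand"][0], systems["protein"][0]
    path = tmp_path / "sapt.in"
    write_sapt_input(lig, prot, pcs, spec, path)
    back = read_back(path)
    # monomer A (ligand) first, then monomer B; atom count conserved
    assert len(back["atoms"]) == len(lig) + len(prot)
    assert back["charge_mult"] == [(lig.charge, lig.multiplicity),
                                   (prot.charge, prot.multiplicity)]
    assert back["atoms"][:len(lig)] == [
        (el, tuple(round(x, 6) for x in xyz), g) for el, xyz, g in lig.atoms]
    assert len(back["charges"]) == len(pcs)


def test_sapt_rejects_counterpoise():
    with pytest.raises(WriterError, match="counterpoise"):
        JobSpec(sapt_mode=True, counterpoise=True)


def test_fsapt_partition_covers_monomer_exactly(state, tmp_path):
    model, asg, pcs = state
    partition = make_fsapt_partition(asg, model)
    n_b = len(asg.qm_serials) + len(asg.cut_bonds) \
        - sum(1 for r in model.residues for a in r.atoms
              if a.element == "EP" and a.serial in asg.qm_serials)
    indices = sorted(i for members in partition["fB"].values()
                     for i in members)
    assert indices == list(range(1, n_b + 1))  # exact partition, no repeats
    n_lig = sum(len(r.atoms) for r in model.ligand_residues)
    assert partition["fA"] == {"Ligand": list(range(1, n_lig + 1))}
    paths = write_fsapt_files(partition, tmp_path)
    assert [p.name for p in paths] == ["fA.dat", "fB.dat"]
    total = sum(len(line.split()) - 1
                for line in paths[1].read_text().splitlines())
    assert total == n_b


def test_fsapt_fragments_follow_backbone_rules(state):
    """Single-residue run: a side-chain fragment for the residue (with the
    CA-side link hydrogen) and a peptide fragment C,O(i-1)+N,H(i) (with the
    carbonyl-side link hydrogen)."""
    model, asg, pcs = state
    partition = make_fsapt_partition(asg, model)
    names = set(partition["fB"])
    sc = [n for n in names if n.startswith("sc_")]
    pep = [n for n in names if n.startswith("pep_")]
    assert len(sc) == 1 and len(pep) == 1
    assert len(partition["fB"][pep[0]]) == 5  # C, O, N, H + link H
    sizes = sum(len(v) for v in partition["fB"].values())
    assert sizes == len(asg.qm_serials) + len(asg.cut_bonds)
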