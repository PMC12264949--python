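"""Charge assignment, water models, topology parsing, integer validation."""

from __future__ import annotations

import numpy as np
import pytest

from qmmmprep import (ChargeTemplateLibrary, WaterModelSpec, assign_charges,
                      check_integer_charges, load_external_topology, parse_pdb)
from qmmmprep.charge_assign import (ChargeAssignmentError, IntegerChargeError,
                                    require_integer_charges,
                                    serialize_library)
from qmmmprep.data.charges import RESIDUE_CHARGES
from qmmmprep.fixtures import FixtureSpec, build_fixture_model, perturb_fixture
from qmmmprep._geom import distance


def test_bundled_template_values_assigned_exactly(std_model):
    model, _ = std_model
    assign_charges(model)
    ala = next(r for r in model.protein_residues
               if r.resname == "ALA" and not r.is_cap)
    for atom in ala.atoms:
        assert atom.charge == RESIDUE_CHARGES["ALA"][atom.name]


def test_three_site_water_is_neutral():
    model, _ = build_fixture_model(FixtureSpec(n_waters=2, seed=4))
    water = WaterModelSpec(name="custom3", site_count=3, qO=-0.834, qH=0.417)
    assign_charges(model, water=water)
    for res in model.residues:
        if res.is_water:
            assert sum(a.charge for a in res.atoms) == pytest.approx(0, abs=1e-6)
            assert res.atom("O").charge == -0.834


def test_four_site_water_ep_placement():
    model, _ = build_fixture_model(FixtureSpec(n_waters=1, seed=4))
    water = WaterModelSpec.bundled("tip4p")
    assign_charges(model, water=water)
    res = next(r for r in model.residues if r.is_water)
    ep = res.atom("EP")
    assert ep is not None and ep.charge == water.qEP
    o, h1, h2 = (res.atom(n) for n in ("O", "H1", "H2"))
    assert distance(o.coords, ep.coords) == pytest.approx(water.rEP, abs=1e-9)
    # independent vector construction: EP on the bisector, in the HOH plane
    bis = 0.5 * (h1.coords + h2.coords) - o.coords
    bis /= np.linalg.norm(bis)
    expected = o.coords + water.rEP * bis
    np.testing.assert_allclose(ep.coords, expected, atol=1e-9)
    normal = np.cross(h1.coords - o.coords, h2.coords - o.coords)
    assert abs(np.dot(ep.coords - o.coords, normal)) < 1e-9
    assert sum(a.charge for a in res.atoms) == pytest.approx(0, abs=1e-6)


def test_nonneutral_water_model_rejected():
    with pytest.raises(ValueError, match="not neutral"):
        WaterModelSpec(name="bad", site_count=3, qO=-0.8, qH=0.417)


def test_assignment_is_order_independent(std_model):
    model, _ = std_model
    assign_charges(model)
    expected = {s: a.charge for s, a in model.atoms.items()}
    for res in model.residues:  # permute atom order within residues
        res.atoms.reverse()
    for a in model.atoms.values():
        a.charge = None
    assign_charges(model)
    assert {s: a.charge for s, a in model.atoms.items()} == expected


def test_unknown_residue_name_raises(std_model):
    model, _ = std_model
    next(r for r in model.protein_residues if r.resname == "ARG").resname = "XXX"
    with pytest.raises(ChargeAssignmentError, match="XXX"):
        assign_charges(model)


MINIMAL_RESI = """\
RESI ALA  0.00
ATOM N    NH1   -0.4157
ATOM H    H      0.2719
ATOM CA   CT1    0.0337
ATOM HA   HB1    0.0823
ATOM CB   CT3   -0.1825
ATOM HB1  HA3    0.0603
ATOM HB2  HA3    0.0603
ATOM HB3  HA3    0.0603
ATOM C    C      0.5973
ATOM O    O     -0.5679
"""


def test_load_topology_minimal_block(tmp_path):
    path = tmp_path / "top.rtf"
    path.write_text(MINIMAL_RESI)
    lib = load_external_topology(path)
    table = lib.lookup("ALA", is_cap=False)
    assert len(table) == 10
    assert table["CB"] == -0.1825


def test_topology_noninteger_block_rejected(tmp_path):
    path = tmp_path / "bad.rtf"
    path.write_text("RESI BAD 0.30\nATOM X Y 0.30\n")
    with pytest.raises(ChargeAssignmentError, match="integer"):
        load_external_topology(path)


def test_topology_parse_error_carries_line_number(tmp_path):
    path = tmp_path / "bad.rtf"
    path.write_text("RESI OK 0.0\nATOM X Y notanumber\n")
    with pytest.raises(ChargeAssignmentError, match=":2:"):
        load_external_topology(path)


def test_library_serialization_round_trip(tmp_path):
    lib = ChargeTemplateLibrary.bundled()
    path = tmp_path / "lib.rtf"
    serialize_library(lib, path)
    back = load_external_topology(path)
    for (resname, _), table in lib.templates.items():
        reloaded = back.lookup(resname, is_cap=False)
        assert reloaded is not None
        assert set(reloaded) == set(table)
        for name, q in table.items():
            assert reloaded[name] == pytest.approx(q, abs=1e-9)


def test_clean_fixture_passes_integer_check(charged_model):
    reports = check_integer_charges(charged_model)
    assert reports and all(r.ok for r in reports)


def _run_perturbed(kind, std_files, tmp_path):
    pdb, chg = std_files
    key = perturb_fixture(kind, pdb, chg, tmp_path / "p.pdb",
                          tmp_path / "p.chg")
    from qmmmprep.fixtures import load_charge_table

    model = parse_pdb(tmp_path / "p.pdb")
    overrides = load_charge_table(tmp_path / "p.chg")
    assign_charges(model, overrides=overrides)
    return key, check_integer_charges(model)


def test_broken_integer_charge_detected(std_files, tmp_path):
    key, reports = _run_perturbed("break_integer_charge", std_files, tmp_path)
    failed = [r for r in reports if not r.ok]
    assert [r.residue_key for r in failed] == [key]
    assert failed[0].deviation == pytest.approx(0.05, abs=1e-9)


def test_deleted_atom_detected_and_named(std_files, tmp_path):
    key, reports = _run_perturbed("delete_atom", std_files, tmp_path)
    failed = [r for r in reports if not r.ok]
    assert [r.residue_key for r in failed] == [key]
    assert any(m.startswith("missing") for m in failed[0].offending_atoms)


def test_failing_check_aborts_with_report(std_files, tmp_path):
    pdb, chg = std_files
    key = perturb_fixture("break_integer_charge", pdb, chg,
                          tmp_path / "p.pdb", tmp_path / "p.chg")
    from qmmmprep.fixtures import load_charge_table

    model = parse_pdb(tmp_path / "p.pdb")
    assign_charges(model, overrides=load_charge_table(tmp_path / "p.chg"))
    with pytest.raises(IntegerChargeError) as err:
        require_integer_charges(model)
    assert str(key[1]) in str(err.value)


def test_total_mm_charge_is_sum_of_formal_charges(charged_model):
    total = sum(a.charge for r in charged_model.residues if not r.is_ligand
                for a in r.atoms)
    # ARG (+1) + ASP (-1) + neutral rest
    assert total == pytest.approx(0.0, abs=1e-6)
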