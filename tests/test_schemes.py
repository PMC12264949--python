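"""Boundary charge schemes: zeroing, redistribution, charge/dipole balance."""

from __future__ import annotations

import numpy as np
import pytest

from qmmmprep import FixtureSpec, SeedSpec, absorb_clashes, apply_scheme, \
    place_cuts, report_mm_totals, select_residues
from qmmmprep.schemes import (BALANCED_SCHEMES, ELIMINATION_SCHEMES,
                              SCHEME_REGISTRY, PointChargeSet, SchemeError,
                              get_scheme)

from conftest import build_charged


@pytest.fixture()
def carved():
    model = build_charged(FixtureSpec(n_residues=6, seed=2))
    sel = select_residues(model, SeedSpec(mode="whole_ligand"), 5.0)
    asg = absorb_clashes(model, place_cuts(model, sel))
    return model, asg


def _mm_charge_by_serial(model, asg):
    return {s: model.atom(s).charge for s in asg.mm_serials()}


def test_z1_zeroes_only_m1(carved):
    model, asg = carved
    before = _mm_charge_by_serial(model, asg)
    pcs = apply_scheme(asg, model, "Z1")
    m1_serials = {c.m1_serial for c in asg.cut_bonds}
    emitted = {pc.origin[1]: pc.value for pc in pcs.charges}
    for s in m1_serials:
        assert s not in emitted  # the M1 charge is gone
    for s, q in before.items():
        if s not in m1_serials:
            assert emitted[s] == q  # everything else untouched, bitwise
    deficit = pcs.total_charge - sum(before.values())
    assert deficit == pytest.approx(-sum(before[s] for s in m1_serials),
                                    abs=1e-12)


@pytest.mark.parametrize("name", ELIMINATION_SCHEMES)
def test_elimination_deficit_equals_sum_of_zeroed_shells(carved, name):
    model, asg = carved
    before = _mm_charge_by_serial(model, asg)
    scheme = get_scheme(name)
    zeroed = set()
    for cut in asg.cut_bonds:
        if "M1" in scheme.zero_shells:
            zeroed.add(cut.m1_serial)
        if "M2" in scheme.zero_shells:
            zeroed |= set(cut.m2_serials)
        if "M3" in scheme.zero_shells:
            zeroed |= set(cut.m3_serials)
    pcs = apply_scheme(asg, model, scheme)
    deficit = pcs.total_charge - sum(before.values())
    assert deficit == pytest.approx(-sum(before[s] for s in zeroed), abs=1e-9)


@pytest.mark.parametrize("name", BALANCED_SCHEMES)
def test_balanced_schemes_yield_integer_total(carved, name):
    model, asg = carved
    pcs = apply_scheme(asg, model, name)
    total = pcs.total_charge
    assert abs(total - round(total)) < 1e-6


def test_rc_conserves_total_charge(carved):
    model, asg = carved
    before = sum(_mm_charge_by_serial(model, asg).values())
    pcs = apply_scheme(asg, model, "RC")
    assert pcs.total_charge == pytest.approx(before, abs=1e-9)
    n_mid = sum(len(c.m2_serials) for c in asg.cut_bonds)
    assert sum(1 for pc in pcs.charges if pc.origin[0] == "midpoint") == n_mid


def test_brcd_midpoint_construction_preserves_charge_and_dipole(carved):
    """Each removed M1 charge q0 reappears as 2q0/n at midpoints minus q0/n on
    M2 atoms, so both the charge and its dipole contribution are conserved;
    checked against a direct vector-arithmetic oracle per cut."""
    model, asg = carved
    before = _mm_charge_by_serial(model, asg)
    pcs = apply_scheme(asg, model, "BRCD")
    for cut in asg.cut_bonds:
        q0 = before[cut.m1_serial]
        n = len(cut.m2_serials)
        mids = [pc for pc in pcs.charges
                if pc.origin[0] == "midpoint" and pc.origin[1] == cut.bond_id]
        assert len(mids) == n
        m1_pos = model.atom(cut.m1_serial).coords
        # oracle: dipole of the replacement distribution about the origin
        dipole = np.zeros(3)
        charge = 0.0
        for pc in mids:
            base = 2.0 * q0 / n  # midpoint charge before q_bal top-up
            dipole += base * pc.position
            charge += base
        for s in sorted(cut.m2_serials):
            delta = -q0 / n
            dipole += delta * model.atom(s).coords
            charge += delta
            np.testing.assert_allclose(
                0.5 * (m1_pos + model.atom(s).coords),
                next(pc.position for pc in mids if pc.origin[2] == s))
        assert charge == pytest.approx(q0, abs=1e-12)
        np.testing.assert_allclose(dipole, q0 * m1_pos, atol=1e-9)


@pytest.mark.parametrize("name", ["Z1", "Z2", "Z3", "RC", "BRC", "BRCD"])
def test_scheme_application_is_local(carved, name):
    """Atoms more than three bonds from every cut keep their charges bitwise.

    The DZ family is excluded here: distributing q_bal evenly over a cut
    residue's remaining atoms touches that whole residue by definition; its
    locality at residue granularity is covered by the far-water test below."""
    model, asg = carved
    before = _mm_charge_by_serial(model, asg)
    shell_serials = set()
    for cut in asg.cut_bonds:
        shell_serials |= {cut.m1_serial} | set(cut.m2_serials) \
            | set(cut.m3_serials)
    pcs = apply_scheme(asg, model, name)
    emitted = {pc.origin[1]: pc.value for pc in pcs.charges
               if pc.origin[0] == "atom"}
    for s, q in before.items():
        if s not in shell_serials:
            assert emitted[s] == q


def test_far_mm_water_charges_never_touched():
    model = build_charged(FixtureSpec(n_residues=6, n_waters=3, seed=8))
    sel = select_residues(model, SeedSpec(mode="whole_ligand"), 5.0)
    asg = absorb_clashes(model, place_cuts(model, sel))
    for name in SCHEME_REGISTRY:
        pcs = apply_scheme(asg, model, name)
        emitted = {pc.origin[1]: pc.value for pc in pcs.charges}
        for res in model.residues:
            if res.is_water:
                for a in res.atoms:
                    assert emitted[a.serial] == a.charge


def test_report_mm_totals(carved):
    model, asg = carved
    pcs = apply_scheme(asg, model, "BRC")
    total, count = report_mm_totals(pcs)
    assert count == len(pcs.charges)
    assert abs(total - round(total)) < 1e-6
    empty_total, empty_count = report_mm_totals(PointChargeSet())
    assert (empty_total, empty_count) == (0.0, 0)


def test_unknown_scheme_lists_registry(carved):
    model, asg = carved
    with pytest.raises(SchemeError, match="Z1"):
        apply_scheme(asg, model, "Z9")


def test_audit_table_written(carved, tmp_path):
    model, asg = carved
    pcs = apply_scheme(asg, model, "BRC")
    path = tmp_path / "audit.csv"
    pcs.write_audit(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "origin,original_charge,final_charge,action"
    assert len(lines) == 1 + len(asg.mm_serials())
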