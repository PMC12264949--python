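"""Boundary charge schemes: turn raw MM charges into the final external
point-charge set.

Nine schemes are registered.  Z1/Z2/Z3 are elimination schemes: they zero the
point charges in the first one/two/three MM shells of every cut, which in
general leaves the MM region with a noninteger total charge.  The remaining
schemes are balanced or redistributed: RC moves the M1 charge onto M1-M2 bond
midpoints (charge-conserving, no balancing); DZ1/DZ2/DZ3, BRC and BRCD
additionally distribute q_bal -- the charge needed to return each cut residue
to its original integer charge -- so the MM region ends up with an integer
total.  BRCD's midpoint construction (twice the M1 charge at each M1-M2
midpoint, minus half per M2 atom for two M2 neighbors, generally 2q/n and
-q/n) preserves both the removed charge and its M1-M2 bond-dipole
contributions.

q_bal bookkeeping: for each cut, the compensating charge is computed against
the full ledger of what that cut did -- the M1 residue's remaining MM atom
charges, plus any midpoint charges the cut introduced, plus any changes it
made to atoms of neighboring residues.  Balancing against the residue's own
atoms alone would leave the total noninteger whenever a cut's midpoints or
M2 shell extend into the next residue (every C-terminal cut does), breaking
the defining property of a balanced scheme.

The registry is data-driven: a SchemeDefinition names which shells to zero,
how to move the M1 charge, and where q_bal goes, so variants can be added
without touching the engine.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .region import RegionAssignment
from .structure import StructureModel

logger = logging.getLogger(__name__)

INTEGER_TOL = 1e-6  # e


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class SchemeDefinition:
    name: str
    zero_shells: frozenset[str] = frozenset()  # subset of {"M1","M2","M3"}
    redistribute_m1_to: str = "none"  # none | midpoints | midpoints_dipole
    balance_target: str = "none"  # none | residue_atoms | m2_atoms | midpoints

    def __post_init__(self):
        if not self.zero_shells <= {"M1", "M2", "M3"}:
            raise ValueError("zero_shells must be a subset of {M1,M2,M3}")
        if self.redistribute_m1_to not in ("none", "midpoints",
                                           "midpoints_dipole"):
            raise ValueError(f"bad redistribute_m1_to for {self.name}")
        if self.balance_target not in ("none", "residue_atoms", "m2_atoms",
                                       "midpoints"):
            raise ValueError(f"bad balance_target for {self.name}")

    @property
    def balanced(self) -> bool:
        return self.balance_target != "none"


SCHEME_REGISTRY: dict[str, SchemeDefinition] = {
    "Z1": SchemeDefinition("Z1", frozenset({"M1"})),
    "Z2": SchemeDefinition("Z2", frozenset({"M1", "M2"})),
    "Z3": SchemeDefinition("Z3", frozenset({"M1", "M2", "M3"})),
    "DZ1": SchemeDefinition("DZ1", frozenset({"M1"}),
                            balance_target="residue_atoms"),
    "DZ2": SchemeDefinition("DZ2", frozenset({"M1", "M2"}),
                            balance_target="residue_atoms"),
    "DZ3": SchemeDefinition("DZ3", frozenset({"M1", "M2", "M3"}),
                            balance_target="residue_atoms"),
    "RC": SchemeDefinition("RC", redistribute_m1_to="midpoints"),
    "BRC": SchemeDefinition("BRC", frozenset({"M1"}),
                            balance_target="m2_atoms"),
    "BRCD": SchemeDefinition("BRCD", redistribute_m1_to="midpoints_dipole",
                             balance_target="midpoints"),
}

BALANCED_SCHEMES = tuple(n for n, s in SCHEME_REGISTRY.items() if s.balanced)
ELIMINATION_SCHEMES = ("Z1", "Z2", "Z3")


@dataclass
class PointCharge:
    position: np.ndarray
    value: float
    origin: tuple  # ("atom", serial) | ("midpoint", bond_id, m2_serial)


@dataclass
class PointChargeSet:
    charges: list[PointCharge] = field(default_factory=list)
    scheme: str = ""
    audit: list[dict] = field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(sum(pc.value for pc in self.charges))

    def __len__(self) -> int:
        return len(self.charges)

    def write_audit(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[
                "origin", "original_charge", "final_charge", "action"])
            writer.writeheader()
            writer.writerows(self.audit)


def get_scheme(name: str) -> SchemeDefinition:
    try:
        return SCHEME_REGISTRY[name.upper()]
    except KeyError:
        raise SchemeError(
            f"unknown charge scheme {name!r}; registered: "
            + ", ".join(SCHEME_REGISTRY)) from None


def apply_scheme(assignment: RegionAssignment, model: StructureModel,
                 scheme: SchemeDefinition | str) -> PointChargeSet:
    """Apply a boundary charge scheme and return the final point-charge set.

    QM/Q1 atoms and link atoms contribute no point charges; MM atoms beyond
    the shells pass through unchanged.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    mm_serials = sorted(assignment.mm_serials())
    working: dict[int, float] = {}
    for s in mm_serials:
        q = model.atom(s).charge
        if q is None:
            raise SchemeError(f"MM atom serial {s} has no assigned charge")
        working[s] = q
    original = dict(working)
    removed: set[int] = set()  # serials whose charge was zeroed or moved
    moved: set[int] = set()
    serial_residue = {a.serial: r for r in model.residues for a in r.atoms}

    needs_m2 = scheme.redistribute_m1_to != "none" or \
        scheme.balance_target in ("m2_atoms", "midpoints")
    for cut in assignment.cut_bonds:
        if needs_m2 and not cut.m2_serials:
            raise SchemeError(
                f"cut {cut.bond_id} has an empty M2 shell; scheme "
                f"{scheme.name} needs M2 atoms")

    # 1. move the M1 charge (RC / BRCD)
    midpoints: dict[int, list[PointCharge]] = {}
    foreign_delta: dict[int, float] = {}
    mid_total: dict[int, float] = {}
    if scheme.redistribute_m1_to != "none":
        for cut in assignment.cut_bonds:
            q0 = working[cut.m1_serial]
            n = len(cut.m2_serials)
            m1_res = serial_residue[cut.m1_serial].key
            mids, fdelta, mtotal = [], 0.0, 0.0
            for m2s in sorted(cut.m2_serials):
                pos = 0.5 * (model.atom(cut.m1_serial).coords
                             + model.atom(m2s).coords)
                if scheme.redistribute_m1_to == "midpoints":
                    value = q0 / n
                else:  # midpoints_dipole
                    value = 2.0 * q0 / n
                    working[m2s] -= q0 / n
                    if serial_residue[m2s].key != m1_res:
                        fdelta += -q0 / n
                mids.append(PointCharge(position=pos, value=value,
                                        origin=("midpoint", cut.bond_id, m2s)))
                mtotal += value
            working[cut.m1_serial] = 0.0
            removed.add(cut.m1_serial)
            moved.add(cut.m1_serial)
            midpoints[cut.bond_id] = mids
            foreign_delta[cut.bond_id] = fdelta
            mid_total[cut.bond_id] = mtotal

    # 2. zero the named shells
    for cut in assignment.cut_bonds:
        for shell, serials in (("M1", {cut.m1_serial}),
                               ("M2", cut.m2_serials),
                               ("M3", cut.m3_serials)):
            if shell in scheme.zero_shells:
                for s in serials:
                    working[s] = 0.0
                    removed.add(s)

    # 3. balancing
    if scheme.balance_target == "residue_atoms":
        _balance_per_residue(assignment, model, working, removed,
                             serial_residue)
    elif scheme.balance_target in ("m2_atoms", "midpoints"):
        for cut in assignment.cut_bonds:
            res = serial_residue[cut.m1_serial]
            res_mm = [a.serial for a in res.atoms if a.serial in working]
            responsible = sum(working[s] for s in res_mm) \
                + mid_total.get(cut.bond_id, 0.0) \
                + foreign_delta.get(cut.bond_id, 0.0)
            q_bal = _formal_charge(res, model) - responsible
            if scheme.balance_target == "m2_atoms":
                for m2s in cut.m2_serials:
                    working[m2s] += q_bal / len(cut.m2_serials)
            else:
                for pc in midpoints[cut.bond_id]:
                    pc.value += q_bal / len(midpoints[cut.bond_id])

    # 4. assemble
    pcs = PointChargeSet(scheme=scheme.name)
    for s in mm_serials:
        if s in removed:
            action = "moved" if s in moved else "zeroed"
            pcs.audit.append({"origin": f"atom:{s}",
                              "original_charge": f"{original[s]:+.6f}",
                              "final_charge": "+0.000000",
                              "action": action})
            continue
        atom = model.atom(s)
        pcs.charges.append(PointCharge(position=atom.coords,
                                       value=working[s],
                                       origin=("atom", s)))
        action = "unchanged" if working[s] == original[s] else "adjusted"
        pcs.audit.append({"origin": f"atom:{s}",
                          "original_charge": f"{original[s]:+.6f}",
                          "final_charge": f"{working[s]:+.6f}",
                          "action": action})
    for bond_id in sorted(midpoints):
        for pc in midpoints[bond_id]:
            pcs.charges.append(pc)
            pcs.audit.append({"origin": f"midpoint:{pc.origin[1]}:{pc.origin[2]}",
                              "original_charge": "+0.000000",
                              "final_charge": f"{pc.value:+.6f}",
                              "action": "midpoint"})
    return pcs


def _formal_charge(res, model: StructureModel) -> float:
    """Original integer charge of a residue (all its atoms, QM side included)."""
    total = sum(a.charge for a in res.atoms if a.charge is not None)
    return float(round(total))


def _balance_per_residue(assignment, model, working, removed,
                         serial_residue) -> None:
    affected = {}
    for s in removed:
        res = serial_residue[s]
        affected[res.key] = res
    for key in sorted(affected):
        res = affected[key]
        res_mm = [a.serial for a in res.atoms if a.serial in working]
        q_bal = _formal_charge(res, model) - sum(working[s] for s in res_mm)
        targets = [s for s in res_mm if s not in removed]
        if not targets:
            targets = _nearest_unzeroed(assignment, model, res, working,
                                        removed)
            logger.warning(
                "residue %s has no nonzeroed MM atoms left; distributing "
                "q_bal over the nearest nonzeroed MM atoms %s", res, targets)
        for s in targets:
            working[s] += q_bal / len(targets)


def _nearest_unzeroed(assignment, model, res, working, removed) -> list[int]:
    """BFS outward from the residue's zeroed atoms through the MM side."""
    mm = set(working)
    frontier = {a.serial for a in res.atoms if a.serial in removed}
    seen = set(frontier)
    for _ in range(len(mm)):
        nxt = set()
        for s in frontier:
            nxt |= {n for n in model.bonds.neighbors(s)
                    if n in mm and n not in seen}
        if not nxt:
            break
        found = sorted(s for s in nxt if s not in removed)
        if found:
            return found
        seen |= nxt
        frontier = nxt
    raise SchemeError(
        f"no nonzeroed MM atoms reachable from residue {res.key} "
        "to carry its balancing charge")


def report_mm_totals(pcs: PointChargeSet,
                     tolerance: float = INTEGER_TOL) -> tuple[float, int]:
    """(total MM charge in e, number of point charges); logs integerness."""
    total = pcs.total_charge
    integral = abs(total - round(total)) <= tolerance
    logger.info("MM region: %d point charges, total charge %+.6f e (%s)",
                len(pcs), total,
                "integer" if integral else "NONINTEGER")
    return total, len(pcs)
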