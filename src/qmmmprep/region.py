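"""QM-region selection, Calpha-C(carbonyl) cut placement, boundary shells and
hydrogen link atoms.

The QM subsystem grows from a seed (a ligand atom, or the whole ligand) by a
distance cutoff over whole residues, then expands or shrinks so every covalent
boundary falls on a Calpha-C(carbonyl) bond.  For each cut, Q1 is the carbon
kept in the QM region and capped with hydrogen; M1, M2 and M3 are the MM-side
atoms at one, two and three bonds from Q1.  Every nonligand atom lands in
exactly one of six categories: QM, Q1(b), M1(b), M2(b), M3(b) or MM.

The link hydrogen sits on the Q1->M1 axis with a bond length scaled from
force-field equilibrium distances:

    r(Q1-H) = r(Q1-M1) * r0(Q1-H) / r0(Q1-M1)

so the capped bond inherits the geometry of the bond it replaces.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from ._geom import unit
from .structure import Atom, Residue, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_GAP_MIN = 1  # residues between two QM runs that forces absorption
LINK_CLASH_MIN = 1.3  # Angstrom between two link hydrogens


class RegionError(ValueError):
    pass


@dataclass
class SeedSpec:
    mode: str  # "atom" | "whole_ligand"
    atom_serial: int | None = None

    def __post_init__(self):
        if self.mode not in ("atom", "whole_ligand"):
            raise ValueError("seed mode must be 'atom' or 'whole_ligand'")
        if self.mode == "atom" and self.atom_serial is None:
            raise ValueError("seed mode 'atom' requires atom_serial")

    def seed_coords(self, model: StructureModel) -> np.ndarray:
        ligand_serials = {a.serial for r in model.ligand_residues
                          for a in r.atoms}
        if not ligand_serials:
            raise RegionError("model has no ligand residue to seed from")
        if self.mode == "atom":
            if self.atom_serial not in ligand_serials:
                raise RegionError(
                    f"seed atom serial {self.atom_serial} is not a ligand atom")
            return model.atom(self.atom_serial).coords[None, :]
        return model.coords_of(sorted(ligand_serials))


@dataclass
class LinkAtomParams:
    r0_q1_h: float = 1.090  # force-field C-H equilibrium, Angstrom
    r0_q1_m1: float = 1.522  # force-field Calpha-C equilibrium, Angstrom

    def __post_init__(self):
        if self.r0_q1_h <= 0 or self.r0_q1_m1 <= 0:
            raise ValueError("link-atom reference bond lengths must be positive")


@dataclass
class CutBond:
    bond_id: int
    q1_serial: int
    m1_serial: int
    m2_serials: frozenset[int]
    m3_serials: frozenset[int]
    link_coords: np.ndarray
    r_q1_m1: float
    r_q1_h: float
    link_element: str = "H"


@dataclass
class RegionAssignment:
    """Six-category atom map plus the list of cut bonds."""

    selected_residue_keys: set[tuple]
    qm_serials: set[int]  # all QM-side protein/water/ion serials (incl. Q1)
    categories: dict[int, str]  # serial -> QM|Q1|M1|M2|M3|MM
    category_bond: dict[int, int | None]  # serial -> owning cut bond id
    cut_bonds: list[CutBond] = field(default_factory=list)

    def category(self, serial: int) -> str:
        return self.categories[serial]

    @property
    def link_atoms(self) -> list[np.ndarray]:
        return [c.link_coords for c in self.cut_bonds]

    def mm_serials(self) -> set[int]:
        return {s for s, c in self.categories.items() if c in
                ("M1", "M2", "M3", "MM")}

    def write_category_map(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["serial", "category", "bond_id"])
            for serial in sorted(self.categories):
                bond = self.category_bond.get(serial)
                writer.writerow([serial, self.categories[serial],
                                 "" if bond is None else bond])


# ---------------------------------------------------------------------------
# selection


def select_residues(model: StructureModel, seed: SeedSpec,
                    cutoff: float) -> set[tuple]:
    """Whole nonligand residues with any atom within ``cutoff`` of the seed.

    Distances are measured to all atoms, hydrogens included.
    """
    if cutoff <= 0:
        raise RegionError("cutoff must be positive")
    seed_xyz = seed.seed_coords(model)
    selected = set()
    for res in model.residues:
        if res.is_ligand:
            continue
        xyz = np.array([a.coords for a in res.atoms])
        if float(cdist(xyz, seed_xyz).min()) <= cutoff:
            selected.add(res.key)
    if not selected:
        raise RegionError(
            f"no residues within {cutoff} Angstrom of the seed; "
            "increase the cutoff")
    return selected


# ---------------------------------------------------------------------------
# cuts and shells


def place_cuts(model: StructureModel, selected: set[tuple]) -> RegionAssignment:
    """Terminate the selection at Calpha-C(carbonyl) bonds and classify shells.

    For each maximal run [j..k] of selected residues in a chain, the QM side
    gains C and O of residue j-1 (the preceding carbonyl) and loses C and O of
    residue k; the corresponding cut bonds are CA(j-1)-C(j-1) with Q1=C(j-1)
    and CA(k)-C(k) with Q1=CA(k).  An adjacent ACE/NME cap or chain terminus
    is absorbed instead of cut.  Waters and ions are cut-free QM.
    """
    if model.bonds is None:
        raise RegionError("model has no bond graph; build it first")
    qm_serials: set[int] = set()
    cut_specs: list[tuple[int, int]] = []  # (q1, m1)

    chains = model.chains()
    chain_keys = {res.key: (cid, idx) for cid, residues in chains.items()
                  for idx, res in enumerate(residues)}

    for res in model.residues:
        if res.is_ligand or res.key not in selected:
            continue
        if res.is_water or StructureModel.is_ion(res):
            qm_serials.update(a.serial for a in res.atoms)
        elif res.key not in chain_keys:  # pragma: no cover - defensive
            logger.warning("selected residue %s is not part of a protein "
                           "chain; treating as cut-free QM", res)
            qm_serials.update(a.serial for a in res.atoms)

    for cid, residues in chains.items():
        sel_idx = [i for i, r in enumerate(residues) if r.key in selected]
        for j, k in _runs(sel_idx):
            run = residues[j:k + 1]
            for r in run:
                qm_serials.update(a.serial for a in r.atoms)
            # N-terminal side
            if j == 0:
                pass  # chain start: nothing to cut or absorb
            elif residues[j - 1].is_cap:
                qm_serials.update(a.serial for a in residues[j - 1].atoms)
            else:
                prev = residues[j - 1]
                q1, m1 = prev.atom("C"), prev.atom("CA")
                _require_cut_atoms(prev, q1, m1)
                qm_serials.update({q1.serial}
                                  | _carbonyl_oxygens(prev))
                cut_specs.append((q1.serial, m1.serial))
            # C-terminal side
            if k == len(residues) - 1:
                pass
            elif residues[k + 1].is_cap:
                qm_serials.update(a.serial for a in residues[k + 1].atoms)
            else:
                last = residues[k]
                q1, m1 = last.atom("CA"), last.atom("C")
                _require_cut_atoms(last, m1, q1)
                qm_serials -= {m1.serial} | _carbonyl_oxygens(last)
                cut_specs.append((q1.serial, m1.serial))

    return _classify(model, selected, qm_serials, cut_specs)


def _carbonyl_oxygens(res: Residue) -> set[int]:
    return {a.serial for a in res.atoms if a.name in ("O", "OXT")}


def _require_cut_atoms(res: Residue, *atoms) -> None:
    if any(a is None for a in atoms):
        raise RegionError(
            f"residue {res.resname} {res.key} lacks CA/C backbone atoms "
            "needed to place a cut")


def _runs(indices: list[int]):
    if not indices:
        return
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
            continue
        yield start, prev
        start = prev = i
    yield start, prev


def _classify(model: StructureModel, selected: set[tuple],
              qm_serials: set[int], cut_specs: list[tuple[int, int]],
              link_params: LinkAtomParams | None = None) -> RegionAssignment:
    link_params = link_params or LinkAtomParams()
    nonligand = {a.serial for r in model.residues if not r.is_ligand
                 for a in r.atoms}
    mm_side = nonligand - qm_serials
    categories = {s: ("QM" if s in qm_serials else "MM") for s in nonligand}
    category_bond: dict[int, int | None] = {s: None for s in nonligand}
    cuts: list[CutBond] = []

    for bond_id, (q1s, m1s) in enumerate(cut_specs):
        if m1s not in model.bonds.neighbors(q1s):
            raise RegionError(
                f"cut bond {q1s}-{m1s} is not a covalent bond")
        frontiers = model.bonds.bfs_frontiers(q1s, mm_side, depth=3)
        m1, m2, m3 = frontiers
        if m1 != {m1s}:  # pragma: no cover - defensive
            raise RegionError(
                f"M1 shell of cut {bond_id} is {m1}, expected {{{m1s}}}")
        q1_atom, m1_atom = model.atom(q1s), model.atom(m1s)
        link, r_q1_m1, r_q1_h = place_link_atom(q1_atom, m1_atom, link_params)
        cuts.append(CutBond(bond_id=bond_id, q1_serial=q1s, m1_serial=m1s,
                            m2_serials=frozenset(m2), m3_serials=frozenset(m3),
                            link_coords=link, r_q1_m1=r_q1_m1, r_q1_h=r_q1_h))
        for serial, label in [(q1s, "Q1"), (m1s, "M1")] + \
                [(s, "M2") for s in sorted(m2)] + \
                [(s, "M3") for s in sorted(m3)]:
            if category_bond[serial] is not None:
                # post-absorption this should not occur; first cut owns
                logger.warning(
                    "atom %d is in the %s shell of cut %d but already owned "
                    "by cut %d as %s", serial, label, bond_id,
                    category_bond[serial], categories[serial])
                continue
            categories[serial] = label
            category_bond[serial] = bond_id

    return RegionAssignment(selected_residue_keys=set(selected),
                            qm_serials=set(qm_serials),
                            categories=categories,
                            category_bond=category_bond, cut_bonds=cuts)


# ---------------------------------------------------------------------------
# clash absorption


def absorb_clashes(model: StructureModel, assignment: RegionAssignment,
                   gap_min: int = DEFAULT_GAP_MIN,
                   link_clash_min: float = LINK_CLASH_MIN) -> RegionAssignment:
    """Expand the selection until no two cuts sit in close sequence proximity.

    Two triggers: an MM gap of at most ``gap_min`` residues between two QM
    runs in the same chain, and two link hydrogens closer than
    ``link_clash_min`` Angstrom.  The QM region only ever grows, so the loop
    terminates.
    """
    selected = set(assignment.selected_residue_keys)
    current = assignment
    for _ in range(len(model.residues) + 1):
        grown = _grow_once(model, current, selected, gap_min, link_clash_min)
        if not grown:
            return current
        selected |= grown
        current = place_cuts(model, selected)
    raise RegionError("clash absorption failed to converge")  # pragma: no cover


def _grow_once(model, assignment, selected, gap_min, link_clash_min):
    to_add: set[tuple] = set()
    chains = model.chains()
    for cid, residues in chains.items():
        sel_idx = [i for i, r in enumerate(residues) if r.key in selected]
        runs = list(_runs(sel_idx))
        for (_, end1), (start2, _) in zip(runs, runs[1:]):
            gap = [r for r in residues[end1 + 1:start2] if not r.is_cap]
            if 0 < len(gap) <= gap_min:
                to_add.update(r.key for r in gap)
    if not to_add and len(assignment.cut_bonds) > 1:
        links = np.array([c.link_coords for c in assignment.cut_bonds])
        d = cdist(links, links)
        ii, jj = np.nonzero((d < link_clash_min) & (d > 0))
        serial_res = {a.serial: r for r in model.residues for a in r.atoms}
        chain_index = {r.key: (cid, i) for cid, residues in chains.items()
                       for i, r in enumerate(residues)}
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            r1 = serial_res[assignment.cut_bonds[i].q1_serial]
            r2 = serial_res[assignment.cut_bonds[j].q1_serial]
            c1 = chain_index.get(r1.key)
            c2 = chain_index.get(r2.key)
            if c1 is None or c2 is None or c1[0] != c2[0]:
                logger.warning("link atoms of cuts %d and %d clash across "
                               "chains; cannot absorb", i, j)
                continue
            lo, hi = sorted((c1[1], c2[1]))
            to_add.update(r.key for r in chains[c1[0]][lo:hi + 1]
                          if not r.is_cap)
    return to_add - selected


# ---------------------------------------------------------------------------
# link atoms


def place_link_atom(q1: Atom, m1: Atom, params: LinkAtomParams
                    ) -> tuple[np.ndarray, float, float]:
    """Hydrogen cap on the Q1->M1 axis with the scaled bond length.

    Returns (coords, r_q1_m1, r_q1_h).
    """
    delta = m1.coords - q1.coords
    r_q1_m1 = float(np.linalg.norm(delta))
    if r_q1_m1 < 1e-8:
        raise RegionError(
            f"Q1 (serial {q1.serial}) and M1 (serial {m1.serial}) coincide")
    r_q1_h = r_q1_m1 * params.r0_q1_h / params.r0_q1_m1
    return q1.coords + r_q1_h * unit(delta), r_q1_m1, r_q1_h


def count_qm_atoms(assignment: RegionAssignment,
                   include_ligand: bool = False,
                   model: StructureModel | None = None) -> int:
    """|QM ∪ Q1| + link atoms (+ ligand atoms for the complex)."""
    n = len(assignment.qm_serials) + len(assignment.cut_bonds)
    if include_ligand:
        if model is None:
            raise ValueError("include_ligand requires the model")
        n += sum(len(r.atoms) for r in model.ligand_residues)
    return n
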