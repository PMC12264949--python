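"""PDB-backed structure model: atoms, residues, chains and the covalent bond graph.

Parsing is delegated to gemmi (fixed-width PDB handling, element inference,
first-model / highest-occupancy-altloc selection).  Writing is done in-package
because the round-trip contract requires original atom serials to survive,
which gemmi's writer does not guarantee.

Bond perception is template-first: bundled per-residue connectivity plus
peptide/disulfide rules, with a covalent-radius distance criterion for
ligands and unknown residues.  CONECT records are deliberately ignored so the
graph does not depend on deposition quality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .data import connectivity
from .data.charges import ION_CHARGES, WATER_RESNAMES

logger = logging.getLogger(__name__)

PEPTIDE_BOND_MAX = 2.0  # Angstrom, C(i)-N(i+1)
DISULFIDE_MAX = 2.3  # Angstrom, SG-SG
COVALENT_SCALE = 1.25  # d <= scale * (r_cov_a + r_cov_b)
ORPHAN_H_MAX = 1.3  # Angstrom, unmatched hydrogen to nearest heavy atom


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    record: str  # "ATOM" | "HETATM"
    residue_key: tuple  # (chain_id, resseq, icode)
    charge: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ValueError(f"atom serial {self.serial} has empty element")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom serial {self.serial} has non-finite coords")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    is_ligand: bool = False
    is_water: bool = False
    is_cap: bool = False

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self):
        return f"<Residue {self.resname} {self.chain_id}{self.resseq}{self.icode}>"


class BondGraph:
    """Symmetric adjacency over atom serials, backed by networkx."""

    def __init__(self):
        self._g = nx.Graph()

    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-bonds are not allowed")
        self._g.add_edge(a, b)

    def add_atom(self, serial: int) -> None:
        self._g.add_node(serial)

    def neighbors(self, serial: int) -> set[int]:
        if serial not in self._g:
            return set()
        return set(self._g.neighbors(serial))

    @property
    def adjacency(self) -> dict[int, set[int]]:
        return {n: set(self._g.neighbors(n)) for n in self._g.nodes}

    def bfs_frontiers(self, start: int, allowed: set[int], depth: int) -> list[set[int]]:
        """Breadth-first frontier sets at 1..depth bonds from ``start``,
        walking only through atoms in ``allowed``."""
        frontiers = []
        seen = {start}
        frontier = {start}
        for _ in range(depth):
            nxt = set()
            for s in frontier:
                nxt |= {n for n in self.neighbors(s) if n in allowed and n not in seen}
            frontiers.append(nxt)
            seen |= nxt
            frontier = nxt
        return frontiers

    @property
    def n_bonds(self) -> int:
        return self._g.number_of_edges()

    def edges(self):
        return list(self._g.edges)


@dataclass
class StructureModel:
    residues: list[Residue] = field(default_factory=list)
    bonds: BondGraph | None = None

    def __post_init__(self):
        self._index: dict[int, Atom] = {}
        self.reindex()

    def reindex(self) -> None:
        self._index = {}
        for res in self.residues:
            for atom in res.atoms:
                if atom.serial in self._index:
                    raise PDBParseError(f"duplicate atom serial {atom.serial}")
                self._index[atom.serial] = atom

    @property
    def atoms(self) -> dict[int, Atom]:
        return self._index

    def atom(self, serial: int) -> Atom:
        return self._index[serial]

    def residue(self, key: tuple) -> Residue:
        for res in self.residues:
            if res.key == key:
                return res
        raise KeyError(key)

    def next_serial(self) -> int:
        return (max(self._index) + 1) if self._index else 1

    @property
    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_ligand]

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues
                if not (r.is_ligand or r.is_water or self.is_ion(r))]

    def chains(self) -> dict[str, list[Residue]]:
        """Protein residues (caps included) grouped by chain, in file order."""
        out: dict[str, list[Residue]] = {}
        for res in self.protein_residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    @staticmethod
    def is_ion(res: Residue) -> bool:
        return res.resname in ION_CHARGES and len(res.atoms) == 1

    def coords_of(self, serials) -> np.ndarray:
        return np.array([self._index[s].coords for s in serials], dtype=float)


# ---------------------------------------------------------------------------
# parsing

def parse_pdb(path, ligand_resnames: set[str] | None = None,
              water_resnames: set[str] | None = None) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Ligand residues are HETATM residues whose name is not in the water/ion
    lists; ``ligand_resnames`` forces specific residue names to be treated as
    the ligand regardless of record type.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    _validate_coordinate_fields(text, path)

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()  # keep highest occupancy
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    model = st[0]

    waters = set(WATER_RESNAMES) | (water_resnames or set())
    residues: list[Residue] = []
    seen_serials: set[int] = set()
    for chain in model:
        for gres in chain:
            resname = gres.name.strip()
            key = (chain.name, gres.seqid.num, gres.seqid.icode.strip())
            is_water = resname in waters
            is_het = gres.het_flag == "H"
            is_ion = resname in ION_CHARGES and len(gres) == 1
            is_ligand = bool(ligand_resnames and resname in ligand_resnames) or (
                is_het and not is_water and not is_ion
                and resname not in ("ACE", "NME", "NMA")
            )
            res = Residue(chain_id=chain.name, resseq=gres.seqid.num,
                          icode=gres.seqid.icode.strip(), resname=resname,
                          is_ligand=is_ligand, is_water=is_water,
                          is_cap=resname in ("ACE", "NME", "NMA"))
            for ga in gres:
                if ga.serial in seen_serials:
                    raise PDBParseError(
                        f"{path}: duplicate atom serial {ga.serial}")
                seen_serials.add(ga.serial)
                element = "H" if ga.element.is_hydrogen else ga.element.name
                if element in ("X", ""):
                    element = _element_from_name(ga.name)
                res.atoms.append(Atom(
                    serial=ga.serial, name=ga.name.strip(), element=element,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    record="HETATM" if is_het else "ATOM",
                    residue_key=key))
            if res.atoms:
                residues.append(res)
    return StructureModel(residues=residues)


def _validate_coordinate_fields(text: str, path) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: malformed coordinate field {fld!r} "
                        f"on line {lineno}") from None


def _element_from_name(name: str) -> str:
    name = name.strip()
    if not name:
        raise PDBParseError("atom with empty name and element")
    stripped = name.lstrip("0123456789")
    if stripped[:1] in ("H",) or name[:1].isdigit():
        return "H"
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Se"):
        return two
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# bond graph

def build_bond_graph(model: StructureModel,
                     templates: dict[str, list[tuple[str, str]]] | None = None
                     ) -> BondGraph:
    """Covalent bond graph from residue templates + geometric rules.

    Intra-residue bonds come from the bundled amino-acid connectivity
    templates; inter-residue peptide bonds, disulfides and distance-based
    perception (ligands, unknown residues) are added geometrically.
    """
    graph = BondGraph()
    for res in model.residues:
        for atom in res.atoms:
            graph.add_atom(atom.serial)

    for res in model.residues:
        tmpl = (templates or {}).get(res.resname) or connectivity.bonds_for(res.resname)
        if res.is_ligand or tmpl is None:
            _distance_bonds(res.atoms, graph)
            if tmpl is None and not res.is_ligand and not res.is_water:
                logger.warning("no connectivity template for residue %s; "
                               "using distance criterion", res)
            continue
        tmpl_names = set()
        for a, b in tmpl:
            tmpl_names.add(a)
            tmpl_names.add(b)
        by_name: dict[str, Atom] = {}
        for atom in res.atoms:
            by_name[connectivity.normalize_atom_name(
                _water_alias(res, atom.name), tmpl_names)] = atom
        for a, b in tmpl:
            if a in by_name and b in by_name:
                graph.add_bond(by_name[a].serial, by_name[b].serial)
        _attach_orphan_hydrogens(res, by_name, tmpl, graph)

    _peptide_bonds(model, graph)
    _disulfide_bonds(model, graph)
    return graph


def _water_alias(res: Residue, name: str) -> str:
    if res.is_water:
        return connectivity.WATER_ATOM_ALIASES.get(name, name)
    return name


def _attach_orphan_hydrogens(res, by_name, tmpl, graph) -> None:
    bonded = set()
    for a, b in tmpl:
        bonded.add(a)
        bonded.add(b)
    heavies = [a for a in res.atoms if a.element != "H"]
    for name, atom in by_name.items():
        if atom.element == "H" and name not in bonded and heavies:
            d = cdist(atom.coords[None, :], np.array([h.coords for h in heavies]))
            i = int(np.argmin(d))
            if d[0, i] <= ORPHAN_H_MAX:
                graph.add_bond(atom.serial, heavies[i].serial)


def _distance_bonds(atoms: list[Atom], graph: BondGraph) -> None:
    if len(atoms) < 2:
        return
    pos = np.array([a.coords for a in atoms])
    rad = np.array([covalent_radius(a.element) for a in atoms])
    d = cdist(pos, pos)
    cut = COVALENT_SCALE * (rad[:, None] + rad[None, :])
    ii, jj = np.nonzero((d <= cut) & (d > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            graph.add_bond(atoms[i].serial, atoms[j].serial)


def covalent_radius(element: str) -> float:
    if element.upper() == "EP":
        return 0.0
    return float(gemmi.Element(element).covalent_r)


def _peptide_bonds(model: StructureModel, graph: BondGraph) -> None:
    for chain_residues in model.chains().values():
        for r1, r2 in zip(chain_residues, chain_residues[1:]):
            c = r1.atom("C")
            n = r2.atom("N")
            if c is None or n is None:
                continue
            if abs(r2.resseq - r1.resseq) > 1 and not (r1.is_cap or r2.is_cap):
                continue
            if float(np.linalg.norm(c.coords - n.coords)) < PEPTIDE_BOND_MAX:
                graph.add_bond(c.serial, n.serial)


def _disulfide_bonds(model: StructureModel, graph: BondGraph) -> None:
    sgs = [res.atom("SG") for res in model.protein_residues
           if res.resname in ("CYS", "CYX") and res.atom("SG") is not None]
    for i, a in enumerate(sgs):
        for b in sgs[i + 1:]:
            if float(np.linalg.norm(a.coords - b.coords)) < DISULFIDE_MAX:
                graph.add_bond(a.serial, b.serial)


# ---------------------------------------------------------------------------
# writing

def write_pdb(model: StructureModel, path) -> None:
    """Write fixed-width ATOM/HETATM records, preserving serials and names."""
    lines = []
    prev_chain = None
    for res in model.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            name = a.name
            # PDB alignment: element symbols of one char start in column 14
            if len(name) < 4 and len(a.element) == 1:
                name = " " + name
            x, y, z = a.coords
            lines.append(
                f"{a.record:<6s}{a.serial:>5d} {name:<4s}{'':1s}{res.resname:>3s} "
                f"{res.chain_id:1s}{res.resseq:>4d}{res.icode or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mol2_charges(model: StructureModel, path) -> None:
    """Write all nonligand atoms with their point charges to a TRIPOS MOL2 file."""
    atoms = [a for res in model.residues if not res.is_ligand for a in res.atoms]
    if not atoms:
        raise ValueError("model has no nonligand atoms to export")
    missing = [a.serial for a in atoms if a.charge is None]
    if missing:
        raise ValueError(
            "nonligand atoms lack assigned charges; serials: "
            + ", ".join(map(str, missing)))
    lines = ["@<TRIPOS>MOLECULE", "nonligand point charges",
             f"{len(atoms)} 0 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    res_ids = {}
    for res in model.residues:
        if not res.is_ligand:
            res_ids[res.key] = len(res_ids) + 1
    for i, a in enumerate(atoms, start=1):
        res = model.residue(a.residue_key)
        x, y, z = a.coords
        lines.append(
            f"{i:>7d} {a.name:<8s}{x:>10.4f}{y:>10.4f}{z:>10.4f} "
            f"{a.element:<5s}{res_ids[res.key]:>4d} {res.resname:<8s}"
            f"{a.charge:>10.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def brute_force_bonds(model: StructureModel) -> set[frozenset[int]]:
    """O(n^2) covalent-radius bond oracle (testing aid, independent of the
    template machinery)."""
    atoms = [a for res in model.residues for a in res.atoms]
    out = set()
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            dmax = COVALENT_SCALE * (covalent_radius(a.element)
                                     + covalent_radius(b.element))
            if 1e-6 < float(np.linalg.norm(a.coords - b.coords)) <= dmax:
                out.add(frozenset((a.serial, b.serial)))
    return out
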