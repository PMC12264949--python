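"""Synthetic protein:ligand fixtures with the structure the pipeline assumes.

Builds an ideal-geometry, extended-conformation polypeptide (phi = psi =
omega = 180 deg) from internal coordinates, optionally ACE/NME capped, places
a small rigid ligand so its nearest contact with a chosen residue is an exact
target distance (approaching along the direction of a chosen anchor atom), adds
far-field waters, and emits a companion per-atom charge table whose residue
sums are exact integers.  Everything is deterministic under a fixed seed.

The geometry is deliberately idealized (no realistic conformations, no
solvation): every constraint the tests assert is checkable from coordinates
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import TETRAHEDRAL, place_internal, complete_hydrogens, unit
from .data import connectivity
from .data.charges import RESIDUE_CHARGES, WATER_MODELS
from .structure import Atom, Residue, StructureModel, build_bond_graph, write_pdb

# ideal backbone internal coordinates (Angstrom / degrees)
R_N_CA, R_CA_C, R_C_N = 1.458, 1.522, 1.329
R_C_O, R_N_H = 1.229, 1.010
A_CA_C_N, A_C_N_CA, A_N_CA_C = 116.6, 121.7, 111.2
A_CA_C_O, A_C_N_H = 120.4, 119.5

_XH_LENGTH = {"C": 1.090, "N": 1.010, "O": 0.960, "S": 1.340}

# side-chain z-matrices: (atom, (ref_a, ref_b, ref_c), r, theta, phi).
# ref "-X" means atom X of the previous residue; ref_c is the bonded parent.
_CHAIN = lambda name, refs, r=1.526, th=111.0, ph=180.0: (name, refs, r, th, ph)  # noqa: E731

SIDECHAIN_ZMATRIX: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.410, 109.5, 180.0),
            ("HG", ("CA", "CB", "OG"), 0.960, 108.5, 180.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.810, 114.0, 180.0),
            ("HG", ("CA", "CB", "SG"), 1.340, 96.0, 180.0)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.410, 109.5, 180.0),
            ("HG1", ("CA", "CB", "OG1"), 0.960, 108.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.526, 111.0, -60.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.526, 111.0, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.526, 111.0, -60.0)],
    "LEU": [_CHAIN("CG", ("N", "CA", "CB"), th=114.0),
            ("CD1", ("CA", "CB", "CG"), 1.526, 111.0, 180.0),
            ("CD2", ("CA", "CB", "CG"), 1.526, 111.0, 60.0)],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.526, 111.0, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.526, 111.0, -60.0),
            _CHAIN("CD1", ("CA", "CB", "CG1"))],
    "MET": [_CHAIN("CG", ("N", "CA", "CB")),
            ("SD", ("CA", "CB", "CG"), 1.810, 112.0, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.790, 100.0, 180.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.522, 112.0, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.250, 118.4, 90.0),
            ("OD2", ("CA", "CB", "CG"), 1.250, 118.4, -90.0)],
    "ASN": [("CG", ("N", "CA", "CB"), 1.522, 112.0, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.229, 120.4, 90.0),
            ("ND2", ("CA", "CB", "CG"), 1.335, 116.6, -90.0),
            ("HD21", ("CB", "CG", "ND2"), 1.010, 119.8, 0.0),
            ("HD22", ("CB", "CG", "ND2"), 1.010, 119.8, 180.0)],
    "GLU": [_CHAIN("CG", ("N", "CA", "CB")),
            ("CD", ("CA", "CB", "CG"), 1.522, 112.0, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.250, 118.4, 90.0),
            ("OE2", ("CB", "CG", "CD"), 1.250, 118.4, -90.0)],
    "GLN": [_CHAIN("CG", ("N", "CA", "CB")),
            ("CD", ("CA", "CB", "CG"), 1.522, 112.0, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.229, 120.4, 90.0),
            ("NE2", ("CB", "CG", "CD"), 1.335, 116.6, -90.0),
            ("HE21", ("CG", "CD", "NE2"), 1.010, 119.8, 0.0),
            ("HE22", ("CG", "CD", "NE2"), 1.010, 119.8, 180.0)],
    "LYS": [_CHAIN("CG", ("N", "CA", "CB")),
            _CHAIN("CD", ("CA", "CB", "CG")),
            _CHAIN("CE", ("CB", "CG", "CD")),
            ("NZ", ("CG", "CD", "CE"), 1.471, 111.0, 180.0)],
    "ARG": [_CHAIN("CG", ("N", "CA", "CB")),
            _CHAIN("CD", ("CA", "CB", "CG")),
            ("NE", ("CB", "CG", "CD"), 1.463, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.340, 124.0, 180.0),
            ("HE", ("CG", "CD", "NE"), 1.010, 118.0, 0.0),
            ("NH1", ("CD", "NE", "CZ"), 1.340, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.340, 120.0, 180.0),
            ("HH11", ("NE", "CZ", "NH1"), 1.010, 120.0, 0.0),
            ("HH12", ("NE", "CZ", "NH1"), 1.010, 120.0, 180.0),
            ("HH21", ("NE", "CZ", "NH2"), 1.010, 120.0, 0.0),
            ("HH22", ("NE", "CZ", "NH2"), 1.010, 120.0, 180.0)],
}

SUPPORTED_RESIDUES = set(SIDECHAIN_ZMATRIX)

def _ligand_template(kind: str) -> list[tuple[str, str, np.ndarray]]:
    """Rigid ligand geometry in a local frame; +x points away from the protein
    and the first-listed atom sits at the origin (roughly proximal)."""
    o1 = np.zeros(3)
    c1 = np.array([1.41, 0.0, 0.0])
    atoms = [("O1", "O", o1), ("C1", "C", c1)]
    (ho1,) = complete_hydrogens(o1, [c1], 1, r=0.96)
    atoms.append(("HO1", "H", ho1))
    if kind == "methanol":
        for i, h in enumerate(complete_hydrogens(c1, [o1], 3), start=1):
            atoms.append((f"H1{i}", "H", h))
    elif kind == "ethanol":
        c2 = place_internal(ho1, o1, c1, 1.526, 109.5, 180.0)
        atoms.insert(2, ("C2", "C", c2))
        for i, h in enumerate(complete_hydrogens(c1, [o1, c2], 2), start=1):
            atoms.append((f"H1{i}", "H", h))
        for i, h in enumerate(complete_hydrogens(c2, [c1], 3), start=1):
            atoms.append((f"H2{i}", "H", h))
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")
    return atoms


LIGAND_TEMPLATES = {"methanol": _ligand_template("methanol"),
                    "ethanol": _ligand_template("ethanol")}


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for one synthetic protein:ligand complex."""

    n_residues: int = 5
    sequence: list[str] | None = None
    capped: bool = True
    ligand_kind: str = "methanol"
    ligand_distance: float = 4.0
    ligand_target_residue: int | None = None  # 1-based protein residue index
    ligand_target_atom: str = "CB"
    n_waters: int = 0
    seed: int = 0
    water_model: str = "tip3p"
    extra_serial_offset: int = 0

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.ligand_distance <= 1.5:
            raise ValueError("ligand_distance must exceed 1.5 Angstrom")
        if self.sequence is None:
            seq = ["ALA"] * self.n_residues
            if self.n_residues >= 4:
                seq[1] = "ARG"
                seq[-2] = "ASP"
            self.sequence = seq
        if len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        unknown = set(self.sequence) - SUPPORTED_RESIDUES
        if unknown:
            raise ValueError(f"unsupported fixture residues: {sorted(unknown)}")
        if self.ligand_target_residue is None:
            middle = (self.n_residues + 1) // 2
            # long charged side chains (ARG) cannot anchor the ligand without
            # shadowing it; aim for the ALA nearest the chain middle instead
            if self.sequence[middle - 1] == "ALA" or "ALA" not in self.sequence:
                self.ligand_target_residue = middle
            else:
                alas = [i + 1 for i, r in enumerate(self.sequence)
                        if r == "ALA"]
                self.ligand_target_residue = min(
                    alas, key=lambda i: (abs(i - middle), i))
        if self.ligand_kind not in LIGAND_TEMPLATES:
            raise ValueError(f"unknown ligand kind {self.ligand_kind!r}")


# ---------------------------------------------------------------------------


def build_fixture_model(spec: FixtureSpec) -> tuple[StructureModel, dict[int, float]]:
    """In-memory fixture: StructureModel plus serial -> charge table."""
    rng = np.random.default_rng(spec.seed)
    residues, charges = _build_peptide(spec)
    model = StructureModel(residues=residues)
    _place_ligand(spec, model, rng)
    _place_waters(spec, model, charges, rng)
    model.reindex()
    model.bonds = build_bond_graph(model)
    return model, charges


def make_polypeptide_complex(spec: FixtureSpec, pdb_path, charges_path
                             ) -> tuple[Path, Path]:
    """Write the fixture complex as a PDB file plus a serial->charge table."""
    model, charges = build_fixture_model(spec)
    pdb_path, charges_path = Path(pdb_path), Path(charges_path)
    write_pdb(model, pdb_path)
    lines = [f"{serial} {charges[serial]:.6f}" for serial in sorted(charges)]
    charges_path.write_text("\n".join(lines) + "\n")
    return pdb_path, charges_path


def perturb_fixture(kind: str, pdb_in, charges_in, pdb_out, charges_out,
                    delta: float = 0.05) -> tuple:
    """Apply exactly one named corruption; returns the affected residue key.

    Kinds: ``break_integer_charge`` (shift one atom's tabulated charge by
    ``delta``), ``delete_atom`` (drop one side-chain atom record),
    ``rename_residue`` (rename the middle residue to an unknown name).
    """
    from .structure import parse_pdb

    model = parse_pdb(pdb_in)
    charges = load_charge_table(charges_in)
    protein = [r for r in model.protein_residues if not r.is_cap]
    target = protein[len(protein) // 2]

    if kind == "break_integer_charge":
        serial = target.atoms[0].serial
        charges[serial] += delta
    elif kind == "delete_atom":
        victim = next(a for a in reversed(target.atoms)
                      if a.name not in ("N", "CA", "C", "O"))
        target.atoms.remove(victim)
        charges.pop(victim.serial, None)
        model.reindex()
    elif kind == "rename_residue":
        target.resname = "UNK"
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")

    write_pdb(model, pdb_out)
    Path(charges_out).write_text(
        "\n".join(f"{s} {charges[s]:.6f}" for s in sorted(charges)) + "\n")
    return target.key


def load_charge_table(path) -> dict[int, float]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        serial, charge = line.split()
        out[int(serial)] = float(charge)
    return out


# ---------------------------------------------------------------------------
# peptide construction


def _build_peptide(spec: FixtureSpec) -> tuple[list[Residue], dict[int, float]]:
    serial = [spec.extra_serial_offset]  # mutable counter

    def new_atom(res: Residue, name: str, element: str, pos) -> Atom:
        serial[0] += 1
        atom = Atom(serial=serial[0], name=name, element=element,
                    coords=np.asarray(pos, float), record="ATOM",
                    residue_key=res.key)
        res.atoms.append(atom)
        return atom

    residues: list[Residue] = []
    pos: dict[tuple[int, str], np.ndarray] = {}  # (res index, name) -> coords

    # ACE frame bootstraps the chain whether or not caps are kept
    ace = Residue(chain_id="A", resseq=0, icode="", resname="ACE", is_cap=True)
    ch3 = np.zeros(3)
    c = np.array([1.522, 0.0, 0.0])
    o = place_internal(np.array([0.0, 0.0, 1.0]), ch3, c, R_C_O, A_CA_C_O, 0.0)
    idx0 = -1
    pos[(idx0, "CA")] = ch3  # ACE CH3 plays the role of the previous CA
    pos[(idx0, "C")] = c
    pos[(idx0, "O")] = o
    # dihedral reference standing in for the previous N: syn to O so that the
    # next residue's N comes out anti to O (planar amide)
    pos[(idx0, "N")] = place_internal(o, c, ch3, 1.09, 109.5, 0.0)
    if spec.capped:
        new_atom(ace, "CH3", "C", ch3)
        for name, p in zip(("HH31", "HH32", "HH33"),
                           [place_internal(o, c, ch3, 1.09, TETRAHEDRAL, ph)
                            for ph in (60.0, 180.0, 300.0)]):
            new_atom(ace, name, "H", p)
        new_atom(ace, "C", "C", c)
        new_atom(ace, "O", "O", o)
        residues.append(ace)

    for i, resname in enumerate(spec.sequence):
        res = Residue(chain_id="A", resseq=i + 1, icode="", resname=resname)
        prev = i - 1
        n = place_internal(pos[(prev, "N")], pos[(prev, "CA")], pos[(prev, "C")],
                           R_C_N, A_CA_C_N, 180.0)
        ca = place_internal(pos[(prev, "CA")], pos[(prev, "C")], n,
                            R_N_CA, A_C_N_CA, 180.0)
        cc = place_internal(pos[(prev, "C")], n, ca, R_CA_C, A_N_CA_C, 180.0)
        oo = place_internal(n, ca, cc, R_C_O, A_CA_C_O, 0.0)
        h = place_internal(pos[(prev, "O")], pos[(prev, "C")], n,
                           R_N_H, A_C_N_H, 180.0)
        pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], pos[(i, "O")] = n, ca, cc, oo

        new_atom(res, "N", "N", n)
        new_atom(res, "H", "H", h)
        new_atom(res, "CA", "C", ca)
        local = {"N": n, "CA": ca, "C": cc,
                 "-N": pos[(prev, "N")], "-CA": pos[(prev, "CA")],
                 "-C": pos[(prev, "C")]}
        if resname == "GLY":
            for name, p in zip(("HA2", "HA3"),
                               complete_hydrogens(ca, [n, cc], 2)):
                new_atom(res, name, "H", p)
        else:
            cb = place_internal(pos[(prev, "C")], n, ca, 1.526, 110.4, -60.0)
            ha = place_internal(pos[(prev, "C")], n, ca, 1.090, 109.0, 60.0)
            local["CB"] = cb
            new_atom(res, "HA", "H", ha)
            new_atom(res, "CB", "C", cb)
            for name, refs, r, th, ph in SIDECHAIN_ZMATRIX[resname]:
                p = place_internal(local[refs[0]], local[refs[1]],
                                   local[refs[2]], r, th, ph)
                local[name] = p
                new_atom(res, name, "H" if name.startswith("H") else name[0], p)
            _complete_residue_hydrogens(res, resname, local, new_atom)
        new_atom(res, "C", "C", cc)
        new_atom(res, "O", "O", oo)
        res.atoms.sort(key=lambda a: _template_order(resname, a.name))
        _renumber_in_place(res, serial)
        residues.append(res)

    last = len(spec.sequence) - 1
    if spec.capped:
        nme = Residue(chain_id="A", resseq=len(spec.sequence) + 1, icode="",
                      resname="NME", is_cap=True)
        n = place_internal(pos[(last, "N")], pos[(last, "CA")], pos[(last, "C")],
                           1.335, A_CA_C_N, 180.0)
        h = place_internal(pos[(last, "O")], pos[(last, "C")], n,
                           R_N_H, A_C_N_H, 180.0)
        ch3 = place_internal(pos[(last, "CA")], pos[(last, "C")], n,
                             1.455, A_C_N_CA, 180.0)
        new_atom(nme, "N", "N", n)
        new_atom(nme, "H", "H", h)
        new_atom(nme, "CH3", "C", ch3)
        for name, p in zip(("HH31", "HH32", "HH33"),
                           [place_internal(pos[(last, "C")], n, ch3, 1.09,
                                           TETRAHEDRAL, ph)
                            for ph in (60.0, 180.0, 300.0)]):
            new_atom(nme, name, "H", p)
        residues.append(nme)

    charges = {}
    for res in residues:
        table = RESIDUE_CHARGES[res.resname]
        for atom in res.atoms:
            charges[atom.serial] = table[atom.name]
    return residues, charges


def _complete_residue_hydrogens(res, resname, local, new_atom) -> None:
    """Fill in the aliphatic hydrogens the z-matrix left out, using the
    connectivity template to find each heavy atom's H names and neighbors."""
    bonds = connectivity.RESIDUE_BONDS[resname]
    placed = {a.name for a in res.atoms} | {"C", "O"}
    adj: dict[str, list[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for heavy, nbrs in adj.items():
        if heavy.startswith("H") or heavy not in local:
            continue
        missing = [n for n in nbrs if n.startswith("H") and n not in placed
                   and n in RESIDUE_CHARGES[resname]]
        if not missing:
            continue
        heavy_nbrs = [local[n] for n in nbrs if not n.startswith("H")
                      and n in local]
        r = _XH_LENGTH.get(heavy[0], 1.090)
        positions = complete_hydrogens(local[heavy], heavy_nbrs,
                                       len(missing), r=r)
        for name, p in zip(missing, positions):
            local[name] = p
            new_atom(res, name, "H", p)
            placed.add(name)


def _template_order(resname: str, name: str) -> int:
    order = list(RESIDUE_CHARGES[resname].keys())
    return order.index(name) if name in order else len(order)


def _renumber_in_place(res: Residue, serial_counter: list[int]) -> None:
    """Re-issue serials in template order so files are stable across builds."""
    start = min(a.serial for a in res.atoms)
    for offset, atom in enumerate(res.atoms):
        atom.serial = start + offset
    serial_counter[0] = start + len(res.atoms) - 1


# ---------------------------------------------------------------------------
# ligand and waters


def _place_ligand(spec: FixtureSpec, model: StructureModel,
                  rng: np.random.Generator) -> None:
    protein = [r for r in model.protein_residues if not r.is_cap]
    target = protein[spec.ligand_target_residue - 1]
    anchor = target.atom(spec.ligand_target_atom)
    if anchor is None:
        raise FixtureError(
            f"target residue {target} has no atom {spec.ligand_target_atom}")
    partner = target.atom("CA") or target.atoms[0]
    base_dir = unit(anchor.coords - partner.coords)

    template = LIGAND_TEMPLATES[spec.ligand_kind]
    other_atoms = np.array([a.coords for r in model.residues for a in r.atoms])
    d_target = spec.ligand_distance
    # tilt axis pointing away from the bulk of the structure, so crowded
    # approach directions (long neighboring side chains) can be escaped
    away = anchor.coords - other_atoms.mean(axis=0)
    away -= np.dot(away, base_dir) * base_dir
    away = unit(away) if np.linalg.norm(away) > 1e-6 \
        else _frame_about(base_dir, 0.0)[:, 1]

    target_coords = np.array([a.coords for a in target.atoms])
    trials = [(tilt, k) for tilt in (0.0, 20.0, -20.0, 40.0, -40.0, 60.0)
              for k in range(8)]
    for tilt, k in trials:
        t_rad = np.radians(tilt)
        direction = unit(np.cos(t_rad) * base_dir + np.sin(t_rad) * away)

        def coords_at(t: float, frame: np.ndarray) -> list[np.ndarray]:
            base = anchor.coords + t * direction
            return [base + frame @ np.asarray(p, float) for _, _, p in template]

        theta = (k / 8.0 + rng.uniform(0, 1 / 8.0)) * 2 * np.pi
        frame = _frame_about(direction, theta)
        # bisect the offset along the approach direction so the nearest
        # ligand / target-residue contact is exactly d_target
        lo_t, hi_t = d_target * 0.5, d_target + 4.0
        for _ in range(80):
            mid = 0.5 * (lo_t + hi_t)
            dmin = min(np.min(np.linalg.norm(target_coords - c, axis=1))
                       for c in coords_at(mid, frame))
            if dmin < d_target:
                lo_t = mid
            else:
                hi_t = mid
        coords = coords_at(hi_t, frame)
        d_res = min(np.min(np.linalg.norm(target_coords - c, axis=1))
                    for c in coords)
        d_all = min(np.min(np.linalg.norm(other_atoms - c, axis=1))
                    for c in coords)
        if abs(d_res - d_target) < 1e-6 and d_all >= d_target - 1e-6:
            lig = Residue(chain_id="L", resseq=1, icode="", resname="LIG",
                          is_ligand=True)
            serial = model.next_serial()
            for (name, element, _), c in zip(template, coords):
                lig.atoms.append(Atom(serial=serial, name=name, element=element,
                                      coords=c, record="HETATM",
                                      residue_key=lig.key))
                serial += 1
            model.residues.append(lig)
            model.reindex()
            return
    raise FixtureError("could not place ligand without violating the "
                       "distance constraint; increase ligand_distance")


def _frame_about(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix mapping the ligand local frame (+x along axis)."""
    x = unit(axis)
    tmp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tmp, x)) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    y0 = unit(np.cross(x, tmp))
    z0 = np.cross(x, y0)
    y = np.cos(theta) * y0 + np.sin(theta) * z0
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _place_waters(spec: FixtureSpec, model: StructureModel,
                  charges: dict[int, float], rng: np.random.Generator) -> None:
    if spec.n_waters == 0:
        return
    water = WATER_MODELS[spec.water_model]
    all_coords = np.array([a.coords for r in model.residues for a in r.atoms])
    lo = all_coords.min(axis=0)
    hi = all_coords.max(axis=0)
    base = np.array([lo[0], lo[1], hi[2] + 6.0])
    placed = 0
    serial = model.next_serial()
    resseq = 1
    for gx in range(10):
        for gy in range(10):
            if placed >= spec.n_waters:
                break
            o = base + np.array([4.0 * gx, 4.0 * gy, 0.0]) \
                + rng.uniform(-0.4, 0.4, size=3)
            if np.min(np.linalg.norm(all_coords - o, axis=1)) < 2.8:
                continue
            h1 = o + 0.9572 * np.array([1.0, 0.0, 0.0])
            h2 = o + 0.9572 * np.array(
                [np.cos(np.radians(104.52)), np.sin(np.radians(104.52)), 0.0])
            res = Residue(chain_id="W", resseq=resseq, icode="", resname="HOH",
                          is_water=True)
            for name, element, c, q in (("O", "O", o, water["qO"]),
                                        ("H1", "H", h1, water["qH"]),
                                        ("H2", "H", h2, water["qH"])):
                res.atoms.append(Atom(serial=serial, name=name, element=element,
                                      coords=c, record="HETATM",
                                      residue_key=res.key))
                charges[serial] = q
                serial += 1
            model.residues.append(res)
            all_coords = np.vstack([all_coords, [o, h1, h2]])
            resseq += 1
            placed += 1
    if placed < spec.n_waters:
        raise FixtureError("could not place the requested number of waters")
    model.reindex()
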