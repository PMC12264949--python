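"""Quantum-chemistry input file emission.

From one pipeline state, up to three supermolecular jobs are written (ligand
QM-only, protein QM/MM, complex QM/MM) so that an interaction energy can be
formed as E_int = E(complex) - E(protein) - E(ligand).  Counterpoise variants
carry the partner subsystem as ghost atoms so every monomer is computed in
the dimer basis.  SAPT mode emits a single two-monomer file instead, since
SAPT returns the interaction energy directly.  Output is deterministic:
stable atom ordering (ligand in file order, protein QM atoms in file order,
link atoms appended last per cut), fixed precision, no timestamps.

Three dialects are supported (Psi4-style, NWChem-style, Q-Chem-style).  The
geometry, external-charge values and charge/multiplicity content is identical
across dialects; only the surrounding syntax differs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .region import RegionAssignment
from .schemes import PointCharge, PointChargeSet
from .structure import StructureModel

logger = logging.getLogger(__name__)

SOFTWARE_TAGS = ("psi4_format", "nwchem_format", "qchem_format")
_EXT = {"psi4_format": "psi4.in", "nwchem_format": "nw", "qchem_format": "qcin"}


class WriterError(ValueError):
    pass


@dataclass
class JobSpec:
    software: str = "psi4_format"
    method: str = "hf"
    basis: str = "sto-3g"
    ligand_charge: int = 0
    ligand_multiplicity: int = 1
    qm_region_charge: int | None = None  # None: derived from formal charges
    qm_region_multiplicity: int = 1
    counterpoise: bool = False
    sapt_mode: bool = False
    fsapt: bool = False
    scf_convergence: int = 6  # exponent: SCF converged to 10^-N
    charges_in_ligand_file: bool = False
    extra_keywords: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.software not in SOFTWARE_TAGS:
            raise WriterError(
                f"unsupported software tag {self.software!r}; "
                f"supported: {', '.join(SOFTWARE_TAGS)}")
        if self.sapt_mode and self.counterpoise:
            raise WriterError(
                "counterpoise is inapplicable to SAPT, which computes the "
                "interaction energy directly")
        if self.ligand_multiplicity < 1 or self.qm_region_multiplicity < 1:
            raise WriterError("multiplicities must be positive")
        if self.sapt_mode and not self.method.lower().startswith("sapt"):
            self.method = "sapt0"


@dataclass
class QMSystem:
    name: str
    atoms: list[tuple[str, np.ndarray, bool]]  # (element, coords, is_ghost)
    charge: int
    multiplicity: int

    @property
    def n_real(self) -> int:
        return sum(1 for _, _, ghost in self.atoms if not ghost)

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# system assembly


def build_systems(assignment: RegionAssignment, pcs: PointChargeSet,
                  model: StructureModel, spec: JobSpec
                  ) -> dict[str, tuple[QMSystem, PointChargeSet]]:
    """Assemble the ligand / protein / complex systems with shared charges."""
    ligand_atoms = [(a.element, a.coords, False)
                    for r in model.ligand_residues for a in r.atoms]
    if not ligand_atoms:
        raise WriterError("model has no ligand atoms")
    protein_atoms = _protein_qm_atoms(assignment, model)

    prot_charge = spec.qm_region_charge
    if prot_charge is None:
        prot_charge = derive_qm_region_charge(assignment, model)
    empty = PointChargeSet(scheme=pcs.scheme)

    lig = QMSystem("ligand", list(ligand_atoms), spec.ligand_charge,
                   spec.ligand_multiplicity)
    prot = QMSystem("protein", list(protein_atoms), prot_charge,
                    spec.qm_region_multiplicity)
    comp = QMSystem("complex", list(ligand_atoms) + list(protein_atoms),
                    spec.ligand_charge + prot_charge,
                    _combine_multiplicity(spec))
    if spec.counterpoise:
        lig.atoms += [(el, xyz, True) for el, xyz, _ in protein_atoms]
        prot.atoms += [(el, xyz, True) for el, xyz, _ in ligand_atoms]
    lig_pcs = pcs if spec.charges_in_ligand_file else empty
    return {"ligand": (lig, lig_pcs), "protein": (prot, pcs),
            "complex": (comp, pcs)}


def _protein_qm_atoms(assignment: RegionAssignment, model: StructureModel):
    atoms = []
    for res in model.residues:
        if res.is_ligand:
            continue
        for a in res.atoms:
            if a.serial in assignment.qm_serials and a.element != "EP":
                atoms.append((a.element, a.coords, False))
    for cut in assignment.cut_bonds:  # link hydrogens last, in bond order
        atoms.append((cut.link_element, cut.link_coords, False))
    return atoms


def derive_qm_region_charge(assignment: RegionAssignment,
                            model: StructureModel) -> int:
    """Sum of formal integer charges of residues with any atom in QM."""
    total = 0
    for res in model.residues:
        if res.is_ligand:
            continue
        if any(a.serial in assignment.qm_serials for a in res.atoms):
            charges = [a.charge for a in res.atoms if a.charge is not None]
            total += int(round(sum(charges)))
    return total


def _combine_multiplicity(spec: JobSpec) -> int:
    if spec.ligand_multiplicity == 1 and spec.qm_region_multiplicity == 1:
        return 1
    return max(spec.ligand_multiplicity, spec.qm_region_multiplicity)


# ---------------------------------------------------------------------------
# dialect writers


def write_input(system: QMSystem, pcs: PointChargeSet, spec: JobSpec,
                path) -> Path:
    """Write one job file in the requested dialect."""
    writer = {"psi4_format": _write_psi4, "nwchem_format": _write_nwchem,
              "qchem_format": _write_qchem}[spec.software]
    text = writer([system], pcs, spec)
    path = Path(path)
    path.write_text(text)
    return path


def write_sapt_input(ligand: QMSystem, protein: QMSystem,
                     pcs: PointChargeSet, spec: JobSpec, path) -> Path:
    """Single SAPT file: monomer A = ligand, monomer B = capped QM protein."""
    if not spec.sapt_mode:
        raise WriterError("write_sapt_input requires sapt_mode")
    if spec.software != "psi4_format":
        raise WriterError("SAPT single-file mode is emitted in the "
                          "Psi4-style dialect only")
    text = _write_psi4([ligand, protein], pcs, spec, sapt=True)
    path = Path(path)
    path.write_text(text)
    return path


def default_filename(system_name: str, spec: JobSpec) -> str:
    return f"{system_name}.{_EXT[spec.software]}"


def _fmt_xyz(xyz) -> str:
    return f"{xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}"


def _write_psi4(systems, pcs, spec, sapt: bool = False) -> str:
    lines = [f"# {systems[0].name if not sapt else 'sapt dimer'} "
             "(qmmmprep, psi4-style)", "",
             "molecule {"]
    for i, system in enumerate(systems):
        if i > 0:
            lines.append("--")
        lines.append(f"{system.charge} {system.multiplicity}")
        for el, xyz, ghost in system.atoms:
            label = f"Gh({el})" if ghost else el
            lines.append(f"  {label:<6s} {_fmt_xyz(xyz)}")
    lines += ["units angstrom", "no_com", "no_reorient", "symmetry c1", "}",
              ""]
    if len(pcs):
        lines.append("external_potentials = [")
        for pc in pcs.charges:
            lines.append(f"  [{pc.value:12.6f}, {_fmt_xyz(pc.position)}],")
        lines += ["]", ""]
    lines += ["set {",
              f"    basis {spec.basis}",
              f"    e_convergence {spec.scf_convergence}",
              f"    d_convergence {spec.scf_convergence}",
              "    scf_type df",
              "}", ""]
    lines += list(spec.extra_keywords)
    args = f"'{spec.method}'"
    if len(pcs):
        args += ", external_potentials=external_potentials"
    lines += [f"energy({args})", ""]
    return "\n".join(lines)


def _write_nwchem(systems, pcs, spec) -> str:
    (system,) = systems
    lines = ["echo", f"start {system.name}",
             f'title "{system.name} (qmmmprep, nwchem-style)"',
             f"charge {system.charge}",
             "geometry units angstroms noautosym noautoz"]
    for el, xyz, ghost in system.atoms:
        label = f"bq{el}" if ghost else el
        lines.append(f"  {label:<6s} {_fmt_xyz(xyz)}")
    lines.append("end")
    if len(pcs):
        lines.append("bq units angstroms")
        for pc in pcs.charges:
            lines.append(f"  {_fmt_xyz(pc.position)} {pc.value:12.6f}")
        lines.append("end")
    lines += ["basis", f" * library {spec.basis}", "end",
              "scf",
              f" nopen {system.multiplicity - 1}",
              f" thresh 1e-{spec.scf_convergence:02d}",
              "end"]
    lines += list(spec.extra_keywords)
    lines += [f"task {spec.method} energy", ""]
    return "\n".join(lines)


def _write_qchem(systems, pcs, spec) -> str:
    (system,) = systems
    lines = ["$comment", f"{system.name} (qmmmprep, qchem-style)", "$end", "",
             "$molecule", f"{system.charge} {system.multiplicity}"]
    for el, xyz, ghost in system.atoms:
        label = f"@{el}" if ghost else el
        lines.append(f"  {label:<6s} {_fmt_xyz(xyz)}")
    lines += ["$end", ""]
    if len(pcs):
        lines.append("$external_charges")
        for pc in pcs.charges:
            lines.append(f"  {_fmt_xyz(pc.position)} {pc.value:12.6f}")
        lines += ["$end", ""]
    lines += ["$rem",
              f"    METHOD {spec.method}",
              f"    BASIS {spec.basis}",
              f"    SCF_CONVERGENCE {spec.scf_convergence}"]
    lines += [f"    {kw}" for kw in spec.extra_keywords]
    lines += ["$end", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# parse-back (verification aid: recover the semantic content of a written file)


def read_back(path) -> dict:
    """Parse a written input file back into its semantic content.

    Returns dict with 'atoms' [(element, (x,y,z), is_ghost)], 'charges'
    [(q, (x,y,z))], and 'charge_mult' [(charge, mult), ...].  Dialect is
    auto-detected.
    """
    text = Path(path).read_text()
    if "$molecule" in text:
        return _read_back_qchem(text)
    if "geometry units" in text:
        return _read_back_nwchem(text)
    return _read_back_psi4(text)


_NUM = r"[-+]?\d+\.\d+"


def _read_back_psi4(text: str) -> dict:
    atoms, charges, cm = [], [], []
    in_mol = in_pot = False
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("molecule"):
            in_mol = True
            continue
        if in_mol:
            if s == "}" or s.startswith(("units", "no_", "symmetry")):
                in_mol = s != "}" and in_mol
                if s == "}":
                    in_mol = False
                continue
            if s == "--":
                continue
            m = re.match(r"^(-?\d+)\s+(\d+)$", s)
            if m:
                cm.append((int(m.group(1)), int(m.group(2))))
                continue
            parts = s.split()
            if len(parts) == 4:
                el = parts[0]
                ghost = el.startswith("Gh(")
                el = el[3:-1] if ghost else el
                atoms.append((el, tuple(float(x) for x in parts[1:]), ghost))
            continue
        if s.startswith("external_potentials"):
            in_pot = True
            continue
        if in_pot:
            if s.startswith("]"):
                in_pot = False
                continue
            nums = [float(x) for x in re.findall(_NUM, s)]
            if len(nums) == 4:
                charges.append((nums[0], tuple(nums[1:])))
    return {"atoms": atoms, "charges": charges, "charge_mult": cm}


def _read_back_nwchem(text: str) -> dict:
    atoms, charges, cm = [], [], []
    charge = 0
    mult = 1
    in_geo = in_bq = in_scf = False
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("charge "):
            charge = int(s.split()[1])
        elif s.startswith("geometry"):
            in_geo = True
        elif s.startswith("bq units"):
            in_bq = True
        elif s == "scf":
            in_scf = True
        elif s == "end":
            in_geo = in_bq = in_scf = False
        elif in_geo:
            parts = s.split()
            if len(parts) == 4:
                el = parts[0]
                ghost = el.startswith("bq")
                el = el[2:] if ghost else el
                atoms.append((el, tuple(float(x) for x in parts[1:]), ghost))
        elif in_bq:
            nums = [float(x) for x in s.split()]
            if len(nums) == 4:
                charges.append((nums[3], tuple(nums[:3])))
        elif in_scf and s.startswith("nopen"):
            mult = int(s.split()[1]) + 1
    return {"atoms": atoms, "charges": charges, "charge_mult": [(charge, mult)]}


def _read_back_qchem(text: str) -> dict:
    atoms, charges, cm = [], [], []
    section = None
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("$"):
            section = s[1:] if s != "$end" else None
            continue
        if section == "molecule":
            m = re.match(r"^(-?\d+)\s+(\d+)$", s)
            if m:
                cm.append((int(m.group(1)), int(m.group(2))))
                continue
            parts = s.split()
            if len(parts) == 4:
                el = parts[0]
                ghost = el.startswith("@")
                el = el[1:] if ghost else el
                atoms.append((el, tuple(float(x) for x in parts[1:]), ghost))
        elif section == "external_charges":
            nums = [float(x) for x in s.split()]
            if len(nums) == 4:
                charges.append((nums[3], tuple(nums[:3])))
    return {"atoms": atoms, "charges": charges, "charge_mult": cm}


# ---------------------------------------------------------------------------
# F-SAPT functional-group partition


def make_fsapt_partition(assignment: RegionAssignment, model: StructureModel
                         ) -> dict[str, dict[str, list[int]]]:
    """Functional-group partitions for F-SAPT post-analysis.

    Monomer A (the ligand) is one fragment.  Monomer B (the capped QM
    protein) is partitioned into per-residue side-chain fragments (CA, HA and
    the side chain), per-peptide-bond fragments {C(i), O(i), N(i+1), H(i+1)},
    cap methyl fragments, and water/ion fragments; each link hydrogen joins
    its Q1 atom's fragment.  Indices are 1-based within each monomer's atom
    list.  Returns {"fA": {...}, "fB": {...}}.
    """
    lig_n = sum(len(r.atoms) for r in model.ligand_residues)
    fa = {"Ligand": list(range(1, lig_n + 1))}

    # 1-based index of each QM serial in the protein monomer atom order
    index: dict[int, int] = {}
    pos = 0
    for res in model.residues:
        if res.is_ligand:
            continue
        for a in res.atoms:
            if a.serial in assignment.qm_serials and a.element != "EP":
                pos += 1
                index[a.serial] = pos
    link_index = {cut.bond_id: pos + i + 1
                  for i, cut in enumerate(assignment.cut_bonds)}

    fb: dict[str, list[int]] = {}
    claimed: set[int] = set()

    def tag(res) -> str:
        return f"{res.resname}{res.chain_id}{res.resseq}{res.icode}"

    # peptide-bond fragments between consecutive chain residues
    for cid, residues in model.chains().items():
        for r1, r2 in zip(residues, residues[1:]):
            members = []
            for res, names in ((r1, ("C", "O", "OXT")), (r2, ("N", "H"))):
                members += [a.serial for a in res.atoms
                            if a.name in names and a.serial in index]
            if members:
                fb[f"pep_{tag(r1)}_{tag(r2)}"] = [index[s] for s in members]
                claimed.update(members)

    # side-chain / cap / water / ion fragments take everything unclaimed
    for res in model.residues:
        if res.is_ligand:
            continue
        members = [a.serial for a in res.atoms
                   if a.serial in index and a.serial not in claimed]
        if members:
            name = ("cap_" if res.is_cap else
                    "wat_" if res.is_water else
                    "ion_" if StructureModel.is_ion(res) else "sc_") + tag(res)
            fb[name] = [index[s] for s in members]
            claimed.update(members)

    # link hydrogens join their Q1 atom's fragment
    for cut in assignment.cut_bonds:
        q1_pos = index[cut.q1_serial]
        for name, members in fb.items():
            if q1_pos in members:
                members.append(link_index[cut.bond_id])
                break
        else:  # pragma: no cover - defensive
            raise WriterError(
                f"link atom of cut {cut.bond_id} has no host fragment "
                f"(Q1 serial {cut.q1_serial})")

    n_total = pos + len(assignment.cut_bonds)
    covered = sorted(i for members in fb.values() for i in members)
    if covered != list(range(1, n_total + 1)):
        missing = set(range(1, n_total + 1)) - set(covered)
        raise WriterError(
            f"F-SAPT partition does not cover monomer B exactly; "
            f"missing/duplicated indices: {sorted(missing) or covered}")
    return {"fA": fa, "fB": fb}


def write_fsapt_files(partition: dict[str, dict[str, list[int]]],
                      outdir) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    for fname in ("fA", "fB"):
        path = outdir / f"{fname}.dat"
        lines = [f"{frag} " + " ".join(map(str, sorted(idx)))
                 for frag, idx in partition[fname].items()]
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths
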