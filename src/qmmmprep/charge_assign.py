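"""Point-charge assignment for all nonligand atoms.

Charges come from the packaged residue charge library (an Amber-family
emulation), from a user-supplied residue-topology file (CHARMM-style RESI
blocks), or from a plain serial->charge override table.  Waters are charged
per a rigid water-model specification; 4-site models get an extra-point (EP)
pseudo-atom inserted on the H-O-H bisector.  The ligand never receives
charges: it is always fully quantum-mechanical.

Residue charge sums are validated against the nearest integer; failures point
at structure-file errors (missing atoms, misnamed residues) and abort the
pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import unit
from .data import connectivity
from .data.charges import (ION_CHARGES, PROVENANCE, RESIDUE_CHARGES,
                           RESNAME_ALIASES, WATER_MODELS)
from .structure import Atom, Residue, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_INTEGER_TOLERANCE = 1e-3  # e


class ChargeAssignmentError(ValueError):
    pass


class IntegerChargeError(ValueError):
    def __init__(self, reports):
        self.reports = reports
        failed = [r for r in reports if not r.ok]
        lines = [f"  {r.describe()}" for r in failed]
        super().__init__(
            "residues with noninteger charges indicate structure-file errors "
            "(missing atoms or improper residue naming); correct the PDB file "
            "and rerun:\n" + "\n".join(lines))


@dataclass
class WaterModelSpec:
    name: str
    site_count: int
    qO: float
    qH: float
    qEP: float = 0.0
    rEP: float = 0.0  # Angstrom, EP on the H-O-H bisector (4-site only)

    def __post_init__(self):
        if self.site_count not in (3, 4):
            raise ValueError("site_count must be 3 or 4")
        total = self.qO + 2 * self.qH + self.qEP
        if abs(total) > 1e-6:
            raise ValueError(f"water model {self.name} is not neutral "
                             f"(sum {total:+.6f} e)")
        if self.site_count == 4 and self.rEP <= 0:
            raise ValueError("4-site water model requires rEP > 0")

    @classmethod
    def bundled(cls, name: str) -> "WaterModelSpec":
        try:
            w = WATER_MODELS[name.lower()]
        except KeyError:
            raise ChargeAssignmentError(
                f"unknown water model {name!r}; bundled: "
                + ", ".join(sorted(WATER_MODELS))) from None
        return cls(name=name.lower(), site_count=w["site_count"], qO=w["qO"],
                   qH=w["qH"], qEP=w["qEP"], rEP=w["rEP"])


@dataclass
class ChargeTemplateLibrary:
    """(resname, variant) -> atom name -> charge.  Variants: internal | cap."""

    templates: dict[tuple[str, str], dict[str, float]]
    provenance: str = PROVENANCE

    def __post_init__(self):
        for key, table in self.templates.items():
            total = sum(table.values())
            if abs(total - round(total)) > 1e-6:
                raise ChargeAssignmentError(
                    f"template {key} charges sum to {total:.6f}, "
                    "not an integer")

    @classmethod
    def bundled(cls) -> "ChargeTemplateLibrary":
        templates = {}
        for resname, table in RESIDUE_CHARGES.items():
            variant = "cap" if resname in ("ACE", "NME") else "internal"
            templates[(resname, variant)] = dict(table)
        return cls(templates=templates)

    def lookup(self, resname: str, is_cap: bool) -> dict[str, float] | None:
        resname = RESNAME_ALIASES.get(resname, resname)
        variant = "cap" if is_cap else "internal"
        table = self.templates.get((resname, variant))
        if table is None:  # fall back across variants (user libraries)
            table = self.templates.get((resname, "internal")) \
                or self.templates.get((resname, "cap"))
        return table

    def formal_charge(self, resname: str, is_cap: bool = False) -> int:
        table = self.lookup(resname, is_cap)
        if table is None:
            if resname in ION_CHARGES:
                return int(round(ION_CHARGES[resname]))
            raise KeyError(resname)
        return int(round(sum(table.values())))


@dataclass
class ResidueChargeReport:
    residue_key: tuple
    resname: str
    total: float
    deviation: float  # from nearest integer, e
    ok: bool
    offending_atoms: list[str] = field(default_factory=list)

    def describe(self) -> str:
        msg = (f"{self.resname} {self.residue_key}: sum {self.total:+.4f} e "
               f"(off integer by {self.deviation:.4f} e)")
        if self.offending_atoms:
            msg += "; template mismatch: " + ", ".join(self.offending_atoms)
        return msg


def assign_charges(model: StructureModel,
                   library: ChargeTemplateLibrary | None = None,
                   water: WaterModelSpec | None = None,
                   overrides: dict[int, float] | None = None) -> StructureModel:
    """Assign a point charge to every nonligand atom, in place.

    ``overrides`` maps atom serials directly to charges (the fixtures'
    two-column table); atoms covered there skip the template lookup.
    Assignment is a pure lookup -- atom order never affects any charge.
    """
    library = library or ChargeTemplateLibrary.bundled()
    water = water or WaterModelSpec.bundled("tip3p")
    missing_resnames = set()
    for res in model.residues:
        if res.is_ligand:
            continue
        if res.is_water:
            _charge_water(model, res, water, overrides)
            continue
        if StructureModel.is_ion(res):
            res.atoms[0].charge = (overrides or {}).get(
                res.atoms[0].serial, ION_CHARGES[res.resname])
            continue
        table = library.lookup(res.resname, res.is_cap)
        covered = overrides is not None and all(
            a.serial in overrides for a in res.atoms)
        if table is None and not covered:
            missing_resnames.add(res.resname)
            continue
        for atom in res.atoms:
            if overrides and atom.serial in overrides:
                atom.charge = overrides[atom.serial]
            elif table is not None:
                name = connectivity.normalize_atom_name(atom.name, set(table))
                atom.charge = table.get(name)
    if missing_resnames:
        raise ChargeAssignmentError(
            "no charge template for residue name(s): "
            + ", ".join(sorted(missing_resnames)))
    return model


def _charge_water(model: StructureModel, res: Residue, water: WaterModelSpec,
                  overrides: dict[int, float] | None) -> None:
    by_name = {}
    for atom in res.atoms:
        by_name[connectivity.WATER_ATOM_ALIASES.get(atom.name, atom.name)] = atom
    o = by_name.get("O")
    hs = [by_name[n] for n in ("H1", "H2") if n in by_name]
    if o is None or len(hs) != 2:
        raise ChargeAssignmentError(
            f"water {res.key} does not have O + 2 H atoms")
    o.charge = water.qO
    for h in hs:
        h.charge = water.qH
    if overrides:
        for atom in res.atoms:
            if atom.serial in overrides:
                atom.charge = overrides[atom.serial]
    if water.site_count == 4 and "EP" not in by_name:
        mid = 0.5 * (hs[0].coords + hs[1].coords)
        ep_pos = o.coords + water.rEP * unit(mid - o.coords)
        ep = Atom(serial=model.next_serial(), name="EP", element="EP",
                  coords=ep_pos, record="HETATM", residue_key=res.key,
                  charge=water.qEP)
        res.atoms.append(ep)
        model.reindex()
        if model.bonds is not None:
            model.bonds.add_bond(ep.serial, o.serial)


def check_integer_charges(model: StructureModel,
                          tolerance: float = DEFAULT_INTEGER_TOLERANCE,
                          library: ChargeTemplateLibrary | None = None
                          ) -> list[ResidueChargeReport]:
    """One report per nonligand residue; charges must already be assigned."""
    library = library or ChargeTemplateLibrary.bundled()
    reports = []
    for res in model.residues:
        if res.is_ligand:
            continue
        charges = [a.charge for a in res.atoms]
        if any(c is None for c in charges):
            unset = [a.name for a in res.atoms if a.charge is None]
            reports.append(ResidueChargeReport(
                residue_key=res.key, resname=res.resname,
                total=float("nan"), deviation=float("inf"), ok=False,
                offending_atoms=[f"{n} (no charge)" for n in unset]))
            continue
        total = float(sum(charges))
        deviation = abs(total - round(total))
        offending = _template_mismatches(res, library)
        ok = deviation <= tolerance
        reports.append(ResidueChargeReport(
            residue_key=res.key, resname=res.resname, total=total,
            deviation=deviation, ok=ok,
            offending_atoms=offending if not ok else []))
    return reports


def _template_mismatches(res: Residue,
                         library: ChargeTemplateLibrary) -> list[str]:
    if res.is_water or StructureModel.is_ion(res):
        return []
    table = library.lookup(res.resname, res.is_cap)
    if table is None:
        return [f"(no template for {res.resname})"]
    tmpl_names = set(table)
    present = {connectivity.normalize_atom_name(a.name, tmpl_names)
               for a in res.atoms}
    missing = sorted(tmpl_names - present)
    extra = sorted(present - tmpl_names)
    return [f"missing {n}" for n in missing] + [f"extra {n}" for n in extra]


def require_integer_charges(model: StructureModel,
                            tolerance: float = DEFAULT_INTEGER_TOLERANCE,
                            library: ChargeTemplateLibrary | None = None
                            ) -> list[ResidueChargeReport]:
    reports = check_integer_charges(model, tolerance, library)
    if any(not r.ok for r in reports):
        raise IntegerChargeError(reports)
    return reports


# ---------------------------------------------------------------------------
# CHARMM-style RESI topology parsing


def load_external_topology(path) -> ChargeTemplateLibrary:
    """Build a charge library from RESI blocks (``ATOM name type charge``)."""
    templates: dict[tuple[str, str], dict[str, float]] = {}
    current: dict[str, float] | None = None
    current_name = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        fields = line.split()
        keyword = fields[0].upper()
        if keyword in ("RESI", "PRES"):
            if len(fields) < 2:
                raise ChargeAssignmentError(
                    f"{path}:{lineno}: RESI line lacks a residue name")
            current_name = fields[1].upper()
            current = {}
            templates[(current_name, "internal")] = current
        elif keyword == "ATOM":
            if current is None:
                raise ChargeAssignmentError(
                    f"{path}:{lineno}: ATOM line outside a RESI block")
            if len(fields) < 4:
                raise ChargeAssignmentError(
                    f"{path}:{lineno}: ATOM line needs name, type, charge")
            try:
                current[fields[1]] = float(fields[3])
            except ValueError:
                raise ChargeAssignmentError(
                    f"{path}:{lineno}: unparseable charge {fields[3]!r}"
                ) from None
        # BOND/ANGLE/IC/GROUP etc. lines are connectivity metadata; ignored
    if not templates:
        raise ChargeAssignmentError(f"{path}: no RESI blocks found")
    return ChargeTemplateLibrary(templates=templates,
                                 provenance=f"user topology {path}")


def serialize_library(library: ChargeTemplateLibrary, path) -> None:
    lines = [f"! {library.provenance}"]
    for (resname, variant), table in sorted(library.templates.items()):
        lines.append(f"RESI {resname}  {sum(table.values()):+.4f} ! {variant}")
        for name, q in table.items():
            lines.append(f"ATOM {name:<6s} {name:<6s} {q:+.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
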