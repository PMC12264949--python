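"""QM-region templating for congeneric protein:ligand pairs.

A fair relative-interaction-energy comparison between two congeneric
complexes needs identical QM regions, but coordinates (and protein:ligand
distances) differ between the structures.  The template records which protein
residues (and which of their atoms) the QM region contained in a finished
run; applying it to a second structure maps each template residue onto the
new protein by comparing a neighborhood of five residues (resnames at
offsets -2..+2, chain ends padded with a sentinel).  Matched residues adopt
the template's membership; unmatched residues -- and all nonprotein atoms --
fall back to the distance cutoff.  Cuts, shells and link atoms are always
recomputed on the resulting selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .region import RegionAssignment, SeedSpec, absorb_clashes, place_cuts, \
    select_residues
from .structure import StructureModel

logger = logging.getLogger(__name__)

SENTINEL = "---"  # pads neighborhoods at chain ends
FORMAT_VERSION = 1


class TemplateError(ValueError):
    pass


@dataclass
class TemplateResidue:
    chain_id: str
    resseq: int
    resname: str
    atom_names: tuple[str, ...]
    signature: tuple[str, str, str, str, str]
    core: bool  # True if the residue itself was selected (CA in QM)


@dataclass
class TemplateRegion:
    residues: list[TemplateResidue]
    cutoff: float
    seed_mode: str
    seed_serial: int | None = None
    version: int = FORMAT_VERSION

    def core_residues(self) -> list[TemplateResidue]:
        return [t for t in self.residues if t.core]


def _signatures(model: StructureModel) -> dict[tuple, tuple]:
    out = {}
    for cid, residues in model.chains().items():
        names = [r.resname for r in residues]
        for i, res in enumerate(residues):
            window = []
            for off in range(-2, 3):
                j = i + off
                window.append(names[j] if 0 <= j < len(names) else SENTINEL)
            out[res.key] = tuple(window)
    return out


def extract_template(assignment: RegionAssignment, model: StructureModel,
                     cutoff: float, seed: SeedSpec) -> TemplateRegion:
    """Record every QM protein residue with its atoms and 5-residue signature."""
    sigs = _signatures(model)
    entries = []
    for res in model.protein_residues:
        qm_names = [a.name for a in res.atoms
                    if a.serial in assignment.qm_serials]
        if not qm_names:
            continue
        core = res.key in assignment.selected_residue_keys or res.is_cap
        entries.append(TemplateResidue(
            chain_id=res.chain_id, resseq=res.resseq, resname=res.resname,
            atom_names=tuple(qm_names), signature=sigs[res.key], core=core))
    return TemplateRegion(residues=entries, cutoff=cutoff,
                          seed_mode=seed.mode, seed_serial=seed.atom_serial)


def apply_template(template: TemplateRegion, model: StructureModel,
                   seed: SeedSpec, cutoff: float | None = None,
                   gap_min: int = 1) -> RegionAssignment:
    """Build a RegionAssignment on a new model guided by the template.

    Matching is order-independent: template records are processed in
    (chain, resseq) order regardless of file order.
    """
    cutoff = cutoff if cutoff is not None else template.cutoff
    sigs = _signatures(model)
    protein = {r.key: r for r in model.protein_residues}
    matched: dict[tuple, TemplateResidue] = {}
    used: set[tuple] = set()
    any_match = False

    for tres in sorted(template.core_residues(),
                       key=lambda t: (t.chain_id, t.resseq)):
        candidates = [key for key, sig in sigs.items()
                      if sig == tres.signature and key not in used]
        if not candidates:
            logger.warning("template residue %s%s %s has no signature match; "
                           "cutoff fallback applies", tres.chain_id,
                           tres.resseq, tres.resname)
            continue
        candidates.sort(key=lambda key: (abs(key[1] - tres.resseq),
                                         key[0] != tres.chain_id, key[1]))
        best = candidates[0]
        matched[best] = tres
        used.add(best)
        any_match = True
        present = {a.name for a in protein[best].atoms}
        missing = set(tres.atom_names) - present - {"OXT"}
        if missing - {"O", "C"}:
            logger.warning("matched residue %s lacks template atoms %s",
                           best, sorted(missing))

    if not any_match:
        logger.warning("no template residue matched; falling back to a pure "
                       "cutoff selection")

    # cutoff rule decides every unmatched residue and all nonprotein residues
    by_cutoff = select_residues(model, seed, cutoff)
    selection = {key for key in by_cutoff
                 if key not in protein or key not in _decided(matched, used)}
    selection |= {key for key in matched if not protein[key].is_cap}
    assignment = place_cuts(model, selection)
    return absorb_clashes(model, assignment, gap_min=gap_min)


def _decided(matched, used) -> set:
    # residues the template explicitly decided (matched -> QM; the rest of
    # the protein was MM in the template run and stays cutoff-governed)
    return set(used)


# ---------------------------------------------------------------------------
# serialization: human-readable key:value blocks


def save_template(template: TemplateRegion, path) -> None:
    lines = [f"qmmmprep-template-version: {template.version}",
             f"cutoff: {template.cutoff}",
             f"seed-mode: {template.seed_mode}",
             f"seed-serial: {template.seed_serial if template.seed_serial is not None else '-'}"]
    for t in template.residues:
        lines += ["residue:",
                  f"  chain: {t.chain_id}",
                  f"  resseq: {t.resseq}",
                  f"  resname: {t.resname}",
                  f"  core: {'yes' if t.core else 'no'}",
                  f"  atoms: {' '.join(t.atom_names)}",
                  f"  signature: {' '.join(t.signature)}"]
    Path(path).write_text("\n".join(lines) + "\n")


def load_template(path) -> TemplateRegion:
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    residues: list[TemplateResidue] = []
    current: dict[str, str] | None = None

    def flush():
        if current is not None:
            residues.append(TemplateResidue(
                chain_id=current["chain"], resseq=int(current["resseq"]),
                resname=current["resname"],
                atom_names=tuple(current.get("atoms", "").split()),
                signature=tuple(current["signature"].split()),
                core=current.get("core", "yes") == "yes"))

    for raw in lines:
        if not raw.strip():
            continue
        if raw.startswith("residue:"):
            flush()
            current = {}
        elif raw.startswith("  ") and current is not None:
            key, _, value = raw.strip().partition(":")
            current[key] = value.strip()
        else:
            key, _, value = raw.partition(":")
            header[key.strip()] = value.strip()
    flush()

    version = int(header.get("qmmmprep-template-version", "0"))
    if version != FORMAT_VERSION:
        raise TemplateError(f"unsupported template version {version}")
    for t in residues:
        if len(t.signature) != 5:
            raise TemplateError(
                f"residue {t.chain_id}{t.resseq}: signature must have "
                "5 entries")
    seed_serial = header.get("seed-serial", "-")
    return TemplateRegion(
        residues=residues, cutoff=float(header["cutoff"]),
        seed_mode=header.get("seed-mode", "whole_ligand"),
        seed_serial=None if seed_serial == "-" else int(seed_serial),
        version=version)
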