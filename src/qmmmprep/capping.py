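"""ACE/NME end-capping of uncapped protein chain termini.

Charged termini are neutralized first (extra amine hydrogens H2/H3 and the
carboxylate OXT are removed) because the cap groups replace the zwitterionic
termini and the charge templates assume neutral attachment.  Cap atoms are
built by internal-coordinate construction, trans (180 deg) to the chain, and
never move pre-existing atoms; the operation is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._geom import TETRAHEDRAL, place_internal
from .structure import Atom, Residue, StructureModel

logger = logging.getLogger(__name__)

NME_ALIASES = {"NME", "NMA"}


class CappingError(ValueError):
    pass


@dataclass
class CapGeometryParams:
    """Ideal cap geometry (Angstrom / degrees)."""

    r_c_n: float = 1.335  # amide C-N
    r_c_c: float = 1.522  # carbonyl C - methyl C
    r_n_c: float = 1.455  # amide N - methyl C
    r_c_h: float = 1.090
    r_n_h: float = 1.010
    r_c_o: float = 1.229
    a_sp2: float = 120.0
    a_sp3: float = 109.47

    def __post_init__(self):
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


def detect_capping_state(model: StructureModel) -> dict[str, str]:
    """Per-chain classification: 'capped' | 'uncapped' | 'partial'."""
    out = {}
    for chain_id, residues in model.chains().items():
        has_ace = residues[0].resname == "ACE"
        has_nme = residues[-1].resname in NME_ALIASES
        if has_ace and has_nme:
            out[chain_id] = "capped"
        elif has_ace or has_nme:
            out[chain_id] = "partial"
        else:
            out[chain_id] = "uncapped"
    return out


def add_terminal_caps(model: StructureModel,
                      params: CapGeometryParams | None = None) -> StructureModel:
    """Add ACE to uncapped N-termini and NME to uncapped C-termini, in place.

    Returns the same model for chaining.  Already-capped chains are untouched.
    """
    params = params or CapGeometryParams()
    state = detect_capping_state(model)
    for chain_id, residues in model.chains().items():
        if state[chain_id] == "capped":
            continue
        if residues[0].resname != "ACE":
            _neutralize_n_terminus(residues[0])
            ace = _build_ace(model, residues[0], params)
            model.residues.insert(model.residues.index(residues[0]), ace)
            model.reindex()
        if residues[-1].resname not in NME_ALIASES:
            _neutralize_c_terminus(residues[-1])
            nme = _build_nme(model, residues[-1], params)
            model.residues.insert(model.residues.index(residues[-1]) + 1, nme)
            model.reindex()
    if model.bonds is not None:
        from .structure import build_bond_graph

        model.bonds = build_bond_graph(model)
    return model


def _require(res: Residue, names: tuple[str, ...]) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        atom = res.atom(name)
        if atom is None:
            raise CappingError(
                f"cannot cap chain {res.chain_id}: residue {res.resname} "
                f"{res.resseq} lacks backbone atom {name}")
        out[name] = atom.coords
    return out


def _neutralize_n_terminus(res: Residue) -> None:
    doomed = [a for a in res.atoms if a.name in ("H2", "H3")]
    for a in doomed:
        res.atoms.remove(a)
    h1 = res.atom("H1")
    if h1 is not None and res.atom("H") is None:
        h1.name = "H"


def _neutralize_c_terminus(res: Residue) -> None:
    oxt = res.atom("OXT")
    if oxt is not None:
        res.atoms.remove(oxt)


def _build_ace(model: StructureModel, first: Residue,
               params: CapGeometryParams) -> Residue:
    bb = _require(first, ("N", "CA", "C"))
    ace = Residue(chain_id=first.chain_id, resseq=first.resseq - 1, icode="",
                  resname="ACE", is_cap=True)
    # trans to the chain: dihedral(C, CA, N, Cace) = 180
    c = place_internal(bb["C"], bb["CA"], bb["N"], params.r_c_n,
                       121.7, 180.0)
    o = place_internal(bb["CA"], bb["N"], c, params.r_c_o, params.a_sp2, 0.0)
    ch3 = place_internal(bb["CA"], bb["N"], c, params.r_c_c, params.a_sp2,
                         180.0)
    serial = model.next_serial()
    atoms = [("CH3", "C", ch3)]
    for name, phi in (("HH31", 60.0), ("HH32", 180.0), ("HH33", 300.0)):
        atoms.append((name, "H",
                      place_internal(o, c, ch3, params.r_c_h, TETRAHEDRAL, phi)))
    atoms += [("C", "C", c), ("O", "O", o)]
    for name, element, coords in atoms:
        ace.atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=coords, record="ATOM",
                              residue_key=ace.key))
        serial += 1
    return ace


def _build_nme(model: StructureModel, last: Residue,
               params: CapGeometryParams) -> Residue:
    bb = _require(last, ("CA", "C", "O"))
    nme = Residue(chain_id=last.chain_id, resseq=last.resseq + 1, icode="",
                  resname="NME", is_cap=True)
    n = place_internal(bb["O"], bb["CA"], bb["C"], params.r_c_n, 116.6, 180.0)
    h = place_internal(bb["O"], bb["C"], n, params.r_n_h, params.a_sp2, 180.0)
    ch3 = place_internal(bb["CA"], bb["C"], n, params.r_n_c, 121.7, 180.0)
    serial = model.next_serial()
    atoms = [("N", "N", n), ("H", "H", h), ("CH3", "C", ch3)]
    for name, phi in (("HH31", 60.0), ("HH32", 180.0), ("HH33", 300.0)):
        atoms.append((name, "H",
                      place_internal(bb["C"], n, ch3, params.r_c_h,
                                     TETRAHEDRAL, phi)))
    for name, element, coords in atoms:
        nme.atoms.append(Atom(serial=serial, name=name, element=element,
                              coords=coords, record="ATOM",
                              residue_key=nme.key))
        serial += 1
    return nme
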