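"""Intra-residue covalent connectivity templates and hydrogen-name handling.

Bond templates are keyed by residue name and list atom-name pairs; they drive
bond-graph construction for residues the library knows about, with a
covalent-radius distance criterion as the fallback for everything else
(ligands, unknown residues).
"""

from __future__ import annotations

_BACKBONE = [("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "C"), ("C", "O")]


def _bb(*side: tuple[str, str], gly: bool = False, pro: bool = False):
    bonds = list(_BACKBONE)
    if gly:
        bonds = [("N", "H"), ("N", "CA"), ("CA", "HA2"), ("CA", "HA3"),
                 ("CA", "C"), ("C", "O")]
    if pro:
        bonds = [("N", "CA"), ("CA", "HA"), ("CA", "C"), ("C", "O")]
    return bonds + list(side)


RESIDUE_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": _bb(gly=True),
    "ALA": _bb(("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")),
    "SER": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"),
               ("OG", "HG")),
    "CYS": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "SG"),
               ("SG", "HG")),
    "THR": _bb(("CA", "CB"), ("CB", "HB"), ("CB", "OG1"), ("OG1", "HG1"),
               ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")),
    "VAL": _bb(("CA", "CB"), ("CB", "HB"),
               ("CB", "CG1"), ("CG1", "HG11"), ("CG1", "HG12"), ("CG1", "HG13"),
               ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")),
    "LEU": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG"),
               ("CG", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
               ("CG", "CD2"), ("CD2", "HD21"), ("CD2", "HD22"), ("CD2", "HD23")),
    "ILE": _bb(("CA", "CB"), ("CB", "HB"),
               ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
               ("CB", "CG1"), ("CG1", "HG12"), ("CG1", "HG13"),
               ("CG1", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13")),
    "MET": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "SD"), ("SD", "CE"),
               ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3")),
    "PRO": _bb(("N", "CD"), ("CD", "HD2"), ("CD", "HD3"), ("CD", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "CB"), ("CB", "HB2"),
               ("CB", "HB3"), ("CB", "CA"), pro=True),
    "PHE": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "CD1"), ("CD1", "HD1"), ("CG", "CD2"), ("CD2", "HD2"),
               ("CD1", "CE1"), ("CE1", "HE1"), ("CD2", "CE2"), ("CE2", "HE2"),
               ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "HZ")),
    "TYR": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "CD1"), ("CD1", "HD1"), ("CG", "CD2"), ("CD2", "HD2"),
               ("CD1", "CE1"), ("CE1", "HE1"), ("CD2", "CE2"), ("CE2", "HE2"),
               ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH"), ("OH", "HH")),
    "TRP": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "NE1"), ("NE1", "HE1"),
               ("NE1", "CE2"), ("CE2", "CD2"), ("CG", "CD2"),
               ("CE2", "CZ2"), ("CZ2", "HZ2"), ("CZ2", "CH2"), ("CH2", "HH2"),
               ("CH2", "CZ3"), ("CZ3", "HZ3"), ("CZ3", "CE3"), ("CE3", "HE3"),
               ("CE3", "CD2")),
    "HIS": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "HE1"), ("CE1", "NE2"),
               ("NE2", "HE2"), ("NE2", "CD2"), ("CD2", "HD2"), ("CG", "CD2")),
    "ASP": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "OD1"), ("CG", "OD2")),
    "GLU": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "OE1"),
               ("CD", "OE2")),
    "ASN": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22")),
    "GLN": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "OE1"),
               ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22")),
    "LYS": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "HD2"),
               ("CD", "HD3"), ("CD", "CE"), ("CE", "HE2"), ("CE", "HE3"),
               ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")),
    "ARG": _bb(("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
               ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "HD2"),
               ("CD", "HD3"), ("CD", "NE"), ("NE", "HE"), ("NE", "CZ"),
               ("CZ", "NH1"), ("NH1", "HH11"), ("NH1", "HH12"),
               ("CZ", "NH2"), ("NH2", "HH21"), ("NH2", "HH22")),
    "ACE": [("CH3", "HH31"), ("CH3", "HH32"), ("CH3", "HH33"),
            ("CH3", "C"), ("C", "O")],
    "NME": [("N", "H"), ("N", "CH3"),
            ("CH3", "HH31"), ("CH3", "HH32"), ("CH3", "HH33")],
    "HOH": [("O", "H1"), ("O", "H2"), ("O", "EP")],
}

# Water atom-name aliases (OW/HW1... -> O/H1...)
WATER_ATOM_ALIASES = {"OW": "O", "OH2": "O", "HW1": "H1", "HW2": "H2",
                      "HW3": "H2", "MW": "EP", "EPW": "EP"}

_HYDROGEN_ALIASES = {"HN": "H", "HT1": "H1", "HT2": "H2", "HT3": "H3"}


def normalize_atom_name(name: str, template_names: set[str] | None = None) -> str:
    """Map hydrogen-name variants onto the template convention.

    Handles digit rotation (``1HB`` -> ``HB1``), ``HN`` -> ``H``, and the
    methylene shift between HB1/HB2 and HB2/HB3 conventions when a template
    name set is supplied.
    """
    name = name.strip()
    out = name
    if out and out[0].isdigit():  # 1HB -> HB1
        out = out[1:] + out[0]
    out = _HYDROGEN_ALIASES.get(out, out)
    if template_names is not None and out not in template_names:
        # methylene convention: file uses HB1/HB2 where template has HB2/HB3
        if out.startswith("H") and out[-1:].isdigit():
            stem, digit = out[:-1], int(out[-1])
            shifted = f"{stem}{digit + 1}"
            if shifted in template_names and f"{stem}{digit + 3}" not in template_names:
                return shifted
    return out


def bonds_for(resname: str) -> list[tuple[str, str]] | None:
    from .charges import RESNAME_ALIASES

    resname = RESNAME_ALIASES.get(resname, resname)
    if resname in {"WAT", "TIP3", "TIP3P", "TIP4", "SPC", "SOL"}:
        resname = "HOH"
    return RESIDUE_BONDS.get(resname)
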