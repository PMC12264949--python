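"""Packaged per-residue point-charge set emulating an Amber-family force field.

The tables carry fixed atomic partial charges (in e) for the 20 standard amino
acids in their neutral-backbone (internal, ACE/NME-capped) form, the ACE/NME
capping groups themselves, monatomic ions and rigid water models.  Each
residue's charges sum to its formal integer charge; the loader enforces this
invariant, which is what makes the downstream integer-charge validation and the
balanced boundary-charge schemes meaningful.

HIS is shipped as the neutral N-epsilon tautomer (HIE); HID/HIE resolve to the
same entry.
"""

from __future__ import annotations

PROVENANCE = "qmmmprep packaged charge set (Amber-family emulation)"

# resname -> atom name -> charge (e).  PDB v3 atom naming.
RESIDUE_CHARGES: dict[str, dict[str, float]] = {
    "GLY": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0252, "HA2": 0.0698, "HA3": 0.0698,
        "C": 0.5973, "O": -0.5679,
    },
    "ALA": {
        "N": -0.4157, "H": 0.2719, "CA": 0.0337, "HA": 0.0823,
        "CB": -0.1825, "HB1": 0.0603, "HB2": 0.0603, "HB3": 0.0603,
        "C": 0.5973, "O": -0.5679,
    },
    "SER": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0249, "HA": 0.0843,
        "CB": 0.2117, "HB2": 0.0352, "HB3": 0.0352, "OG": -0.6546, "HG": 0.4275,
        "C": 0.5973, "O": -0.5679,
    },
    "CYS": {
        "N": -0.4157, "H": 0.2719, "CA": 0.0213, "HA": 0.1124,
        "CB": -0.1231, "HB2": 0.1112, "HB3": 0.1112, "SG": -0.3119, "HG": 0.1933,
        "C": 0.5973, "O": -0.5679,
    },
    "THR": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0389, "HA": 0.1007,
        "CB": 0.3654, "HB": 0.0043, "OG1": -0.6761, "HG1": 0.4102,
        "CG2": -0.2438, "HG21": 0.0642, "HG22": 0.0642, "HG23": 0.0642,
        "C": 0.5973, "O": -0.5679,
    },
    "VAL": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0875, "HA": 0.0969,
        "CB": 0.2985, "HB": -0.0297,
        "CG1": -0.3192, "HG11": 0.0791, "HG12": 0.0791, "HG13": 0.0791,
        "CG2": -0.3192, "HG21": 0.0791, "HG22": 0.0791, "HG23": 0.0791,
        "C": 0.5973, "O": -0.5679,
    },
    "LEU": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0518, "HA": 0.0922,
        "CB": -0.1102, "HB2": 0.0457, "HB3": 0.0457, "CG": 0.3531, "HG": -0.0361,
        "CD1": -0.4121, "HD11": 0.1000, "HD12": 0.1000, "HD13": 0.1000,
        "CD2": -0.4121, "HD21": 0.1000, "HD22": 0.1000, "HD23": 0.1000,
        "C": 0.5973, "O": -0.5679,
    },
    "ILE": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0597, "HA": 0.0869,
        "CB": 0.1303, "HB": 0.0187,
        "CG2": -0.3204, "HG21": 0.0882, "HG22": 0.0882, "HG23": 0.0882,
        "CG1": -0.0430, "HG12": 0.0236, "HG13": 0.0236,
        "CD1": -0.0660, "HD11": 0.0186, "HD12": 0.0186, "HD13": 0.0186,
        "C": 0.5973, "O": -0.5679,
    },
    "MET": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0237, "HA": 0.0880,
        "CB": 0.0342, "HB2": 0.0241, "HB3": 0.0241,
        "CG": 0.0018, "HG2": 0.0440, "HG3": 0.0440,
        "SD": -0.2737, "CE": -0.0536, "HE1": 0.0684, "HE2": 0.0684, "HE3": 0.0684,
        "C": 0.5973, "O": -0.5679,
    },
    "PRO": {
        "N": -0.2548, "CD": 0.0192, "HD2": 0.0391, "HD3": 0.0391,
        "CG": 0.0189, "HG2": 0.0213, "HG3": 0.0213,
        "CB": -0.0070, "HB2": 0.0253, "HB3": 0.0253,
        "CA": -0.0266, "HA": 0.0641, "C": 0.5896, "O": -0.5748,
    },
    "PHE": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0024, "HA": 0.0978,
        "CB": -0.0343, "HB2": 0.0295, "HB3": 0.0295, "CG": 0.0118,
        "CD1": -0.1256, "HD1": 0.1330, "CD2": -0.1256, "HD2": 0.1330,
        "CE1": -0.1704, "HE1": 0.1430, "CE2": -0.1704, "HE2": 0.1430,
        "CZ": -0.1072, "HZ": 0.1297,
        "C": 0.5973, "O": -0.5679,
    },
    "TYR": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0014, "HA": 0.0876,
        "CB": -0.0152, "HB2": 0.0295, "HB3": 0.0295, "CG": -0.0011,
        "CD1": -0.1906, "HD1": 0.1699, "CD2": -0.1906, "HD2": 0.1699,
        "CE1": -0.2341, "HE1": 0.1656, "CE2": -0.2341, "HE2": 0.1656,
        "CZ": 0.3226, "OH": -0.5579, "HH": 0.3992,
        "C": 0.5973, "O": -0.5679,
    },
    "TRP": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0275, "HA": 0.1123,
        "CB": -0.0050, "HB2": 0.0339, "HB3": 0.0339, "CG": -0.1415,
        "CD1": -0.1638, "HD1": 0.2062, "NE1": -0.3418, "HE1": 0.3412,
        "CE2": 0.1380, "CZ2": -0.2601, "HZ2": 0.1572, "CH2": -0.1134,
        "HH2": 0.1417, "CZ3": -0.1972, "HZ3": 0.1447, "CE3": -0.2387,
        "HE3": 0.1700, "CD2": 0.1243,
        "C": 0.5973, "O": -0.5679,
    },
    "HIS": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0581, "HA": 0.1360,
        "CB": -0.0074, "HB2": 0.0367, "HB3": 0.0367, "CG": 0.1868,
        "ND1": -0.5432, "CE1": 0.1635, "HE1": 0.1435, "NE2": -0.2795,
        "HE2": 0.3339, "CD2": -0.2207, "HD2": 0.1862,
        "C": 0.5973, "O": -0.5679,
    },
    "ASP": {
        "N": -0.5163, "H": 0.2936, "CA": 0.0381, "HA": 0.0880,
        "CB": -0.0303, "HB2": -0.0122, "HB3": -0.0122,
        "CG": 0.7994, "OD1": -0.8014, "OD2": -0.8014,
        "C": 0.5366, "O": -0.5819,
    },
    "GLU": {
        "N": -0.5163, "H": 0.2936, "CA": 0.0397, "HA": 0.1105,
        "CB": 0.0560, "HB2": -0.0173, "HB3": -0.0173,
        "CG": 0.0136, "HG2": -0.0425, "HG3": -0.0425,
        "CD": 0.8054, "OE1": -0.8188, "OE2": -0.8188,
        "C": 0.5366, "O": -0.5819,
    },
    "ASN": {
        "N": -0.4157, "H": 0.2719, "CA": 0.0143, "HA": 0.1048,
        "CB": -0.2041, "HB2": 0.0797, "HB3": 0.0797,
        "CG": 0.7130, "OD1": -0.5931, "ND2": -0.9191,
        "HD21": 0.4196, "HD22": 0.4196,
        "C": 0.5973, "O": -0.5679,
    },
    "GLN": {
        "N": -0.4157, "H": 0.2719, "CA": -0.0031, "HA": 0.0850,
        "CB": -0.0036, "HB2": 0.0171, "HB3": 0.0171,
        "CG": -0.0645, "HG2": 0.0352, "HG3": 0.0352,
        "CD": 0.6951, "OE1": -0.6086, "NE2": -0.9407,
        "HE21": 0.4251, "HE22": 0.4251,
        "C": 0.5973, "O": -0.5679,
    },
    "LYS": {
        "N": -0.3479, "H": 0.2747, "CA": -0.2400, "HA": 0.1426,
        "CB": -0.0094, "HB2": 0.0362, "HB3": 0.0362,
        "CG": 0.0187, "HG2": 0.0103, "HG3": 0.0103,
        "CD": -0.0479, "HD2": 0.0621, "HD3": 0.0621,
        "CE": -0.0143, "HE2": 0.1135, "HE3": 0.1135,
        "NZ": -0.3854, "HZ1": 0.3400, "HZ2": 0.3400, "HZ3": 0.3400,
        "C": 0.7341, "O": -0.5894,
    },
    "ARG": {
        "N": -0.3479, "H": 0.2747, "CA": -0.2637, "HA": 0.1560,
        "CB": -0.0007, "HB2": 0.0327, "HB3": 0.0327,
        "CG": 0.0390, "HG2": 0.0285, "HG3": 0.0285,
        "CD": 0.0486, "HD2": 0.0687, "HD3": 0.0687,
        "NE": -0.5295, "HE": 0.3456, "CZ": 0.8076,
        "NH1": -0.8627, "HH11": 0.4478, "HH12": 0.4478,
        "NH2": -0.8627, "HH21": 0.4478, "HH22": 0.4478,
        "C": 0.7341, "O": -0.5894,
    },
    "ACE": {
        "HH31": 0.1123, "CH3": -0.3662, "HH32": 0.1123, "HH33": 0.1123,
        "C": 0.5972, "O": -0.5679,
    },
    "NME": {
        "N": -0.4157, "H": 0.2719, "CH3": -0.1490,
        "HH31": 0.0976, "HH32": 0.0976, "HH33": 0.0976,
    },
}

RESNAME_ALIASES = {"HIE": "HIS", "HID": "HIS", "NMA": "NME", "CYX": "CYS"}

# Monatomic ions: resname -> (atom name, formal charge e)
ION_CHARGES: dict[str, float] = {
    "NA": 1.0, "K": 1.0, "LI": 1.0, "RB": 1.0, "CS": 1.0,
    "CL": -1.0, "BR": -1.0, "F": -1.0, "IOD": -1.0,
    "MG": 2.0, "ZN": 2.0,
}

# Rigid water models.  qO + n_H*qH + qEP = 0 for all of them.
WATER_MODELS: dict[str, dict] = {
    # 3-site, the packaged default
    "tip3p": {"site_count": 3, "qO": -0.834, "qH": 0.417, "qEP": 0.0, "rEP": 0.0},
    "spce": {"site_count": 3, "qO": -0.8476, "qH": 0.4238, "qEP": 0.0, "rEP": 0.0},
    # 4-site: the negative charge sits on an extra point (EP) on the HOH bisector
    "tip4p": {"site_count": 4, "qO": 0.0, "qH": 0.52, "qEP": -1.04, "rEP": 0.15},
    "tip4pew": {"site_count": 4, "qO": 0.0, "qH": 0.52422, "qEP": -1.04844,
                "rEP": 0.125},
}

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP3P", "TIP4", "SPC", "SOL"}


def formal_charge(resname: str) -> int:
    """Formal integer charge of a bundled residue template."""
    resname = RESNAME_ALIASES.get(resname, resname)
    if resname in ION_CHARGES:
        return int(round(ION_CHARGES[resname]))
    total = sum(RESIDUE_CHARGES[resname].values())
    return int(round(total))


def _selfcheck() -> None:
    for name, table in RESIDUE_CHARGES.items():
        total = sum(table.values())
        if abs(total - round(total)) > 1e-6:
            raise AssertionError(
                f"packaged charge template {name} sums to {total:.6f}, "
                "not an integer"
            )


_selfcheck()
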