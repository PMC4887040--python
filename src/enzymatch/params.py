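"""Atomic parameters: elements, van der Waals radii, partial charges.

The charge set is a compact CHARMM-22-flavoured table for backbone and polar
side-chain groups (nonpolar carbons/hydrogens carry small or zero charges);
it is a documented surrogate sufficient for hydrogen-bond and screened
electrostatic scoring, not a full force field.
"""

from __future__ import annotations

__all__ = ["element_from_name", "vdw_radius", "partial_charge", "VDW_RADII"]

VDW_RADII = {
    "C": 1.90,
    "N": 1.70,
    "O": 1.60,
    "S": 2.00,
    "P": 1.90,
    "H": 1.00,
    "F": 1.50,
    "CL": 1.80,
    "BR": 1.95,
    "I": 2.10,
}

_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE"}


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Digit-led names (e.g. ``1HB``) and trailing digits are handled; protein
    atom names map on their first alphabetic character.
    """
    s = name.strip().upper().lstrip("0123456789")
    if not s:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    return s[0]


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        return 1.80


# (residue, atom) -> charge in e; '*' matches any residue for backbone atoms.
_CHARGES = {
    ("*", "N"): -0.47,
    ("*", "H"): 0.31,
    ("*", "CA"): 0.07,
    ("*", "HA"): 0.09,
    ("*", "HA1"): 0.09,
    ("*", "HA2"): 0.09,
    ("*", "C"): 0.51,
    ("*", "O"): -0.51,
    ("SER", "CB"): 0.05,
    ("SER", "OG"): -0.66,
    ("SER", "HG1"): 0.43,
    ("THR", "OG1"): -0.66,
    ("THR", "HG1"): 0.43,
    ("TYR", "OH"): -0.54,
    ("TYR", "HH"): 0.43,
    ("CYS", "SG"): -0.23,
    ("CYS", "HG1"): 0.16,
    ("ASP", "CG"): 0.62,
    ("ASP", "OD1"): -0.76,
    ("ASP", "OD2"): -0.76,
    ("ASP", "CB"): -0.28,
    ("GLU", "CD"): 0.62,
    ("GLU", "OE1"): -0.76,
    ("GLU", "OE2"): -0.76,
    ("GLU", "CG"): -0.28,
    ("ASN", "CG"): 0.55,
    ("ASN", "OD1"): -0.55,
    ("ASN", "ND2"): -0.62,
    ("ASN", "HD21"): 0.32,
    ("ASN", "HD22"): 0.30,
    ("GLN", "CD"): 0.55,
    ("GLN", "OE1"): -0.55,
    ("GLN", "NE2"): -0.62,
    ("GLN", "HE21"): 0.32,
    ("GLN", "HE22"): 0.30,
    # doubly protonated (imidazolium-like) histidine
    ("HIS", "ND1"): -0.36,
    ("HIS", "HD1"): 0.32,
    ("HIS", "NE2"): -0.36,
    ("HIS", "HE2"): 0.32,
    ("HIS", "CE1"): 0.25,
    ("HIS", "CD2"): 0.22,
    ("HIS", "CG"): 0.10,
    ("LYS", "NZ"): -0.30,
    ("LYS", "HZ1"): 0.33,
    ("LYS", "HZ2"): 0.33,
    ("LYS", "HZ3"): 0.33,
    ("LYS", "CE"): 0.21,
    ("ARG", "NE"): -0.70,
    ("ARG", "HE"): 0.44,
    ("ARG", "CZ"): 0.64,
    ("ARG", "NH1"): -0.80,
    ("ARG", "NH2"): -0.80,
    ("ARG", "HH11"): 0.46,
    ("ARG", "HH12"): 0.46,
    ("ARG", "HH21"): 0.46,
    ("ARG", "HH22"): 0.46,
    ("TRP", "NE1"): -0.51,
    ("TRP", "HE1"): 0.37,
}


def partial_charge(resname: str, atom_name: str) -> float:
    key = (resname.upper(), atom_name.upper())
    if key in _CHARGES:
        return _CHARGES[key]
    key = ("*", atom_name.upper())
    return _CHARGES.get(key, 0.0)
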