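"""Idealized amino-acid geometry templates.

Each residue is described by a z-matrix rooted in its backbone (N, CA, C):
every atom is placed by NeRF from three previously available atoms with an
ideal bond length, bond angle and a torsion that is either fixed, tied to a
side-chain chi angle (possibly with an offset, e.g. methylene hydrogens at
chi +/- 120 deg), or a rotatable polar-hydrogen torsion (Ser/Thr/Tyr/Cys).

Bond lengths and angles are CHARMM-22-style ideal values rounded to typical
small-molecule geometry; rings are built as exact planar polygons.  The
templates are deliberately idealized: they are used to graft motif residues
onto scaffolds, to place rotamers, to add missing hydrogens, and to derive
the reversed (functional-group-first) construction used by loop kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    InternalCoordinate,
    dihedral,
    ic_from_points,
    internal_to_cartesian,
    wrap_degrees,
)

__all__ = [
    "TorsionSpec",
    "TemplateRow",
    "ResidueTemplate",
    "get_template",
    "build_residue",
    "place_missing_hydrogens",
    "sidechain_path",
    "reversed_rows",
    "PEPTIDE",
    "STANDARD_AA",
    "N_CHI",
    "CHI_ATOMS",
]

# Ideal peptide-backbone internal coordinates (lengths in A, angles in deg).
PEPTIDE = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.229,
    "N-H": 0.997,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 121.0,
    "omega": 180.0,
}


@dataclass(frozen=True)
class TorsionSpec:
    """Torsion of a template row: fixed, chi-linked, or rotatable hydroxyl."""

    kind: str  # "fixed" | "chi" | "roth"
    value: float = 0.0  # fixed value, or offset for chi rows, or default for roth
    chi: int = 0  # 1-based chi index for chi rows
    sign: float = 1.0  # torsion = sign * chi_k + offset for chi rows

    def resolve(self, chis: Sequence[float], hydroxyl: Optional[float] = None) -> float:
        if self.kind == "fixed":
            return self.value
        if self.kind == "chi":
            return wrap_degrees(self.sign * chis[self.chi - 1] + self.value)
        if self.kind == "roth":
            return self.value if hydroxyl is None else hydroxyl
        raise ValueError(self.kind)


@dataclass(frozen=True)
class TemplateRow:
    name: str
    frame: tuple[str, str, str]  # (a, b, c); new atom is placed from c
    length: float
    angle: float
    torsion: TorsionSpec


def _fx(v: float) -> TorsionSpec:
    return TorsionSpec("fixed", wrap_degrees(v))


def _chi(k: int, offset: float = 0.0, sign: float = 1.0) -> TorsionSpec:
    return TorsionSpec("chi", wrap_degrees(offset), k, sign)


def _roth(default: float = 180.0) -> TorsionSpec:
    return TorsionSpec("roth", default)


def _row(name, frame, r, ang, tors) -> TemplateRow:
    return TemplateRow(name, tuple(frame), float(r), float(ang), tors)


# ---------------------------------------------------------------------------
# Per-residue template construction helpers

_CB = _row("CB", ("N", "C", "CA"), 1.530, 111.1, _fx(123.2))
_HA = _row("HA", ("N", "C", "CA"), 1.080, 107.4, _fx(-118.3))


def _methyl(prefix, frame, k=None, base=(60.0, 180.0, -60.0), r=1.090, ang=110.0):
    rows = []
    for i, t in enumerate(base, start=1):
        tors = _chi(k, t) if k else _fx(t)
        rows.append(_row(f"{prefix}{i}", frame, r, ang, tors))
    return rows


def _methylene(prefix, frame, k, r=1.090, ang=109.4):
    """Two H atoms flanking the next-chi heavy substituent."""
    return [
        _row(f"{prefix}1", frame, r, ang, _chi(k, 120.0)),
        _row(f"{prefix}2", frame, r, ang, _chi(k, -120.0)),
    ]


def _build_rows() -> dict[str, list[TemplateRow]]:
    T: dict[str, list[TemplateRow]] = {}

    T["GLY"] = [
        _row("HA1", ("N", "C", "CA"), 1.080, 107.4, _fx(-118.3)),
        _row("HA2", ("N", "C", "CA"), 1.080, 107.4, _fx(123.2)),
    ]

    T["ALA"] = [_CB, _HA] + _methyl("HB", ("N", "CA", "CB"))

    T["SER"] = [
        _CB,
        _HA,
        _row("OG", ("N", "CA", "CB"), 1.417, 110.7, _chi(1)),
        *_methylene("HB", ("N", "CA", "CB"), 1),
        _row("HG1", ("CA", "CB", "OG"), 0.960, 108.5, _roth()),
    ]

    T["CYS"] = [
        _CB,
        _HA,
        _row("SG", ("N", "CA", "CB"), 1.808, 113.9, _chi(1)),
        *_methylene("HB", ("N", "CA", "CB"), 1),
        _row("HG1", ("CA", "CB", "SG"), 1.330, 96.0, _roth()),
    ]

    T["THR"] = [
        _CB,
        _HA,
        _row("OG1", ("N", "CA", "CB"), 1.420, 109.6, _chi(1)),
        _row("CG2", ("N", "CA", "CB"), 1.540, 110.5, _chi(1, -120.0)),
        _row("HB", ("N", "CA", "CB"), 1.090, 108.0, _chi(1, 120.0)),
        _row("HG1", ("CA", "CB", "OG1"), 0.960, 108.5, _roth()),
        *_methyl("HG2", ("CA", "CB", "CG2")),
    ]

    T["VAL"] = [
        _CB,
        _HA,
        _row("CG1", ("N", "CA", "CB"), 1.540, 110.4, _chi(1)),
        _row("CG2", ("N", "CA", "CB"), 1.540, 110.4, _chi(1, 120.0)),
        _row("HB", ("N", "CA", "CB"), 1.090, 108.0, _chi(1, -120.0)),
        *_methyl("HG1", ("CA", "CB", "CG1")),
        *_methyl("HG2", ("CA", "CB", "CG2")),
    ]

    T["LEU"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("CD1", ("CA", "CB", "CG"), 1.530, 110.5, _chi(2)),
        _row("CD2", ("CA", "CB", "CG"), 1.530, 110.5, _chi(2, 120.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        _row("HG", ("CA", "CB", "CG"), 1.090, 108.0, _chi(2, -120.0)),
        *_methyl("HD1", ("CB", "CG", "CD1")),
        *_methyl("HD2", ("CB", "CG", "CD2")),
    ]

    T["ILE"] = [
        _CB,
        _HA,
        _row("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        _row("CG2", ("N", "CA", "CB"), 1.540, 110.5, _chi(1, -120.0)),
        _row("CD1", ("CA", "CB", "CG1"), 1.530, 113.8, _chi(2)),
        _row("HB", ("N", "CA", "CB"), 1.090, 108.0, _chi(1, 120.0)),
        *_methylene("HG1", ("CA", "CB", "CG1"), 2),
        *_methyl("HG2", ("CA", "CB", "CG2")),
        *_methyl("HD1", ("CB", "CG1", "CD1")),
    ]

    T["ASP"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.520, 112.6, _chi(1)),
        _row("OD1", ("CA", "CB", "CG"), 1.250, 118.4, _chi(2)),
        _row("OD2", ("CA", "CB", "CG"), 1.250, 118.4, _chi(2, 180.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
    ]

    T["ASN"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.520, 112.6, _chi(1)),
        _row("OD1", ("CA", "CB", "CG"), 1.230, 120.8, _chi(2)),
        _row("ND2", ("CA", "CB", "CG"), 1.330, 116.4, _chi(2, 180.0)),
        _row("HD21", ("CB", "CG", "ND2"), 1.000, 119.0, _fx(180.0)),
        _row("HD22", ("CB", "CG", "ND2"), 1.000, 119.0, _fx(0.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
    ]

    T["GLU"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("CD", ("CA", "CB", "CG"), 1.520, 112.6, _chi(2)),
        _row("OE1", ("CB", "CG", "CD"), 1.250, 118.4, _chi(3)),
        _row("OE2", ("CB", "CG", "CD"), 1.250, 118.4, _chi(3, 180.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        *_methylene("HG", ("CA", "CB", "CG"), 3),
    ]

    T["GLN"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("CD", ("CA", "CB", "CG"), 1.520, 112.6, _chi(2)),
        _row("OE1", ("CB", "CG", "CD"), 1.230, 120.8, _chi(3)),
        _row("NE2", ("CB", "CG", "CD"), 1.330, 116.4, _chi(3, 180.0)),
        _row("HE21", ("CG", "CD", "NE2"), 1.000, 119.0, _fx(180.0)),
        _row("HE22", ("CG", "CD", "NE2"), 1.000, 119.0, _fx(0.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        *_methylene("HG", ("CA", "CB", "CG"), 3),
    ]

    # Histidine ring as an exact planar regular pentagon.  Both ring nitrogens
    # carry protons (imidazolium-like): in the catalytic context modeled here
    # the His base accepts the nucleophile proton during the reaction, so the
    # doubly protonated form donates hydrogen bonds on both sides.  Acceptor
    # histidine tautomers are not modeled.
    T["HIS"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.500, 113.8, _chi(1)),
        _row("ND1", ("CA", "CB", "CG"), 1.370, 122.7, _chi(2)),
        _row("CE1", ("CB", "CG", "ND1"), 1.370, 108.0, _fx(180.0)),
        _row("NE2", ("CG", "ND1", "CE1"), 1.370, 108.0, _fx(0.0)),
        _row("CD2", ("ND1", "CE1", "NE2"), 1.370, 108.0, _fx(0.0)),
        _row("HD1", ("NE2", "CE1", "ND1"), 1.010, 126.0, _fx(180.0)),
        _row("HE2", ("ND1", "CE1", "NE2"), 1.010, 126.0, _fx(180.0)),
        _row("HE1", ("ND1", "NE2", "CE1"), 1.080, 126.0, _fx(180.0)),
        _row("HD2", ("CE1", "NE2", "CD2"), 1.080, 126.0, _fx(180.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
    ]

    def _phenyl(with_oh: bool) -> list[TemplateRow]:
        rows = [
            _CB,
            _HA,
            _row("CG", ("N", "CA", "CB"), 1.500, 113.8, _chi(1)),
            _row("CD1", ("CA", "CB", "CG"), 1.390, 120.3, _chi(2)),
            _row("CD2", ("CA", "CB", "CG"), 1.390, 120.3, _chi(2, 180.0)),
            _row("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, _fx(180.0)),
            _row("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, _fx(180.0)),
            _row("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, _fx(0.0)),
            _row("HD1", ("CE1", "CG", "CD1"), 1.080, 120.0, _fx(180.0)),
            _row("HD2", ("CE2", "CG", "CD2"), 1.080, 120.0, _fx(180.0)),
            _row("HE1", ("CZ", "CD1", "CE1"), 1.080, 120.0, _fx(180.0)),
            _row("HE2", ("CZ", "CD2", "CE2"), 1.080, 120.0, _fx(180.0)),
            *_methylene("HB", ("N", "CA", "CB"), 2),
        ]
        if with_oh:
            rows += [
                _row("OH", ("CD1", "CE1", "CZ"), 1.380, 120.0, _fx(180.0)),
                _row("HH", ("CE1", "CZ", "OH"), 0.960, 109.5, _roth(0.0)),
            ]
        else:
            rows.append(_row("HZ", ("CD1", "CE1", "CZ"), 1.080, 120.0, _fx(180.0)))
        return rows

    T["PHE"] = _phenyl(with_oh=False)
    T["TYR"] = _phenyl(with_oh=True)

    # Indole built from idealized planar values; the six-ring closure is
    # approximate, which is acceptable for packing/template purposes.
    T["TRP"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.500, 113.6, _chi(1)),
        _row("CD1", ("CA", "CB", "CG"), 1.370, 126.9, _chi(2)),
        _row("CD2", ("CA", "CB", "CG"), 1.430, 126.6, _chi(2, 180.0)),
        _row("NE1", ("CD2", "CG", "CD1"), 1.380, 110.0, _fx(0.0)),
        _row("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, _fx(0.0)),
        _row("CE3", ("CD1", "CG", "CD2"), 1.400, 133.9, _fx(180.0)),
        _row("CZ2", ("CD1", "NE1", "CE2"), 1.390, 130.1, _fx(180.0)),
        _row("CZ3", ("CG", "CD2", "CE3"), 1.390, 118.8, _fx(180.0)),
        _row("CH2", ("NE1", "CE2", "CZ2"), 1.390, 117.5, _fx(180.0)),
        _row("HE1", ("CE2", "CD1", "NE1"), 1.010, 125.0, _fx(180.0)),
        _row("HD1", ("NE1", "CG", "CD1"), 1.080, 125.0, _fx(180.0)),
        _row("HE3", ("CZ3", "CD2", "CE3"), 1.080, 120.0, _fx(180.0)),
        _row("HZ2", ("CH2", "CE2", "CZ2"), 1.080, 120.0, _fx(180.0)),
        _row("HZ3", ("CE3", "CZ3", "CH2"), 1.080, 120.0, _fx(60.0)),
        _row("HH2", ("CE2", "CZ2", "CH2"), 1.080, 120.0, _fx(180.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
    ]

    T["MET"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("SD", ("CA", "CB", "CG"), 1.810, 112.7, _chi(2)),
        _row("CE", ("CB", "CG", "SD"), 1.790, 100.7, _chi(3)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        *_methylene("HG", ("CA", "CB", "CG"), 3),
        *_methyl("HE", ("CG", "SD", "CE")),
    ]

    T["LYS"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("CD", ("CA", "CB", "CG"), 1.530, 111.3, _chi(2)),
        _row("CE", ("CB", "CG", "CD"), 1.530, 111.3, _chi(3)),
        _row("NZ", ("CG", "CD", "CE"), 1.490, 112.0, _chi(4)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        *_methylene("HG", ("CA", "CB", "CG"), 3),
        *_methylene("HD", ("CB", "CG", "CD"), 4),
        _row("HE1", ("CG", "CD", "CE"), 1.090, 109.4, _chi(4, 120.0)),
        _row("HE2", ("CG", "CD", "CE"), 1.090, 109.4, _chi(4, -120.0)),
        *_methyl("HZ", ("CD", "CE", "NZ"), r=1.040),
    ]

    T["ARG"] = [
        _CB,
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.530, 114.0, _chi(1)),
        _row("CD", ("CA", "CB", "CG"), 1.530, 111.3, _chi(2)),
        _row("NE", ("CB", "CG", "CD"), 1.460, 112.0, _chi(3)),
        _row("CZ", ("CG", "CD", "NE"), 1.330, 124.2, _chi(4)),
        _row("NH1", ("CD", "NE", "CZ"), 1.330, 120.0, _fx(0.0)),
        _row("NH2", ("CD", "NE", "CZ"), 1.330, 120.0, _fx(180.0)),
        _row("HE", ("CG", "CD", "NE"), 1.010, 118.0, _chi(4, 180.0)),
        _row("HH11", ("NE", "CZ", "NH1"), 1.010, 120.0, _fx(0.0)),
        _row("HH12", ("NE", "CZ", "NH1"), 1.010, 120.0, _fx(180.0)),
        _row("HH21", ("NE", "CZ", "NH2"), 1.010, 120.0, _fx(0.0)),
        _row("HH22", ("NE", "CZ", "NH2"), 1.010, 120.0, _fx(180.0)),
        *_methylene("HB", ("N", "CA", "CB"), 2),
        *_methylene("HG", ("CA", "CB", "CG"), 3),
        *_methylene("HD", ("CB", "CG", "CD"), 4),
    ]

    # Proline ring with a fixed, idealized Cgamma-endo-like pucker.
    T["PRO"] = [
        _row("CB", ("N", "C", "CA"), 1.530, 111.1, _fx(115.0)),
        _HA,
        _row("CG", ("N", "CA", "CB"), 1.500, 104.0, _fx(-27.0)),
        _row("CD", ("CA", "CB", "CG"), 1.510, 105.0, _fx(38.0)),
        _row("HB1", ("N", "CA", "CB"), 1.090, 109.4, _fx(-147.0)),
        _row("HB2", ("N", "CA", "CB"), 1.090, 109.4, _fx(93.0)),
        _row("HG1", ("CA", "CB", "CG"), 1.090, 109.4, _fx(158.0)),
        _row("HG2", ("CA", "CB", "CG"), 1.090, 109.4, _fx(-82.0)),
        _row("HD1", ("CB", "CG", "CD"), 1.090, 109.4, _fx(150.0)),
        _row("HD2", ("CB", "CG", "CD"), 1.090, 109.4, _fx(-90.0)),
    ]

    return T


_SIDECHAIN_ROWS = _build_rows()

STANDARD_AA = tuple(sorted(_SIDECHAIN_ROWS))

CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "GLY": [],
    "ALA": [],
    "PRO": [],
}

N_CHI = {name: len(chis) for name, chis in CHI_ATOMS.items()}

# Rotatable hydroxyl/thiol hydrogens (expanded during repacking).
HYDROXYL_H = {"SER": "HG1", "THR": "HG1", "TYR": "HH", "CYS": "HG1"}


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    rows: tuple[TemplateRow, ...]
    chi_atoms: tuple[tuple[str, str, str, str], ...]

    @property
    def n_chi(self) -> int:
        return len(self.chi_atoms)

    @property
    def heavy_rows(self) -> tuple[TemplateRow, ...]:
        return tuple(r for r in self.rows if not r.name.startswith("H"))

    @property
    def hydrogen_rows(self) -> tuple[TemplateRow, ...]:
        return tuple(r for r in self.rows if r.name.startswith("H"))

    def chi_axis(self, k: int) -> frozenset:
        a = self.chi_atoms[k - 1]
        return frozenset((a[1], a[2]))


_TEMPLATES: dict[str, ResidueTemplate] = {
    name: ResidueTemplate(name, tuple(rows), tuple(CHI_ATOMS[name]))
    for name, rows in _SIDECHAIN_ROWS.items()
}


def get_template(resname: str) -> ResidueTemplate:
    try:
        return _TEMPLATES[resname.upper()]
    except KeyError:
        raise KeyError(f"no idealized template for residue type {resname!r}") from None


def build_residue(
    resname: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chis: Sequence[float] = (),
    hydroxyl: Optional[float] = None,
    include_hydrogens: bool = True,
    include_backbone_extras: bool = True,
) -> dict[str, np.ndarray]:
    """Construct all atoms of a residue from its backbone N/CA/C positions.

    ``chis`` supplies the side-chain torsions (missing ones default to 180 deg
    apart from proline, whose ring is fixed).  Returns atom name -> coords.
    """
    tpl = get_template(resname)
    chis = list(chis) + [180.0] * max(0, tpl.n_chi - len(chis))
    atoms: dict[str, np.ndarray] = {
        "N": np.asarray(n, float),
        "CA": np.asarray(ca, float),
        "C": np.asarray(c, float),
    }
    if include_backbone_extras:
        atoms["O"] = internal_to_cartesian(
            atoms["N"], atoms["CA"], atoms["C"],
            InternalCoordinate(PEPTIDE["C-O"], PEPTIDE["CA-C-O"], 133.0),
        )
        if include_hydrogens and resname.upper() != "PRO":
            atoms["H"] = internal_to_cartesian(
                atoms["C"], atoms["CA"], atoms["N"],
                InternalCoordinate(PEPTIDE["N-H"], 119.0, 180.0),
            )
    for r in tpl.rows:
        if r.name.startswith("H") and not include_hydrogens:
            continue
        a, b, c3 = (atoms[x] for x in r.frame)
        tors = r.torsion.resolve(chis, hydroxyl)
        atoms[r.name] = internal_to_cartesian(
            a, b, c3, InternalCoordinate(r.length, r.angle, tors)
        )
    return atoms


def measure_chis(resname: str, atoms: dict[str, np.ndarray]) -> list[float]:
    """Measure the side-chain chi angles present in an atom dictionary."""
    tpl = get_template(resname)
    out = []
    for quad in tpl.chi_atoms:
        if all(q in atoms for q in quad):
            out.append(dihedral(*(atoms[q] for q in quad)))
        else:
            out.append(180.0)
    return out


def place_missing_hydrogens(resname: str, atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Hydrogens to add to an existing residue, placed from its actual heavy atoms.

    Chi-linked hydrogen torsions are resolved against the measured chi angles,
    so the placement is idempotent and consistent with the real side chain.
    Existing hydrogens are never overwritten.
    """
    tpl = get_template(resname)
    chis = measure_chis(resname, atoms)
    new: dict[str, np.ndarray] = {}
    have = dict(atoms)
    if resname.upper() != "PRO" and "H" not in have and all(
        x in have for x in ("C", "CA", "N")
    ):
        new["H"] = internal_to_cartesian(
            have["C"], have["CA"], have["N"],
            InternalCoordinate(PEPTIDE["N-H"], 119.0, 180.0),
        )
        have.update(new)
    for r in tpl.hydrogen_rows:
        if r.name in have:
            continue
        if not all(x in have for x in r.frame):
            continue
        tors = r.torsion.resolve(chis, None)
        new[r.name] = internal_to_cartesian(
            have[r.frame[0]], have[r.frame[1]], have[r.frame[2]],
            InternalCoordinate(r.length, r.angle, tors),
        )
        have[r.name] = new[r.name]
    return new


def residue_bond_graph(resname: str) -> dict[str, set[str]]:
    """Bond adjacency of a residue's template atoms (backbone included).

    Template rows place each atom bonded to the last frame atom, which gives
    the covalent graph directly; backbone connectivity is added explicitly.
    """
    nbrs: dict[str, set[str]] = {}

    def _add(a, b):
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)

    _add("N", "CA")
    _add("CA", "C")
    _add("C", "O")
    if resname.upper() != "PRO":
        _add("N", "H")
    for row in get_template(resname).rows:
        _add(row.frame[2], row.name)
    return nbrs


def bond_distance(nbrs: dict[str, set[str]], start: str, max_depth: int = 3) -> dict[str, int]:
    """Bond-graph distances from ``start`` up to ``max_depth``."""
    dist = {start: 0}
    frontier = [start]
    for d in range(1, max_depth + 1):
        nxt = []
        for a in frontier:
            for b in nbrs.get(a, ()):
                if b not in dist:
                    dist[b] = d
                    nxt.append(b)
        frontier = nxt
    return dist


def bonded_extension(resname: str, atom: str) -> Optional[str]:
    """The first heavy template atom bonded outward of ``atom`` (e.g. OG for
    serine CB) — the atom a covalent pseudo-bond to a ligand replaces."""
    for r in get_template(resname).heavy_rows:
        if r.frame[2] == atom:
            return r.name
    return None


def with_dependents(resname: str, names: set[str]) -> set[str]:
    """Close a set of atom names under template-frame dependency (atoms whose
    placement references a dropped atom are dropped too)."""
    out = set(names)
    changed = True
    while changed:
        changed = False
        for r in get_template(resname).rows:
            if r.name not in out and any(f in out for f in r.frame):
                out.add(r.name)
                changed = True
    return out


def sidechain_path(resname: str, target_atom: str) -> list[TemplateRow]:
    """Ordered heavy-atom rows needed to build ``target_atom`` from the backbone."""
    tpl = get_template(resname)
    rows_by_name = {r.name: r for r in tpl.heavy_rows}
    if target_atom in ("N", "CA", "C"):
        return []
    if target_atom not in rows_by_name:
        raise KeyError(f"{resname} has no heavy atom {target_atom!r}")
    needed: list[str] = []

    def _require(name: str):
        if name in ("N", "CA", "C") or name in needed:
            return
        row = rows_by_name[name]
        for f in row.frame:
            _require(f)
        needed.append(name)

    _require(target_atom)
    return [rows_by_name[n] for n in needed]


# ---------------------------------------------------------------------------
# Reversed construction: build a residue outward from its functional triple.

_REF_SEED = (
    np.array([1.458, 0.0, 0.0]),  # N
    np.array([0.0, 0.0, 0.0]),  # CA
    np.array([0.53, 1.43, 0.0]),  # C (ideal N-CA-C angle)
)
_REF_CHI = 47.0  # arbitrary non-degenerate reference chi for derivations


def _reference_atoms(resname: str, chis: Sequence[float]) -> dict[str, np.ndarray]:
    return build_residue(resname, *_REF_SEED, chis=chis, include_hydrogens=False)


def reversed_rows(resname: str, triple: tuple[str, str, str]) -> list[TemplateRow]:
    """Z-matrix rows that rebuild a residue starting from a placed functional triple.

    ``triple`` = (A1, A2, A3) is the outermost functional atom and its two
    inner path neighbours (e.g. ``("OG", "CB", "CA")`` for serine,
    ``("NE2", "CE1", "ND1")`` for histidine).  The returned rows place the
    remaining heavy atoms down to the backbone N, CA and C; torsions that
    cross a chi axis become chi-linked variables with numerically derived
    sign and offset, everything else is fixed at the template value.

    The construction is derived numerically from the forward template, so the
    reversed build exactly reproduces forward-built coordinates.
    """
    tpl = get_template(resname)
    path = [r.name for r in sidechain_path(resname, triple[0])]
    order = list(triple)
    for name in reversed(path):
        if name not in order:
            order.append(name)
    for name in ("CA", "N", "C"):
        if name not in order:
            order.append(name)
    if order[1] != triple[1] or order[2] != triple[2]:
        raise ValueError(
            f"functional triple {triple} is not an inward path of {resname}"
        )

    nchi = tpl.n_chi
    ref0 = _reference_atoms(resname, [_REF_CHI] * nchi)
    axis_of = {tpl.chi_axis(k): k for k in range(1, nchi + 1)}

    rows: list[TemplateRow] = []
    for i in range(3, len(order)):
        name = order[i]
        a, b, c = order[i - 3], order[i - 2], order[i - 1]
        ic0 = ic_from_points(ref0[a], ref0[b], ref0[c], ref0[name])
        k = axis_of.get(frozenset((b, c)))
        if k is None:
            spec = _fx(ic0.torsion)
        else:
            chis1 = [_REF_CHI] * nchi
            chis1[k - 1] = _REF_CHI + 10.0
            ref1 = _reference_atoms(resname, chis1)
            t1 = dihedral(ref1[a], ref1[b], ref1[c], ref1[name])
            sign = 1.0 if wrap_degrees(t1 - ic0.torsion) > 0 else -1.0
            offset = wrap_degrees(ic0.torsion - sign * _REF_CHI)
            spec = _chi(k, offset, sign)
        rows.append(_row(name, (a, b, c), ic0.bond_length, ic0.bond_angle, spec))
    return rows
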