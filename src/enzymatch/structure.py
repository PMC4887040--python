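"""Macromolecular structure I/O and site selection.

PDB reading/writing is delegated to gemmi; this module layers the policies
used throughout the package on top of it: alternate locations resolved to the
highest-occupancy conformer (ties prefer altloc 'A', then alphabetical),
waters dropped, HETATM ligands kept separately from the polymer, and explicit
hydrogens built from idealized internal coordinates.

A transition-state (TS) model — the ligand placed by matching — is a small
molecule defined by a serial z-matrix with partial charges and optional
rotatable torsions, read from a YAML file.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import yaml

from . import params, templates
from .geometry import InternalCoordinate, ic_from_points, internal_to_cartesian

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "TSModel",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "build_hydrogens",
    "candidate_sites",
    "design_sites",
]

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False
    partial_charge: Optional[float] = None
    vdw_radius: Optional[float] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius is None:
            self.vdw_radius = params.vdw_radius(self.element)
        self.is_hydrogen = self.element.upper() == "H"


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)
    usable_site: bool = True

    @property
    def res_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode}"

    @property
    def is_proline(self) -> bool:
        return self.name.upper() == "PRO"

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].coords

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms.values() if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        return np.array([a.coords for a in heavy]).reshape(len(heavy), 3)

    def backbone_coords(self) -> dict[str, np.ndarray]:
        return {n: self.atoms[n].coords for n in ("N", "CA", "C", "O", "H") if n in self.atoms}

    def coords_dict(self) -> dict[str, np.ndarray]:
        return {n: a.coords for n, a in self.atoms.items()}

    def set_atom(self, name: str, coords, element: Optional[str] = None):
        el = element or params.element_from_name(name)
        self.atoms[name] = Atom(name=name, element=el, coords=coords)


@dataclass
class ProteinStructure:
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    source_id: str = ""
    resolution: Optional[float] = None
    hydrogens_built: bool = False

    def __post_init__(self):
        self._index = {r.res_id: r for r in self.residues}

    def reindex(self):
        self._index = {r.res_id: r for r in self.residues}

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        return self._index[(chain_id, number, icode)]

    def get(self, res_id) -> Optional[Residue]:
        return self._index.get(tuple(res_id))

    def __len__(self) -> int:
        return len(self.residues)

    def heavy_coords(self) -> np.ndarray:
        rows = [r.heavy_coords() for r in self.residues if r.heavy_atoms()]
        return np.vstack(rows) if rows else np.zeros((0, 3))


def _resolve_altlocs(names_to_variants: dict[str, list]) -> list:
    chosen = []
    for _name, variants in names_to_variants.items():
        variants.sort(key=lambda a: (-a[1], a[2] != "A", a[2]))
        chosen.append(variants[0])
    return chosen


def _check_atom_records(pdb_text: str):
    n_atoms = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atoms += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"truncated ATOM/HETATM record at line {lineno}")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBParseError(
                    f"malformed coordinates in ATOM/HETATM record at line {lineno}"
                ) from None
    if n_atoms == 0:
        raise PDBParseError("no ATOM/HETATM records found (empty model)")


def read_structure(pdb_text: str, source_id: str = "", keep_waters: bool = False) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    First model only; alternate locations are resolved to the highest
    occupancy (ties prefer 'A', then alphabetical); waters are dropped by
    default; HETATM ligand residues are stored in ``ligands``.
    """
    _check_atom_records(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB input")
    model = st[0]
    residues: list[Residue] = []
    ligands: list[Residue] = []
    for chain in model:
        for res in chain:
            rname = res.name.strip().upper()
            if rname in _WATER_NAMES and not keep_waters:
                continue
            variants: dict[str, list] = {}
            for at in res:
                variants.setdefault(at.name, []).append(
                    (at, at.occ, at.altloc if at.altloc else "")
                )
            out = Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name=rname,
            )
            for at, occ, _alt in _resolve_altlocs(variants):
                el = at.element.name if at.element and at.element.name != "X" else params.element_from_name(at.name)
                out.atoms[at.name] = Atom(
                    name=at.name,
                    element=el.upper(),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=occ,
                )
            if res.het_flag == "H" and rname not in templates.STANDARD_AA:
                ligands.append(out)
            else:
                residues.append(out)
    if not residues and not ligands:
        raise PDBParseError("empty model after filtering")
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return ProteinStructure(
        residues=residues,
        ligands=ligands,
        source_id=source_id or (st.name.lower() if st.name else ""),
        resolution=resolution,
    )


def write_structure(structure: ProteinStructure) -> str:
    """Serialize to PDB-format text (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "enzymatch"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def _add(res: Residue, het: bool):
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id or "A")
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        ch.add_residue(gres)

    for res in structure.residues:
        _add(res, het=False)
    for res in structure.ligands:
        _add(res, het=True)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def build_hydrogens(structure: ProteinStructure) -> ProteinStructure:
    """Add missing hydrogens to all standard residues from ideal geometry.

    Existing hydrogens are preserved; the operation is idempotent.  Residues
    missing backbone heavy atoms are flagged unusable as sites.  Ser/Thr/Tyr
    hydroxyl (and Cys thiol) hydrogen torsions remain rotatable downstream.
    """
    for res in structure.residues:
        if res.name not in templates.STANDARD_AA:
            continue
        if not res.has_backbone():
            logger.warning("residue %s %s lacks backbone; skipped as site", res.name, res.label)
            res.usable_site = False
            continue
        coords = res.coords_dict()
        try:
            new = templates.place_missing_hydrogens(res.name, coords)
        except KeyError:
            logger.warning("no template for %s %s; hydrogens not built", res.name, res.label)
            continue
        for name, xyz in new.items():
            res.set_atom(name, xyz, element="H")
    structure.hydrogens_built = True
    return structure


def _parse_res_ids(reference_residues: Iterable) -> list[tuple[str, int, str]]:
    out = []
    for rid in reference_residues:
        if isinstance(rid, str):
            chain, _, rest = rid.partition(":")
            num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
            icode = rest[len(num):].strip()
            out.append((chain, int(num), icode))
        else:
            rid = tuple(rid)
            out.append((rid[0], int(rid[1]), rid[2] if len(rid) > 2 else ""))
    return out


def candidate_sites(
    structure: ProteinStructure,
    reference_residues: Sequence,
    radius: float = 15.0,
) -> list[Residue]:
    """Residues whose CA lies within ``radius`` of the reference-CA centroid.

    Reference residues (e.g. native catalytic residues from a CSA-style
    annotation) must exist and have CA atoms.  Prolines are included here;
    role-level exclusion happens during matching.  Deterministic order
    (chain, number, icode).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    ids = _parse_res_ids(reference_residues)
    missing = [i for i in ids if structure.get(i) is None or "CA" not in structure.get(i).atoms]
    if missing or not ids:
        raise KeyError(f"reference residues not found or lacking CA: {missing or ids}")
    centroid = np.mean([structure.get(i).coord("CA") for i in ids], axis=0)
    hits = [
        r
        for r in structure.residues
        if "CA" in r.atoms and np.linalg.norm(r.coord("CA") - centroid) <= radius
    ]
    hits.sort(key=lambda r: (r.chain_id, r.number, r.icode))
    return hits


def design_sites(
    structure: ProteinStructure,
    ts_coords: np.ndarray,
    radius: float = 7.0,
) -> list[Residue]:
    """Residues with any heavy atom within ``radius`` of any TS heavy atom.

    Prolines are excluded (their backbone and ring allow no repacking
    freedom at the design stage).
    """
    ts = np.atleast_2d(np.asarray(ts_coords, float))
    if ts.size == 0:
        raise ValueError("empty TS coordinates")
    hits = []
    for r in structure.residues:
        if r.is_proline:
            continue
        hv = r.heavy_coords()
        if hv.size == 0:
            continue
        d2 = np.sum((hv[:, None, :] - ts[None, :, :]) ** 2, axis=-1)
        if np.any(d2 <= radius * radius):
            hits.append(r)
    hits.sort(key=lambda r: (r.chain_id, r.number, r.icode))
    return hits


# ---------------------------------------------------------------------------
# Transition-state model


@dataclass
class ZMatrixRow:
    atom: str
    frame: tuple[str, str, str]  # empty strings for the first three seed rows
    length: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0


@dataclass
class TSModel:
    """A ligand/transition-state fragment with internal-coordinate definition.

    The z-matrix is serial in file order: row 0 seeds the origin, row 1 a
    bond, row 2 a bond+angle, and each later row places its atom from three
    named, previously defined atoms.  ``rotatable`` lists bonds (atom-name
    pairs) whose torsions are free during matching.
    """

    name: str
    atoms: list[Atom]
    zmatrix: list[ZMatrixRow]
    rotatable: list[tuple[str, str]] = field(default_factory=list)
    charge_set: str = "charmm"

    def __post_init__(self):
        self._by_name = {a.name: a for a in self.atoms}
        names = [r.atom for r in self.zmatrix]
        if names != [a.name for a in self.atoms]:
            raise ValueError("z-matrix order must match atom list order")
        for pair in self.rotatable:
            bonds = self.bonds()
            if frozenset(pair) not in {frozenset(b) for b in bonds}:
                raise ValueError(f"rotatable torsion references non-bond {pair}")
        self.reference_coords()  # validates reconstructability

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def heavy_names(self) -> list[str]:
        return [a.name for a in self.atoms if not a.is_hydrogen]

    def bonds(self) -> list[tuple[str, str]]:
        out = []
        if len(self.zmatrix) > 1:
            out.append((self.zmatrix[0].atom, self.zmatrix[1].atom))
        if len(self.zmatrix) > 2:
            out.append((self.zmatrix[1].atom, self.zmatrix[2].atom))
        for row in self.zmatrix[3:]:
            out.append((row.frame[2], row.atom))
        return out

    def reference_coords(self) -> dict[str, np.ndarray]:
        """Reconstruct canonical coordinates from the z-matrix."""
        z = self.zmatrix
        coords: dict[str, np.ndarray] = {z[0].atom: np.zeros(3)}
        if len(z) > 1:
            coords[z[1].atom] = np.array([z[1].length, 0.0, 0.0])
        if len(z) > 2:
            th = math.radians(z[2].angle)
            coords[z[2].atom] = coords[z[1].atom] + z[2].length * np.array(
                [-math.cos(th), math.sin(th), 0.0]
            )
        for row in z[3:]:
            a, b, c = (coords[x] for x in row.frame)
            coords[row.atom] = internal_to_cartesian(
                a, b, c, InternalCoordinate(row.length, row.angle, row.torsion)
            )
        return coords

    @classmethod
    def from_reference_coords(
        cls,
        name: str,
        atoms: Sequence[tuple[str, str, float]],
        coords: dict[str, np.ndarray],
        rotatable: Sequence[tuple[str, str]] = (),
        charge_set: str = "charmm",
        frames: Optional[dict[str, tuple[str, str, str]]] = None,
    ) -> "TSModel":
        """Derive the z-matrix from explicit coordinates (helper for authoring)."""
        names = [a[0] for a in atoms]
        rows: list[ZMatrixRow] = [ZMatrixRow(names[0], ("", "", ""))]
        if len(names) > 1:
            rows.append(
                ZMatrixRow(
                    names[1], ("", "", ""),
                    length=float(np.linalg.norm(coords[names[1]] - coords[names[0]])),
                )
            )
        if len(names) > 2:
            from .geometry import angle as _angle

            rows.append(
                ZMatrixRow(
                    names[2], ("", "", ""),
                    length=float(np.linalg.norm(coords[names[2]] - coords[names[1]])),
                    angle=_angle(coords[names[0]], coords[names[1]], coords[names[2]]),
                )
            )
        for i, nm in enumerate(names[3:], start=3):
            frame = (frames or {}).get(nm, (names[i - 3], names[i - 2], names[i - 1]))
            ic = ic_from_points(*(coords[f] for f in frame), coords[nm])
            rows.append(ZMatrixRow(nm, frame, ic.bond_length, ic.bond_angle, ic.torsion))
        atom_objs = [
            Atom(name=n, element=e, coords=coords[n], partial_charge=q) for n, e, q in atoms
        ]
        return cls(name, atom_objs, rows, [tuple(p) for p in rotatable], charge_set)

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "charge_set": self.charge_set,
            "atoms": [
                {"name": a.name, "element": a.element, "charge": a.partial_charge or 0.0}
                for a in self.atoms
            ],
            "zmatrix": [
                {
                    "atom": r.atom,
                    **({"frame": list(r.frame)} if r.frame[0] else {}),
                    **({"length": round(r.length, 6)} if r.length else {}),
                    **({"angle": round(r.angle, 6)} if r.angle else {}),
                    **({"torsion": round(r.torsion, 6)} if r.frame[0] else {}),
                }
                for r in self.zmatrix
            ],
            "rotatable": [list(p) for p in self.rotatable],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TSModel":
        doc = yaml.safe_load(text)
        atoms = [
            Atom(
                name=a["name"],
                element=a.get("element", params.element_from_name(a["name"])),
                coords=np.zeros(3),
                partial_charge=float(a.get("charge", 0.0)),
            )
            for a in doc["atoms"]
        ]
        rows = []
        for r in doc["zmatrix"]:
            rows.append(
                ZMatrixRow(
                    atom=r["atom"],
                    frame=tuple(r.get("frame", ("", "", ""))),
                    length=float(r.get("length", 0.0)),
                    angle=float(r.get("angle", 0.0)),
                    torsion=float(r.get("torsion", 0.0)),
                )
            )
        model = cls(
            name=doc.get("name", "ts"),
            atoms=atoms,
            zmatrix=rows,
            rotatable=[tuple(p) for p in doc.get("rotatable", [])],
            charge_set=doc.get("charge_set", "charmm"),
        )
        ref = model.reference_coords()
        for a in model.atoms:
            a.coords = ref[a.name]
        return model
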