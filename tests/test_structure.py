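import numpy as np
import pytest

from enzymatch.geometry import distance
from enzymatch.structure import (
    PDBParseError,
    TSModel,
    build_hydrogens,
    candidate_sites,
    design_sites,
    read_structure,
    write_structure,
)
from enzymatch.templates import PEPTIDE, build_residue

MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.944  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.573  -5.899  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.246   4.690  -4.898  1.00  0.00           C
ATOM      6  N  ASER A   2      12.800   7.600  -3.700  0.60  0.00           N
ATOM      7  N  BSER A   2      12.900   7.700  -3.800  0.40  0.00           N
ATOM      8  CA  SER A   2      13.800   8.600  -3.300  1.00  0.00           C
ATOM      9  C   SER A   2      13.200   9.900  -2.800  1.00  0.00           C
ATOM     10  CB  SER A   2      14.600   8.900  -4.560  1.00  0.00           C
ATOM     11  OG  SER A   2      15.000   8.000  -2.700  1.00  0.00           O
ATOM     12  N   GLY A   3      13.000  10.200  -1.500  1.00  0.00           N
ATOM     13  CA  GLY A   3      12.400  11.400  -0.900  1.00  0.00           C
ATOM     14  C   GLY A   3      13.300  12.600  -1.100  1.00  0.00           C
HETATM   15  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
HETATM   16  C1  LIG A 201       5.000   5.000   5.000  1.00  0.00           C
TER
END
"""


def test_read_structure_basics():
    s = read_structure(MINI_PDB, source_id="mini")
    assert len(s.residues) == 3  # water dropped
    assert [r.name for r in s.residues] == ["ALA", "SER", "GLY"]
    assert [r.number for r in s.residues] == [1, 2, 3]
    assert len(s.ligands) == 1 and s.ligands[0].name == "LIG"
    # altloc resolved to highest occupancy (A at 0.6)
    assert s.residue("A", 2).coord("N")[0] == pytest.approx(12.800)


def test_round_trip_preserves_coordinates():
    s = read_structure(MINI_PDB)
    s2 = read_structure(write_structure(s))
    for r1, r2 in zip(s.residues, s2.residues):
        assert r1.res_id == r2.res_id
        for name, atom in r1.atoms.items():
            assert np.allclose(atom.coords, r2.atoms[name].coords, atol=1e-3)


@pytest.mark.parametrize(
    "bad,msg",
    [
        ("ATOM      1  N   ALA A   1      xx.xxx   6.134  -6.504\n", "malformed"),
        ("ATOM      1  N   ALA A   1      11.1\n", "truncated"),
        ("HEADER    NOTHING HERE\nEND\n", "no ATOM"),
    ],
)
def test_parse_errors(bad, msg):
    with pytest.raises(PDBParseError, match=msg):
        read_structure(bad)


def test_build_hydrogens_alanine_and_serine():
    s = read_structure(MINI_PDB)
    build_hydrogens(s)
    ala = s.residue("A", 1)
    hs = sorted(n for n, a in ala.atoms.items() if a.is_hydrogen)
    assert hs == ["H", "HA", "HB1", "HB2", "HB3"]
    assert distance(ala.coord("N"), ala.coord("H")) == pytest.approx(
        PEPTIDE["N-H"], abs=1e-6
    )
    ser = s.residue("A", 2)
    # serine gains exactly one rotatable hydroxyl hydrogen
    assert "HG1" in ser.atoms
    assert distance(ser.coord("OG"), ser.coord("HG1")) == pytest.approx(0.96, abs=1e-6)


def test_build_hydrogens_idempotent():
    s = read_structure(MINI_PDB)
    build_hydrogens(s)
    snapshot = {
        (r.res_id, n): a.coords.copy() for r in s.residues for n, a in r.atoms.items()
    }
    build_hydrogens(s)
    for r in s.residues:
        for n, a in r.atoms.items():
            assert np.allclose(a.coords, snapshot[(r.res_id, n)])


def test_candidate_sites_brute_force(planted):
    s = planted.scaffold
    refs = planted.catalytic_site_ids
    for radius in (5.0, 10.0, 15.0):
        sites = candidate_sites(s, refs, radius)
        centroid = np.mean([s.get(r).coord("CA") for r in refs], axis=0)
        expected = sorted(
            r.res_id
            for r in s.residues
            if np.linalg.norm(r.coord("CA") - centroid) <= radius
        )
        assert sorted(r.res_id for r in sites) == expected
    # reference residues are always within the default radius
    sites15 = {r.res_id for r in candidate_sites(s, refs, 15.0)}
    assert set(tuple(r) for r in refs) <= sites15
    with pytest.raises(KeyError):
        candidate_sites(s, [("Z", 999, "")], 15.0)


def test_design_sites_brute_force(planted):
    s = planted.scaffold
    ts = np.array(list(planted.truth.ts_pose.values()))
    for radius in (4.0, 7.0):
        sites = design_sites(s, ts, radius)
        expected = []
        for r in s.residues:
            if r.is_proline:
                continue
            hv = r.heavy_coords()
            dmin = np.min(
                np.linalg.norm(hv[:, None] - ts[None], axis=-1)
            )
            if dmin <= radius:
                expected.append(r.res_id)
        assert [r.res_id for r in sites] == sorted(expected)
    assert design_sites(s, ts + 500.0, 7.0) == []


def test_design_sites_boundary_and_proline():
    n = np.array([1.458, 0.0, 0.0]); ca = np.zeros(3); c = np.array([0.53, 1.43, 0.0])
    from enzymatch.structure import ProteinStructure, Residue

    def make(num, name, shift):
        r = Residue("A", num, name)
        for an, xyz in build_residue(name, n + shift, ca + shift, c + shift).items():
            r.set_atom(an, xyz)
        return r

    # residues parked far away, each with one probe atom at a controlled distance
    near = make(1, "ALA", np.array([40.0, 0, 0]))
    near.set_atom("OXT", np.array([6.9, 0.0, 0.0]))
    far = make(2, "ALA", np.array([40.0, 10.0, 0]))
    far.set_atom("OXT", np.array([7.1, 0.0, 0.0]))
    pro = make(3, "PRO", np.array([3.0, 0, 0]))
    s = ProteinStructure(residues=[near, far, pro])
    ts = np.zeros((1, 3))
    ids = [r.res_id for r in design_sites(s, ts, 7.0)]
    assert ("A", 1, "") in ids  # one atom at 6.9 A -> included
    assert ("A", 2, "") not in ids  # 7.1 A -> excluded
    assert ("A", 3, "") not in ids  # proline excluded even when close


def test_ts_model_yaml_round_trip(toy_motif):
    ts = toy_motif.ts
    ts2 = TSModel.from_yaml(ts.to_yaml())
    ref1, ref2 = ts.reference_coords(), ts2.reference_coords()
    for name in ts.atom_names():
        assert np.allclose(ref1[name], ref2[name], atol=1e-9)
    # internal coordinates reconstruct the stored atom coordinates
    for atom in ts2.atoms:
        assert np.allclose(atom.coords, ref2[atom.name], atol=1e-6)


def test_ts_model_rejects_bad_rotatable(toy_motif):
    import yaml

    doc = yaml.safe_load(toy_motif.ts.to_yaml())
    doc["rotatable"] = [["OX", "O1"]]  # not a bond
    with pytest.raises(ValueError, match="non-bond"):
        TSModel.from_yaml(yaml.safe_dump(doc))
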