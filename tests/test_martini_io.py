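"""Mapping tables, CG-PDB round trips and ITP topology parsing."""

import numpy as np
import pytest

from cgppi.mapping import MartiniVersion, bead_type_vocabulary
from cgppi.martini_io import (
    CGParseError, CGTopology, CGValidationError, categorize_bond,
    parse_cg_structure, parse_topology, sidechain_bead_count, simple_martinize,
    write_cg_structure,
)
from conftest import chain_topology

M22 = MartiniVersion.MARTINI22
M3 = MartiniVersion.MARTINI3


@pytest.mark.parametrize("residue, version, expected", [
    ("TRP", M22, 4),
    ("TRP", M3, 5),
    ("ALA", M22, 0),
    ("ALA", M3, 1),
    ("GLY", M22, 0),
    ("GLY", M3, 0),
    ("HIS", M22, 3),
    ("LYS", M22, 2),
])
def test_sidechain_bead_counts(residue, version, expected):
    assert sidechain_bead_count(residue, version) == expected


def test_sidechain_count_rejects_nonnatural_residue():
    with pytest.raises(ValueError, match="non-natural"):
        sidechain_bead_count("MSE", M22)


@pytest.mark.parametrize("version, size", [(M22, 17), (M3, 23)])
def test_vocabulary_sizes(version, size):
    vocab = bead_type_vocabulary(version)
    assert len(vocab) == size
    assert len(set(vocab)) == size
    assert bead_type_vocabulary(version) == vocab  # deterministic ordering


def test_all_mapped_bead_types_are_in_vocabulary():
    from cgppi.mapping import (STANDARD_RESIDUES, backbone_bead_type,
                               sidechain_bead_types)
    for version in (M22, M3):
        vocab = set(bead_type_vocabulary(version))
        for res in STANDARD_RESIDUES:
            for ss in "HEC":
                assert backbone_bead_type(res, ss, version) in vocab
            assert set(sidechain_bead_types(res, version)) <= vocab


# ---------------------------------------------------------------------------
# CG-PDB structure IO
# ---------------------------------------------------------------------------

def test_structure_round_trip(tmp_path):
    topo = chain_topology("HHHHCCEEEE", seed=5)
    path = tmp_path / "chain.pdb"
    write_cg_structure(topo.beads, path)
    parsed = parse_cg_structure(path, M22)
    assert len(parsed) == len(topo.beads)
    for orig, back in zip(topo.beads, parsed):
        assert back.bead_index == orig.bead_index
        assert back.bead_role == orig.bead_role
        assert back.residue_index == orig.residue_index
        np.testing.assert_allclose(back.coord, orig.coord, atol=1.5e-3)


def test_parse_empty_file_is_validation_error(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises((CGParseError, CGValidationError)):
        parse_cg_structure(path)


def test_parse_malformed_record_reports_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(
        "ATOM      1  BB  GLY A   1       0.000   0.000   0.000\n"
        "ATOM      2  BB  GLY A   2       x.xxx   0.000   3.500\n"
    )
    with pytest.raises(CGParseError, match=":2:"):
        parse_cg_structure(path)


def test_parse_duplicate_backbone_bead_rejected(tmp_path):
    path = tmp_path / "dup.pdb"
    path.write_text(_pdb_line(1, 1, 0.0) + _pdb_line(2, 1, 1.0))
    with pytest.raises(CGValidationError, match="duplicate"):
        parse_cg_structure(path)


def _pdb_line(serial: int, res_id: int, z: float) -> str:
    return (f"ATOM  {serial:5d}  BB  GLY A{res_id:4d}    "
            f"{0.0:8.3f}{0.0:8.3f}{z:8.3f}  1.00  0.00           C\n")


def test_backbone_only_file_parses_three_beads(tmp_path):
    path = tmp_path / "bb.pdb"
    path.write_text("".join(_pdb_line(i + 1, i + 1, i * 3.5) for i in range(3)))
    beads = parse_cg_structure(path)
    assert [b.bead_role for b in beads] == ["B", "B", "B"]


# ---------------------------------------------------------------------------
# ITP topology parsing
# ---------------------------------------------------------------------------

ITP_HELIX_PAIR = """
[ moleculetype ]
Protein 1

[ atoms ]
 1 N0 1 ALA BB 1 0
 2 N0 2 LYS BB 2 0
 3 C3 2 LYS SC1 3 0
 4 Qd 2 LYS SC2 4 1

[ constraints ]
 1 2 1 0.310

[ bonds ]
 2 3 1 0.330 5000
 3 4 1 0.280 5000

[ angles ]
 2 3 4 2 180 25
"""


def test_parse_topology_assigns_constraint_and_sidechain_categories(tmp_path):
    path = tmp_path / "mol.itp"
    path.write_text(ITP_HELIX_PAIR)
    topo = parse_topology(path, "HH", M22)
    cats = sorted(t.category for t in topo.bonds())
    assert cats == ["d_BB_H", "d_S", "d_S"]
    # nm in the file, Angstrom in memory
    constraint = next(t for t in topo.bonds() if t.category == "d_BB_H")
    assert constraint.ref_value == pytest.approx(3.10)
    (angle,) = topo.angles()
    assert angle.category == "theta_BSS"


def test_parse_topology_coil_pair_is_cts(tmp_path):
    path = tmp_path / "mol.itp"
    path.write_text(ITP_HELIX_PAIR)
    topo = parse_topology(path, "HC", M22)  # second residue not helical
    assert sorted(t.category for t in topo.bonds())[0] == "d_BB_CTS"


def test_parse_topology_without_angles_gives_empty_angle_list(tmp_path):
    path = tmp_path / "noang.itp"
    path.write_text(
        "[ atoms ]\n 1 P5 1 GLY BB 1 0\n 2 P5 2 GLY BB 2 0\n"
        "[ bonds ]\n 1 2 1 0.350 1250\n"
    )
    topo = parse_topology(path, "CC", M22)
    assert topo.angles() == []


def test_parse_topology_unknown_bead_reference_rejected(tmp_path):
    path = tmp_path / "badref.itp"
    path.write_text(
        "[ atoms ]\n 1 P5 1 GLY BB 1 0\n"
        "[ bonds ]\n 1 9 1 0.350 1250\n"
    )
    with pytest.raises(CGValidationError, match="unknown bead"):
        parse_topology(path, "C", M22)


def test_bond_categories_pure_function_of_roles_offsets_ss():
    """Permuting file record order cannot change the category multiset."""
    topo = chain_topology("EEEEEE", ["LEU"] * 6, seed=2)
    residue_ss = topo.residue_ss()
    cats = sorted(
        categorize_bond(topo.beads[t.member_beads[0]],
                        topo.beads[t.member_beads[1]], residue_ss)
        for t in topo.bonds()
    )
    rng = np.random.default_rng(0)
    for _ in range(3):
        order = rng.permutation(len(topo.bonds()))
        permuted = sorted(
            categorize_bond(topo.beads[topo.bonds()[i].member_beads[0]],
                            topo.beads[topo.bonds()[i].member_beads[1]],
                            residue_ss)
            for i in order
        )
        assert permuted == cats


# ---------------------------------------------------------------------------
# built-in simplified mapper
# ---------------------------------------------------------------------------

def _ideal_atomistic(residues, coords_offset=3.8):
    """A minimal poly-peptide AtomArray with N/CA/C/O (+CB for non-GLY)."""
    import biotite.structure as bst
    atoms = []
    names_by_res = []
    for i, res in enumerate(residues):
        base = np.array([i * coords_offset, 0.0, 0.0])
        names = ["N", "CA", "C", "O"] + ([] if res == "GLY" else ["CB"])
        offsets = {
            "N": (0.0, 0.8, 0.0), "CA": (0.5, 0.0, 0.0),
            "C": (1.0, 0.6, 0.0), "O": (1.2, 1.6, 0.3),
            "CB": (0.5, -1.5, 0.2),
        }
        for name in names:
            atoms.append((res, i + 1, name, base + np.asarray(offsets[name])))
        names_by_res.append(names)
    arr = bst.AtomArray(len(atoms))
    arr.coord = np.asarray([a[3] for a in atoms], dtype=np.float32)
    arr.chain_id = np.asarray(["A"] * len(atoms))
    arr.res_id = np.asarray([a[1] for a in atoms])
    arr.res_name = np.asarray([a[0] for a in atoms])
    arr.atom_name = np.asarray([a[2] for a in atoms])
    arr.element = np.asarray([a[2][0] for a in atoms])
    return arr


def test_simple_martinize_triglycine_terms():
    topo = simple_martinize(_ideal_atomistic(["GLY"] * 3), "CCC", M22)
    assert len(topo.beads) == 3
    assert len(topo.bonds()) == 2
    assert [a.category for a in topo.angles()] == ["theta_BBB"]


def test_simple_martinize_single_residue_has_no_bonds():
    topo = simple_martinize(_ideal_atomistic(["GLY"]), "C", M22)
    assert topo.bonds() == []


def test_simple_martinize_triala_martini3_bead_count():
    topo = simple_martinize(_ideal_atomistic(["ALA"] * 3), "CCC", M3)
    assert len(topo.beads) == 6  # 3 x (backbone + 1 side-chain bead)


def test_simple_martinize_counts_match_mapping_table():
    for version in (M22, M3):
        for res, n_side in (("GLY", 0), ("TRP", 4 if version is M22 else 5)):
            arr = _ideal_atomistic([res])
            if n_side:
                # give TRP enough side-chain heavy atoms
                import biotite.structure as bst
                extra = bst.AtomArray(8)
                extra.coord = np.asarray(
                    [[0.5, -1.5 - 0.4 * k, 0.0] for k in range(8)],
                    dtype=np.float32)
                extra.chain_id = np.asarray(["A"] * 8)
                extra.res_id = np.asarray([1] * 8)
                extra.res_name = np.asarray([res] * 8)
                extra.atom_name = np.asarray([f"C{k}" for k in range(8)])
                extra.element = np.asarray(["C"] * 8)
                arr = arr + extra
            topo = simple_martinize(arr, "C", version)
            side = [b for b in topo.beads if b.bead_role != "B"]
            assert len(side) == n_side


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def test_topology_json_round_trip():
    topo = chain_topology("HHHHEEEECCC", seed=9)
    back = CGTopology.from_json(topo.to_json())
    assert len(back.beads) == len(topo.beads)
    assert back.ss_codes == topo.ss_codes
    assert [t.category for t in back.bonded_terms] == \
        [t.category for t in topo.bonded_terms]
    np.testing.assert_allclose(back.coords(), topo.coords())
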