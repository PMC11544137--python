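"""Graph construction: edges, re-calibrated geometry, features, invariants."""

import numpy as np
import pytest

from cgppi.geometry import interior_angle, torsion_angle
from cgppi.graph import (
    ANGULAR_CATEGORIES, AblationFlags, NUM_RELATIONS, POSITIONAL_BINS,
    RELATION_INDEX, RELATIONS, assign_angular_features, bond_edges,
    build_graph, edge_feature_dim, load_graph, node_feature_dim, radius_edges,
    recalibrate_geometry, save_graph,
)
from cgppi.mapping import MartiniVersion, bead_type_vocabulary
from cgppi.martini_io import CGBead, CGTopology, generate_bonded_terms
from conftest import chain_topology, random_rotation, rigid_transform_topology

M22 = MartiniVersion.MARTINI22
M3 = MartiniVersion.MARTINI3


def _beads_at(coords, chain="A", residue_indices=None, roles=None):
    residue_indices = residue_indices or [1] * len(coords)
    roles = roles or ["B"] + [f"S{k}" for k in range(1, len(coords))]
    return [
        CGBead(bead_index=i, chain_id=chain, residue_index=residue_indices[i],
               residue_name="LYS", bead_role=roles[i], bead_type="P5",
               coord=tuple(c))
        for i, c in enumerate(coords)
    ]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def test_collinear_triple_angle_is_180():
    assert interior_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)


def test_right_angle():
    assert interior_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)


def test_cis_planar_torsion_is_zero():
    assert torsion_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == \
        pytest.approx(0.0, abs=1e-9)


def test_trans_planar_torsion_is_180():
    assert abs(torsion_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))) == \
        pytest.approx(180.0)


def test_coincident_points_raise():
    with pytest.raises(ValueError, match="coincident"):
        interior_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


# ---------------------------------------------------------------------------
# radius edges
# ---------------------------------------------------------------------------

def test_intra_residue_pair_at_3A_gives_two_directed_intra_edges():
    beads = _beads_at([(0, 0, 0), (3.0, 0, 0)])
    idx, rel = radius_edges(beads)
    assert idx.shape == (2, 2)
    assert set(rel) == {RELATION_INDEX["d_intra"]}
    assert {(int(a), int(b)) for a, b in idx.T} == {(0, 1), (1, 0)}


def test_pair_beyond_cutoff_gives_no_edge():
    beads = _beads_at([(0, 0, 0), (6.0, 0, 0)],
                      residue_indices=[1, 1], roles=["B", "S1"])
    idx, _ = radius_edges(beads)
    assert idx.shape[1] == 0


def test_pair_exactly_at_cutoff_excluded():
    beads = _beads_at([(0, 0, 0), (5.0, 0, 0)])
    idx, _ = radius_edges(beads)
    assert idx.shape[1] == 0  # strict '<'


def test_all_close_beads_give_complete_directed_graph():
    n = 6
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 1.5, size=(n, 3))
    beads = _beads_at(list(coords), residue_indices=list(range(1, n + 1)),
                      roles=["B"] * n)
    idx, rel = radius_edges(beads)
    assert idx.shape[1] == n * (n - 1)
    assert set(rel) == {RELATION_INDEX["d_inter"]}


def test_radius_edges_match_brute_force_oracle():
    """Production KD-tree path vs an O(n^2) double loop."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 12, size=(40, 3))
    residues = list(rng.integers(1, 10, size=40))
    beads = _beads_at(list(coords), residue_indices=residues, roles=["B"] * 40)
    # oracle: enumerate unordered pairs directly
    expected = set()
    for i in range(40):
        for j in range(i + 1, 40):
            if np.linalg.norm(coords[i] - coords[j]) < 5.0:
                r = ("d_intra" if residues[i] == residues[j] else "d_inter")
                expected.add((i, j, r))
                expected.add((j, i, r))
    idx, rel = radius_edges(beads)
    got = {(int(s), int(t), RELATIONS[r])
           for s, t, r in zip(idx[0], idx[1], rel)}
    assert got == expected


# ---------------------------------------------------------------------------
# bond edges
# ---------------------------------------------------------------------------

def test_coil_chain_bond_edges_all_cts(coil_triple):
    idx, rel = bond_edges(coil_triple)
    assert idx.shape[1] == 4  # 2 bonds, bidirectional
    assert set(rel) == {RELATION_INDEX["d_BB_CTS"]}


def test_strand_chain_has_long_harmonic_bonds():
    topo = chain_topology("EEEEE", ["VAL"] * 5, seed=1)
    idx, rel = bond_edges(topo)
    cats = [RELATIONS[r] for r in rel]
    assert cats.count("d_BB3_E") == 4   # (1,4) and (2,5), both directions
    assert cats.count("d_BB4_E") == 2   # (1,5)


def test_two_sidechain_bead_residue_has_linear_d_s_bonds():
    topo = chain_topology("C", ["LYS"], seed=0)
    pairs = [t.member_beads for t in topo.bonds() if t.category == "d_S"]
    assert pairs == [(0, 1), (1, 2)]  # B-S1, S1-S2


# ---------------------------------------------------------------------------
# re-calibration and angular assignment
# ---------------------------------------------------------------------------

def test_recalibrated_bond_length_is_euclidean():
    from dataclasses import replace
    beads = [replace(b, residue_name="CYS")
             for b in _beads_at([(0, 0, 0), (0, 0, 4.7)])]
    topo = CGTopology(beads=beads, bonded_terms=generate_bonded_terms(beads, "C"),
                      ss_codes="C", version=M22)
    _, lengths = recalibrate_geometry(topo)
    assert lengths[0][1] == pytest.approx(4.7)


def test_statistical_ref_values_not_used_in_features():
    """Edge length features come from coordinates, not the topology file."""
    from dataclasses import replace
    topo = chain_topology("CCC", ["GLY"] * 3, seed=1)
    skewed = CGTopology(
        beads=topo.beads,
        bonded_terms=[replace(t, ref_value=99.9) for t in topo.bonded_terms],
        ss_codes=topo.ss_codes, version=topo.version,
    )
    g1 = build_graph(topo, {"A": 1})
    g2 = build_graph(skewed, {"A": 1})
    np.testing.assert_array_equal(g1.edge_features, g2.edge_features)


def test_interior_bead_holds_the_single_theta_bbb(coil_triple):
    angular, _ = recalibrate_geometry(coil_triple)
    assignment = assign_angular_features(coil_triple, angular)
    cat = ANGULAR_CATEGORIES.index("theta_BBB")
    assert assignment.mask[:, cat].tolist() == [False, True, False]


def test_chain_terminal_backbone_bead_has_empty_angular_block(coil_triple):
    angular, _ = recalibrate_geometry(coil_triple)
    assignment = assign_angular_features(coil_triple, angular)
    assert not assignment.mask[0].any()
    assert not assignment.mask[-1].any()


def test_helical_four_residue_run_gets_exactly_one_dihedral():
    topo = chain_topology("HHHH", ["ALA"] * 4, seed=2)
    angular, _ = recalibrate_geometry(topo)
    assignment = assign_angular_features(topo, angular)
    cat = ANGULAR_CATEGORIES.index("psi_BBBB")
    assert assignment.mask[:, cat].sum() == 1
    assert assignment.mask[1, cat]  # hosted by B_{i+1}


def test_no_dihedral_outside_all_helical_quadruples():
    topo = chain_topology("HHHC", ["ALA"] * 4, seed=2)
    assert topo.dihedrals() == []


# ---------------------------------------------------------------------------
# feature encoding and dimension laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("version, node_dim, edge_dim", [
    (M22, 25, 53), (M3, 31, 65),
])
def test_feature_dimension_laws(version, node_dim, edge_dim):
    vocab = len(bead_type_vocabulary(version))
    assert node_feature_dim(version) == vocab + 8 == node_dim
    assert edge_feature_dim(version) == 2 * vocab + NUM_RELATIONS \
        + POSITIONAL_BINS + 1 == edge_dim


@pytest.mark.parametrize("version", [M22, M3])
def test_built_graph_feature_shapes(version):
    topo = chain_topology("HHHHHH", seed=3, version=version)
    g = build_graph(topo, {"A": 1})
    assert g.node_features.shape[1] == node_feature_dim(version)
    assert g.edge_features.shape[1] == edge_feature_dim(version)


def test_positional_bin_count_forced_by_dimension_arithmetic():
    for version, edge_dim in ((M22, 53), (M3, 65)):
        vocab = len(bead_type_vocabulary(version))
        assert edge_dim - 2 * vocab - NUM_RELATIONS - 1 == POSITIONAL_BINS == 11


def test_sine_cosine_pair_for_right_angle():
    assert np.sin(np.radians(90.0)) == pytest.approx(1.0)
    topo = _right_angle_triple()
    g = build_graph(topo, {"A": 1})
    vocab = len(bead_type_vocabulary(M22))
    cat = ANGULAR_CATEGORIES.index("theta_BBB")
    sin_col, cos_col = vocab + 2 * cat, vocab + 2 * cat + 1
    assert g.node_features[1, sin_col] == pytest.approx(1.0)
    assert g.node_features[1, cos_col] == pytest.approx(0.0, abs=1e-12)


def _right_angle_triple():
    beads = _beads_at([(3.8, 0, 0), (0, 0, 0), (0, 3.8, 0)],
                      residue_indices=[1, 2, 3], roles=["B", "B", "B"])
    from dataclasses import replace
    beads = [replace(b, residue_name="GLY") for b in beads]
    return CGTopology(beads=beads,
                      bonded_terms=generate_bonded_terms(beads, "CCC"),
                      ss_codes="CCC", version=M22)


def test_sin2_cos2_law(small_graph):
    """Present angular pairs lie on the unit circle; absent pairs are (0,0)."""
    vocab = len(bead_type_vocabulary(small_graph.version))
    trig = small_graph.node_features[:, vocab:]
    for c in range(4):
        s, co = trig[:, 2 * c], trig[:, 2 * c + 1]
        norm = s**2 + co**2
        present = small_graph.angular.mask[:, c]
        np.testing.assert_allclose(norm[present], 1.0, atol=1e-12)
        np.testing.assert_allclose(norm[~present], 0.0, atol=1e-12)


def test_adjacent_bead_edge_activates_position_bin_one(coil_triple):
    g = build_graph(coil_triple, {"A": 1})
    vocab = len(bead_type_vocabulary(M22))
    pos_block = g.edge_features[:, 2 * vocab + NUM_RELATIONS:
                                2 * vocab + NUM_RELATIONS + POSITIONAL_BINS]
    adjacent = np.abs(g.edge_index[0] - g.edge_index[1]) == 1
    assert np.all(pos_block[adjacent, 1] == 1.0)
    assert np.all(pos_block[adjacent].sum(axis=1) == 1.0)


# ---------------------------------------------------------------------------
# full assembly, ablations, invariants
# ---------------------------------------------------------------------------

def test_seven_relations_in_label_space(small_graph):
    assert len(RELATIONS) == 7
    assert NUM_RELATIONS == 7


def test_toy_dimer_contains_both_contact_and_bond_relations(small_graph):
    present = {RELATIONS[r] for r in small_graph.edge_relation}
    assert {"d_intra", "d_inter", "d_BB_H", "d_S"} <= present


def test_angular_ablation_zeroes_trig_block(helix_dimer):
    topo, _, _ = helix_dimer
    g = build_graph(topo, {"A": 1, "B": 2},
                    flags=AblationFlags(use_angular=False))
    vocab = len(bead_type_vocabulary(g.version))
    assert np.all(g.node_features[:, vocab:] == 0.0)


def test_bead_type_ablation_makes_onehots_identical(helix_dimer):
    topo, _, _ = helix_dimer
    g = build_graph(topo, {"A": 1, "B": 2},
                    flags=AblationFlags(use_bead_types=False))
    vocab = len(bead_type_vocabulary(g.version))
    onehots = g.node_features[:, :vocab]
    assert np.all(onehots == onehots[0])


def test_bond_edge_ablation_leaves_only_contacts(helix_dimer):
    topo, _, _ = helix_dimer
    g = build_graph(topo, {"A": 1, "B": 2},
                    flags=AblationFlags(use_bond_edges=False))
    present = {RELATIONS[r] for r in g.edge_relation}
    assert present <= {"d_intra", "d_inter"}


def test_intra_inter_merge_ablation(helix_dimer):
    topo, _, _ = helix_dimer
    g = build_graph(topo, {"A": 1, "B": 2},
                    flags=AblationFlags(distinguish_intra_inter=False))
    contact = np.isin(g.edge_relation,
                      [RELATION_INDEX["d_intra"], RELATION_INDEX["d_inter"]])
    assert set(g.edge_relation[contact]) == {RELATION_INDEX["d_inter"]}


def test_duplicated_bond_edge_ablation(helix_dimer):
    topo, full_graph, _ = helix_dimer
    g = build_graph(topo, {"A": 1, "B": 2},
                    flags=AblationFlags(drop_duplicated_bond_edges=True))
    contact_pairs = {
        (int(s), int(t)) for s, t, r in
        zip(g.edge_index[0], g.edge_index[1], g.edge_relation)
        if RELATIONS[r] in ("d_intra", "d_inter")
    }
    bond_pairs = {
        (int(s), int(t)) for s, t, r in
        zip(g.edge_index[0], g.edge_index[1], g.edge_relation)
        if RELATIONS[r] not in ("d_intra", "d_inter")
    }
    assert not (bond_pairs & contact_pairs)
    assert g.num_edges < full_graph.num_edges


def test_rigid_motion_leaves_all_features_bit_identical(helix_dimer):
    topo, graph, _ = helix_dimer
    rng = np.random.default_rng(7)
    moved = rigid_transform_topology(topo, random_rotation(rng),
                                     rng.uniform(-30, 30, 3))
    g2 = build_graph(moved, {"A": 1, "B": 2})
    np.testing.assert_allclose(g2.node_features, graph.node_features,
                               rtol=0, atol=1e-9)
    np.testing.assert_allclose(g2.edge_features, graph.edge_features,
                               rtol=0, atol=1e-9)
    np.testing.assert_array_equal(g2.edge_index, graph.edge_index)
    np.testing.assert_array_equal(g2.edge_relation, graph.edge_relation)


def test_edge_symmetry_with_equal_lengths(small_graph):
    triples = {}
    for k, (s, t, r) in enumerate(zip(small_graph.edge_index[0],
                                      small_graph.edge_index[1],
                                      small_graph.edge_relation)):
        triples[(int(s), int(t), int(r))] = small_graph.edge_features[k, -1]
    for (s, t, r), length in triples.items():
        assert (t, s, r) in triples
        assert triples[(t, s, r)] == pytest.approx(length)


def test_graph_serialization_round_trip(tmp_path, small_graph):
    path = tmp_path / "graph.npz"
    save_graph(small_graph, path)
    back = load_graph(path)
    np.testing.assert_array_equal(back.node_features, small_graph.node_features)
    np.testing.assert_array_equal(back.edge_features, small_graph.edge_features)
    np.testing.assert_array_equal(back.edge_index, small_graph.edge_index)
    assert back.part_labels == small_graph.part_labels
    assert back.version == small_graph.version
    assert [b.bead_type for b in back.beads] == \
        [b.bead_type for b in small_graph.beads]
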