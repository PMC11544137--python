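"""Multi-relational CG complex graph construction.

A complex is modelled as a directed multi-relational graph G = (V, E, R):
nodes are MARTINI beads, and seven edge relations describe the geometry
from complementary perspectives --

* five force-field bond categories (``d_BB_CTS``, ``d_BB_H``, ``d_BB3_E``,
  ``d_BB4_E``, ``d_S``), injected from the topology;
* two composition-aware radius contacts (``d_intra`` within a residue,
  ``d_inter`` between residues) wired for bead pairs closer than 5 A.

Node features concatenate a one-hot bead type with sine/cosine encodings of
the re-calibrated backbone/side-chain angles and the backbone dihedral
(vocab + 8 components: 25 for MARTINI22, 31 for MARTINI3).  Edge features
concatenate source/target bead-type one-hots, a 7-way relation one-hot, an
11-bin one-hot of the clipped |bead-index difference| and the re-calibrated
edge length in Angstrom (2*vocab + 19: 53 / 65).

All geometry enters through distances and angles, so features are invariant
under rigid motion of the input coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .geometry import interior_angle, torsion_angle
from .mapping import MartiniVersion, bead_type_index, bead_type_vocabulary
from .martini_io import BondedTerm, CGBead, CGTopology, CGValidationError

logger = logging.getLogger(__name__)

RELATIONS: tuple[str, ...] = (
    "d_BB_CTS", "d_BB_H", "d_BB3_E", "d_BB4_E", "d_S", "d_intra", "d_inter",
)
RELATION_INDEX = {r: i for i, r in enumerate(RELATIONS)}
NUM_RELATIONS = len(RELATIONS)

ANGULAR_CATEGORIES: tuple[str, ...] = (
    "theta_BBB", "theta_BBS", "theta_BSS", "psi_BBBB",
)
_ANGULAR_INDEX = {c: i for i, c in enumerate(ANGULAR_CATEGORIES)}

POSITIONAL_BINS = 11  # |bead index difference| clipped at >= 10
RADIUS_CUTOFF = 5.0  # Angstrom, strict '<'


@dataclass(frozen=True)
class AblationFlags:
    """Switches that remove individual geometric components of the graph.

    Defaults reproduce the full graph; each flag mirrors one ablation
    variant (dropping bond edges, merging the composition-aware contacts
    into one radius label, making bead-type one-hots identical, zeroing
    angular features, or discarding bond edges duplicated by a contact).
    """

    use_bond_edges: bool = True
    distinguish_intra_inter: bool = True
    use_bead_types: bool = True
    use_angular: bool = True
    drop_duplicated_bond_edges: bool = False


@dataclass
class AngularAssignment:
    """Sparse per-node angular values (degrees) with a presence mask.

    ``values``/``mask`` have one column per category in
    :data:`ANGULAR_CATEGORIES`; ``records`` keeps (node, category index,
    member bead tuple, value) so that cropping can drop any assignment whose
    member beads were removed.
    """

    values: np.ndarray  # (n_nodes, 4) degrees; 0 where absent
    mask: np.ndarray    # (n_nodes, 4) bool
    records: list[tuple[int, int, tuple[int, ...], float]]


@dataclass
class ComplexGraph:
    """A built multi-relational CG complex graph with assembled features."""

    beads: list[CGBead]
    coords: np.ndarray            # (n, 3) Angstrom
    edge_index: np.ndarray        # (2, E) int64, row 0 = source, row 1 = target
    edge_relation: np.ndarray     # (E,) int64 into RELATIONS
    node_features: np.ndarray     # (n, vocab + 8)
    edge_features: np.ndarray     # (E, 2*vocab + 19)
    part_labels: dict[str, int]   # chain id -> interaction part (1 or 2)
    version: MartiniVersion
    flags: AblationFlags = field(default_factory=AblationFlags)
    ss_codes: str = ""
    angular: AngularAssignment | None = None

    @property
    def num_nodes(self) -> int:
        return len(self.beads)

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]

    @property
    def edges(self) -> list[tuple[int, int, str]]:
        """Directed (source, target, relation) triples."""
        return [
            (int(s), int(t), RELATIONS[r])
            for s, t, r in zip(self.edge_index[0], self.edge_index[1],
                               self.edge_relation)
        ]

    def residues(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for b in self.beads:
            seen.setdefault((b.chain_id, b.residue_index), None)
        return list(seen)


# ---------------------------------------------------------------------------
# edge construction
# ---------------------------------------------------------------------------

def radius_edges(
    beads: list[CGBead],
    coords: np.ndarray | None = None,
    cutoff: float = RADIUS_CUTOFF,
    distinguish_intra_inter: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Wire directed contact edges for bead pairs strictly closer than ``cutoff``.

    Pairs within one residue are labelled ``d_intra``, across residues
    ``d_inter`` (or all ``d_inter`` when the distinction is ablated).  Every
    unordered pair yields two directed edges; self-edges never occur.
    Returns ``(edge_index (2,E), relation (E,))``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if coords is None:
        coords = np.asarray([b.coord for b in beads], dtype=np.float64)
    if len(beads) < 2:
        return np.zeros((2, 0), dtype=np.int64), np.zeros(0, dtype=np.int64)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict '<': ties at the cutoff excluded
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]  # canonical order
    src, dst, rel = [], [], []
    for i, j in pairs:
        bi, bj = beads[i], beads[j]
        same_residue = (bi.chain_id == bj.chain_id
                        and bi.residue_index == bj.residue_index)
        if distinguish_intra_inter:
            r = RELATION_INDEX["d_intra"] if same_residue else RELATION_INDEX["d_inter"]
        else:
            r = RELATION_INDEX["d_inter"]
        src += [i, j]
        dst += [j, i]
        rel += [r, r]
    return (np.asarray([src, dst], dtype=np.int64).reshape(2, -1),
            np.asarray(rel, dtype=np.int64))


def bond_edges(topology: CGTopology) -> tuple[np.ndarray, np.ndarray]:
    """Materialise each topology bond as a bidirectional typed edge pair."""
    src, dst, rel = [], [], []
    for t in topology.bonds():
        i, j = t.member_beads
        r = RELATION_INDEX[t.category]
        src += [i, j]
        dst += [j, i]
        rel += [r, r]
    return (np.asarray([src, dst], dtype=np.int64).reshape(2, -1),
            np.asarray(rel, dtype=np.int64))


# ---------------------------------------------------------------------------
# geometry re-calibration and angular feature assignment
# ---------------------------------------------------------------------------

def recalibrate_geometry(
    topology: CGTopology, coords: np.ndarray | None = None
) -> tuple[list[tuple[BondedTerm, float]], list[tuple[BondedTerm, float]]]:
    """Recompute bonded-term values from actual coordinates.

    The statistical reference values shipped in topology files are PDB-wide
    averages; features use the conformation-specific values instead.
    Returns ``(angular_values, bond_lengths)`` as (term, value) pairs with
    lengths in Angstrom and angles/torsions in degrees.
    """
    if coords is None:
        coords = topology.coords()
    angular: list[tuple[BondedTerm, float]] = []
    lengths: list[tuple[BondedTerm, float]] = []
    for t in topology.bonded_terms:
        m = t.member_beads
        try:
            if t.kind == "bond":
                lengths.append((t, float(np.linalg.norm(coords[m[0]] - coords[m[1]]))))
            elif t.kind == "angle":
                angular.append((t, interior_angle(coords[m[0]], coords[m[1]], coords[m[2]])))
            else:
                angular.append((t, torsion_angle(*[coords[i] for i in m])))
        except ValueError as exc:
            raise ValueError(
                f"degenerate geometry in {t.kind} {t.category} over beads {m}: {exc}"
            ) from exc
    return angular, lengths


def _host_node(term: BondedTerm) -> int:
    """The bead that hosts a re-calibrated angular value as a node feature.

    theta_BBB and psi_BBBB go to the second backbone bead of their tuple
    (the angle's centre / the dihedral's B_{i+1}); theta_BBS and theta_BSS
    go to the residue's first side-chain bead, which is the last and middle
    member respectively.
    """
    if term.category in ("theta_BBB", "psi_BBBB"):
        return term.member_beads[1]
    if term.category == "theta_BBS":
        return term.member_beads[2]
    return term.member_beads[1]  # theta_BSS -> S_{i,1}


def assign_angular_features(
    topology: CGTopology,
    angular_values: list[tuple[BondedTerm, float]],
) -> AngularAssignment:
    """Place sparse angular values on specific host beads without conflicts.

    Each node holds at most one value per category; if two terms of a
    category target the same bead, the term whose members include the lower
    minimum bead index wins and the conflict is logged.  Absent categories
    stay masked (their sine/cosine pair encodes to (0, 0), distinguishable
    from any real angle since sin^2 + cos^2 = 1).
    """
    n = len(topology.beads)
    values = np.zeros((n, len(ANGULAR_CATEGORIES)))
    mask = np.zeros((n, len(ANGULAR_CATEGORIES)), dtype=bool)
    winner_key: dict[tuple[int, int], int] = {}
    records: list[tuple[int, int, tuple[int, ...], float]] = []
    kept: dict[tuple[int, int], tuple[int, ...]] = {}

    for term, value in sorted(angular_values,
                              key=lambda tv: min(tv[0].member_beads)):
        node = _host_node(term)
        cat = _ANGULAR_INDEX[term.category]
        key = (node, cat)
        if key in winner_key:
            logger.warning(
                "angular conflict: %s over beads %s also targets bead %d; "
                "keeping the lower-index term", term.category,
                term.member_beads, node,
            )
            continue
        winner_key[key] = min(term.member_beads)
        values[node, cat] = value
        mask[node, cat] = True
        kept[key] = term.member_beads
        records.append((node, cat, term.member_beads, value))

    return AngularAssignment(values=values, mask=mask, records=records)


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

def node_feature_dim(version: MartiniVersion | str) -> int:
    return len(bead_type_vocabulary(version)) + 2 * len(ANGULAR_CATEGORIES)


def edge_feature_dim(version: MartiniVersion | str) -> int:
    return 2 * len(bead_type_vocabulary(version)) + NUM_RELATIONS + POSITIONAL_BINS + 1


def _type_onehots(beads: list[CGBead], version: MartiniVersion,
                  use_bead_types: bool) -> np.ndarray:
    vocab = bead_type_index(version)
    onehot = np.zeros((len(beads), len(vocab)))
    for i, b in enumerate(beads):
        if b.bead_type not in vocab:
            raise CGValidationError(
                f"bead type {b.bead_type!r} not in the {version.value} vocabulary"
            )
        onehot[i, 0 if not use_bead_types else vocab[b.bead_type]] = 1.0
    return onehot


def encode_node_features(
    beads: list[CGBead],
    angular: AngularAssignment,
    version: MartiniVersion | str,
    flags: AblationFlags = AblationFlags(),
) -> np.ndarray:
    """[one-hot bead type | sin,cos of the four angular categories]."""
    version = MartiniVersion(version)
    onehot = _type_onehots(beads, version, flags.use_bead_types)
    rad = np.radians(angular.values)
    sin = np.where(angular.mask, np.sin(rad), 0.0)
    cos = np.where(angular.mask, np.cos(rad), 0.0)
    trig = np.empty((len(beads), 2 * len(ANGULAR_CATEGORIES)))
    trig[:, 0::2] = sin
    trig[:, 1::2] = cos
    if not flags.use_angular:
        trig[:] = 0.0
    return np.concatenate([onehot, trig], axis=1)


def encode_edge_features(
    edge_index: np.ndarray,
    edge_relation: np.ndarray,
    beads: list[CGBead],
    coords: np.ndarray,
    version: MartiniVersion | str,
    flags: AblationFlags = AblationFlags(),
) -> np.ndarray:
    """[src one-hot | dst one-hot | relation one-hot | position-bin | length A].

    The positional component one-hot encodes the absolute bead-sequence
    index difference, clipped into 11 bins (0..9, >=10); the length is the
    re-calibrated endpoint distance for bond and contact edges alike.
    """
    version = MartiniVersion(version)
    onehot = _type_onehots(beads, version, flags.use_bead_types)
    src, dst = edge_index
    n_edges = src.shape[0]
    rel_oh = np.zeros((n_edges, NUM_RELATIONS))
    rel_oh[np.arange(n_edges), edge_relation] = 1.0
    diff = np.minimum(np.abs(src - dst), POSITIONAL_BINS - 1)
    pos_oh = np.zeros((n_edges, POSITIONAL_BINS))
    pos_oh[np.arange(n_edges), diff] = 1.0
    length = np.linalg.norm(coords[src] - coords[dst], axis=1)[:, None]
    return np.concatenate([onehot[src], onehot[dst], rel_oh, pos_oh, length], axis=1)


# ---------------------------------------------------------------------------
# full graph assembly
# ---------------------------------------------------------------------------

def build_graph(
    topology: CGTopology,
    part_labels: dict[str, int],
    flags: AblationFlags = AblationFlags(),
    cutoff: float = RADIUS_CUTOFF,
) -> ComplexGraph:
    """Assemble the multi-relational complex graph with all features.

    ``part_labels`` maps each chain id to interaction part 1 or 2 (used
    downstream by the cropper).  Ablation flags independently disable bond
    edges, the intra/inter distinction, bead-type one-hots, angular features
    or bond edges duplicated by a contact edge.
    """
    chains = {b.chain_id for b in topology.beads}
    missing = chains - set(part_labels)
    if missing:
        raise CGValidationError(f"part_labels missing chains: {sorted(missing)}")

    coords = topology.coords()
    r_idx, r_rel = radius_edges(
        topology.beads, coords, cutoff=cutoff,
        distinguish_intra_inter=flags.distinguish_intra_inter,
    )
    if flags.use_bond_edges:
        b_idx, b_rel = bond_edges(topology)
        if flags.drop_duplicated_bond_edges and r_idx.size and b_idx.size:
            contact_pairs = set(zip(r_idx[0].tolist(), r_idx[1].tolist()))
            keep = np.asarray([
                (int(s), int(t)) not in contact_pairs
                for s, t in zip(b_idx[0], b_idx[1])
            ], dtype=bool)
            b_idx, b_rel = b_idx[:, keep], b_rel[keep]
        edge_index = np.concatenate([r_idx, b_idx], axis=1)
        edge_relation = np.concatenate([r_rel, b_rel])
    else:
        edge_index, edge_relation = r_idx, r_rel

    angular_values, _ = recalibrate_geometry(topology, coords)
    angular = assign_angular_features(topology, angular_values)

    node_features = encode_node_features(topology.beads, angular,
                                         topology.version, flags)
    edge_features = encode_edge_features(edge_index, edge_relation,
                                         topology.beads, coords,
                                         topology.version, flags)
    return ComplexGraph(
        beads=list(topology.beads),
        coords=coords,
        edge_index=edge_index,
        edge_relation=edge_relation,
        node_features=node_features,
        edge_features=edge_features,
        part_labels=dict(part_labels),
        version=topology.version,
        flags=flags,
        ss_codes=topology.ss_codes,
        angular=angular,
    )


# ---------------------------------------------------------------------------
# serialization: NPZ arrays + JSON sidecar
# ---------------------------------------------------------------------------

def save_graph(graph: ComplexGraph, npz_path) -> None:
    """Write numeric arrays to ``.npz`` and metadata to a ``.json`` sidecar."""
    npz_path = str(npz_path)
    np.savez(
        npz_path,
        coords=graph.coords,
        edge_index=graph.edge_index,
        edge_relation=graph.edge_relation,
        node_features=graph.node_features,
        edge_features=graph.edge_features,
        angular_values=(graph.angular.values if graph.angular is not None
                        else np.zeros((graph.num_nodes, 4))),
        angular_mask=(graph.angular.mask if graph.angular is not None
                      else np.zeros((graph.num_nodes, 4), dtype=bool)),
    )
    meta = {
        "version": graph.version.value,
        "ss_codes": graph.ss_codes,
        "part_labels": graph.part_labels,
        "flags": asdict(graph.flags),
        "beads": [
            [b.bead_index, b.chain_id, b.residue_index, b.residue_name,
             b.bead_role, b.bead_type]
            for b in graph.beads
        ],
        "angular_records": (
            [[n, c, list(m), v] for n, c, m, v in graph.angular.records]
            if graph.angular is not None else []
        ),
    }
    with open(_sidecar(npz_path), "w") as fh:
        json.dump(meta, fh)


def load_graph(npz_path) -> ComplexGraph:
    npz_path = str(npz_path)
    data = np.load(npz_path)
    with open(_sidecar(npz_path)) as fh:
        meta = json.load(fh)
    beads = [
        CGBead(bead_index=bi, chain_id=ch, residue_index=ri, residue_name=rn,
               bead_role=role, bead_type=bt,
               coord=tuple(data["coords"][k]))
        for k, (bi, ch, ri, rn, role, bt) in enumerate(meta["beads"])
    ]
    angular = AngularAssignment(
        values=data["angular_values"],
        mask=data["angular_mask"],
        records=[(n, c, tuple(m), v) for n, c, m, v in meta["angular_records"]],
    )
    return ComplexGraph(
        beads=beads,
        coords=data["coords"],
        edge_index=data["edge_index"],
        edge_relation=data["edge_relation"],
        node_features=data["node_features"],
        edge_features=data["edge_features"],
        part_labels=dict(meta["part_labels"]),
        version=MartiniVersion(meta["version"]),
        flags=AblationFlags(**meta["flags"]),
        ss_codes=meta["ss_codes"],
        angular=angular,
    )


def _sidecar(npz_path: str) -> str:
    base = npz_path[:-4] if npz_path.endswith(".npz") else npz_path
    return base + ".json"


__all__ = [
    "RELATIONS", "RELATION_INDEX", "NUM_RELATIONS", "ANGULAR_CATEGORIES",
    "POSITIONAL_BINS", "RADIUS_CUTOFF",
    "AblationFlags", "AngularAssignment", "ComplexGraph",
    "radius_edges", "bond_edges", "recalibrate_geometry",
    "assign_angular_features", "encode_node_features", "encode_edge_features",
    "node_feature_dim", "edge_feature_dim",
    "build_graph", "save_graph", "load_graph",
]
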