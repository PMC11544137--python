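"""Dual-strategy interface cropping of CG complex graphs.

The complex is split into two interaction parts (chain sets).  A residue
distance matrix M^dis of shape (L_AA1, L_AA2) holds the backbone bead (B)
distances between the parts -- the CG analogue of using C-alpha positions.
Cropping retains:

* the **core** region: residues of either part participating in any
  cross-part pair with B-B distance strictly below ``core_cutoff``
  (default 8.5 A);
* the **adjacent** shell: any other residue (of either part, same or other
  chain) whose B-B distance to a core residue is strictly below
  ``adjacent_cutoff`` (default 10 A).

The cropped graph keeps exactly the beads of retained residues and the
edges among them; non-angular node features are unchanged, while any
angular assignment whose member beads were removed is zeroed on its host
node (its sine/cosine pair returns to the absent (0, 0) encoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import AngularAssignment, ComplexGraph

logger = logging.getLogger(__name__)

CORE_CUTOFF = 8.5
ADJACENT_CUTOFF = 10.0


@dataclass(frozen=True)
class CropSpec:
    """Chain partition and distance thresholds for interface cropping."""

    part1_chains: frozenset[str]
    part2_chains: frozenset[str]
    core_cutoff: float = CORE_CUTOFF
    adjacent_cutoff: float = ADJACENT_CUTOFF

    def __post_init__(self) -> None:
        object.__setattr__(self, "part1_chains", frozenset(self.part1_chains))
        object.__setattr__(self, "part2_chains", frozenset(self.part2_chains))
        if not self.part1_chains or not self.part2_chains:
            raise ValueError("both interaction parts must be non-empty")
        if self.part1_chains & self.part2_chains:
            raise ValueError("interaction parts must be disjoint chain sets")
        if self.core_cutoff <= 0 or self.adjacent_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class CropResult:
    """Outcome of cropping: retained residues, M^dis shape, cropped graph."""

    retained_residues: set[tuple[str, int]]
    core_residues: set[tuple[str, int]]
    dist_matrix_shape: tuple[int, int]
    graph: ComplexGraph


def _backbone_positions(
    graph: ComplexGraph, chains: frozenset[str]
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Residue keys and backbone bead coordinates of one part, in bead order."""
    keys: list[tuple[str, int]] = []
    rows: list[int] = []
    for i, b in enumerate(graph.beads):
        if b.chain_id in chains and b.bead_role == "B":
            keys.append((b.chain_id, b.residue_index))
            rows.append(i)
    return keys, graph.coords[rows]


def residue_distance_matrix(
    graph: ComplexGraph, spec: CropSpec
) -> tuple[np.ndarray, list[tuple[str, int]], list[tuple[str, int]]]:
    """Pairwise B-B distances between the two parts.

    Returns (M^dis of shape (L_AA1, L_AA2) in Angstrom, part-1 residue keys,
    part-2 residue keys).
    """
    present = {b.chain_id for b in graph.beads}
    for part in (spec.part1_chains, spec.part2_chains):
        missing = part - present
        if missing:
            raise ValueError(f"chains {sorted(missing)} not present in the graph")
    keys1, pos1 = _backbone_positions(graph, spec.part1_chains)
    keys2, pos2 = _backbone_positions(graph, spec.part2_chains)
    diff = pos1[:, None, :] - pos2[None, :, :]
    return np.linalg.norm(diff, axis=2), keys1, keys2


def crop(graph: ComplexGraph, spec: CropSpec) -> CropResult:
    """Reduce the graph to the interface core plus its adjacent shell."""
    mdis, keys1, keys2 = residue_distance_matrix(graph, spec)

    core: set[tuple[str, int]] = set()
    ii, jj = np.nonzero(mdis < spec.core_cutoff)
    for i, j in zip(ii, jj):
        core.add(keys1[i])
        core.add(keys2[j])

    if not core:
        logger.warning(
            "empty core: no cross-part residue pair below %.2f A; "
            "returning an empty cropped graph", spec.core_cutoff,
        )

    # adjacent shell: any non-core residue of either part within
    # adjacent_cutoff of any core residue
    all_keys = keys1 + keys2
    all_pos = np.concatenate([
        _backbone_positions(graph, spec.part1_chains)[1],
        _backbone_positions(graph, spec.part2_chains)[1],
    ])
    retained = set(core)
    if core:
        core_rows = [k for k, key in enumerate(all_keys) if key in core]
        core_pos = all_pos[core_rows]
        d_to_core = np.linalg.norm(
            all_pos[:, None, :] - core_pos[None, :, :], axis=2
        ).min(axis=1)
        for k, key in enumerate(all_keys):
            if key not in core and d_to_core[k] < spec.adjacent_cutoff:
                retained.add(key)

    sub = _subset_graph(graph, retained)
    return CropResult(
        retained_residues=retained,
        core_residues=core,
        dist_matrix_shape=mdis.shape,
        graph=sub,
    )


def _subset_graph(
    graph: ComplexGraph, retained: set[tuple[str, int]]
) -> ComplexGraph:
    """Keep beads of retained residues, edges among them, and re-zero any
    angular feature whose term lost a member bead."""
    keep = np.asarray([
        (b.chain_id, b.residue_index) in retained for b in graph.beads
    ], dtype=bool)
    old_to_new = -np.ones(len(graph.beads), dtype=np.int64)
    old_to_new[keep] = np.arange(int(keep.sum()))

    from dataclasses import replace as dc_replace
    beads = [
        dc_replace(b, bead_index=int(old_to_new[i]))
        for i, b in enumerate(graph.beads) if keep[i]
    ]
    coords = graph.coords[keep]
    node_features = graph.node_features[keep].copy()

    if graph.num_edges:
        e_keep = keep[graph.edge_index[0]] & keep[graph.edge_index[1]]
        edge_index = old_to_new[graph.edge_index[:, e_keep]]
        edge_relation = graph.edge_relation[e_keep]
        edge_features = graph.edge_features[e_keep]
    else:
        edge_index = np.zeros((2, 0), dtype=np.int64)
        edge_relation = np.zeros(0, dtype=np.int64)
        edge_features = np.zeros((0, graph.edge_features.shape[1]))

    n_new = len(beads)
    vocab_len = node_features.shape[1] - 8
    new_records: list[tuple[int, int, tuple[int, ...], float]] = []
    values = np.zeros((n_new, 4))
    mask = np.zeros((n_new, 4), dtype=bool)
    if graph.angular is not None:
        for node, cat, members, value in graph.angular.records:
            if not keep[node]:
                continue
            new_node = int(old_to_new[node])
            if all(keep[m] for m in members):
                new_members = tuple(int(old_to_new[m]) for m in members)
                new_records.append((new_node, cat, new_members, value))
                values[new_node, cat] = value
                mask[new_node, cat] = True
            else:
                # member bead removed by the crop: zero this angular pair
                node_features[new_node, vocab_len + 2 * cat] = 0.0
                node_features[new_node, vocab_len + 2 * cat + 1] = 0.0

    angular = AngularAssignment(values=values, mask=mask, records=new_records)

    ss_map = dict(zip(graph.residues(), graph.ss_codes)) if graph.ss_codes else {}
    residue_order = list(dict.fromkeys(
        (b.chain_id, b.residue_index) for b in beads
    ))
    ss_codes = "".join(ss_map.get(k, "C") for k in residue_order) if ss_map else ""

    return ComplexGraph(
        beads=beads,
        coords=coords,
        edge_index=edge_index,
        edge_relation=edge_relation,
        node_features=node_features,
        edge_features=edge_features,
        part_labels=dict(graph.part_labels),
        version=graph.version,
        flags=graph.flags,
        ss_codes=ss_codes,
        angular=angular,
    )


__all__ = [
    "CORE_CUTOFF", "ADJACENT_CUTOFF",
    "CropSpec", "CropResult",
    "residue_distance_matrix", "crop",
]
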