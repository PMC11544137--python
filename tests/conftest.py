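import numpy as np
import pytest

from cgppi.crop import crop
from cgppi.graph import build_graph
from cgppi.mapping import MartiniVersion
from cgppi.martini_io import CGBead, CGTopology, generate_bonded_terms
from cgppi.synthetic import SyntheticSpec, make_chain, make_dimer


def chain_topology(ss: str, sequence=None, seed=0,
                   version=MartiniVersion.MARTINI22) -> CGTopology:
    """A single synthetic chain with the given SS pattern."""
    seq = tuple(sequence) if sequence else ()
    spec = SyntheticSpec(n_residues=len(ss), ss_pattern=ss, sequence=seq,
                         version=version, seed=seed)
    return make_chain(spec)


@pytest.fixture
def coil_triple() -> CGTopology:
    """Three glycine residues in a coil (backbone beads only)."""
    return chain_topology("CCC", ["GLY"] * 3, seed=1)


@pytest.fixture
def helix_dimer():
    """Two 10-residue helical chains at a close interface, plus crop spec."""
    s1 = SyntheticSpec(n_residues=10, seed=3)
    s2 = SyntheticSpec(n_residues=10, seed=3)
    topo, spec = make_dimer(s1, s2, 7.0)
    graph = build_graph(topo, {"A": 1, "B": 2})
    return topo, graph, spec


@pytest.fixture
def small_graph(helix_dimer):
    return helix_dimer[1]


@pytest.fixture
def cropped_graph(helix_dimer):
    _, graph, spec = helix_dimer
    return crop(graph, spec).graph


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform_topology(topo: CGTopology, rotation: np.ndarray,
                             translation: np.ndarray) -> CGTopology:
    """Apply a rigid motion to every bead (bonded terms re-listed as-is)."""
    from dataclasses import replace
    beads = [
        replace(b, coord=tuple(rotation @ np.asarray(b.coord) + translation))
        for b in topo.beads
    ]
    return CGTopology(beads=beads, bonded_terms=topo.bonded_terms,
                      ss_codes=topo.ss_codes, version=topo.version)
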