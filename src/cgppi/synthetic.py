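"""Synthetic CG complexes with known geometric structure.

The generator emulates martinize-processed protein complexes at the level
the rest of the package consumes: backbone bead chains with ideal secondary
structure geometry (helix: 1.5 A rise and 100 degrees per residue; strand:
extended zig-zag; coil: perturbed linear), residue-type-dependent
side-chain beads at fixed canonical offsets, and two chains placed at a
controllable axis-to-axis interface distance.  A small seeded coordinate
jitter (default 0.15 A) makes realisations distinct across seeds without
altering the secondary-structure geometry.

Labelled datasets plant a known geometric rule: the regression label is an
affine function of the cross-part contact count (the number of directed
``d_inter`` edges joining the two interaction parts at the 5 A cutoff) plus
Gaussian noise of stated sigma; the classification label thresholds the
same count at a quantile chosen to hit the stated class balance.  All
generation parameters are recorded so recovery is checkable.

These fixtures are geometric stand-ins, not physical decoys: side-chain
placement is canonical rather than rotamer-sampled, and chains are ideal
rather than energy-minimised.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crop import CropSpec
from .graph import (AblationFlags, ComplexGraph, RELATION_INDEX, build_graph)
from .mapping import (MartiniVersion, STANDARD_RESIDUES, backbone_bead_type,
                      sidechain_bead_types)
from .martini_io import CGBead, CGTopology, generate_bonded_terms

HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A
STRAND_RISE = 3.4       # A per residue
COIL_SPACING = 3.5      # A per residue
SIDECHAIN_OFFSET = 3.0  # A between consecutive beads of a side chain
JITTER_SIGMA = 0.15     # A, seeded coordinate jitter

# Default interface-distance window for labelled datasets: axis separations
# spanning tight contact to barely-touching for two helices of radius 2.3 A
# with side chains, so cross-part contact counts sweep from dozens to near 0.
DISPLACEMENT_RANGE = (6.0, 14.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one chain: length, SS pattern, sequence, version, seed."""

    n_residues: int
    ss_pattern: str = ""          # H/E/C per residue; all-H when empty
    sequence: tuple[str, ...] = ()  # 3-letter codes; random when empty
    version: MartiniVersion = MartiniVersion.MARTINI22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        pattern = self.ss_pattern or "H" * self.n_residues
        if len(pattern) != self.n_residues:
            raise ValueError("ss pattern length must equal n_residues")
        if any(c not in "HEC" for c in pattern):
            raise ValueError("ss pattern must use the H/E/C alphabet")
        object.__setattr__(self, "ss_pattern", pattern)
        if self.sequence and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def _resolve_sequence(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, ...]:
    if spec.sequence:
        return spec.sequence
    return tuple(rng.choice(STANDARD_RESIDUES, size=spec.n_residues))


def _backbone_positions(ss: str, rng: np.random.Generator) -> np.ndarray:
    """Ideal backbone bead positions for one chain along the +z axis."""
    n = len(ss)
    pos = np.zeros((n, 3))
    z = 0.0
    for i, code in enumerate(ss):
        if code == "H":
            ang = np.radians(HELIX_TWIST * i)
            pos[i] = (HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), z)
            z += HELIX_RISE
        elif code == "E":
            pos[i] = (1.0 if i % 2 else -1.0, 0.0, z)
            z += STRAND_RISE
        else:  # coil: linear with a modest lateral wobble
            pos[i] = (0.6 * rng.standard_normal(), 0.6 * rng.standard_normal(), z)
            z += COIL_SPACING
    return pos


def _chain_beads(
    spec: SyntheticSpec,
    chain_id: str,
    rng: np.random.Generator,
    start_index: int = 0,
) -> tuple[list[CGBead], str, tuple[str, ...]]:
    """Beads of one chain (backbone + canonical side-chain offsets)."""
    sequence = _resolve_sequence(spec, rng)
    bb = _backbone_positions(spec.ss_pattern, rng)
    beads: list[CGBead] = []
    idx = start_index
    for i, (res_name, ss) in enumerate(zip(sequence, spec.ss_pattern)):
        coord = bb[i]
        beads.append(CGBead(
            bead_index=idx, chain_id=chain_id, residue_index=i + 1,
            residue_name=res_name, bead_role="B",
            bead_type=backbone_bead_type(res_name, ss, spec.version),
            coord=tuple(coord),
        ))
        idx += 1
        # side chains point radially away from the chain axis (+x fallback)
        radial = coord[:2]
        direction = np.array([1.0, 0.0, 0.0])
        if np.linalg.norm(radial) > 1e-9:
            direction = np.array([radial[0], radial[1], 0.0])
            direction /= np.linalg.norm(direction)
        for k, btype in enumerate(sidechain_bead_types(res_name, spec.version),
                                  start=1):
            sc = coord + direction * SIDECHAIN_OFFSET * k
            beads.append(CGBead(
                bead_index=idx, chain_id=chain_id, residue_index=i + 1,
                residue_name=res_name, bead_role=f"S{k}", bead_type=btype,
                coord=tuple(sc),
            ))
            idx += 1
    return beads, spec.ss_pattern, sequence


def _jitter(beads: list[CGBead], rng: np.random.Generator,
            sigma: float = JITTER_SIGMA) -> list[CGBead]:
    from dataclasses import replace
    noise = rng.normal(0.0, sigma, size=(len(beads), 3))
    return [replace(b, coord=tuple(np.asarray(b.coord) + noise[i]))
            for i, b in enumerate(beads)]


def make_chain(spec: SyntheticSpec, chain_id: str = "A") -> CGTopology:
    """A single-chain CG topology with ideal geometry and bonded terms."""
    rng = np.random.default_rng(spec.seed)
    beads, ss, _ = _chain_beads(spec, chain_id, rng)
    beads = _jitter(beads, rng)
    return CGTopology(beads=beads, bonded_terms=generate_bonded_terms(beads, ss),
                      ss_codes=ss, version=spec.version)


def make_dimer(
    spec1: SyntheticSpec,
    spec2: SyntheticSpec,
    displacement: float,
    jitter_sigma: float = JITTER_SIGMA,
) -> tuple[CGTopology, CropSpec]:
    """Two chains with chain 2 rigidly displaced along +x by ``displacement``.

    The cross-interface contact count is a monotonically non-increasing
    function of the displacement (up to the small coordinate jitter).
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if spec1.version != spec2.version:
        raise ValueError("both chains must use the same MARTINI version")
    rng = np.random.default_rng(spec1.seed)
    beads1, ss1, _ = _chain_beads(spec1, "A", rng)
    beads2, ss2, _ = _chain_beads(spec2, "B", rng, start_index=len(beads1))

    from dataclasses import replace
    shift = np.array([displacement, 0.0, 0.0])
    beads2 = [replace(b, coord=tuple(np.asarray(b.coord) + shift))
              for b in beads2]
    beads = _jitter(beads1 + beads2, rng, jitter_sigma)
    ss = ss1 + ss2
    topo = CGTopology(beads=beads, bonded_terms=generate_bonded_terms(beads, ss),
                      ss_codes=ss, version=spec1.version)
    return topo, CropSpec(part1_chains=frozenset({"A"}),
                          part2_chains=frozenset({"B"}))


def cross_part_contact_count(graph: ComplexGraph) -> int:
    """Directed ``d_inter`` edges whose endpoints lie in different parts."""
    if graph.num_edges == 0:
        return 0
    src, dst = graph.edge_index
    part = np.asarray([graph.part_labels[b.chain_id] for b in graph.beads])
    inter = graph.edge_relation == RELATION_INDEX["d_inter"]
    return int(np.sum(inter & (part[src] != part[dst])))


@dataclass
class SyntheticSample:
    """One generated labelled complex."""

    complex_id: str
    topology: CGTopology
    graph: ComplexGraph
    crop_spec: CropSpec
    label: float
    contact_count: int
    displacement: float


@dataclass
class SyntheticDataset:
    """Labelled samples plus the generation parameters that planted them."""

    samples: list[SyntheticSample]
    task: str
    params: dict


def make_labelled_dataset(
    n: int,
    task: str,
    seed: int,
    n_residues: int = 12,
    version: MartiniVersion = MartiniVersion.MARTINI22,
    sigma: float = 0.3,
    class_balance: float = 0.5,
    slope: float = -0.08,
    intercept: float = -4.0,
    displacement_range: tuple[float, float] = DISPLACEMENT_RANGE,
    flags: AblationFlags = AblationFlags(),
) -> SyntheticDataset:
    """Generate ``n`` labelled dimer complexes with a planted geometric rule.

    Regression labels mimic binding free energies (kcal/mol):
    ``label = slope * cross_contact_count + intercept + Normal(0, sigma)``.
    Classification labels are 1 when the contact count exceeds the
    ``1 - class_balance`` quantile of the realised counts.  The chain
    sequence and SS pattern are drawn once per dataset (all-helical), so
    cross-sample variation is driven by the interface distance and jitter.
    """
    if n < 2:
        raise ValueError("need at least two samples")
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    master = np.random.SeedSequence(seed)
    seq_rng = np.random.default_rng(master.spawn(1)[0])
    sequence = tuple(seq_rng.choice(STANDARD_RESIDUES, size=n_residues))
    disp_rng = np.random.default_rng(master.spawn(1)[0])
    label_rng = np.random.default_rng(master.spawn(1)[0])

    lo, hi = displacement_range
    displacements = disp_rng.uniform(lo, hi, size=n)
    chain_seeds = disp_rng.integers(0, 2**31 - 1, size=n)

    samples: list[SyntheticSample] = []
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        spec1 = SyntheticSpec(n_residues=n_residues, sequence=sequence,
                              version=version, seed=int(chain_seeds[i]))
        spec2 = SyntheticSpec(n_residues=n_residues, sequence=sequence,
                              version=version, seed=int(chain_seeds[i]))
        topo, crop_spec = make_dimer(spec1, spec2, float(displacements[i]))
        graph = build_graph(topo, {"A": 1, "B": 2}, flags=flags)
        counts[i] = cross_part_contact_count(graph)
        samples.append(SyntheticSample(
            complex_id=f"synth{i:04d}", topology=topo, graph=graph,
            crop_spec=crop_spec, label=np.nan, contact_count=int(counts[i]),
            displacement=float(displacements[i]),
        ))

    params: dict = {
        "task": task, "n": n, "seed": seed, "n_residues": n_residues,
        "version": version.value, "displacement_range": list(displacement_range),
        "sequence": list(sequence),
    }
    if task == "regression":
        noise = label_rng.normal(0.0, sigma, size=n)
        labels = slope * counts + intercept + noise
        params.update({"slope": slope, "intercept": intercept, "sigma": sigma})
    else:
        threshold = float(np.quantile(counts, 1.0 - class_balance))
        labels = (counts > threshold).astype(float)
        params.update({"threshold": threshold, "class_balance": class_balance})
    for s, y in zip(samples, labels):
        s.label = float(y)
    return SyntheticDataset(samples=samples, task=task, params=params)


# ---------------------------------------------------------------------------
# on-disk emission (CLI `synth` verb)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Emit CG-PDB + topology JSON per sample, labels CSV and crop manifest."""
    from .martini_io import write_cg_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.csv", "w", newline="") as lf, \
         open(out / "crop_manifest.csv", "w", newline="") as mf:
        labels = csv.writer(lf)
        manifest = csv.writer(mf)
        labels.writerow(["complex_id", "label"])
        manifest.writerow(["complex_id", "part1_chains", "part2_chains"])
        for s in dataset.samples:
            write_cg_structure(s.topology.beads, out / f"{s.complex_id}.pdb")
            (out / f"{s.complex_id}.topology.json").write_text(
                s.topology.to_json())
            labels.writerow([s.complex_id, f"{s.label:.6f}"])
            manifest.writerow([
                s.complex_id,
                ";".join(sorted(s.crop_spec.part1_chains)),
                ";".join(sorted(s.crop_spec.part2_chains)),
            ])
    (out / "generation_params.json").write_text(json.dumps(dataset.params))


__all__ = [
    "SyntheticSpec", "SyntheticSample", "SyntheticDataset",
    "make_chain", "make_dimer", "make_labelled_dataset",
    "cross_part_contact_count", "write_dataset",
    "HELIX_RISE", "HELIX_TWIST", "HELIX_RADIUS", "JITTER_SIGMA",
    "DISPLACEMENT_RANGE",
]
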