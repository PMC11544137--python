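# Methods

## Coarse-grained representation

`cgppi` represents a protein–protein complex at the MARTINI coarse-grained
(CG) scale: each residue contributes one backbone bead **B** (the CG
analogue of Cα, used as the residue position) and 0–5 side-chain beads
**S₁..Sₖ**, with k fixed per residue type and force-field version
(MARTINI 2.2 or MARTINI 3; e.g. alanine has no side-chain bead in 2.2 but
one in 3, tryptophan four vs. five). Structures are read from the CG-PDB
dialect written by the martinize tools and topologies from their ITP
dialect; all lengths are converted to Ångström at parse time so a single
unit governs the package (the interface thresholds below are stated in Å).

Secondary structure enters as an explicit per-residue H/E/C string rather
than an internal DSSP call; DSSP coil, turn and bend all collapse to C.
This removes an external binary from the workflow at the cost of requiring
the caller (or the synthetic generator) to supply the assignment.

Bonded terms follow the MARTINI protein model:

* five bond categories — `d_BB_CTS` (adjacent backbone, irregular SS),
  `d_BB_H` (adjacent backbone constraint inside helices, assigned only
  when *both* residues are H), `d_BB3_E` / `d_BB4_E` (long harmonic i,i+3
  and i,i+4 bonds in extended strands; generated when every residue of the
  span is E), and `d_S` (any bond touching a side-chain bead);
* three angle categories — θ_BBB (consecutive backbone triple),
  θ_BBS (B_{i+1}, B_i, S_{i,1}), θ_BSS (B_i, S_{i,1}, S_{i,2});
* one dihedral — ψ_BBBB over four consecutive backbone beads, imposed
  only when all four residues are helical.

Topology files ship PDB-statistics reference values for these terms; the
package never uses them as features. Every length, angle and torsion is
**re-calibrated** from the actual coordinates (interior angle at the middle
bead, IUPAC-signed torsion), so features describe the specific
conformation.

The built-in simplified mapper (`simple_martinize`) coarse-grains an
atomistic structure by placing the backbone bead at the unweighted centroid
of N/CA/C/O and splitting the side-chain heavy atoms, in file order, into k
contiguous centroid groups. It is an approximation of martinize (no
mass weighting, no rotamer-aware assignments, linear side-chain bond
topology rather than ring constraints for HIS/PHE/TYR/TRP) intended for
fixtures and examples; parsing real martinize output is the canonical path.

### Bead-type vocabularies

One-hot bead-type encodings use fixed ordered vocabularies of 17 tokens
(MARTINI 2.2) and 23 tokens (MARTINI 3), curated from the published protein
bead-type tables of the two force fields. The sizes are what the feature
dimensions require (17 + 8 = 25 and 23 + 8 = 31 node components); the exact
token membership is pinned in `cgppi.mapping` and may differ at the margin
from what a particular martinize release emits.

## The multi-relational complex graph

Nodes are beads. Seven directed edge relations:

* `d_intra` / `d_inter`: radius contacts for bead pairs strictly closer
  than 5.0 Å, split by whether the beads share a residue — the
  composition-aware contacts;
* the five bond categories above, injected from the topology. Bond and
  contact edges between the same pair co-exist by default (multigraph); an
  ablation flag collapses the duplicate bond edge.

Undirected relations are materialised as two directed edges; counts in the
tests are therefore stated as directed. Ties exactly at a cutoff are
excluded (strict `<` everywhere a threshold appears).

Node features (25 / 31): `[one-hot bead type | sin,cos θ_BBB | sin,cos
θ_BBS | sin,cos θ_BSS | sin,cos ψ_BBBB]`. Angular values are sparse; each
re-calibrated term is hosted on one bead (θ_BBB and ψ_BBBB on the second
backbone bead of their tuple, θ_BBS and θ_BSS on S_{i,1}). If two terms of
one category target the same bead, the term with the lower minimum member
index wins and the conflict is logged. Absent categories encode as
(0, 0) — distinguishable from any real angle because a present pair
satisfies sin² + cos² = 1.

Edge features (53 / 65): `[source one-hot | target one-hot | relation
one-hot (7) | clipped |Δ bead index| one-hot (11 bins: 0–9, ≥10) |
re-calibrated length in Å]`. The 11-bin clip point is forced by the
dimension arithmetic (53 − 2·17 − 7 − 1 = 11). The length column is raw
Ångström, not normalised.

All geometry enters through distances and angles, so every feature is
invariant under rigid motion of the input coordinates — a property the
tests assert bit-level.

Ablation flags reproduce the component-removal variants: no bond edges;
one undifferentiated radius relation; identical bead-type one-hots;
zeroed angular features; bond edges dropped where a contact duplicates
them.

## Interface cropping

Given a chain partition into two interaction parts, the residue distance
matrix **M**ᵈⁱˢ (L_AA1 × L_AA2) holds backbone–backbone distances across
parts. The **core** is every residue participating in a cross-part pair
with distance < 8.5 Å; the **adjacent shell** adds any other residue (of
either part, same or other chain) whose B–B distance to a core residue is
< 10 Å. The cropped graph keeps exactly the beads of retained residues and
the edges among them. Cropping is residue-granular, idempotent, monotone
in both cutoffs and symmetric in the two parts. Non-angular features of
retained beads are untouched; an angular assignment whose member bead was
removed is zeroed on its host node. An empty core produces an empty graph
plus a warning — the caller decides whether to skip or fall back to the
uncropped graph (the synthetic pipeline falls back).

## Encoder

A relational message-passing encoder in the GearNet-Edge family, adapted
to the seven CG relations. Per layer

    uᵢ = W_self hᵢ + Σ_r Σ_{(j→i)∈r} W_r hⱼ + W_z Σ_{e→i} z_e + b
    hᵢ ← hᵢ + ReLU(LayerNorm(uᵢ))

where z_e are edge hidden states initialised from the projected edge
features. With edge message passing enabled, a line graph over directed
edges updates z each layer: edges e=(i→j) and e′=(j→k), k≠i, are related
by the interior angle at j discretised into 8 bins, and the same
relation-typed aggregation runs over the line graph. The graph
representation is the sum (default) or mean readout of node states,
concatenated across layers, feeding a three-layer MLP head with halving
widths (regression: raw scalar in label units; classification: sigmoid
probability).

Two committed choices where the architecture family leaves room:

* **Layer normalisation** (per node, no running statistics) replaces batch
  normalisation. Sum-aggregated messages otherwise grow with node degree
  and layer count until training diverges; layer norm bounds the scale
  while keeping evaluation deterministic and independent of batch
  composition.
* Edge states enter the node update through one shared linear map W_z
  rather than per-relation maps — the relation identity is already carried
  by both the edge features and the W_r term.

Library defaults follow the family convention (6 layers, 512 hidden, sum
readout with per-layer concatenation); the synthetic benchmarks use a
documented desk-scale configuration (below). All parameters live in a flat
named dict; checkpoints are a `.npz` archive plus a JSON config. A global
seed (default 0) controls initialisation and data order; repeated runs are
bit-identical on one device.

The engine underneath is a small reverse-mode autodiff over numpy
(`cgppi.autodiff`) with a fused relation-typed message-passing primitive
(transform-then-gather with a sort/reduceat scatter). Gradients are
verified against central finite differences in the test suite.

## Denoising pre-training

Unlabelled CG graphs (domain–domain-interaction-style dimers in the
synthetic setting) are corrupted at a sampled diffusion step t ∈ {1..T}:

* coordinates: x_t = x₀ + σ(t)·ε with σ(t) = σ_max·√(1 − ᾱ(t)) under a
  cosine cumulative-variance schedule ᾱ (T = 100, σ_max = 1.5 Å by
  default); β_t increments stay in (0, 1) and increase monotonically;
* bead types: masked independently with probability (t/T)·ρ
  (ρ = `type_corruption_rate`, default 0.3); masking zeroes the one-hot
  block, a state distinct from every real type. t = 0 is the identity;
  t = T with ρ = 1 masks every bead.

Geometric edge features are refreshed from the noised coordinates. The
loss is a weighted sum of (a) mean-squared recovery of the *clean*
pairwise distances along the graph's edges, predicted by a two-layer head
on concatenated endpoint states — rigid-motion invariant by construction —
and (b) softmax cross-entropy of the original bead type at masked
positions only, so the type gradient at unmasked positions is exactly
zero. Checkpoints store encoder parameters in the format the fine-tuning
entry point consumes.

At desk scale, pre-trained initialisation does **not** accelerate
convergence on the planted synthetic tasks: the planted signal is simple
enough that training from scratch recovers it within a few epochs, leaving
no room for transfer (and a fresh task head must first adapt to the
pre-trained representation). The pre-training machinery is therefore
validated mechanistically — falling denoising loss, deterministic
checkpoints, end-to-end fine-tuning — rather than by a transfer-benefit
claim, which would require the large heterogeneous corpora the full-scale
workflow uses.

## Evaluation pipeline

Tenfold cross-validation with uniform fold sizes (differing by ≤ 1),
per-fold model re-initialisation from seed-derived streams, Adam with
fixed epoch budgets and no early stopping. Metrics: Pearson R_P, RMSE and
MAE for regression; AUROC and AUPR for classification; aggregated as the
mean over folds, with pooled-prediction metrics reported alongside.
Undefined cases (zero-variance predictions, single-class folds) are
flagged, not silently dropped. Regression labels are standardised on the
training fold and predictions mapped back before scoring. Every report
carries the fold assignment, seed and a SHA-256 hash of the full
configuration; a fixed seed reproduces the report bit-for-bit.

Full-scale defaults follow the reference protocol (Adam, lr 1e-4, 150
epochs regression / 30 classification, batch-size sweeps starting at 32).
The **desk-scale configuration** used by the synthetic benchmarks and the
acceptance run (`synthetic_benchmark_config`) is 2 layers, 32 hidden,
mean readout, lr 1e-3, 25 epochs (regression) / 15 (classification),
batch 32 — sized so a tenfold n = 200 run completes in minutes on one CPU
while recovering the planted signal.

## Synthetic study conditions

The generator emulates martinize-processed complexes: ideal helix backbone
geometry (1.5 Å rise, 100°/residue, 2.3 Å radius), extended zig-zag
strands (3.4 Å rise), perturbed-linear coils (3.5 Å spacing), side-chain
beads at canonical 3.0 Å radial offsets, and a 0.15 Å seeded coordinate
jitter that makes realisations distinct without disturbing the secondary
structure. A dimer places chain 2 at a controllable axis-to-axis
displacement; the cross-part contact count decreases monotonically with
displacement (up to jitter).

Labelled datasets draw one sequence and one displacement window
(6–14 Å, sweeping contact counts from ~90 to 0, including no-interface
complexes) per dataset. Regression labels are
`−0.08 × contacts − 4.0 + N(0, σ)` kcal/mol (σ = 0.3 by default, 0 in the
noiseless recovery runs), placing ΔG in a realistic −12…−4 kcal/mol band;
classification thresholds the contact count at the quantile matching the
requested class balance (default 0.5).

What these fixtures do *not* emulate: side-chain rotamer variability,
packing and electrostatics, sequence-driven interface composition, or
energy-minimised conformations. Passing the recovery checks therefore
shows that the representation preserves, and the encoder can read,
interface contact structure — not that the pipeline attains any particular
accuracy on experimentally determined complexes.

## Numerical choices and degenerate inputs

Strict `<` at all distance thresholds; ties excluded. Radius edges come
from a KD-tree with a canonical (sorted) pair order so edge ordering never
depends on coordinate frame; an O(n²) brute-force oracle backs the tests.
Coincident points make an interior angle undefined and raise, naming the
term. Dihedral sign follows the IUPAC convention (cis = 0); the sign only
affects the sine component. Single-bead graphs encode through the
self-term path; empty graphs are rejected by the encoder (the caller skips
or falls back on empty crops). The masked type state and the "no angle"
state are representable exactly (all-zero blocks), never approximated by
sentinel values.

## Known limitations

* The simplified mapper approximates martinize; workflows on real
  structures should parse martinize/martinize2 output.
* Bead-type vocabulary membership beyond the dimension-forced sizes is
  curated, not machine-extracted from a martinize run.
* Non-protein molecules, elastic networks and nonbonded (LJ/Coulomb)
  terms are out of scope; features use bead types and bonded geometry
  only.
* Pre-training shows no transfer benefit at desk scale (see above).
* Training is CPU-bound numpy; the desk-scale configuration is sized for
  hundreds of small graphs, not the thousands of full-size complexes of
  the large benchmark workflows.
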