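"""Build a multi-relational CG complex graph from a synthetic dimer.

Generates two 10-residue helical chains at a 7 A interface, builds the
graph and prints its anatomy: bead/edge counts, the relation census and
the feature dimensions.
"""

from collections import Counter

from cgppi.graph import RELATIONS, build_graph
from cgppi.synthetic import SyntheticSpec, make_dimer

spec = SyntheticSpec(n_residues=10, seed=0)
topology, crop_spec = make_dimer(spec, spec, displacement=7.0)
graph = build_graph(topology, {"A": 1, "B": 2})

print(f"beads (nodes):        {graph.num_nodes}")
print(f"directed edges:       {graph.num_edges}")
print(f"node feature length:  {graph.node_features.shape[1]}  (vocab 17 + 8 sin/cos)")
print(f"edge feature length:  {graph.edge_features.shape[1]}  (2x17 + 7 + 11 + 1)")
census = Counter(RELATIONS[r] for r in graph.edge_relation)
for relation in RELATIONS:
    print(f"  {relation:10s} {census.get(relation, 0):5d}")
print("Contact relations (d_intra/d_inter) dominate; the MARTINI bond "
      "relations encode secondary structure and side-chain connectivity.")
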