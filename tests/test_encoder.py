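"""Encoder contracts: invariances, determinism, gradient flow, capacity."""

import numpy as np
import pytest

from cgppi.autodiff import Adam, mse_loss
from cgppi.encoder import (
    CGGraphEncoder, EncoderConfig, collate, line_graph, load_checkpoint,
    prepare_graph, save_checkpoint,
)
from cgppi.graph import ComplexGraph, build_graph
from cgppi.synthetic import SyntheticSpec, make_dimer
from conftest import random_rotation, rigid_transform_topology

CFG = dict(node_feature_dim=25, edge_feature_dim=53, num_layers=2,
           hidden_dim=16)


def _dimer_graph(seed=3, displacement=7.0):
    s = SyntheticSpec(n_residues=8, seed=seed)
    topo, _ = make_dimer(s, s, displacement)
    return topo, build_graph(topo, {"A": 1, "B": 2})


def _permute_graph(graph: ComplexGraph, perm: np.ndarray) -> ComplexGraph:
    """Relabel nodes by a permutation (features follow their nodes)."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    from dataclasses import replace
    beads = [None] * len(graph.beads)
    for old, b in enumerate(graph.beads):
        beads[inv[old]] = replace(b, bead_index=int(inv[old]))
    return ComplexGraph(
        beads=beads,
        coords=graph.coords[perm],
        edge_index=inv[graph.edge_index],
        edge_relation=graph.edge_relation,
        node_features=graph.node_features[perm],
        edge_features=graph.edge_features,
        part_labels=graph.part_labels,
        version=graph.version,
        flags=graph.flags,
        ss_codes=graph.ss_codes,
        angular=graph.angular,
    )


def test_line_graph_relations_are_incident_angles():
    # three nodes on a right angle: 0-1-2, edges (0->1) and (1->2)
    coords = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
    edge_index = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
    li, lrel = line_graph(edge_index, coords, num_bins=8)
    pairs = set(zip(li[0].tolist(), li[1].tolist()))
    assert (0, 2) in pairs           # (0->1) feeds (1->2)
    assert (0, 1) not in pairs       # backtracking (1->0) excluded
    k = list(zip(li[0], li[1])).index((0, 2))
    assert lrel[k] == 4              # 90 degrees falls in bin [90, 112.5)


def test_node_permutation_leaves_graph_repr_invariant():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=0)
    out1 = model.forward(collate([prepare_graph(graph, cfg)]))
    rng = np.random.default_rng(0)
    perm = rng.permutation(graph.num_nodes)
    out2 = model.forward(collate([prepare_graph(_permute_graph(graph, perm),
                                                cfg)]))
    np.testing.assert_allclose(out2.graph_repr, out1.graph_repr, atol=1e-9)
    np.testing.assert_allclose(out2.prediction, out1.prediction, atol=1e-9)


def test_rigid_motion_leaves_prediction_invariant():
    topo, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=1)
    pred1 = model.predict_regression(graph)
    rng = np.random.default_rng(5)
    moved = rigid_transform_topology(topo, random_rotation(rng),
                                     rng.uniform(-20, 20, 3))
    graph2 = build_graph(moved, {"A": 1, "B": 2})
    pred2 = model.predict_regression(graph2)
    assert pred2 == pytest.approx(pred1, abs=1e-9)


def test_single_node_graph_runs_and_shapes_hold():
    from cgppi.martini_io import CGBead, CGTopology
    bead = CGBead(bead_index=0, chain_id="A", residue_index=1,
                  residue_name="GLY", bead_role="B", bead_type="P5",
                  coord=(0.0, 0.0, 0.0))
    topo = CGTopology(beads=[bead], bonded_terms=[], ss_codes="C",
                      version="martini22")
    graph = build_graph(topo, {"A": 1})
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=0)
    out = model.forward(collate([prepare_graph(graph, cfg)]))
    assert out.graph_repr.shape == (1, cfg.graph_repr_dim)
    assert np.all(np.isfinite(out.graph_repr))


def test_empty_graph_is_rejected():
    from cgppi.graph import AngularAssignment
    empty = ComplexGraph(
        beads=[], coords=np.zeros((0, 3)),
        edge_index=np.zeros((2, 0), dtype=np.int64),
        edge_relation=np.zeros(0, dtype=np.int64),
        node_features=np.zeros((0, 25)), edge_features=np.zeros((0, 53)),
        part_labels={}, version="martini22",
    )
    with pytest.raises(ValueError, match="empty"):
        prepare_graph(empty, EncoderConfig(**CFG))


def test_zero_initialised_final_layer_gives_zero_and_half():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=0)
    model.params["head3_w"].data[:] = 0.0
    model.params["head3_b"].data[:] = 0.0
    assert model.predict_regression(graph) == 0.0
    cfg_c = EncoderConfig(**{**CFG, "task": "classification"})
    clf = CGGraphEncoder(cfg_c, seed=0)
    clf.params["head3_w"].data[:] = 0.0
    clf.params["head3_b"].data[:] = 0.0
    assert clf.predict_interface_class(graph) == pytest.approx(0.5)


def test_classification_probability_bounds():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**{**CFG, "task": "classification"})
    for seed in range(3):
        p = CGGraphEncoder(cfg, seed=seed).predict_interface_class(graph)
        assert 0.0 <= p <= 1.0


def test_fixed_seed_fixed_graph_is_bit_reproducible():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    p1 = CGGraphEncoder(cfg, seed=7).predict_regression(graph)
    p2 = CGGraphEncoder(cfg, seed=7).predict_regression(graph)
    assert p1 == p2


def test_one_sample_mse_is_squared_error():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=0)
    batch = collate([prepare_graph(graph, cfg)])
    _, logit = model.forward_tensors(batch)
    loss = mse_loss(logit, np.array([2.5]))
    assert float(loss.data) == pytest.approx((float(logit.data[0]) - 2.5) ** 2)


def test_gradients_reach_line_graph_parameters():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=0)
    batch = collate([prepare_graph(graph, cfg)])
    _, logit = model.forward_tensors(batch)
    loss = mse_loss(logit, np.array([1.0]))
    loss.backward()
    line_grads = [model.params[k].grad for k in model.params
                  if "_line" in k or "_zself" in k]
    assert any(g is not None and np.any(g != 0) for g in line_grads)
    assert model.params["w_edge"].grad is not None
    assert np.any(model.params["w_edge"].grad != 0)


def test_readout_flags_change_repr_dim():
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**{**CFG, "layer_concat": False})
    model = CGGraphEncoder(cfg, seed=0)
    out = model.forward(collate([prepare_graph(graph, cfg)]))
    assert out.graph_repr.shape[1] == cfg.hidden_dim


def test_checkpoint_round_trip(tmp_path):
    _, graph = _dimer_graph()
    cfg = EncoderConfig(**CFG)
    model = CGGraphEncoder(cfg, seed=3)
    pred = model.predict_regression(graph)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    assert back.predict_regression(graph) == pytest.approx(pred, abs=1e-12)


def test_missing_checkpoint_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_checkpoint(tmp_path / "nope.npz")


def test_encoder_overfits_small_labelled_set():
    """Capacity check: training loss near zero on 32 graphs in 200 epochs."""
    rng = np.random.default_rng(0)
    graphs, labels = [], []
    for i in range(32):
        _, g = _dimer_graph(seed=i, displacement=float(rng.uniform(5, 12)))
        graphs.append(g)
        labels.append(float(rng.normal()))
    labels = np.asarray(labels)
    cfg = EncoderConfig(node_feature_dim=25, edge_feature_dim=53,
                        num_layers=2, hidden_dim=32,
                        edge_message_passing=False, readout="mean")
    prepared = [prepare_graph(g, cfg) for g in graphs]
    batch = collate(prepared)
    model = CGGraphEncoder(cfg, seed=0)
    opt = Adam(model.params, lr=3e-3)
    first = None
    for _ in range(200):
        _, logit = model.forward_tensors(batch)
        loss = mse_loss(logit, labels)
        first = first if first is not None else float(loss.data)
        opt.zero_grad()
        loss.backward()
        opt.step()
    final = float(loss.data)
    assert final < 0.05
    assert final < first / 20
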