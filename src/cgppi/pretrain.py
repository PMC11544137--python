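"""Diffusion-style noise/denoise self-supervised pre-training.

Domain-domain interaction (DDI) complexes provide abundant unlabelled CG
structures; the encoder is pre-trained to undo a two-channel corruption:

* **coordinates** receive Gaussian noise whose scale grows with the
  diffusion step t through a cosine cumulative-variance schedule,
  ``x_t = x_0 + sigma(t) * eps`` with ``sigma(t) = sigma_max *
  sqrt(1 - alpha_bar(t))``;
* **bead types** are masked with probability ``(t / T) *
  type_corruption_rate`` (their one-hot block zeroed -- the mask state,
  distinguishable from every real type).

The denoising objective is rigid-motion invariant: a distance head must
recover the clean pairwise distances along the corrupted graph's edges
(coordinate channel), and a type head must classify the original bead type
at masked positions only (masked-token cross-entropy).  After pre-training,
the encoder parameters initialise fine-tuning on labelled tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concat, cross_entropy, glorot
from .encoder import CGGraphEncoder, EncoderConfig, collate, prepare_graph, save_checkpoint
from .graph import ComplexGraph
from .mapping import bead_type_index

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionConfig", "CorruptedGraph", "DenoisingModel",
    "corrupt", "denoise_loss", "pretrain_loop",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """Noise schedule and loss weighting for the denoising objective."""

    num_steps: int = 100
    sigma_max: float = 1.5            # A, coordinate noise scale at t = T
    type_corruption_rate: float = 0.3  # masking probability at t = T
    coord_weight: float = 1.0
    type_weight: float = 1.0
    cosine_s: float = 0.008

    def __post_init__(self) -> None:
        if self.num_steps < 1:
            raise ValueError("num_steps must be >= 1")
        if not (0.0 <= self.type_corruption_rate <= 1.0):
            raise ValueError("type_corruption_rate must lie in [0, 1]")
        betas = self.betas()
        if np.any(betas <= 0) or np.any(betas >= 1):
            raise ValueError("noise schedule must keep 0 < beta_t < 1")

    def alpha_bar(self) -> np.ndarray:
        """Cosine cumulative signal level alpha_bar(t), t = 0..T."""
        t = np.arange(self.num_steps + 1) / self.num_steps
        f = np.cos((t + self.cosine_s) / (1 + self.cosine_s) * np.pi / 2) ** 2
        return f / f[0]

    def betas(self) -> np.ndarray:
        """Per-step variance increments beta_1..beta_T (monotone increasing)."""
        ab = self.alpha_bar()
        return np.clip(1.0 - ab[1:] / ab[:-1], 1e-8, 0.999)

    def sigma(self, t: int) -> float:
        """Cumulative coordinate noise scale at step t (0 at t = 0)."""
        if not (0 <= t <= self.num_steps):
            raise ValueError(f"step {t} outside [0, {self.num_steps}]")
        return float(self.sigma_max * np.sqrt(1.0 - self.alpha_bar()[t]))

    def mask_rate(self, t: int) -> float:
        return (t / self.num_steps) * self.type_corruption_rate


@dataclass
class CorruptedGraph:
    """A graph after step-t corruption, with recovery targets recorded."""

    graph: ComplexGraph           # noised coords, geometric features refreshed
    masked_nodes: np.ndarray      # indices whose bead type was masked
    type_targets: np.ndarray      # vocabulary index of every original bead type
    clean_edge_lengths: np.ndarray  # original distances along the edges (A)
    t: int


def corrupt(
    graph: ComplexGraph,
    t: int,
    rng: np.random.Generator,
    config: DiffusionConfig = DiffusionConfig(),
) -> CorruptedGraph:
    """Apply step-t coordinate noise and bead-type masking.

    t = 0 is the identity by convention.  Masked beads keep their angular
    features but lose the bead-type one-hot (zeroed, the mask state); the
    edge-length feature column is recomputed from the noised coordinates.
    """
    vocab = bead_type_index(graph.version)
    type_targets = np.asarray([vocab[b.bead_type] for b in graph.beads],
                              dtype=np.int64)
    src, dst = graph.edge_index
    clean_lengths = (np.linalg.norm(graph.coords[src] - graph.coords[dst], axis=1)
                     if graph.num_edges else np.zeros(0))

    if t == 0:
        return CorruptedGraph(graph=graph, masked_nodes=np.zeros(0, dtype=np.int64),
                              type_targets=type_targets,
                              clean_edge_lengths=clean_lengths, t=0)

    sigma = config.sigma(t)
    coords = graph.coords + rng.normal(0.0, sigma, size=graph.coords.shape)

    rate = config.mask_rate(t)
    masked = np.nonzero(rng.random(graph.num_nodes) < rate)[0]

    vocab_len = len(vocab)
    node_features = graph.node_features.copy()
    node_features[masked, :vocab_len] = 0.0

    edge_features = graph.edge_features.copy()
    if graph.num_edges:
        edge_features[:, -1] = np.linalg.norm(coords[src] - coords[dst], axis=1)

    noised = ComplexGraph(
        beads=graph.beads,
        coords=coords,
        edge_index=graph.edge_index,
        edge_relation=graph.edge_relation,
        node_features=node_features,
        edge_features=edge_features,
        part_labels=graph.part_labels,
        version=graph.version,
        flags=graph.flags,
        ss_codes=graph.ss_codes,
        angular=graph.angular,
    )
    return CorruptedGraph(graph=noised, masked_nodes=masked,
                          type_targets=type_targets,
                          clean_edge_lengths=clean_lengths, t=t)


class DenoisingModel:
    """Encoder plus the two reconstruction heads used during pre-training."""

    def __init__(self, config: EncoderConfig, vocab_size: int, seed: int = 0):
        self.encoder = CGGraphEncoder(config, seed=seed)
        rng = np.random.default_rng(seed + 1)
        d = config.graph_repr_dim
        h = config.hidden_dim
        self.heads: dict[str, Parameter] = {
            "type_w": glorot(rng, d, vocab_size),
            "type_b": Parameter(np.zeros(vocab_size)),
            "dist_w1": glorot(rng, 2 * d, h),
            "dist_b1": Parameter(np.zeros(h)),
            "dist_w2": glorot(rng, h, 1),
            "dist_b2": Parameter(np.zeros(1)),
        }

    @property
    def params(self) -> dict[str, Parameter]:
        merged = dict(self.encoder.params)
        merged.update({f"pt::{k}": v for k, v in self.heads.items()})
        return merged


def denoise_loss(
    model: DenoisingModel,
    corrupted: CorruptedGraph,
    config: DiffusionConfig = DiffusionConfig(),
) -> Tensor:
    """Weighted sum of distance-recovery MSE and masked-type cross-entropy.

    The type term is computed on masked positions only, so its gradient
    with respect to logits at unmasked positions is exactly zero; the
    coordinate term targets clean pairwise distances and is therefore
    invariant to rigid motion of the original structure.
    """
    enc_cfg = model.encoder.config
    batch = collate([prepare_graph(corrupted.graph, enc_cfg)])
    node_states, _ = model.encoder.encode(batch)
    p = model.heads

    loss = Tensor(np.zeros(1))
    if batch.num_edges:
        src, dst = batch.edge_index
        pair = concat([node_states.take_rows(src), node_states.take_rows(dst)],
                      axis=1)
        hidden = (pair @ p["dist_w1"] + p["dist_b1"]).relu()
        d_hat = (hidden @ p["dist_w2"] + p["dist_b2"]).reshape(-1)
        diff = d_hat - Tensor(corrupted.clean_edge_lengths)
        loss = loss + config.coord_weight * (diff * diff).mean()

    if corrupted.masked_nodes.size:
        logits = node_states.take_rows(corrupted.masked_nodes) @ p["type_w"] \
            + p["type_b"]
        targets = corrupted.type_targets[corrupted.masked_nodes]
        loss = loss + config.type_weight * cross_entropy(logits, targets)

    return loss.sum()


@dataclass(frozen=True)
class PretrainConfig:
    """Loop settings for denoising pre-training."""

    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    epochs: int = 50
    lr: float = 1e-4
    seed: int = 0


def pretrain_loop(
    graphs: list[ComplexGraph],
    encoder_config: EncoderConfig,
    config: PretrainConfig = PretrainConfig(),
    checkpoint_path=None,
) -> tuple[DenoisingModel, list[float]]:
    """Pre-train on unlabelled CG graphs; returns (model, per-epoch losses).

    Each epoch visits every graph once with a freshly sampled diffusion
    step t ~ Uniform{1..T}.  Aborts with diagnostics if the loss diverges.
    The checkpoint (when a path is given) stores encoder parameters in the
    format the fine-tuning entry point consumes.
    """
    if not graphs:
        raise ValueError("pre-training needs at least one graph")
    vocab_size = len(bead_type_index(graphs[0].version))
    model = DenoisingModel(encoder_config, vocab_size, seed=config.seed)
    opt = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed)

    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(graphs))
        epoch_loss = 0.0
        for i in order:
            t = int(rng.integers(1, config.diffusion.num_steps + 1))
            corrupted = corrupt(graphs[i], t, rng, config.diffusion)
            loss = denoise_loss(model, corrupted, config.diffusion)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent pre-training loss at epoch {epoch}, graph {i}, "
                    f"t={t}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        history.append(epoch_loss / len(graphs))

    if checkpoint_path is not None:
        save_checkpoint(model.encoder, checkpoint_path,
                        extra_params={k: v.data for k, v in model.heads.items()})
    return model, history
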