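"""Self-supervised subgraph-contrastive pre-training.

The pretext task needs no annotation: for an anchor node v, a positive m is
drawn from its neighbours (pairs sharing an entity) and a negative n from
its non-neighbours, and the encoder is trained so that the subgraph
representation of v is closer (in cosine) to that of m than to that of n
under a temperature-scaled two-candidate softmax:

    L = -ln exp(sim(s_v, s_m)/tau) / (exp(sim(s_v,s_m)/tau) + exp(sim(s_v,s_n)/tau))

Three negative-sampling rules are available: ``random`` (uniform over
non-neighbours), ``community`` (non-neighbours outside the anchor's Louvain
community, which lowers the false-negative rate) and ``degree``
(degree-stratified, favouring low-degree nodes outside the anchor's degree
tier). Node labels are never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, concat, cosine_rows, spmm
from .encoder import (
    EncoderParams,
    _EncoderTensors,
    encode_tensors,
    init_encoder_params,
    readout_matrix,
)
from .graph_construction import HeteroPairGraph

__all__ = [
    "Triplet",
    "PretrainConfig",
    "sample_triplets",
    "contrastive_loss",
    "pretrain_encoder",
]

NEGATIVE_STRATEGIES = ("random", "community", "degree")


class Triplet(NamedTuple):
    anchor: int
    positive: int
    negative: int


@dataclass
class PretrainConfig:
    """Hyper-parameters of the contrastive pre-training stage."""

    strategy: str = "random"
    tau: float = 1.0
    epochs: int = 200
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    delta: int = 1
    seed: int = 0
    triplets_per_epoch: Optional[int] = None  # None -> one per eligible anchor
    input_dim: int = 32
    hidden_dim: int = 16
    num_layers: int = 3
    center_once: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if self.strategy not in NEGATIVE_STRATEGIES:
            raise ValueError(f"unknown negative-sampling strategy {self.strategy!r}")


class TripletSampler:
    """Negative-sampling machinery shared across epochs.

    Community assignments (Louvain modularity partition) and degree tiers
    (tertiles of the degree distribution, sampling weight 1/(1+degree)) are
    computed once per graph.
    """

    def __init__(self, graph: HeteroPairGraph, strategy: str, seed: int = 0):
        if strategy not in NEGATIVE_STRATEGIES:
            raise ValueError(f"unknown negative-sampling strategy {strategy!r}")
        self.strategy = strategy
        self.n = graph.n_nodes
        # sorted for determinism regardless of set construction history
        self.neighbors = [
            np.array(sorted(graph.adjacency.get(v, ())), dtype=np.intp)
            for v in range(self.n)
        ]
        self.degrees = graph.degrees()
        self.anchors = np.flatnonzero(self.degrees > 0)
        if len(self.anchors) == 0:
            raise ValueError("graph has no edges; nothing to contrast")

        self.community = None
        if strategy == "community":
            g = nx.Graph()
            g.add_nodes_from(range(self.n))
            g.add_edges_from(graph.edges)
            parts = nx.algorithms.community.louvain_communities(g, seed=seed)
            self.community = np.zeros(self.n, dtype=np.intp)
            for c, members in enumerate(parts):
                for v in members:
                    self.community[v] = c

        self.tier = None
        self.neg_weight = None
        if strategy == "degree":
            lo, hi = np.quantile(self.degrees, [1 / 3, 2 / 3])
            self.tier = np.digitize(self.degrees, [lo, hi])
            self.neg_weight = 1.0 / (1.0 + self.degrees.astype(float))

    def _candidates(self, v: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[v] = False
        mask[self.neighbors[v]] = False
        if self.strategy == "community":
            mask &= self.community != self.community[v]
        elif self.strategy == "degree":
            tier_mask = mask & (self.tier != self.tier[v])
            if tier_mask.any():
                mask = tier_mask
        return np.flatnonzero(mask)

    def sample(self, count: int, rng: np.random.Generator) -> list[Triplet]:
        if count < 1:
            raise ValueError("count must be >= 1")
        if np.all(self.degrees >= self.n - 1):
            raise ValueError("graph is fully connected; no negatives exist")
        triplets: list[Triplet] = []
        order = self.anchors.copy()
        skipped = 0
        while len(triplets) < count:
            rng.shuffle(order)
            for v in order:
                if len(triplets) >= count:
                    break
                cand = self._candidates(v)
                if len(cand) == 0:
                    skipped += 1
                    continue
                m = int(rng.choice(self.neighbors[v]))
                if self.strategy == "degree":
                    w = self.neg_weight[cand]
                    neg = int(rng.choice(cand, p=w / w.sum()))
                else:
                    neg = int(rng.choice(cand))
                triplets.append(Triplet(int(v), m, neg))
            if not triplets:
                raise ValueError(
                    f"no anchor admits a negative under strategy {self.strategy!r}"
                )
        if skipped:
            warnings.warn(
                f"{skipped} anchor draws had no eligible negative and were skipped",
                stacklevel=2,
            )
        return triplets


def sample_triplets(
    graph: HeteroPairGraph,
    config: PretrainConfig,
    count: int,
    seed: Optional[int] = None,
) -> list[Triplet]:
    """Draw ``count`` contrastive triplets under the configured strategy."""
    sampler = TripletSampler(graph, config.strategy, seed=config.seed)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return sampler.sample(count, rng)


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return np.sum(a * b, axis=-1) / (na * nb)


def contrastive_loss(s_v, s_m, s_n, tau: float = 1.0) -> float:
    """Two-candidate softmax cross-entropy of the anchor against (m, n).

    Accepts single vectors or batches of rows; batches return the mean.
    """
    s_v, s_m, s_n = (np.atleast_2d(np.asarray(x, float)) for x in (s_v, s_m, s_n))
    sim_m = _cosine(s_v, s_m)
    sim_n = _cosine(s_v, s_n)
    losses = np.logaddexp(0.0, (sim_n - sim_m) / tau)
    return float(losses.mean())


def pretrain_encoder(
    graph: HeteroPairGraph,
    config: PretrainConfig,
    params: Optional[EncoderParams] = None,
) -> tuple[EncoderParams, pd.DataFrame]:
    """Minimise the mean contrastive loss over sampled triplets.

    Returns the trained parameters and a per-epoch training log with columns
    (epoch, mean_loss, margin), margin being mean sim(v,m) - sim(v,n).
    """
    if params is None:
        params = init_encoder_params(
            graph, config.input_dim, config.hidden_dim, config.num_layers,
            seed=config.seed,
        )
    params = params.copy()
    log_rows: list[dict] = []
    if config.epochs == 0:
        return params, pd.DataFrame(log_rows, columns=["epoch", "mean_loss", "margin"])

    sampler = TripletSampler(graph, config.strategy, seed=config.seed)
    count = config.triplets_per_epoch or len(sampler.anchors)
    adjacency = graph.adjacency_matrix()
    S = readout_matrix(graph, config.delta, config.center_once)
    tensors = _EncoderTensors(params, trainable=True)
    opt = Adam(
        tensors.all(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(config.seed)

    for epoch in range(config.epochs):
        triplets = sampler.sample(count, rng)
        idx = np.array(triplets, dtype=np.intp)
        layers = encode_tensors(adjacency, tensors)
        H = concat(layers, axis=1)
        reps = spmm(S, H)
        s_v = reps.take(idx[:, 0])
        s_m = reps.take(idx[:, 1])
        s_n = reps.take(idx[:, 2])
        sim_m = cosine_rows(s_v, s_m)
        sim_n = cosine_rows(s_v, s_n)
        loss = (((sim_n - sim_m) * (1.0 / config.tau)).softplus()).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"pre-training diverged at epoch {epoch}: loss={loss.data!r}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        log_rows.append(
            {
                "epoch": epoch,
                "mean_loss": float(loss.data),
                "margin": float((sim_m.data - sim_n.data).mean()),
            }
        )

    tensors.write_back()
    return params, pd.DataFrame(log_rows)
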