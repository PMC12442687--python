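"""GIN encoder over the entity-pair graph.

The encoder is a stack of graph-isomorphism-network layers

    h_v^k = MLP_k( (1 + eps_k) * h_v^{k-1} + sum_{u in N(v)} h_u^{k-1} )

applied to learnable per-node input features (there are no measured node
attributes on entity pairs, so the initial feature table is itself part of
the trainable parameters, as is a linear projection from the input width to
the hidden width). Downstream stages consume the concatenation of all K
layer outputs, so a node representation has width hidden_dim * K.

A delta-subgraph of a node is the set of nodes within graph distance delta
of it, with induced edges. Subgraph representations are produced by a
readout over member representations; three strategies are provided:

* ``sum``  — the centre representation plus the sum over members. Because
  the centre is itself a member, it contributes twice; this literal form is
  kept (``center_once=True`` switches to single counting for sensitivity
  checks).
* ``linear_mean`` — the same multiset averaged instead of summed, followed
  by a square linear map W.
* ``feature_weighted_sum`` — the ``sum`` readout followed by W.
"""

from __future__ import annotations

import hashlib
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, spmm
from .graph_construction import HeteroPairGraph

__all__ = [
    "EncoderParams",
    "Subgraph",
    "init_features",
    "init_encoder_params",
    "gin_layer",
    "encode",
    "extract_subgraph",
    "readout",
    "readout_matrix",
    "base_readouts",
]

READOUT_STRATEGIES = ("sum", "linear_mean", "feature_weighted_sum")


@dataclass
class EncoderParams:
    """All learnable state of the encoder (GIN parameters Theta)."""

    num_layers: int
    input_dim: int
    hidden_dim: int
    features: np.ndarray                 # (n_nodes, input_dim), learnable
    proj_w: np.ndarray                   # (input_dim, hidden_dim)
    proj_b: np.ndarray                   # (hidden_dim,)
    mlp_w1: list[np.ndarray] = field(default_factory=list)
    mlp_b1: list[np.ndarray] = field(default_factory=list)
    mlp_w2: list[np.ndarray] = field(default_factory=list)
    mlp_b2: list[np.ndarray] = field(default_factory=list)
    eps: np.ndarray = None               # (num_layers,)

    @property
    def rep_dim(self) -> int:
        return self.hidden_dim * self.num_layers

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            self.num_layers, self.input_dim, self.hidden_dim,
            self.features.copy(), self.proj_w.copy(), self.proj_b.copy(),
            [w.copy() for w in self.mlp_w1], [b.copy() for b in self.mlp_b1],
            [w.copy() for w in self.mlp_w2], [b.copy() for b in self.mlp_b2],
            self.eps.copy(),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        out = {"features": self.features, "proj_w": self.proj_w,
               "proj_b": self.proj_b, "eps": self.eps}
        for k in range(self.num_layers):
            out[f"mlp_w1_{k}"] = self.mlp_w1[k]
            out[f"mlp_b1_{k}"] = self.mlp_b1[k]
            out[f"mlp_w2_{k}"] = self.mlp_w2[k]
            out[f"mlp_b2_{k}"] = self.mlp_b2[k]
        return out

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.arrays()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.arrays()[name]).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "format": "pairprompt-encoder-v1",
            "num_layers": self.num_layers,
            "input_dim": self.input_dim,
            "hidden_dim": self.hidden_dim,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.arrays())

    @classmethod
    def load(cls, path: str | Path) -> "EncoderParams":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta.get("format") != "pairprompt-encoder-v1":
                raise ValueError("unrecognized checkpoint format")
            K = int(meta["num_layers"])
            return cls(
                K, int(meta["input_dim"]), int(meta["hidden_dim"]),
                data["features"], data["proj_w"], data["proj_b"],
                [data[f"mlp_w1_{k}"] for k in range(K)],
                [data[f"mlp_b1_{k}"] for k in range(K)],
                [data[f"mlp_w2_{k}"] for k in range(K)],
                [data[f"mlp_b2_{k}"] for k in range(K)],
                data["eps"],
            )


def init_features(graph: HeteroPairGraph, input_dim: int, seed: int = 0) -> np.ndarray:
    """Seeded standard-Gaussian feature table, one row per node."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((graph.n_nodes, input_dim))


def _glorot(rng, fan_in, fan_out):
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_encoder_params(
    graph: HeteroPairGraph,
    input_dim: int = 32,
    hidden_dim: int = 16,
    num_layers: int = 3,
    seed: int = 0,
) -> EncoderParams:
    """Glorot-initialised GIN stack with learnable eps (initialised to 0)."""
    rng = np.random.default_rng(seed)
    features = init_features(graph, input_dim, seed=int(rng.integers(2**31 - 1)))
    params = EncoderParams(
        num_layers=num_layers,
        input_dim=input_dim,
        hidden_dim=hidden_dim,
        features=features,
        proj_w=_glorot(rng, input_dim, hidden_dim),
        proj_b=np.zeros(hidden_dim),
        eps=np.zeros(num_layers),
    )
    for _ in range(num_layers):
        params.mlp_w1.append(_glorot(rng, hidden_dim, hidden_dim))
        params.mlp_b1.append(np.zeros(hidden_dim))
        params.mlp_w2.append(_glorot(rng, hidden_dim, hidden_dim))
        params.mlp_b2.append(np.zeros(hidden_dim))
    return params


def gin_layer(
    h_prev: np.ndarray,
    adjacency: sp.spmatrix | np.ndarray,
    eps: float = 0.0,
    mlp: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """One GIN aggregation step for all nodes simultaneously.

    ``mlp`` is any callable applied row-wise after aggregation; ``None``
    means the identity. Isolated nodes receive mlp((1 + eps) * h_v).
    """
    h_prev = np.asarray(h_prev, dtype=float)
    if not np.all(np.isfinite(h_prev)):
        raise FloatingPointError("non-finite encoder input")
    agg = (1.0 + eps) * h_prev + adjacency @ h_prev
    return agg if mlp is None else mlp(agg)


class _EncoderTensors:
    """Autodiff view of EncoderParams sharing the underlying arrays."""

    def __init__(self, params: EncoderParams, trainable: bool = True):
        self.params = params
        t = trainable
        self.features = Tensor(params.features, requires_grad=t)
        self.proj_w = Tensor(params.proj_w, requires_grad=t)
        self.proj_b = Tensor(params.proj_b, requires_grad=t)
        self.eps = [Tensor(np.array([e]), requires_grad=t) for e in params.eps]
        self.mlp = [
            tuple(
                Tensor(arr, requires_grad=t)
                for arr in (params.mlp_w1[k], params.mlp_b1[k],
                            params.mlp_w2[k], params.mlp_b2[k])
            )
            for k in range(params.num_layers)
        ]

    def all(self) -> list[Tensor]:
        out = [self.features, self.proj_w, self.proj_b, *self.eps]
        for layer in self.mlp:
            out.extend(layer)
        return out

    def write_back(self) -> None:
        p = self.params
        p.features = self.features.data
        p.proj_w = self.proj_w.data
        p.proj_b = self.proj_b.data
        p.eps = np.array([e.data[0] for e in self.eps])
        for k, (w1, b1, w2, b2) in enumerate(self.mlp):
            p.mlp_w1[k], p.mlp_b1[k] = w1.data, b1.data
            p.mlp_w2[k], p.mlp_b2[k] = w2.data, b2.data


def encode_tensors(
    adjacency: sp.spmatrix, tensors: _EncoderTensors
) -> list[Tensor]:
    """Forward pass returning per-layer states [h^1 .. h^K] as tensors."""
    h = tensors.features @ tensors.proj_w + tensors.proj_b
    layers = []
    for k in range(tensors.params.num_layers):
        w1, b1, w2, b2 = tensors.mlp[k]
        agg = h * (tensors.eps[k] + 1.0) + spmm(adjacency, h)
        h = (agg @ w1 + b1).relu() @ w2 + b2
        layers.append(h)
    return layers


def encode(graph: HeteroPairGraph, params: EncoderParams) -> list[np.ndarray]:
    """Per-layer node representations [h^1 .. h^K] (numpy, inference)."""
    if params.features.shape[0] != graph.n_nodes:
        raise ValueError("feature table does not match graph size")
    adjacency = graph.adjacency_matrix()
    tensors = _EncoderTensors(params, trainable=False)
    return [t.data for t in encode_tensors(adjacency, tensors)]


def concat_states(states: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate layer states into (n, hidden_dim * K)."""
    return np.concatenate(list(states), axis=1)


@dataclass(frozen=True)
class Subgraph:
    center: int
    radius: int
    members: frozenset[int]
    induced_edges: frozenset[tuple[int, int]]


def _bfs_members(graph: HeteroPairGraph, v: int, delta: int) -> set[int]:
    members = {v}
    frontier = deque([(v, 0)])
    while frontier:
        u, d = frontier.popleft()
        if d == delta:
            continue
        for w in graph.adjacency[u]:
            if w not in members:
                members.add(w)
                frontier.append((w, d + 1))
    return members


def extract_subgraph(graph: HeteroPairGraph, v: int, delta: int) -> Subgraph:
    """Nodes within graph distance ``delta`` of ``v`` plus induced edges."""
    if v not in graph.adjacency:
        raise KeyError(f"node {v} not in graph")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    members = _bfs_members(graph, v, delta)
    induced = {
        (u, w) if u < w else (w, u)
        for u in members
        for w in graph.adjacency[u]
        if w in members
    }
    return Subgraph(v, delta, frozenset(members), frozenset(induced))


def readout(
    sub: Subgraph,
    node_reps: np.ndarray,
    strategy: str = "sum",
    weight: Optional[np.ndarray] = None,
    center_once: bool = False,
) -> np.ndarray:
    """Aggregate member representations of one subgraph into a vector.

    ``node_reps`` is the (n, D) matrix of concatenated layer states. The
    ``sum`` strategy adds the centre representation to the sum over all
    members (the centre therefore counts twice unless ``center_once``).
    """
    if strategy not in READOUT_STRATEGIES:
        raise ValueError(f"unknown readout strategy {strategy!r}")
    members = sorted(sub.members)
    total = node_reps[members].sum(axis=0)
    count = len(members)
    if not center_once:
        total = total + node_reps[sub.center]
        count += 1
    if strategy == "sum":
        return total
    if weight is None:
        raise ValueError(f"strategy {strategy!r} requires a weight matrix")
    if strategy == "linear_mean":
        return (total / count) @ weight
    return total @ weight  # feature_weighted_sum


def readout_matrix(
    graph: HeteroPairGraph, delta: int = 1, center_once: bool = False
) -> sp.csr_matrix:
    """Sparse S with S @ H equal to the ``sum`` readout of every node.

    Row v holds coefficient 1 for each member of the delta-subgraph of v,
    plus an extra 1 on the centre (2 total) unless ``center_once``.
    """
    rows, cols, vals = [], [], []
    for v in range(graph.n_nodes):
        members = _bfs_members(graph, v, delta)
        for u in members:
            rows.append(v)
            cols.append(u)
            vals.append(2.0 if (u == v and not center_once) else 1.0)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(graph.n_nodes, graph.n_nodes)
    )


@dataclass
class BaseReadouts:
    """Frozen-encoder readouts reused across prompt tuning and evaluation."""

    rep: np.ndarray          # (n, D) sum readout per node
    rep_mean: np.ndarray     # (n, D) mean readout per node
    rep_dim: int
    delta: int
    encoder_digest: str


def base_readouts(
    graph: HeteroPairGraph,
    params: EncoderParams,
    delta: int = 1,
    center_once: bool = False,
) -> BaseReadouts:
    """Precompute the plain readout of every node under a frozen encoder."""
    states = encode(graph, params)
    H = concat_states(states)
    S = readout_matrix(graph, delta, center_once)
    rep = S @ H
    counts = np.asarray(S.sum(axis=1)).ravel()
    rep_mean = rep / counts[:, None]
    return BaseReadouts(rep, rep_mean, params.rep_dim, delta, params.digest())
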