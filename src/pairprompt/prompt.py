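"""Task-specific prompt vectors, virtual task bridges and few-shot tuning.

A prompt is a learnable vector p of the same width as the concatenated
encoder representation (hidden_dim * K). During readout every member
representation of a subgraph is gated element-wise by p before aggregation,
so the frozen encoder can be steered per task without touching its weights.

Classification is nearest-bridge: the positive and negative *virtual task
bridges* B_T and B_F are the means of the prompted subgraph representations
of the few labelled examples of each class, and a query node takes the label
of the bridge with the higher cosine similarity (ties resolve negative).
Tuning minimises the two-class softmax cross-entropy of each labelled
example against the bridges; the bridges are recomputed from the current
prompt at every step because they depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .autodiff import Adam, Tensor, cosine_rows
from .encoder import BaseReadouts, Subgraph, readout

__all__ = [
    "PromptState",
    "TaskBridges",
    "prompt_readout",
    "prompted_reps",
    "compute_bridges",
    "prompt_loss",
    "tune_prompt",
    "classify",
    "prompt_similarity",
    "transfer_prompt",
]


@dataclass
class PromptState:
    """Learnable prompt for one downstream task."""

    task_id: str
    p: np.ndarray
    strategy: str = "sum"
    weight: Optional[np.ndarray] = None  # square W for the W-using strategies
    tau: float = 1.0
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.strategy in ("linear_mean", "feature_weighted_sum"):
            if self.weight is None:
                raise ValueError(f"strategy {self.strategy!r} requires W")
            self.weight = np.asarray(self.weight, dtype=float)
            if self.weight.shape != (self.p.size, self.p.size):
                raise ValueError("W must be square with the prompt's width")


@dataclass
class TaskBridges:
    """Class prototypes in prompted representation space."""

    b_true: np.ndarray
    b_false: np.ndarray
    n_pos: int
    n_neg: int


def prompt_readout(
    sub: Subgraph,
    node_reps: np.ndarray,
    prompt: PromptState,
    center_once: bool = False,
) -> np.ndarray:
    """Readout of one subgraph with every member rep gated by the prompt."""
    if prompt.p.size != node_reps.shape[1]:
        raise ValueError(
            f"prompt width {prompt.p.size} != representation width {node_reps.shape[1]}"
        )
    gated = node_reps * prompt.p[None, :]
    return readout(sub, gated, prompt.strategy, prompt.weight, center_once)


def _base_rows(base: BaseReadouts, strategy: str) -> np.ndarray:
    return base.rep_mean if strategy == "linear_mean" else base.rep


def prompted_reps(
    node_ids: Sequence[int], base: BaseReadouts, prompt: PromptState
) -> np.ndarray:
    """Prompted subgraph representations of the given nodes (frozen encoder).

    Element-wise gating commutes with the linear aggregation, so gating the
    precomputed plain readouts equals gating each member first.
    """
    rows = _base_rows(base, prompt.strategy)[np.asarray(node_ids, dtype=np.intp)]
    s = rows * prompt.p[None, :]
    if prompt.weight is not None:
        s = s @ prompt.weight
    return s


def compute_bridges(
    train: Sequence[tuple[int, int]], base: BaseReadouts, prompt: PromptState
) -> TaskBridges:
    nodes = np.array([n for n, _ in train], dtype=np.intp)
    labels = np.array([y for _, y in train], dtype=int)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("bridges undefined: need >= 1 example of each class")
    s = prompted_reps(nodes, base, prompt)
    return TaskBridges(
        s[labels == 1].mean(axis=0),
        s[labels == 0].mean(axis=0),
        int((labels == 1).sum()),
        int((labels == 0).sum()),
    )


def _cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return np.sum(a * b, axis=-1) / (na * nb)


def prompt_loss(
    train: Sequence[tuple[int, int]],
    bridges: TaskBridges,
    base: BaseReadouts,
    prompt: PromptState,
    tau: float = 1.0,
) -> float:
    """Summed two-class softmax cross-entropy against the bridges."""
    nodes = np.array([n for n, _ in train], dtype=np.intp)
    labels = np.array([y for _, y in train], dtype=int)
    s = prompted_reps(nodes, base, prompt)
    sim_t = _cos(s, bridges.b_true)
    sim_f = _cos(s, bridges.b_false)
    sign = np.where(labels == 1, 1.0, -1.0)
    return float(np.logaddexp(0.0, sign * (sim_f - sim_t) / tau).sum())


def tune_prompt(
    train: Sequence[tuple[int, int]],
    base: BaseReadouts,
    strategy: str = "sum",
    tau: float = 1.0,
    steps: int = 100,
    learning_rate: float = 1e-2,
    seed: int = 0,
    init: str = "ones",
    frozen_bridges: bool = False,
    task_id: str = "task",
) -> PromptState:
    """Fit a prompt (and W when the strategy uses one) on a few-shot set.

    Only the prompt parameters receive gradient updates — the encoder is
    frozen and enters solely through the precomputed ``base`` readouts. The
    prompt initialises to all-ones (identity readout) unless
    ``init='normal'``.
    """
    if len(train) == 0:
        raise ValueError("empty few-shot training set")
    d = base.rep_dim
    rng = np.random.default_rng(seed)
    p0 = np.ones(d) if init == "ones" else rng.standard_normal(d)
    needs_w = strategy in ("linear_mean", "feature_weighted_sum")

    nodes = np.array([n for n, _ in train], dtype=np.intp)
    labels = np.array([y for _, y in train], dtype=int)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("few-shot set must contain both classes")
    rows = Tensor(_base_rows(base, strategy)[nodes])
    sign = np.where(labels == 1, 1.0, -1.0)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)

    p = Tensor(p0, requires_grad=True)
    w = Tensor(np.eye(d), requires_grad=True) if needs_w else None
    params = [p] + ([w] if needs_w else [])
    opt = Adam(params, lr=learning_rate)

    frozen: Optional[tuple[np.ndarray, np.ndarray]] = None
    if frozen_bridges:
        s0 = rows.data * p0[None, :]
        if needs_w:
            s0 = s0 @ np.eye(d)
        frozen = (s0[pos].mean(axis=0), s0[neg].mean(axis=0))

    history: list[float] = []
    for _ in range(steps):
        s = rows * p
        if needs_w:
            s = s @ w
        if frozen is not None:
            b_t, b_f = Tensor(frozen[0]), Tensor(frozen[1])
        else:
            b_t = s.take(pos).mean(axis=0)
            b_f = s.take(neg).mean(axis=0)
        sim_t = cosine_rows(s, b_t)
        sim_f = cosine_rows(s, b_f)
        loss = (((sim_f - sim_t) * Tensor(sign)) * (1.0 / tau)).softplus().sum()
        history.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()

    return PromptState(
        task_id=task_id,
        p=p.data.copy(),
        strategy=strategy,
        weight=w.data.copy() if needs_w else None,
        tau=tau,
        loss_history=history,
    )


def classify(
    node_ids: Sequence[int] | int,
    prompt: PromptState,
    bridges: TaskBridges,
    base: BaseReadouts,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-bridge labels and softmax positive-class scores.

    Ties in similarity resolve to the negative class. Returns scalar-shaped
    arrays for a scalar input.
    """
    scalar = np.isscalar(node_ids)
    ids = np.atleast_1d(np.asarray(node_ids, dtype=np.intp))
    s = prompted_reps(ids, base, prompt)
    sim_t = _cos(s, bridges.b_true)
    sim_f = _cos(s, bridges.b_false)
    labels = (sim_t > sim_f).astype(int)
    z = np.stack([sim_f, sim_t], axis=1) / prompt.tau
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    scores = e[:, 1] / e.sum(axis=1)
    if scalar:
        return labels[0], scores[0]
    return labels, scores


def prompt_similarity(prompts: Sequence[PromptState]) -> np.ndarray:
    """Pairwise cosine similarity of prompt vectors (unit diagonal)."""
    widths = {p.p.size for p in prompts}
    if len(widths) > 1:
        raise ValueError("prompts have mismatched widths")
    mat = cosine_similarity(np.stack([p.p for p in prompts]))
    np.fill_diagonal(mat, 1.0)
    return (mat + mat.T) / 2.0


def transfer_prompt(
    source: PromptState,
    target_train: Sequence[tuple[int, int]],
    target_eval: Sequence[tuple[int, int]],
    base: BaseReadouts,
) -> float:
    """Accuracy on a target task using an unchanged source-task prompt.

    The prompt vector is reused as-is; only the bridges are recomputed from
    the target task's few-shot labelled set.
    """
    bridges = compute_bridges(target_train, base, source)
    nodes = [n for n, _ in target_eval]
    labels = np.array([y for _, y in target_eval], dtype=int)
    pred, _ = classify(nodes, source, bridges, base)
    return float((pred == labels).mean())
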