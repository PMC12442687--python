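"""Model/Results facade over the library modules.

`GraphPromptModel` is constructed from a heterogeneous entity-pair graph
(or directly from an interaction table); `fit()` runs the self-supervised
contrastive pre-training and returns a `PretrainResults` object that holds
the trained encoder, the training log and everything downstream: few-shot
prompt tuning (`tune`), cross-validated task evaluation (`evaluate_task`)
and checkpointing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation as _evaluation
from .encoder import (
    BaseReadouts,
    EncoderParams,
    base_readouts,
    init_encoder_params,
)
from .evaluation import EvalReport, evaluate_task
from .graph_construction import HeteroPairGraph, build_graph, read_interactions
from .pretrain import PretrainConfig, pretrain_encoder
from .prompt import (
    PromptState,
    TaskBridges,
    classify,
    compute_bridges,
    transfer_prompt,
    tune_prompt,
)
from .synthetic_data import SyntheticBenchmark

__all__ = ["GraphPromptModel", "PretrainResults", "PromptResults"]


class GraphPromptModel:
    """Few-shot multi-task prompt learner over an entity-pair graph."""

    def __init__(
        self,
        graph: HeteroPairGraph,
        input_dim: int = 32,
        hidden_dim: int = 16,
        num_layers: int = 3,
        delta: int = 1,
        center_once: bool = False,
    ):
        self.graph = graph
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.delta = delta
        self.center_once = center_once

    @classmethod
    def from_interactions(
        cls,
        table: pd.DataFrame | str | Path,
        per_type_cap: int = 10_000,
        seed: int = 0,
        **kwargs,
    ) -> "GraphPromptModel":
        if not isinstance(table, pd.DataFrame):
            table = read_interactions(table)
        return cls(build_graph(table, per_type_cap, seed), **kwargs)

    @classmethod
    def from_benchmark(
        cls, benchmark: SyntheticBenchmark, seed: int = 0, **kwargs
    ) -> "GraphPromptModel":
        return cls.from_interactions(benchmark.interactions, seed=seed, **kwargs)

    def _config(self, **overrides) -> PretrainConfig:
        base = dict(
            input_dim=self.input_dim,
            hidden_dim=self.hidden_dim,
            num_layers=self.num_layers,
            delta=self.delta,
            center_once=self.center_once,
        )
        base.update(overrides)
        return PretrainConfig(**base)

    def fit(
        self,
        strategy: str = "random",
        tau: float = 1.0,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        seed: int = 0,
        triplets_per_epoch: Optional[int] = None,
    ) -> "PretrainResults":
        """Contrastive pre-training of the encoder (no labels consulted)."""
        config = self._config(
            strategy=strategy, tau=tau, epochs=epochs,
            learning_rate=learning_rate, weight_decay=weight_decay,
            seed=seed, triplets_per_epoch=triplets_per_epoch,
        )
        params, log = pretrain_encoder(self.graph, config)
        return PretrainResults(self, params, log, config)

    def random_results(self, seed: int = 0) -> "PretrainResults":
        """Frozen randomly-initialised encoder (the no-pretrain ablation)."""
        params = init_encoder_params(
            self.graph, self.input_dim, self.hidden_dim, self.num_layers, seed
        )
        config = self._config(epochs=0, seed=seed)
        return PretrainResults(
            self, params, pd.DataFrame(columns=["epoch", "mean_loss", "margin"]),
            config,
        )

    def load_results(self, path: str | Path) -> "PretrainResults":
        params = EncoderParams.load(path)
        return PretrainResults(self, params, pd.DataFrame(), self._config())


@dataclass
class PretrainResults:
    """Trained (or deliberately untrained) encoder plus downstream API."""

    model: GraphPromptModel
    params: EncoderParams
    log: pd.DataFrame
    config: PretrainConfig
    _base: Optional[BaseReadouts] = None

    def readouts(self) -> BaseReadouts:
        """Plain per-node subgraph readouts under the frozen encoder."""
        if self._base is None or self._base.encoder_digest != self.params.digest():
            self._base = base_readouts(
                self.model.graph, self.params, self.model.delta,
                self.model.center_once,
            )
        return self._base

    def tune(
        self,
        train: Sequence[tuple[int, int]],
        strategy: str = "feature_weighted_sum",
        tau: float = 1.0,
        steps: int = 100,
        learning_rate: float = 1e-2,
        seed: int = 0,
        task_id: str = "task",
    ) -> "PromptResults":
        """Few-shot prompt tuning against the frozen encoder."""
        base = self.readouts()
        prompt = tune_prompt(
            train, base, strategy=strategy, tau=tau, steps=steps,
            learning_rate=learning_rate, seed=seed, task_id=task_id,
        )
        bridges = compute_bridges(train, base, prompt)
        return PromptResults(prompt, bridges, base, list(train))

    def evaluate_task(
        self,
        labeled: Sequence[tuple[int, int]],
        task_id: str = "task",
        k_pct: float = 1.0,
        strategy: str = "feature_weighted_sum",
        seed: int = 0,
        **kwargs,
    ) -> EvalReport:
        """10-fold cross-validated few-shot accuracy on one task."""
        return evaluate_task(
            self.readouts(), labeled, task_id, k_pct,
            strategy=strategy, seed=seed, **kwargs,
        )

    def transfer(
        self,
        source: "PromptResults",
        target_train: Sequence[tuple[int, int]],
        target_eval: Sequence[tuple[int, int]],
    ) -> float:
        return transfer_prompt(
            source.prompt, target_train, target_eval, self.readouts()
        )

    def save(self, path: str | Path) -> None:
        self.params.save(path)

    def summary(self) -> str:
        lines = [
            "Graph prompt model — contrastive pre-training results",
            "=" * 53,
            f"nodes: {self.model.graph.n_nodes}   edges: {self.model.graph.n_edges}",
            f"encoder: GIN x{self.params.num_layers}, hidden {self.params.hidden_dim}, "
            f"input {self.params.input_dim}, delta {self.model.delta}",
            f"representation width: {self.params.rep_dim}",
            f"strategy: {self.config.strategy}   tau: {self.config.tau}   "
            f"epochs: {self.config.epochs}",
        ]
        if len(self.log):
            first, last = self.log.iloc[0], self.log.iloc[-1]
            lines += [
                f"loss: {first.mean_loss:.4f} -> {last.mean_loss:.4f}",
                f"contrastive margin: {first.margin:+.4f} -> {last.margin:+.4f}",
            ]
        else:
            lines.append("encoder not pre-trained (0 epochs)")
        return "\n".join(lines)


@dataclass
class PromptResults:
    """A tuned task prompt with its bridges, ready to classify."""

    prompt: PromptState
    bridges: TaskBridges
    base: BaseReadouts
    train: list[tuple[int, int]]

    def predict(self, node_ids) -> tuple[np.ndarray, np.ndarray]:
        return classify(node_ids, self.prompt, self.bridges, self.base)

    def accuracy(self, labeled: Sequence[tuple[int, int]]) -> float:
        pred, _ = self.predict([n for n, _ in labeled])
        truth = np.array([y for _, y in labeled], dtype=int)
        return float((pred == truth).mean())

    def summary(self) -> str:
        hist = self.prompt.loss_history
        lines = [
            f"Prompt for task {self.prompt.task_id!r} "
            f"(strategy {self.prompt.strategy}, width {self.prompt.p.size})",
            f"few-shot set: {self.bridges.n_pos} positive / "
            f"{self.bridges.n_neg} negative",
        ]
        if hist:
            lines.append(f"tuning loss: {hist[0]:.4f} -> {hist[-1]:.4f} "
                         f"({len(hist)} steps)")
        return "\n".join(lines)
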