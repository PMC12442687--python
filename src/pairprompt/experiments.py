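"""Reproducible desk-scale benchmark experiments.

These drivers tie the whole pipeline together on the default synthetic
benchmark: the few-shot ablation sweep (full model vs no-pretrain vs
no-prompt, across k and across negative-sampling strategies), the prompt
transfer experiment on a two-group benchmark (task pairs that share
entities vs entity-disjoint task pairs), and a permuted-label null
calibration. Every function is deterministic given its seeds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .encoder import base_readouts
from .evaluation import evaluate_task, make_splits, run_ablation
from .graph_construction import build_graph
from .model import GraphPromptModel
from .pretrain import NEGATIVE_STRATEGIES, PretrainConfig, pretrain_encoder
from .prompt import prompt_similarity, transfer_prompt, tune_prompt
from .synthetic_data import GeneratorConfig, generate_benchmark

__all__ = [
    "benchmark_sweep",
    "transfer_experiment",
    "null_calibration",
    "TRANSFER_CONFIG",
]

#: Two entity-disjoint task groups on one graph: the drug tasks share drugs,
#: the substituent tasks share substituents, and the groups share nothing.
TRANSFER_CONFIG = dict(
    entity_counts={
        "drug": 60, "protein": 80, "disease": 50,
        "substituent": 60, "side_effect": 80, "go_term": 50,
    },
    tasks=(
        ("drug", "protein"),
        ("drug", "disease"),
        ("substituent", "side_effect"),
        ("substituent", "go_term"),
    ),
    pairs_per_task=250,
)

_SHARED_TASK_PAIRS = {
    frozenset({"disease-drug", "drug-protein"}),
    frozenset({"side_effect-substituent", "go_term-substituent"}),
}


def _tasks_of(graph):
    return {t: graph.labeled_nodes(t) for t in graph.pair_types()}


def benchmark_sweep(
    seeds: Sequence[int],
    k_values: Sequence[float] = (1.0, 10.0),
    config: PretrainConfig | None = None,
    generator: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Ablations and negative-sampling comparison on the default benchmark.

    Per seed the benchmark is regenerated, one encoder is pre-trained per
    negative-sampling strategy, and every labelled task is evaluated by
    10-fold cross-validated few-shot prompt tuning. Rows:
    (seed, variant, task, k_pct, accuracy) where variant is full /
    no_pretrain / no_prompt / neg:<strategy>.
    """
    config = config or PretrainConfig()
    rows = []
    for seed in seeds:
        gen = GeneratorConfig(**{**(generator or GeneratorConfig()).__dict__,
                                 "seed": seed})
        bench = generate_benchmark(gen)
        graph = build_graph(bench.interactions, seed=seed)
        tasks = _tasks_of(graph)
        encoders = {}
        for strategy in NEGATIVE_STRATEGIES:
            cfg = PretrainConfig(
                **{**config.__dict__, "strategy": strategy, "seed": seed}
            )
            encoders[strategy], _ = pretrain_encoder(graph, cfg)

        for k in k_values:
            table = run_ablation(
                graph, tasks, config, k_pct=k, seeds=(seed,),
                modes=("full",) if k != min(k_values)
                else ("full", "no_pretrain", "no_prompt"),
                encoders={seed: encoders["random"]},
            )
            for rec in table.itertuples(index=False):
                rows.append(
                    dict(seed=seed, variant=rec.mode, task=rec.task,
                         k_pct=k, accuracy=rec.accuracy)
                )
        k_min = min(k_values)
        for strategy in NEGATIVE_STRATEGIES:
            base = base_readouts(
                graph, encoders[strategy], config.delta, config.center_once
            )
            for task, labeled in tasks.items():
                report = evaluate_task(base, labeled, task, k_min, seed=seed)
                rows.append(
                    dict(seed=seed, variant=f"neg:{strategy}", task=task,
                         k_pct=k_min, accuracy=report.mean_accuracy)
                )
    return pd.DataFrame(rows)


def transfer_experiment(
    seeds: Sequence[int],
    k_pct: float = 10.0,
    folds: int = 5,
    steps: int = 300,
    learning_rate: float = 5e-2,
    epochs: int = 200,
) -> pd.DataFrame:
    """Prompt similarity and cross-task transfer, shared vs disjoint pairs.

    One graph holds two entity-disjoint task groups; prompts tuned per task
    (and fold) are applied unchanged to every other task, recomputing only
    the target's bridges. Rows: (seed, kind, task_src, task_dst, similarity,
    accuracy) with kind 'shared' or 'disjoint'.
    """
    rows = []
    for seed in seeds:
        gen = GeneratorConfig(**TRANSFER_CONFIG, seed=seed)
        bench = generate_benchmark(gen)
        model = GraphPromptModel.from_benchmark(bench, seed=seed)
        results = model.fit(epochs=epochs, seed=seed)
        base = results.readouts()
        graph = model.graph
        prompts, splits = {}, {}
        for task in graph.pair_types():
            labeled = graph.labeled_nodes(task)
            splits[task] = make_splits(labeled, k_pct, 10, seed, task)[:folds]
            prompts[task] = [
                tune_prompt(
                    s.train, base, strategy="feature_weighted_sum",
                    steps=steps, learning_rate=learning_rate,
                    seed=seed, task_id=task,
                )
                for s in splits[task]
            ]
        for src in graph.pair_types():
            for dst in graph.pair_types():
                if src == dst:
                    continue
                kind = (
                    "shared"
                    if frozenset({src, dst}) in _SHARED_TASK_PAIRS
                    else "disjoint"
                )
                for fold in range(folds):
                    sim = prompt_similarity(
                        [prompts[src][fold], prompts[dst][fold]]
                    )[0, 1]
                    acc = transfer_prompt(
                        prompts[src][fold],
                        splits[dst][fold].train,
                        splits[dst][fold].eval,
                        base,
                    )
                    rows.append(
                        dict(seed=seed, kind=kind, task_src=src, task_dst=dst,
                             similarity=float(sim), accuracy=float(acc))
                    )
    return pd.DataFrame(rows)


def null_calibration(
    seed: int = 0, k_pct: float = 10.0, epochs: int = 200
) -> tuple[int, int]:
    """Permuted-label accuracy audit: (correct predictions, total).

    Labels of every task are randomly permuted before split construction,
    severing any node-label linkage; under the null the classifier should
    be right half the time.
    """
    bench = generate_benchmark(GeneratorConfig(seed=seed))
    model = GraphPromptModel.from_benchmark(bench, seed=seed)
    results = model.fit(epochs=epochs, seed=seed)
    base = results.readouts()
    graph = model.graph
    rng = np.random.default_rng(seed)
    correct, total = 0, 0
    for task in graph.pair_types():
        labeled = graph.labeled_nodes(task)
        labels = np.array([y for _, y in labeled])
        rng.shuffle(labels)
        permuted = [(n, int(y)) for (n, _), y in zip(labeled, labels)]
        report = evaluate_task(base, permuted, task, k_pct, seed=seed)
        n_eval = len(labeled)
        correct += int(round(report.mean_accuracy * n_eval))
        total += n_eval
    return correct, total
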