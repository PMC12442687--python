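"""Few-shot splits, cross-validated accuracy, ablations and sweeps.

The evaluation protocol for one association task: its labelled pair nodes
are partitioned into 10 stratified folds; for each fold the held-out fold is
the evaluation set and the *tuning* set is a fresh balanced sample from the
remaining nine folds containing ceil(k/2 % of the task's labelled count)
positives and equally many negatives. A prompt is tuned on the tuning set
against the frozen encoder and the evaluation fold is classified by nearest
bridge; accuracy is averaged over folds (AUROC is reported as a
supplementary column).

Ablations: ``no_pretrain`` keeps the full prompt machinery but freezes a
randomly initialised encoder; ``no_prompt`` uses the pre-trained encoder's
plain sum readout with a logistic-regression head fitted on the tuning set.
All modes consume identical splits for a given seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .encoder import BaseReadouts, EncoderParams, base_readouts, init_encoder_params
from .graph_construction import HeteroPairGraph
from .pretrain import NEGATIVE_STRATEGIES, PretrainConfig, pretrain_encoder
from .prompt import classify, compute_bridges, tune_prompt

__all__ = [
    "FewShotSplit",
    "EvalReport",
    "make_splits",
    "evaluate_task",
    "run_ablation",
    "compare_strategies",
]

ABLATION_MODES = ("full", "no_pretrain", "no_prompt")


class InfeasibleSplitError(ValueError):
    pass


@dataclass
class FewShotSplit:
    task_id: str
    train: list[tuple[int, int]]
    eval: list[tuple[int, int]]
    k_pct: float
    fold: int
    seed: int


@dataclass
class EvalReport:
    task_id: str
    k_pct: float
    strategy: str
    fold_accuracies: list[float]
    fold_aurocs: list[float]
    config_digest: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def summary(self) -> str:
        return (
            f"task={self.task_id} k={self.k_pct}% strategy={self.strategy} "
            f"accuracy={self.mean_accuracy:.3f} +/- {self.sd_accuracy:.3f} "
            f"({len(self.fold_accuracies)} folds)"
        )


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def make_splits(
    labeled: Sequence[tuple[int, int]],
    k_pct: float,
    n_folds: int = 10,
    seed: int = 0,
    task_id: str = "task",
) -> list[FewShotSplit]:
    """Stratified folds with a balanced k% tuning set per fold.

    The tuning set holds ceil(k/2% of the labelled count) examples of each
    class, drawn from the nine training folds with a per-fold seeded shuffle
    of the negatives (and positives), so each fold sees a fresh balanced
    sample.
    """
    labeled = list(labeled)
    nodes = np.array([n for n, _ in labeled], dtype=np.intp)
    labels = np.array([y for _, y in labeled], dtype=int)
    per_class = math.ceil(len(labeled) * k_pct / 200.0)
    if per_class < 1:
        raise InfeasibleSplitError("k% too small: no examples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    splits = []
    rng = np.random.default_rng(seed)
    for fold, (train_idx, eval_idx) in enumerate(skf.split(nodes, labels)):
        fold_rng = np.random.default_rng(rng.integers(2**31 - 1))
        train_set = []
        for cls in (1, 0):
            pool = train_idx[labels[train_idx] == cls]
            if len(pool) < per_class:
                name = "positive" if cls == 1 else "negative"
                raise InfeasibleSplitError(
                    f"task {task_id}: {name} class exhausted "
                    f"(need {per_class}, have {len(pool)})"
                )
            chosen = fold_rng.choice(pool, size=per_class, replace=False)
            train_set += [(int(nodes[i]), int(labels[i])) for i in chosen]
        eval_set = [(int(nodes[i]), int(labels[i])) for i in eval_idx]
        splits.append(FewShotSplit(task_id, train_set, eval_set, k_pct, fold, seed))
    return splits


def _eval_fold_prompt(
    split: FewShotSplit,
    base: BaseReadouts,
    strategy: str,
    tau: float,
    steps: int,
    learning_rate: float,
    seed: int,
) -> tuple[float, float]:
    prompt = tune_prompt(
        split.train, base, strategy=strategy, tau=tau, steps=steps,
        learning_rate=learning_rate, seed=seed, task_id=split.task_id,
    )
    bridges = compute_bridges(split.train, base, prompt)
    nodes = [n for n, _ in split.eval]
    labels = np.array([y for _, y in split.eval], dtype=int)
    pred, score = classify(nodes, prompt, bridges, base)
    acc = float((pred == labels).mean())
    auc = float("nan")
    if len(np.unique(labels)) == 2:
        auc = float(roc_auc_score(labels, score))
    return acc, auc


def _eval_fold_linear(
    split: FewShotSplit, base: BaseReadouts, seed: int
) -> tuple[float, float]:
    """Plain sum-readout features with a logistic-regression head."""
    x_tr = base.rep[[n for n, _ in split.train]]
    y_tr = np.array([y for _, y in split.train], dtype=int)
    x_ev = base.rep[[n for n, _ in split.eval]]
    y_ev = np.array([y for _, y in split.eval], dtype=int)
    clf = LogisticRegression(max_iter=1000, random_state=seed % 2**31)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_ev)
    acc = float((pred == y_ev).mean())
    auc = float("nan")
    if len(np.unique(y_ev)) == 2:
        auc = float(roc_auc_score(y_ev, clf.predict_proba(x_ev)[:, 1]))
    return acc, auc


def evaluate_task(
    base: BaseReadouts,
    labeled: Sequence[tuple[int, int]],
    task_id: str = "task",
    k_pct: float = 1.0,
    strategy: str = "feature_weighted_sum",
    seed: int = 0,
    n_folds: int = 10,
    tau: float = 1.0,
    steps: int = 100,
    learning_rate: float = 1e-2,
    head: str = "prompt",
) -> EvalReport:
    """10-fold cross-validated few-shot accuracy for one task."""
    splits = make_splits(labeled, k_pct, n_folds, seed, task_id)
    accs, aucs = [], []
    for split in splits:
        fold_seed = (seed * 1000 + split.fold) % 2**31
        if head == "prompt":
            acc, auc = _eval_fold_prompt(
                split, base, strategy, tau, steps, learning_rate, fold_seed
            )
        else:
            acc, auc = _eval_fold_linear(split, base, fold_seed)
        accs.append(acc)
        aucs.append(auc)
    digest = _digest(
        dict(task=task_id, k=k_pct, strategy=strategy, seed=seed,
             folds=n_folds, tau=tau, steps=steps, lr=learning_rate, head=head)
    )
    return EvalReport(task_id, k_pct, strategy, accs, aucs, digest)


def _pretrain_for(
    graph: HeteroPairGraph, config: PretrainConfig, seed: int
) -> EncoderParams:
    cfg = PretrainConfig(**{**config.__dict__, "seed": seed})
    params, _ = pretrain_encoder(graph, cfg)
    return params


def run_ablation(
    graph: HeteroPairGraph,
    tasks: dict[str, Sequence[tuple[int, int]]],
    config: PretrainConfig,
    k_pct: float = 1.0,
    seeds: Sequence[int] = (0,),
    modes: Sequence[str] = ABLATION_MODES,
    strategy: str = "feature_weighted_sum",
    encoders: Optional[dict[int, EncoderParams]] = None,
    **eval_kwargs,
) -> pd.DataFrame:
    """Full pipeline vs no-pretrain vs no-prompt on identical splits.

    ``encoders`` may supply already pre-trained parameters per seed to avoid
    repeating the expensive stage. Returns one row per (mode, seed, task).
    """
    for mode in modes:
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}")
    rows = []
    for seed in seeds:
        bases: dict[str, BaseReadouts] = {}
        if {"full", "no_prompt"} & set(modes):
            params = (encoders or {}).get(seed) or _pretrain_for(graph, config, seed)
            bases["pretrained"] = base_readouts(
                graph, params, config.delta, config.center_once
            )
        if "no_pretrain" in modes:
            rand = init_encoder_params(
                graph, config.input_dim, config.hidden_dim, config.num_layers,
                seed=seed,
            )
            bases["random"] = base_readouts(
                graph, rand, config.delta, config.center_once
            )
        for mode in modes:
            base = bases["random" if mode == "no_pretrain" else "pretrained"]
            head = "linear" if mode == "no_prompt" else "prompt"
            for task_id, labeled in tasks.items():
                report = evaluate_task(
                    base, labeled, task_id, k_pct,
                    strategy=strategy, seed=seed, head=head, **eval_kwargs,
                )
                rows.append(
                    {
                        "mode": mode,
                        "seed": seed,
                        "task": task_id,
                        "k_pct": k_pct,
                        "accuracy": report.mean_accuracy,
                        "sd": report.sd_accuracy,
                    }
                )
    return pd.DataFrame(rows)


def compare_strategies(
    graph: HeteroPairGraph,
    tasks: dict[str, Sequence[tuple[int, int]]],
    config: PretrainConfig,
    axis: str = "readout",
    k_pct: float = 1.0,
    seeds: Sequence[int] = (0,),
    encoders: Optional[dict[tuple[int, str], EncoderParams]] = None,
    **eval_kwargs,
) -> pd.DataFrame:
    """Sweep readout strategies or negative-sampling strategies.

    Splits are shared across options (they depend only on task and seed).
    For ``axis='neg_sampling'``, ``encoders`` may map (seed, strategy) to
    pre-trained parameters.
    """
    if axis not in ("readout", "neg_sampling"):
        raise ValueError(f"unknown comparison axis {axis!r}")
    rows = []
    if axis == "readout":
        options = ("sum", "linear_mean", "feature_weighted_sum")
        for seed in seeds:
            params = _pretrain_for(graph, config, seed)
            base = base_readouts(graph, params, config.delta, config.center_once)
            for option in options:
                for task_id, labeled in tasks.items():
                    report = evaluate_task(
                        base, labeled, task_id, k_pct,
                        strategy=option, seed=seed, **eval_kwargs,
                    )
                    rows.append(
                        {
                            "option": option,
                            "seed": seed,
                            "task": task_id,
                            "k_pct": k_pct,
                            "accuracy": report.mean_accuracy,
                        }
                    )
    else:
        for seed in seeds:
            for option in NEGATIVE_STRATEGIES:
                params = (encoders or {}).get((seed, option))
                if params is None:
                    cfg = PretrainConfig(
                        **{**config.__dict__, "strategy": option, "seed": seed}
                    )
                    params, _ = pretrain_encoder(graph, cfg)
                base = base_readouts(graph, params, config.delta, config.center_once)
                for task_id, labeled in tasks.items():
                    report = evaluate_task(
                        base, labeled, task_id, k_pct,
                        strategy="feature_weighted_sum", seed=seed, **eval_kwargs,
                    )
                    rows.append(
                        {
                            "option": option,
                            "seed": seed,
                            "task": task_id,
                            "k_pct": k_pct,
                            "accuracy": report.mean_accuracy,
                        }
                    )
    return pd.DataFrame(rows)
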