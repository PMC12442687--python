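"""Synthetic multi-task heterogeneous association benchmarks.

The generator emulates the schema of real drug-association interaction
tables — typed entities, several interaction types sharing entities — with
planted, tunable structure so the whole pipeline (pre-training, prompt
tuning, transfer, ablations) is testable offline.

Model. Every entity carries a latent vector u ~ N(0, I_d) and a scalar
activity alpha ~ N(0, activity_sd^2). A pair (a, b) is truly associated
with probability

    sigmoid( b0 + alpha_a + alpha_b + (scale / sqrt(d)) * u_a . u_b )

— a logistic latent-factor interactome in which promiscuous (high-alpha)
entities associate broadly and latently aligned entities associate
specifically. The intercept b0 is calibrated per task so the interactome
density hits its target. The labelled benchmark then mirrors how real
association tables are assembled: the positives of a task are drawn from
the pairs that truly interact, with an observation bias
exp(observation_bias * (alpha_a + alpha_b)) favouring well-studied hub
entities (the literature records famous drugs' interactions far more
completely than obscure ones), and the negatives are drawn uniformly from
unobserved (non-interacting) pairs, in the configured positive:negative
ratio; finally labels are flipped at the label-noise rate. Positives
therefore concentrate around active, mutually compatible entities — they
share component entities and form a dense region of the pair graph — while
negatives are scattered random combinations, which is the structural
asymmetry the shared-entity edge rule and the contrastive objective are
built to exploit. Tasks sharing entities are generated over overlapping
pools (``sharing_fraction``), enabling cross-task edges and prompt
transfer; ``sharing_fraction=0`` produces entity-disjoint tasks as a
negative control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .graph_construction import Entity, canonical_pair

__all__ = [
    "GeneratorConfig",
    "EntitySet",
    "SyntheticBenchmark",
    "CalibrationError",
    "association_probability",
    "simulate_entities",
    "simulate_interactions",
    "generate_benchmark",
    "export_benchmark",
    "regenerate",
]

FORMAT_VERSION = "pairprompt-benchmark-v1"

DEFAULT_ENTITY_COUNTS = {"drug": 60, "protein": 80, "disease": 50, "side_effect": 40}
DEFAULT_TASKS = (
    ("drug", "protein"),
    ("drug", "disease"),
    ("drug", "side_effect"),
    ("disease", "protein"),
)


class CalibrationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    entity_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_COUNTS)
    )
    tasks: tuple[tuple[str, str], ...] = DEFAULT_TASKS
    latent_dim: int = 8
    pairs_per_task: int = 500
    positive_rate: float = 0.5
    interactome_density: float = 0.25
    label_noise: float = 0.1
    sharing_fraction: float = 1.0
    activity_sd: float = 2.0
    observation_bias: float = 2.0
    interaction_scale: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1 or self.pairs_per_task < 1:
            raise ValueError("latent_dim and pairs_per_task must be >= 1")
        for r in (self.positive_rate, self.interactome_density,
                  self.label_noise, self.sharing_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(c < 1 for c in self.entity_counts.values()):
            raise ValueError("entity counts must be >= 1")
        self.tasks = tuple(tuple(t) for t in self.tasks)


@dataclass
class EntitySet:
    ids: dict[str, list[str]]
    latents: dict[Entity, np.ndarray]
    activity: dict[Entity, float]

    @property
    def n_entities(self) -> int:
        return sum(len(v) for v in self.ids.values())


@dataclass
class SyntheticBenchmark:
    interactions: pd.DataFrame   # the graph_construction TSV schema + label
    ground_truth: pd.DataFrame   # per pair: probability, clean & noisy label
    entities: EntitySet
    provenance: dict


def association_probability(
    u_a: np.ndarray,
    u_b: np.ndarray,
    alpha_a: float = 0.0,
    alpha_b: float = 0.0,
    scale: float = 1.0,
    intercept: float = 0.0,
) -> float:
    """Logistic latent-factor association probability of one pair."""
    u_a = np.asarray(u_a, float)
    u_b = np.asarray(u_b, float)
    logit = intercept + alpha_a + alpha_b + scale / np.sqrt(u_a.size) * (u_a @ u_b)
    return float(1.0 / (1.0 + np.exp(-logit)))


def simulate_entities(config: GeneratorConfig) -> EntitySet:
    """Typed entities with seeded Gaussian latents and activities."""
    rng = np.random.default_rng(config.seed)
    ids: dict[str, list[str]] = {}
    latents: dict[Entity, np.ndarray] = {}
    activity: dict[Entity, float] = {}
    for etype in sorted(config.entity_counts):
        count = config.entity_counts[etype]
        ids[etype] = [f"{etype}_{i:04d}" for i in range(count)]
        u = rng.standard_normal((count, config.latent_dim))
        a = rng.standard_normal(count) * config.activity_sd
        for i, eid in enumerate(ids[etype]):
            e = Entity(eid, etype)
            latents[e] = u[i]
            activity[e] = float(a[i])
    return EntitySet(ids, latents, activity)


def _task_pools(config: GeneratorConfig, entities: EntitySet) -> dict[tuple, dict]:
    """Per-task entity pools honouring the sharing fraction.

    For an entity type used by several tasks, the first ``sharing_fraction``
    of its entities is available to all of them; the remainder is split
    evenly among those tasks, giving each a private slice.
    """
    users: dict[str, list[int]] = {}
    for t, task in enumerate(config.tasks):
        for etype in set(task):
            users.setdefault(etype, []).append(t)
    pools: dict[tuple, dict] = {task: {} for task in config.tasks}
    for etype, task_idx in users.items():
        all_ids = entities.ids[etype]
        if len(task_idx) == 1:
            pools[config.tasks[task_idx[0]]][etype] = list(all_ids)
            continue
        n_shared = int(round(config.sharing_fraction * len(all_ids)))
        shared = all_ids[:n_shared]
        rest = all_ids[n_shared:]
        for j, t in enumerate(task_idx):
            private = rest[j::len(task_idx)]
            pools[config.tasks[t]][etype] = shared + private
    return pools


def _calibrate_intercept(raw_logits: np.ndarray, target: float) -> float:
    """Bisect b0 so that mean sigmoid(b0 + raw) == target."""

    def rate(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + raw_logits)))))

    lo, hi = -30.0, 30.0
    if not rate(lo) <= target <= rate(hi):
        raise CalibrationError(f"positive-rate target {target} unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    if abs(rate(b0) - target) > 1e-3:
        raise CalibrationError(
            f"calibration failed: achieved {rate(b0):.4f}, target {target}"
        )
    return b0


def simulate_interactions(
    entities: EntitySet, config: GeneratorConfig
) -> SyntheticBenchmark:
    """Sample labelled pairs for every task under the planted interactome.

    Per task: every candidate pair is assigned a true interaction status by
    a Bernoulli draw from the logistic latent-factor probability (with the
    intercept calibrated to the interactome density); the task's positives
    are sampled from the interacting pairs with observation-bias weights
    exp(observation_bias * (alpha_a + alpha_b)) and its negatives uniformly
    from the non-interacting pairs, then labels are flipped at the noise
    rate.
    """
    rng = np.random.default_rng(config.seed + 1)
    pools = _task_pools(config, entities)
    rows, truth_rows = [], []
    for task in config.tasks:
        ta, tb = task
        pool_a = [Entity(i, ta) for i in pools[task][ta]]
        if ta == tb:
            candidates = list(combinations(pool_a, 2))
        else:
            pool_b = [Entity(i, tb) for i in pools[task][tb]]
            candidates = [canonical_pair(a, b) for a, b in product(pool_a, pool_b)]
        raw = np.array(
            [
                entities.activity[a]
                + entities.activity[b]
                + config.interaction_scale
                / np.sqrt(config.latent_dim)
                * float(entities.latents[a] @ entities.latents[b])
                for a, b in candidates
            ]
        )
        b0 = _calibrate_intercept(raw, config.interactome_density)
        prob = 1.0 / (1.0 + np.exp(-(b0 + raw)))
        interacts = rng.random(len(candidates)) < prob
        n_pos = int(round(config.pairs_per_task * config.positive_rate))
        n_neg = config.pairs_per_task - n_pos
        pos_pool = np.flatnonzero(interacts)
        neg_pool = np.flatnonzero(~interacts)
        if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
            raise ValueError(
                f"task {task}: need {n_pos} interacting / {n_neg} non-interacting "
                f"pairs but interactome has {len(pos_pool)} / {len(neg_pool)}"
            )
        act = np.array(
            [
                entities.activity[a] + entities.activity[b]
                for a, b in candidates
            ]
        )
        w = np.exp(config.observation_bias * act[pos_pool])
        chosen_idx = np.concatenate(
            [
                rng.choice(pos_pool, size=n_pos, replace=False, p=w / w.sum()),
                rng.choice(neg_pool, size=n_neg, replace=False),
            ]
        )
        chosen_idx.sort()
        flip = rng.random(len(chosen_idx)) < config.label_noise
        task_name = f"{min(ta, tb)}-{max(ta, tb)}"
        for i, do_flip in zip(chosen_idx, flip):
            a, b = candidates[i]
            p = prob[i]
            yc = int(interacts[i])
            yn = int(1 - yc) if do_flip else yc
            rows.append(
                {
                    "entity_a_id": a.id,
                    "entity_a_type": a.etype,
                    "entity_b_id": b.id,
                    "entity_b_type": b.etype,
                    "interaction_type": task_name,
                    "label": int(yn),
                }
            )
            truth_rows.append(
                {
                    "entity_a_id": a.id,
                    "entity_a_type": a.etype,
                    "entity_b_id": b.id,
                    "entity_b_type": b.etype,
                    "interaction_type": task_name,
                    "probability": round(float(p), 10),
                    "label_clean": int(yc),
                    "label": int(yn),
                }
            )
    provenance = {
        "format": FORMAT_VERSION,
        "config": asdict(config),
    }
    return SyntheticBenchmark(
        pd.DataFrame(rows), pd.DataFrame(truth_rows), entities, provenance
    )


def generate_benchmark(config: Optional[GeneratorConfig] = None) -> SyntheticBenchmark:
    config = config or GeneratorConfig()
    return simulate_interactions(simulate_entities(config), config)


def export_benchmark(benchmark: SyntheticBenchmark, outdir: str | Path) -> None:
    """Write interactions.tsv, ground_truth.tsv and provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    benchmark.interactions.to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )
    benchmark.ground_truth.to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False
    )
    (outdir / "provenance.json").write_text(
        json.dumps(benchmark.provenance, indent=2, sort_keys=True) + "\n"
    )


def regenerate(provenance: dict) -> SyntheticBenchmark:
    """Rebuild a benchmark bit-exactly from its provenance record."""
    if provenance.get("format") != FORMAT_VERSION:
        raise ValueError("unrecognized provenance format")
    cfg = dict(provenance["config"])
    cfg["tasks"] = tuple(tuple(t) for t in cfg["tasks"])
    return generate_benchmark(GeneratorConfig(**cfg))
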