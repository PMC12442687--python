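"""Heterogeneous entity-pair graph construction.

Biomedical association tasks (drug-target, drug-disease, ...) are recast as
binary classification over *entity pairs*: each candidate pair becomes a node
of a heterogeneous graph, and two pair nodes are joined by an undirected,
unweighted edge whenever they share at least one component entity. Pairs that
share an entity have a structural basis for similar behaviour, which the
contrastive pre-training stage later exploits. Labels, when present, are
carried on the nodes but never consulted while building the graph.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DEFAULT_ENTITY_TYPES",
    "Entity",
    "EntityPairNode",
    "HeteroPairGraph",
    "SchemaError",
    "read_interactions",
    "build_pair_nodes",
    "connect_shared_entity",
    "build_graph",
    "graph_summary",
]

DEFAULT_ENTITY_TYPES = frozenset(
    {
        "drug",
        "protein",
        "disease",
        "side_effect",
        "substituent",
        "chemical_substructure",
        "go_term",
        "target",
    }
)

INTERACTION_COLUMNS = [
    "entity_a_id",
    "entity_a_type",
    "entity_b_id",
    "entity_b_type",
    "interaction_type",
]


class SchemaError(ValueError):
    """An interaction row violates the input schema."""


class Entity(NamedTuple):
    id: str
    etype: str


@dataclass(frozen=True)
class EntityPairNode:
    """A graph node formed from an unordered pair of typed entities."""

    node_id: int
    entity_a: Entity
    entity_b: Entity
    pair_type: str
    label: Optional[int] = None

    @property
    def entities(self) -> tuple[Entity, Entity]:
        return (self.entity_a, self.entity_b)


def canonical_pair(a: Entity, b: Entity) -> tuple[Entity, Entity]:
    """Order the two entities of a pair by (etype, id) so (a,b) == (b,a)."""
    return (a, b) if (a.etype, a.id) <= (b.etype, b.id) else (b, a)


def pair_type_of(a: Entity, b: Entity) -> str:
    a, b = canonical_pair(a, b)
    return f"{a.etype}-{b.etype}"


@dataclass
class HeteroPairGraph:
    """Undirected, unweighted graph over entity-pair nodes.

    ``edges`` holds unordered node-id pairs stored as (u, v) with u < v;
    ``adjacency`` maps every node id to its neighbour set and is kept
    consistent with the edge set.
    """

    nodes: list[EntityPairNode]
    edges: set[tuple[int, int]]
    node_type_map: dict[int, str]
    edge_type_map: dict[tuple[int, int], tuple[str, str]]
    adjacency: dict[int, set[int]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int) -> set[int]:
        return self.adjacency.get(v, set())

    def degrees(self) -> np.ndarray:
        return np.array([len(self.adjacency.get(i, ())) for i in range(self.n_nodes)])

    def adjacency_matrix(self) -> sp.csr_matrix:
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols = [], []
        for u, v in self.edges:
            rows += [u, v]
            cols += [v, u]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def pair_types(self) -> list[str]:
        return sorted({n.pair_type for n in self.nodes})

    def nodes_of_type(self, pair_type: str) -> list[EntityPairNode]:
        return [n for n in self.nodes if n.pair_type == pair_type]

    def labeled_nodes(self, pair_type: str) -> list[tuple[int, int]]:
        """(node_id, label) for labelled nodes of one task."""
        return [
            (n.node_id, int(n.label))
            for n in self.nodes
            if n.pair_type == pair_type and n.label is not None
        ]

    def strip_labels(self) -> "HeteroPairGraph":
        nodes = [
            EntityPairNode(n.node_id, n.entity_a, n.entity_b, n.pair_type, None)
            for n in self.nodes
        ]
        return HeteroPairGraph(
            nodes, set(self.edges), dict(self.node_type_map),
            dict(self.edge_type_map),
            {k: set(v) for k, v in self.adjacency.items()},
        )

    # ----- serialization --------------------------------------------------
    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        node_rows = [
            {
                "node_id": n.node_id,
                "entity_a_id": n.entity_a.id,
                "entity_a_type": n.entity_a.etype,
                "entity_b_id": n.entity_b.id,
                "entity_b_type": n.entity_b.etype,
                "pair_type": n.pair_type,
                "label": "" if n.label is None else int(n.label),
            }
            for n in self.nodes
        ]
        edge_rows = [{"u": u, "v": v} for u, v in sorted(self.edges)]
        return pd.DataFrame(node_rows), pd.DataFrame(edge_rows, columns=["u", "v"])

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        node_table, edge_table = self.to_tables()
        node_table.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        edge_table.to_csv(outdir / "edges.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "HeteroPairGraph":
        indir = Path(indir)
        node_table = pd.read_csv(indir / "nodes.tsv", sep="\t", dtype=str)
        edge_table = pd.read_csv(indir / "edges.tsv", sep="\t")
        nodes = []
        for row in node_table.itertuples(index=False):
            label = None
            if isinstance(row.label, str) and row.label != "" or (
                not isinstance(row.label, str) and pd.notna(row.label)
            ):
                label = int(float(row.label))
            nodes.append(
                EntityPairNode(
                    int(row.node_id),
                    Entity(str(row.entity_a_id), str(row.entity_a_type)),
                    Entity(str(row.entity_b_id), str(row.entity_b_type)),
                    str(row.pair_type),
                    label,
                )
            )
        nodes.sort(key=lambda n: n.node_id)
        graph = connect_shared_entity(nodes)
        expected = {(int(r.u), int(r.v)) for r in edge_table.itertuples(index=False)}
        if expected != graph.edges:  # pragma: no cover - corrupted input
            raise ValueError("edge table inconsistent with shared-entity rule")
        return graph


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated interaction schema (label column optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    return df


def build_pair_nodes(
    interactions: pd.DataFrame,
    per_type_cap: int = 10_000,
    seed: int = 0,
    entity_types: Iterable[str] = DEFAULT_ENTITY_TYPES,
) -> list[EntityPairNode]:
    """Create pair nodes from an interaction table.

    Unordered duplicates are collapsed (the first occurrence's label is kept)
    and, per interaction type, at most ``per_type_cap`` pairs are retained by
    seeded uniform subsampling without replacement. Node ids are assigned
    densely from 0, iterating interaction types in sorted order.
    """
    if len(interactions) == 0:
        raise ValueError("empty interaction table")
    if per_type_cap < 1:
        raise ValueError("per_type_cap must be >= 1")
    vocab = set(entity_types)
    has_label = "label" in interactions.columns

    by_type: dict[str, dict[tuple, Optional[int]]] = {}
    for i, row in enumerate(interactions.itertuples(index=False)):
        a = Entity(str(row.entity_a_id), str(row.entity_a_type))
        b = Entity(str(row.entity_b_id), str(row.entity_b_type))
        for e in (a, b):
            if e.etype not in vocab:
                raise SchemaError(f"row {i}: unknown entity type {e.etype!r}")
        a, b = canonical_pair(a, b)
        itype = str(row.interaction_type)
        label = None
        if has_label:
            raw = getattr(row, "label")
            if raw not in ("", None) and not (isinstance(raw, float) and np.isnan(raw)):
                label = int(float(raw))
        by_type.setdefault(itype, {}).setdefault((a, b), label)

    rng = np.random.default_rng(seed)
    nodes: list[EntityPairNode] = []
    for itype in sorted(by_type):
        pairs = list(by_type[itype].items())
        if len(pairs) > per_type_cap:
            idx = rng.choice(len(pairs), size=per_type_cap, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        for (a, b), label in pairs:
            nodes.append(
                EntityPairNode(len(nodes), a, b, pair_type_of(a, b), label)
            )
    return nodes


def connect_shared_entity(nodes: list[EntityPairNode]) -> HeteroPairGraph:
    """Join every two pair nodes that share >= 1 component entity.

    Edges are found by hashing each entity to its incident node list, so the
    cost is linear in nodes plus output edges rather than quadratic in nodes.
    """
    incident: dict[Entity, list[int]] = {}
    for node in nodes:
        for e in node.entities:
            incident.setdefault(e, []).append(node.node_id)

    edges: set[tuple[int, int]] = set()
    for ids in incident.values():
        for u, v in combinations(ids, 2):
            if u != v:
                edges.add((u, v) if u < v else (v, u))

    adjacency: dict[int, set[int]] = {n.node_id: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    node_type_map = {n.node_id: n.pair_type for n in nodes}
    edge_type_map = {
        (u, v): (node_type_map[u], node_type_map[v]) for u, v in edges
    }
    return HeteroPairGraph(list(nodes), edges, node_type_map, edge_type_map, adjacency)


def build_graph(
    interactions: pd.DataFrame,
    per_type_cap: int = 10_000,
    seed: int = 0,
    entity_types: Iterable[str] = DEFAULT_ENTITY_TYPES,
) -> HeteroPairGraph:
    """Pair-node sampling followed by shared-entity edge construction."""
    return connect_shared_entity(
        build_pair_nodes(interactions, per_type_cap, seed, entity_types)
    )


def graph_summary(graph: HeteroPairGraph) -> dict:
    degrees = graph.degrees()
    per_type: dict[str, int] = {}
    for n in graph.nodes:
        per_type[n.pair_type] = per_type.get(n.pair_type, 0) + 1
    hist: dict[int, int] = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "nodes_per_type": per_type,
        "degree_distribution": hist,
    }


def graph_digest(graph: HeteroPairGraph) -> str:
    """Stable digest of the full graph content (used in provenance records)."""
    h = hashlib.sha256()
    for n in graph.nodes:
        h.update(
            f"{n.node_id}|{n.entity_a}|{n.entity_b}|{n.pair_type}|{n.label}".encode()
        )
    for u, v in sorted(graph.edges):
        h.update(f"{u}-{v}".encode())
    return h.hexdigest()
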