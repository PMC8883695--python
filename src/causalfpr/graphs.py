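"""Directed acyclic graphs, d-separation, and adjustment-set search.

A :class:`Dag` is the qualitative part of a structural causal model: nodes
are observable variables, edges point from cause to effect.  Error terms of
a Markovian model are *not* nodes -- their mutual independence is encoded by
their absence, so adjustment sets range over observable nodes only.

d-separation is the graphical criterion under which a conditioning set
blocks every path between two nodes, implying conditional independence (a
vanishing partial regression coefficient) in every compatible linear
Markovian model.  The single-door and backdoor criteria identify,
respectively, a single edge coefficient and a total effect with a partial
regression coefficient; both are found here by exhaustive minimal-cardinality
search, which is exact and deterministic at the motif sizes this package
works with (<= 4 observable nodes).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "Dag",
    "Path",
    "NodeNotFoundError",
    "EdgeNotFoundError",
    "d_separated",
    "enumerate_paths",
    "directed_paths",
    "single_door_set",
    "backdoor_set",
]

Node = str
Edge = tuple[Node, Node]


class NodeNotFoundError(KeyError):
    """A queried node is not declared in the graph."""


class EdgeNotFoundError(KeyError):
    """A queried edge is not present in the graph."""


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named observable nodes.

    Parameters
    ----------
    nodes
        Ordered node labels.  Order is preserved and defines column order
        for simulated samples.
    edges
        Ordered ``(parent, child)`` pairs.

    Raises
    ------
    ValueError
        On duplicate nodes/edges, self-loops, undeclared endpoints, or a
        directed cycle.
    """

    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Sequence[Node]]):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple((u, v) for u, v in edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        declared = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in declared or v not in declared:
                raise ValueError(f"edge ({u!r}, {v!r}) has undeclared endpoint")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")

    # -- basic accessors ---------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: Node) -> tuple[Node, ...]:
        self._require(node)
        return tuple(u for u, v in self.edges if v == node)

    def children(self, node: Node) -> tuple[Node, ...]:
        self._require(node)
        return tuple(v for u, v in self.edges if u == node)

    def descendants(self, node: Node) -> frozenset[Node]:
        """Strict descendants (excluding the node itself)."""
        self._require(node)
        return frozenset(nx.descendants(self.to_networkx(), node))

    def has_edge(self, parent: Node, child: Node) -> bool:
        return (parent, child) in set(self.edges)

    def _require(self, *nodes: Node) -> None:
        for n in nodes:
            if n not in self.nodes:
                raise NodeNotFoundError(f"unknown node {n!r}")

    # -- pure-functional edits --------------------------------------------

    def without_edge(self, parent: Node, child: Node) -> "Dag":
        if (parent, child) not in self.edges:
            raise EdgeNotFoundError(f"edge ({parent!r}, {child!r}) not in graph")
        return Dag(self.nodes, tuple(e for e in self.edges if e != (parent, child)))

    def with_edge(self, parent: Node, child: Node) -> "Dag":
        """Return a copy with the edge added (no-op if already present)."""
        if (parent, child) in self.edges:
            return self
        return Dag(self.nodes, self.edges + ((parent, child),))

    def topological_order(self) -> tuple[Node, ...]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return tuple(order)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "edges": [list(e) for e in self.edges]}

    @classmethod
    def from_dict(cls, doc: dict) -> "Dag":
        return cls(doc["nodes"], [tuple(e) for e in doc["edges"]])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "Dag":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class Path:
    """A simple path, stored as the node sequence plus edge orientations.

    ``forward[i]`` is True when the i-th traversed edge is
    ``nodes[i] -> nodes[i+1]`` and False when it is ``nodes[i] <- nodes[i+1]``.
    """

    nodes: tuple[Node, ...]
    forward: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("paths are simple: no repeated nodes")
        if len(self.forward) != len(self.nodes) - 1:
            raise ValueError("orientation length mismatch")

    def edges(self) -> tuple[Edge, ...]:
        """The traversed edges in their stored (parent, child) orientation."""
        out = []
        for i, fwd in enumerate(self.forward):
            u, v = self.nodes[i], self.nodes[i + 1]
            out.append((u, v) if fwd else (v, u))
        return tuple(out)

    def is_directed(self) -> bool:
        return all(self.forward)


def _undirected_adjacency(g: Dag) -> dict[Node, set[Node]]:
    adj: dict[Node, set[Node]] = {n: set() for n in g.nodes}
    for u, v in g.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def enumerate_paths(g: Dag, x: Node, y: Node) -> list[Path]:
    """All simple paths between ``x`` and ``y``, ignoring edge direction.

    Orientation of each traversed edge is recorded relative to the
    traversal from ``x`` to ``y``.  Output is sorted by node sequence, so the
    order is deterministic.
    """
    g._require(x, y)
    if x == y:
        raise ValueError("path endpoints must differ")
    adj = _undirected_adjacency(g)
    edge_set = set(g.edges)
    found: list[tuple[Node, ...]] = []

    def dfs(trail: list[Node]) -> None:
        here = trail[-1]
        if here == y:
            found.append(tuple(trail))
            return
        for nxt in sorted(adj[here]):
            if nxt not in trail:
                trail.append(nxt)
                dfs(trail)
                trail.pop()

    dfs([x])
    found.sort()
    paths = []
    for seq in found:
        fwd = tuple((seq[i], seq[i + 1]) in edge_set for i in range(len(seq) - 1))
        paths.append(Path(seq, fwd))
    return paths


def directed_paths(g: Dag, x: Node, y: Node) -> list[Path]:
    """All directed paths from ``x`` to ``y`` (every edge pointing toward y)."""
    return [p for p in enumerate_paths(g, x, y) if p.is_directed()]


def d_separated(g: Dag, x: Node, y: Node, z: Iterable[Node] = ()) -> bool:
    """Whether ``z`` d-separates ``x`` from ``y`` in ``g``.

    True iff every path between x and y is blocked: a chain or fork whose
    middle node is in z, or a collider whose middle node and all of its
    descendants are outside z.
    """
    zset = frozenset(z)
    g._require(x, y, *zset)
    if x == y:
        raise ValueError("d-separation requires two distinct nodes")
    if x in zset or y in zset:
        raise ValueError("conditioning set must not contain the queried nodes")
    return nx.is_d_separator(g.to_networkx(), {x}, {y}, set(zset))


def _candidate_sets(pool: Sequence[Node]) -> Iterator[frozenset[Node]]:
    """Subsets of ``pool`` by increasing cardinality, lexicographic within."""
    ordered = sorted(pool)
    for k in range(len(ordered) + 1):
        for combo in itertools.combinations(ordered, k):
            yield frozenset(combo)


def single_door_set(g: Dag, edge: Edge) -> frozenset[Node] | None:
    """Minimal single-door admissible set for the coefficient on ``edge``.

    A set Z identifies the coefficient on x -> y when Z contains no
    descendant of y and Z d-separates x from y in the graph with the edge
    deleted; then the coefficient equals the partial regression coefficient
    of x in the regression of y on {x} | Z.  Returns the smallest such set
    (ties broken lexicographically) or None when none exists among the
    observable nodes.
    """
    x, y = edge
    if (x, y) not in g.edges:
        raise EdgeNotFoundError(f"edge ({x!r}, {y!r}) not in graph")
    g_cut = g.without_edge(x, y)
    forbidden = g.descendants(y) | {x, y}
    pool = [n for n in g.nodes if n not in forbidden]
    for zset in _candidate_sets(pool):
        if d_separated(g_cut, x, y, zset):
            return zset
    return None


def backdoor_set(g: Dag, x: Node, y: Node) -> frozenset[Node] | None:
    """Minimal backdoor-admissible set for the total effect of x on y.

    Z must contain no descendant of x and must d-separate x from y in the
    subgraph with every edge leaving x removed (equivalently, block every
    backdoor path).  Returns the smallest admissible set, lexicographic
    tie-break, or None if no subset of observables qualifies.
    """
    g._require(x, y)
    if x == y:
        raise ValueError("backdoor query requires two distinct nodes")
    trimmed = Dag(g.nodes, tuple(e for e in g.edges if e[0] != x))
    forbidden = g.descendants(x) | {x, y}
    pool = [n for n in g.nodes if n not in forbidden]
    for zset in _candidate_sets(pool):
        if d_separated(trimmed, x, y, zset):
            return zset
    return None
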