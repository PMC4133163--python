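"""Core types: state-transition graphs, partitions into connected regions,
and the options each partition induces.

A problem domain is an undirected graph whose vertices are discrete states
and whose edges are atomic actions (deterministic, fully reversible
transitions, so each undirected edge stands for the two directed moves).  A
candidate behavioral hierarchy is a partition of the vertices into connected
regions; every region induces one option per *exit* vertex, following the
Hauskrecht-style region-interface construction:

* *entrances* of a region: vertices inside it with at least one neighbor
  outside;
* *exits* of a region: vertices outside it that receive at least one edge
  from a vertex inside it.

Each option drives through the region to one designated exit (its subgoal);
its initiation set is the region's entrances (plus, at parse time, the start
state of the current task).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

import networkx as nx

Edge = Tuple[str, str]


class GraphError(ValueError):
    """Raised for structurally invalid graphs."""


class PartitionError(ValueError):
    """Raised when a partition does not validate against its graph."""


def canonical_edge(u: str, v: str) -> Edge:
    """Undirected edge as an ordered pair (lexicographic)."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class StateGraph:
    """Undirected, connected, simple graph of discrete states.

    Vertex ids are opaque strings; every deterministic ordering in this
    package is by lexicographic vertex id.
    """

    adjacency: Mapping[str, FrozenSet[str]]

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str]]) -> "StateGraph":
        adj: Dict[str, set] = {}
        seen = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphError(f"self-loop at vertex {u!r}")
            e = canonical_edge(u, v)
            if e in seen:
                raise GraphError(f"duplicate edge {e!r}")
            seen.add(e)
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        if not adj:
            raise GraphError("empty graph")
        g = cls(adjacency={v: frozenset(ns) for v, ns in adj.items()})
        if not nx.is_connected(g.to_networkx()):
            raise GraphError("graph is not connected")
        return g

    @property
    def vertices(self) -> FrozenSet[str]:
        return frozenset(self.adjacency)

    @property
    def edges(self) -> FrozenSet[Edge]:
        return frozenset(
            canonical_edge(u, v) for u, ns in self.adjacency.items() for v in ns
        )

    def sorted_vertices(self) -> List[str]:
        return sorted(self.adjacency)

    def sorted_edges(self) -> List[Edge]:
        return sorted(self.edges)

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.adjacency.get(u, ())

    def neighbors(self, v: str) -> FrozenSet[str]:
        return self.adjacency[v]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adjacency)
        g.add_edges_from(self.edges)
        return g

    def __len__(self) -> int:
        return len(self.adjacency)


@dataclass(frozen=True)
class Partition:
    """Assignment of every vertex to exactly one region.

    Region labels are canonicalized to ``0..R-1`` ordered by the smallest
    vertex id each region contains, so partitions compare by equality
    regardless of how they were encoded.
    """

    assignment: Mapping[str, int]

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, object]) -> "Partition":
        """Build from any vertex -> hashable-label mapping (labels recoded)."""
        groups: Dict[object, List[str]] = {}
        for v, lab in assignment.items():
            groups.setdefault(lab, []).append(str(v))
        ordered = sorted(groups.values(), key=lambda vs: min(vs))
        canon = {v: i for i, vs in enumerate(ordered) for v in vs}
        return cls(assignment=canon)

    @classmethod
    def from_regions(cls, regions: Iterable[Iterable[str]]) -> "Partition":
        assignment: Dict[str, int] = {}
        for i, vs in enumerate(regions):
            for v in vs:
                if v in assignment:
                    raise PartitionError(f"vertex {v!r} assigned to two regions")
                assignment[v] = i
        return cls.from_assignment(assignment)

    @classmethod
    def flat(cls, graph: StateGraph) -> "Partition":
        return cls(assignment={v: 0 for v in graph.adjacency})

    @property
    def regions(self) -> Dict[int, FrozenSet[str]]:
        out: Dict[int, set] = {}
        for v, r in self.assignment.items():
            out.setdefault(r, set()).add(v)
        return {r: frozenset(vs) for r, vs in out.items()}

    @property
    def num_regions(self) -> int:
        return len(set(self.assignment.values()))

    def region_of(self, v: str) -> int:
        return self.assignment[v]

    def key(self) -> Tuple[int, ...]:
        """Canonical hashable key (labels in sorted-vertex order)."""
        return tuple(self.assignment[v] for v in sorted(self.assignment))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.assignment.items())))


@dataclass(frozen=True)
class OptionSpec:
    """One option: drive through ``region`` to the exit ``subgoal``.

    ``termination`` holds all exits of the region; the option's own target is
    the single exit ``subgoal``.  ``initiation_core`` is the region's
    entrance set; the current task's start vertex is added at parse time.
    """

    region: int
    subgoal: str
    initiation_core: FrozenSet[str]
    termination: FrozenSet[str]
    policy_domain: FrozenSet[str]

    @property
    def option_id(self) -> Tuple[int, str]:
        return (self.region, self.subgoal)

    def __post_init__(self) -> None:
        if self.subgoal not in self.termination:
            raise ValueError("subgoal must be a member of the termination set")
        if not self.initiation_core <= self.policy_domain:
            raise ValueError("initiation_core must lie inside the policy domain")
        if self.termination & self.policy_domain:
            raise ValueError("termination set must be disjoint from the region")


def validate_partition(graph: StateGraph, partition: Partition) -> Partition:
    """Check coverage and per-region connectivity; return canonicalized copy.

    Raises :class:`PartitionError` naming the offending region or vertex.
    """
    assigned = set(partition.assignment)
    missing = graph.vertices - assigned
    if missing:
        raise PartitionError(f"vertices missing from partition: {sorted(missing)}")
    unknown = assigned - graph.vertices
    if unknown:
        raise PartitionError(f"unknown vertices in partition: {sorted(unknown)}")
    canon = Partition.from_assignment(partition.assignment)
    gnx = graph.to_networkx()
    for r, vs in sorted(canon.regions.items()):
        if len(vs) > 1 and not nx.is_connected(gnx.subgraph(vs)):
            raise PartitionError(
                f"region {r} ({sorted(vs)}) does not induce a connected subgraph"
            )
    return canon


def region_boundary(
    graph: StateGraph, partition: Partition, region: int
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Entrance and exit vertex sets of one region.

    For a single-region (flat) partition both sets are empty.
    """
    regions = partition.regions
    if region not in regions:
        raise PartitionError(f"unknown region label {region!r}")
    inside = regions[region]
    entrances = frozenset(
        v for v in inside if any(u not in inside for u in graph.neighbors(v))
    )
    exits = frozenset(
        u for v in inside for u in graph.neighbors(v) if u not in inside
    )
    return entrances, exits


def induce_options(graph: StateGraph, partition: Partition) -> List[OptionSpec]:
    """One option per (region, exit) pair, sorted by (region label, subgoal).

    A flat partition induces no options.
    """
    partition = validate_partition(graph, partition)
    options: List[OptionSpec] = []
    for r, inside in sorted(partition.regions.items()):
        entrances, exits = region_boundary(graph, partition, r)
        for e in sorted(exits):
            options.append(
                OptionSpec(
                    region=r,
                    subgoal=e,
                    initiation_core=entrances,
                    termination=exits,
                    policy_domain=inside,
                )
            )
    return options


def partition_from_edge_mask(
    graph: StateGraph, mask: Mapping[Edge, bool]
) -> Partition:
    """Partition whose regions are the components of the 'on'-edge subgraph.

    This is the binary-integer encoding of the partition search space: one
    bit per edge, vertices incident to no 'on' edge become singletons.
    """
    edges = graph.edges
    mask_keys = {canonical_edge(*e) for e in mask}
    missing = edges - mask_keys
    if missing:
        raise PartitionError(f"mask missing edges: {sorted(missing)[:5]}")
    parent: Dict[str, str] = {v: v for v in graph.adjacency}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e, on in mask.items():
        if on:
            u, v = canonical_edge(*e)
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return Partition.from_assignment({v: find(v) for v in graph.adjacency})
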