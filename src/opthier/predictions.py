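"""Experimental predictions derived from an optimal partition.

Two kinds of behavioral prediction follow from an evidence-optimal
decomposition: (1) *bus-stop* predictions -- the option subgoal vertices
(typically topological bottlenecks) are where an agent planning
hierarchically should place a shortcut destination; (2) *path-preference*
predictions -- among tied shortest paths, an agent planning at the level
of regions should prefer the path crossing the fewest region boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from opthier.graph_domain import Partition, StateGraph, induce_options
from opthier.search import SearchResult
from opthier.task_ensemble import EnsembleData


@dataclass(frozen=True)
class Prediction:
    """A ranked-vertex or chosen-path prediction with provenance."""

    kind: str  # "bus_stop" | "path_preference"
    payload: tuple
    provenance: str


def bus_stop_ranking(
    graph: StateGraph,
    ensemble: EnsembleData,
    search_result: SearchResult,
) -> List[str]:
    """Vertices ranked by their prominence as optimal subgoals.

    Vertices appearing as option subgoals in any tie-optimal partition
    come first, ranked by the number of (tie-optimal partition, option)
    pairs naming them; the remaining vertices follow, ranked by the best
    evidence among evaluated partitions naming them as a subgoal (vertices
    never named rank last).  If the optimum is the flat partition the
    ranking is uniform (flagged by an empty leading group upstream).
    """
    counts: Dict[str, int] = {}
    for p in search_result.best_partitions:
        for o in induce_options(graph, p):
            counts[o.subgoal] = counts.get(o.subgoal, 0) + 1
    optimal_group = sorted(counts, key=lambda v: (-counts[v], v))
    rest = [v for v in graph.sorted_vertices() if v not in counts]
    best_named = search_result.subgoal_best_score
    rest.sort(key=lambda v: (-best_named.get(v, float("-inf")), v))
    return optimal_group + rest


def boundary_crossings(
    path: Sequence[str],
    partition: Partition,
    graph: Optional[StateGraph] = None,
) -> int:
    """Number of consecutive path steps joining different regions.

    If ``graph`` is supplied, consecutive vertices must be adjacent.
    """
    if graph is not None:
        for a, b in zip(path, path[1:]):
            if not graph.has_edge(a, b):
                raise ValueError(f"path step ({a!r} -> {b!r}) is not an edge")
    return sum(
        1
        for a, b in zip(path, path[1:])
        if partition.region_of(a) != partition.region_of(b)
    )


@dataclass(frozen=True)
class PathPreference:
    """All tied shortest paths with crossing counts and the preferred ones."""

    chosen: Tuple[Tuple[str, ...], ...]
    tied_paths: Tuple[Tuple[str, ...], ...]
    crossings: Tuple[int, ...]
    tie_flag: bool  # multiple paths attain the minimum crossing count


def tied_path_preference(
    graph: StateGraph,
    partition: Partition,
    start: str,
    goal: str,
) -> PathPreference:
    """Among all unweighted shortest paths, prefer fewest boundary crossings.

    Enumerates every shortest path from start to goal, counts region
    boundary crossings for each, and returns the path(s) minimizing the
    count (ties reported via ``tie_flag``).
    """
    gnx = graph.to_networkx()
    paths = [tuple(p) for p in nx.all_shortest_paths(gnx, start, goal)]
    paths.sort()
    crossings = tuple(boundary_crossings(p, partition) for p in paths)
    lo = min(crossings)
    chosen = tuple(p for p, c in zip(paths, crossings) if c == lo)
    return PathPreference(
        chosen=chosen,
        tied_paths=tuple(paths),
        crossings=crossings,
        tie_flag=len(chosen) > 1,
    )


def find_crossing_asymmetric_pairs(
    graph: StateGraph,
    partition: Partition,
    counts: Tuple[int, int] = (1, 2),
) -> List[Tuple[str, str]]:
    """(start, goal) pairs with exactly two tied shortest paths whose
    boundary-crossing counts are exactly ``counts`` (in any order).

    Used to locate the Tower-of-Hanoi style problems where two equal-length
    solutions differ in how many region boundaries they traverse.
    """
    want = tuple(sorted(counts))
    gnx = graph.to_networkx()
    out = []
    verts = graph.sorted_vertices()
    for s in verts:
        for g in verts:
            if s >= g:
                continue
            paths = list(nx.all_shortest_paths(gnx, s, g))
            if len(paths) != 2:
                continue
            cs = tuple(
                sorted(boundary_crossings(p, partition) for p in paths)
            )
            if cs == want:
                out.append((s, g))
    return out
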