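"""Target-behavior construction: frozen-noise edge costs, consistent unique
all-pairs shortest paths, betweenness-matched path-set selection, and the
concatenated state-action data stream.

The task ensemble is the set of all ordered start-goal shortest-path
problems on the graph.  Traversing any edge incurs a strictly negative
reward drawn once (frozen) per edge; the small noise around a unit cost
breaks ties so that exactly one shortest path exists per ordered pair and
the same route is followed between any two vertices regardless of task --
the consistency needed for deterministic option policies to transfer
across tasks.

Because a path choice can channel behavior across a few edges and create
spurious "behavioral bottlenecks", the selected path set is the one (out of
a sample of frozen-noise draws) whose per-edge usage statistics are closest,
in Euclidean distance, to the unweighted edge-betweenness statistics of the
graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from heapq import heappop, heappush
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from opthier.graph_domain import Edge, StateGraph, canonical_edge

logger = logging.getLogger(__name__)

#: Relative tolerance for declaring two path costs tied.
TIE_RTOL = 1e-9

#: How many derived seeds to try before giving up on a tie-free draw.
MAX_REDRAWS = 64


class TieError(ValueError):
    """Raised when edge weights admit tied shortest paths; resample."""


@dataclass(frozen=True)
class EdgeWeights:
    """Frozen-noise edge costs: one strictly negative reward per edge."""

    cost: Mapping[Edge, float]
    seed: int

    def length(self, u: str, v: str) -> float:
        """Positive traversal length (negated reward) for Dijkstra."""
        return -self.cost[canonical_edge(u, v)]


@dataclass(frozen=True)
class PathSet:
    """Exactly one shortest path per ordered (start, goal) pair.

    Invariants (asserted in :func:`all_pairs_unique_paths`): each stored
    path is shortest under ``weights_used``; ``paths[(g, s)]`` is the
    reverse of ``paths[(s, g)]``; and every contiguous subpath of a stored
    path equals the stored path between its endpoints.
    """

    paths: Mapping[Tuple[str, str], Tuple[str, ...]]
    weights_used: EdgeWeights

    def path(self, s: str, g: str) -> Tuple[str, ...]:
        return self.paths[(s, g)]

    def edge_usage(self) -> Dict[Edge, int]:
        """Number of unordered vertex pairs whose path traverses each edge."""
        usage: Dict[Edge, int] = {}
        for (s, g), p in self.paths.items():
            if s < g:  # count each unordered pair once
                for a, b in zip(p, p[1:]):
                    e = canonical_edge(a, b)
                    usage[e] = usage.get(e, 0) + 1
        return usage


@dataclass(frozen=True)
class EnsembleData:
    """Ordered tasks with target trajectories and task-boundary markers.

    ``trajectories[i]`` is the list of (state, action) pairs for task
    ``tasks[i]``, where the action is the successor state.  ``boundaries``
    gives the index, in the concatenated element stream, at which each task
    begins; the markers delimit tasks and carry no state-action content.
    """

    tasks: Tuple[Tuple[str, str], ...]
    trajectories: Tuple[Tuple[Tuple[str, str], ...], ...]
    boundaries: Tuple[int, ...]

    @property
    def num_tasks(self) -> int:
        return len(self.tasks)

    def total_elements(self) -> int:
        return sum(len(t) for t in self.trajectories)


def _derive_seed(seed: int, stream: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed) % (2**31), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def sample_edge_costs(
    graph: StateGraph,
    seed: int,
    lo: float = -1.05,
    hi: float = -0.95,
) -> EdgeWeights:
    """One i.i.d. uniform(lo, hi) cost per edge, redrawn until tie-free.

    The draw is reproducible from ``seed``; if the all-pairs unique
    shortest-path check fails, a derived seed is used for the next attempt.
    """
    if not (lo < hi < 0):
        raise ValueError(f"need lo < hi < 0, got lo={lo}, hi={hi}")
    edges = graph.sorted_edges()
    for attempt in range(MAX_REDRAWS):
        rng = np.random.default_rng(_derive_seed(seed, attempt))
        draws = lo + (hi - lo) * rng.random(len(edges))
        weights = EdgeWeights(
            cost={e: float(c) for e, c in zip(edges, draws)}, seed=seed
        )
        try:
            _unique_predecessors_all_sources(graph, weights)
        except TieError:
            continue
        return weights
    raise TieError(
        f"no tie-free edge costs found for seed {seed} after {MAX_REDRAWS} redraws"
    )


def _unique_predecessors_all_sources(
    graph: StateGraph, weights: EdgeWeights
) -> Dict[str, Dict[str, str]]:
    """Dijkstra from every source; error on any tied shortest path.

    Returns ``pred[source][v]`` = unique predecessor of v on the shortest
    path from source.  A tie exists iff some vertex has two neighbors both
    attaining ``dist[v] == dist[u] + length(u, v)`` within tolerance.
    """
    out: Dict[str, Dict[str, str]] = {}
    verts = graph.sorted_vertices()
    for s in verts:
        dist: Dict[str, float] = {s: 0.0}
        done: Dict[str, float] = {}
        heap: List[Tuple[float, str]] = [(0.0, s)]
        while heap:
            d, v = heappop(heap)
            if v in done:
                continue
            done[v] = d
            for u in graph.neighbors(v):
                nd = d + weights.length(v, u)
                if u not in dist or nd < dist[u]:
                    dist[u] = nd
                    heappush(heap, (nd, u))
        pred: Dict[str, str] = {}
        for v in verts:
            if v == s:
                continue
            d = done[v]
            cands = [
                u
                for u in graph.neighbors(v)
                if abs(done[u] + weights.length(u, v) - d) <= TIE_RTOL * max(1.0, d)
            ]
            if len(cands) != 1:
                raise TieError(
                    f"tied shortest paths into {v!r} from source {s!r}; "
                    "resample the edge costs"
                )
            pred[v] = cands[0]
        out[s] = pred
    return out


def all_pairs_unique_paths(graph: StateGraph, weights: EdgeWeights) -> PathSet:
    """The unique shortest path for every ordered pair under tie-free weights.

    Raises :class:`TieError` (instructing a resample) if any tie is
    detected.  Reversal symmetry and subpath consistency -- automatic for
    unique shortest paths in an undirected graph -- are asserted.
    """
    preds = _unique_predecessors_all_sources(graph, weights)
    verts = graph.sorted_vertices()
    paths: Dict[Tuple[str, str], Tuple[str, ...]] = {}
    for s in verts:
        pred = preds[s]
        for g in verts:
            if g == s:
                continue
            rev = [g]
            v = g
            while v != s:
                v = pred[v]
                rev.append(v)
            paths[(s, g)] = tuple(reversed(rev))
    for (s, g), p in paths.items():
        assert paths[(g, s)] == tuple(reversed(p)), "reversal symmetry violated"
    return PathSet(paths=paths, weights_used=weights)


def edge_betweenness_all(graph: StateGraph) -> Dict[Edge, float]:
    """Unweighted edge betweenness over all-pairs shortest paths.

    Fractional credit is split equally among tied shortest paths; pairs are
    unordered (each contributes once).  Deterministic.
    """
    bc = nx.edge_betweenness_centrality(graph.to_networkx(), normalized=False)
    return {canonical_edge(u, v): float(b) for (u, v), b in bc.items()}


def _normalize(vec: np.ndarray) -> np.ndarray:
    total = vec.sum()
    return vec / total if total > 0 else vec


def select_path_set(
    graph: StateGraph,
    n_samples: int,
    seed: int,
    normalize: bool = True,
) -> PathSet:
    """Betweenness-matched consistent path set.

    Draws ``n_samples`` frozen-noise weight vectors, computes each
    candidate PathSet's per-edge usage counts, and returns the candidate
    minimizing the Euclidean distance between the (L1-normalized, unless
    ``normalize=False``) usage vector and the all-paths edge-betweenness
    vector.  Ties broken by lowest sample index.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    edges = graph.sorted_edges()
    target = np.array([edge_betweenness_all(graph)[e] for e in edges])
    if normalize:
        target = _normalize(target)
    best: Optional[PathSet] = None
    best_dist = float("inf")
    for k in range(n_samples):
        weights = sample_edge_costs(graph, _derive_seed(seed, 1000 + k))
        ps = all_pairs_unique_paths(graph, weights)
        usage = ps.edge_usage()
        vec = np.array([float(usage.get(e, 0)) for e in edges])
        if normalize:
            vec = _normalize(vec)
        dist = float(np.linalg.norm(vec - target))
        if dist < best_dist:
            best, best_dist = ps, dist
    logger.info(
        "select_path_set: %d samples, achieved betweenness-match distance %.6g",
        n_samples,
        best_dist,
    )
    assert best is not None
    return best


def trajectory_from_path(path: Sequence[str]) -> Tuple[Tuple[str, str], ...]:
    """State-action transcription of a vertex sequence."""
    return tuple((path[i], path[i + 1]) for i in range(len(path) - 1))


def build_ensemble(
    path_set: PathSet,
    order_seed: int,
    tasks: Optional[Sequence[Tuple[str, str]]] = None,
) -> EnsembleData:
    """All ordered (s, g) tasks (s != g) in a seed-shuffled order.

    ``tasks``, if given, overrides the all-pairs default (a user-supplied
    task list; each task must have a stored path).
    """
    if tasks is None:
        task_list = sorted(path_set.paths)
    else:
        task_list = [(s, g) for s, g in tasks]
    rng = np.random.default_rng(_derive_seed(order_seed, 2))
    order = rng.permutation(len(task_list))
    task_list = [task_list[i] for i in order]
    trajectories = []
    boundaries = []
    pos = 0
    for s, g in task_list:
        traj = trajectory_from_path(path_set.path(s, g))
        boundaries.append(pos)
        trajectories.append(traj)
        pos += len(traj)
    return EnsembleData(
        tasks=tuple(task_list),
        trajectories=tuple(trajectories),
        boundaries=tuple(boundaries),
    )
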