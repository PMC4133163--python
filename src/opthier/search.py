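"""Search for the evidence-maximizing partition.

The search space is encoded as binary edge masks (one bit per edge; the
connected components of the 'on'-edge subgraph are the regions), so many
masks map to one partition and fitness is cached by canonical partition.
Small graphs are searched exhaustively; larger ones with a seeded genetic
algorithm (tournament selection, uniform crossover, per-bit mutation,
halting on stagnation, restarted from fresh populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Dict, List, Optional, Tuple

import numpy as np

from opthier.evidence import EnsembleIndex, codelength_bits_fast, log_evidence
from opthier.graph_domain import (
    Partition,
    StateGraph,
    induce_options,
    partition_from_edge_mask,
)
from opthier.task_ensemble import EnsembleData

logger = logging.getLogger(__name__)

#: Two partitions whose log2-evidence differs by less than this are tied.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Genetic-algorithm and guard settings.

    The desk-scale defaults (population 200, 10 restarts) keep runs quick;
    ``full_scale()`` returns heavy-duty settings (population 2000,
    stagnation 20, hundreds of restarts) for overnight searches.
    """

    method: str = "ga"  # "exhaustive" | "ga"
    population: int = 200
    stagnation_generations: int = 20
    restarts: int = 10
    seed: int = 0
    max_edges_exhaustive: int = 18
    tournament_k: int = 3
    crossover_rate: float = 0.9
    elitism: int = 2

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.stagnation_generations < 1:
            raise ValueError("stagnation_generations must be >= 1")

    @classmethod
    def full_scale(cls, restarts: int = 500, seed: int = 0) -> "SearchConfig":
        return cls(population=2000, stagnation_generations=20,
                   restarts=restarts, seed=seed)


@dataclass
class SearchResult:
    """Best-scoring partition(s) and search diagnostics.

    ``best_partitions`` holds every evaluated partition within TIE_TOL of
    the best score.  ``subgoal_best_score`` maps each vertex to the best
    log2-evidence among evaluated partitions in which the vertex appears
    as an option subgoal (used by the bus-stop ranking).
    """

    best_partitions: List[Partition]
    best_log2_evidence: float
    evaluations: int
    history: List[List[float]]
    method: str
    subgoal_best_score: Dict[str, float] = field(default_factory=dict)


class _Scorer:
    """Cached fitness: canonical partition key -> log2 evidence."""

    def __init__(self, graph: StateGraph, ensemble: EnsembleData):
        self.graph = graph
        self.index = EnsembleIndex(graph, ensemble)
        self.verts = graph.sorted_vertices()
        self.cache: Dict[Tuple[int, ...], float] = {}
        self.partitions: Dict[Tuple[int, ...], Partition] = {}
        self.subgoal_best: Dict[str, float] = {}
        self.evaluations = 0

    def score_partition(self, p: Partition) -> float:
        key = p.key()
        if key in self.cache:
            return self.cache[key]
        bits = codelength_bits_fast(
            self.index, [p.assignment[v] for v in self.verts]
        )
        score = -bits
        self.cache[key] = score
        self.partitions[key] = p
        self.evaluations += 1
        for o in induce_options(self.graph, p):
            prev = self.subgoal_best.get(o.subgoal)
            if prev is None or score > prev:
                self.subgoal_best[o.subgoal] = score

        return score

    def score_mask_bits(self, bits: np.ndarray, edges) -> float:
        mask = {e: bool(b) for e, b in zip(edges, bits)}
        return self.score_partition(partition_from_edge_mask(self.graph, mask))

    def result(self, method: str, history: List[List[float]]) -> SearchResult:
        best = max(self.cache.values())
        ties = [
            self.partitions[k]
            for k, s in self.cache.items()
            if s >= best - TIE_TOL
        ]
        ties.sort(key=lambda p: p.key())
        return SearchResult(
            best_partitions=ties,
            best_log2_evidence=best,
            evaluations=self.evaluations,
            history=history,
            method=method,
            subgoal_best_score=dict(self.subgoal_best),
        )


def exhaustive_search(
    graph: StateGraph,
    ensemble: EnsembleData,
    max_edges: int = 18,
) -> SearchResult:
    """Score every partition reachable by a binary edge mask.

    Enumerates all 2^|E| masks, deduplicating identical partitions, and
    returns every argmax partition.  Guarded by ``max_edges``.
    """
    edges = graph.sorted_edges()
    if len(edges) > max_edges:
        raise ValueError(
            f"{len(edges)} edges exceeds the exhaustive guard ({max_edges}); "
            "use ga_search"
        )
    scorer = _Scorer(graph, ensemble)
    for bits in iproduct((0, 1), repeat=len(edges)):
        mask = dict(zip(edges, bits))
        scorer.score_partition(partition_from_edge_mask(graph, mask))
    res = scorer.result("exhaustive", history=[])
    _verify_best(graph, ensemble, res)
    return res


def ga_search(
    graph: StateGraph,
    ensemble: EnsembleData,
    config: Optional[SearchConfig] = None,
) -> SearchResult:
    """Genetic algorithm over binary edge masks; fully seeded.

    Per restart: a fresh random population evolves by tournament
    selection, uniform crossover and per-bit mutation (rate 1/|E|), with
    elitism, halting when the restart's best fitness is unchanged for
    ``stagnation_generations`` generations.  Ties are collected across all
    evaluated partitions.
    """
    cfg = config or SearchConfig()
    edges = graph.sorted_edges()
    n = len(edges)
    scorer = _Scorer(graph, ensemble)
    rng = np.random.default_rng(cfg.seed % (2**31))
    mut_rate = 1.0 / n
    history: List[List[float]] = []

    for restart in range(cfg.restarts):
        pop = (rng.random((cfg.population, n)) < 0.5).astype(np.int8)
        fitness = np.array(
            [scorer.score_mask_bits(ind, edges) for ind in pop]
        )
        best_fit = float(fitness.max())
        stagnant = 0
        curve = [best_fit]
        while stagnant < cfg.stagnation_generations:
            order = np.argsort(fitness)[::-1]
            elite = pop[order[: cfg.elitism]].copy()
            children = [e for e in elite]
            while len(children) < cfg.population:
                # tournament selection of two parents
                parents = []
                for _ in range(2):
                    idx = rng.integers(0, cfg.population, cfg.tournament_k)
                    parents.append(pop[idx[np.argmax(fitness[idx])]])
                a, b = parents
                if rng.random() < cfg.crossover_rate:
                    cross = rng.random(n) < 0.5
                    child = np.where(cross, a, b)
                else:
                    child = a.copy()
                flip = rng.random(n) < mut_rate
                child = np.bitwise_xor(child, flip.astype(np.int8))
                children.append(child)
            pop = np.array(children)
            fitness = np.array(
                [scorer.score_mask_bits(ind, edges) for ind in pop]
            )
            gen_best = float(fitness.max())
            if gen_best > best_fit + TIE_TOL:
                best_fit = gen_best
                stagnant = 0
            else:
                stagnant += 1
            curve.append(best_fit)
        history.append(curve)
        logger.info(
            "ga_search restart %d/%d: best %.6f after %d generations",
            restart + 1, cfg.restarts, best_fit, len(curve) - 1,
        )
    res = scorer.result("ga", history=history)
    _verify_best(graph, ensemble, res)
    return res


def _verify_best(
    graph: StateGraph, ensemble: EnsembleData, result: SearchResult
) -> None:
    """Recompute the winner's evidence with the full (ledger) scorer."""
    check = log_evidence(graph, result.best_partitions[0], ensemble)
    if abs(check.log2_evidence - result.best_log2_evidence) > 1e-6:
        raise AssertionError(
            "search fitness disagrees with log_evidence recomputation: "
            f"{result.best_log2_evidence} vs {check.log2_evidence}"
        )
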