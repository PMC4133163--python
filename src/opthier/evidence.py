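"""Model evidence, codelength, and search time for a candidate hierarchy.

The evidence of a decomposition M given target data D (the concatenated
state-action stream of an ensemble of shortest-path tasks) is the fraction
of deterministic policy parameterizations compatible with D, under a
uniform prior over parameterizations.  The agent carries one root policy
per task -- at each state choosing among the atomic actions plus the
options initiable there -- and one shared policy per option, choosing among
atomic actions.  Walking the data, every element either fixes a root
parameter (m_i possible values: vertex degree plus initiable options), an
option parameter (n_i values: vertex degree), both (first step of an option
invocation), or neither (a parameter fixed earlier), so

    P(D | M) = prod_i 1 / k_i,      k_i = m_i**I_T(i) * n_i**I_O(i).

Option use is mandatory: whenever the remaining subsequence leaves the
current region and an option is initiable, the option reaching the first
vertex outside the region is invoked, constraining the root choice and the
option policy along the way.  Option parameters persist across tasks; root
parameters are per-task (recurring tasks reuse them).

Equivalent metrics: the codelength of the data under a Shannon code induced
by the hierarchy is -log2 P(D|M); the geometric-mean number of
trial-and-error attempts needed to discover the policy of a random task or
subtask is 2**(codelength / (num_tasks + num_options)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product as iproduct
from typing import Dict, List, Optional, Sequence, Set, Tuple

from opthier.graph_domain import (
    OptionSpec,
    Partition,
    StateGraph,
    induce_options,
    region_boundary,
    validate_partition,
)
from opthier.task_ensemble import EnsembleData

OptionId = Tuple[int, str]  # (region label, subgoal vertex)


class OptionConflictError(ValueError):
    """Evidence-zero signal: the data contradict an already-fixed policy
    parameter (deterministic shared policies cannot encode both)."""


@dataclass(frozen=True)
class ConstraintRecord:
    """Per-element constraint bookkeeping for one state-action pair."""

    element_index: int
    task_id: int
    state: str
    action: str
    I_T: int
    I_O: int
    n_i: int  # degree of state
    m_i: int  # degree + number of options initiable at state for this task
    option_id: Optional[OptionId] = None

    @property
    def k_i(self) -> int:
        return (self.m_i ** self.I_T) * (self.n_i ** self.I_O)


@dataclass
class ConstraintLedger:
    """Already-fixed policy parameters and the values they were fixed to.

    Root parameters are keyed per task; option parameters persist across
    tasks.  A root value is either an atomic action (successor vertex) or
    an option id.
    """

    fixed_root: Dict[Tuple[int, str], object] = field(default_factory=dict)
    fixed_option: Dict[Tuple[OptionId, str], str] = field(default_factory=dict)


@dataclass
class EvidenceResult:
    log2_evidence: float
    codelength_bits: float
    search_time_geomean: float
    records: List[ConstraintRecord]
    per_task_attempts: Dict[Tuple[str, str], float]
    per_option_attempts: Dict[OptionId, float]
    num_tasks: int
    num_options: int


class _PartitionContext:
    """Derived structures for parsing: region ids, entrances, option lookup."""

    def __init__(self, graph: StateGraph, partition: Partition):
        self.graph = graph
        self.partition = partition
        self.options = induce_options(graph, partition)
        self.region_of = dict(partition.assignment)
        self.opts_by_region: Dict[int, List[OptionSpec]] = {}
        for o in self.options:
            self.opts_by_region.setdefault(o.region, []).append(o)
        self.option_by_exit: Dict[OptionId, OptionSpec] = {
            o.option_id: o for o in self.options
        }
        self.entrances: Dict[int, frozenset] = {}
        for r in partition.regions:
            ent, _ = region_boundary(graph, partition, r)
            self.entrances[r] = ent

    def n_initiable(self, v: str, start: str) -> int:
        r = self.region_of[v]
        opts = self.opts_by_region.get(r)
        if not opts:
            return 0
        if v == start or v in self.entrances[r]:
            return len(opts)
        return 0


def parse_trajectory(
    graph: StateGraph,
    partition: Partition,
    options: Sequence[OptionSpec],
    task: Tuple[int, str, str],
    trajectory: Sequence[Tuple[str, str]],
    ledger: ConstraintLedger,
    _ctx: Optional[_PartitionContext] = None,
) -> List[ConstraintRecord]:
    """Deterministic segmentation of one task's trajectory into constraints.

    ``task`` is (task_id, start, goal).  Walking under root control at
    state v, the initiable options are those of region(v) when v is an
    entrance of its region or the task start; if the remaining subsequence
    leaves region(v), the option whose subgoal is the first vertex reached
    outside is invoked (mandatory use), constraining the root choice on the
    first step and the option policy along the segment; otherwise the step
    is root-level.  The ledger is updated in place.

    Raises :class:`OptionConflictError` (evidence-zero) if an element
    contradicts a previously fixed parameter.
    """
    ctx = _ctx if _ctx is not None else _PartitionContext(graph, partition)
    task_id, start, goal = task
    if not trajectory:
        return []
    states = [trajectory[0][0]] + [a for (_, a) in trajectory]
    for s, a in trajectory:
        if not graph.has_edge(s, a):
            raise ValueError(f"trajectory element ({s!r} -> {a!r}) is not an edge")
    if states[0] != start:
        raise ValueError("trajectory does not begin at the task start")

    records: List[ConstraintRecord] = []
    last = len(states) - 1
    i = 0
    while i < last:
        v = states[i]
        r = ctx.region_of[v]
        q = ctx.n_initiable(v, start)
        # first position after i whose vertex lies outside region(v)
        j = i + 1
        while j <= last and ctx.region_of[states[j]] == r:
            j += 1
        if q > 0 and j <= last:
            # option invocation: drive to the first vertex outside the region
            e = states[j]
            opt = ctx.option_by_exit.get((r, e))
            if opt is None:  # cannot occur for induced options
                raise ValueError(
                    f"no option of region {r} with subgoal {e!r}"
                )
            oid = opt.option_id
            root_key = (task_id, v)
            I_T = 0
            if root_key in ledger.fixed_root:
                if ledger.fixed_root[root_key] != oid:
                    raise OptionConflictError(
                        f"task {task_id} root parameter at {v!r} already fixed "
                        f"to {ledger.fixed_root[root_key]!r}, data require {oid!r}"
                    )
            else:
                ledger.fixed_root[root_key] = oid
                I_T = 1
            for k in range(i, j):
                sv, act = states[k], states[k + 1]
                okey = (oid, sv)
                I_O = 0
                if okey in ledger.fixed_option:
                    if ledger.fixed_option[okey] != act:
                        raise OptionConflictError(
                            f"option {oid!r} parameter at {sv!r} already fixed "
                            f"to {ledger.fixed_option[okey]!r}, data require {act!r}"
                        )
                else:
                    ledger.fixed_option[okey] = act
                    I_O = 1
                records.append(
                    ConstraintRecord(
                        element_index=k,
                        task_id=task_id,
                        state=sv,
                        action=act,
                        I_T=I_T if k == i else 0,
                        I_O=I_O,
                        n_i=graph.degree(sv),
                        m_i=graph.degree(sv) + ctx.n_initiable(sv, start),
                        option_id=oid,
                    )
                )
            i = j
        else:
            # root-level step (goal inside the region, or no initiable option)
            act = states[i + 1]
            root_key = (task_id, v)
            I_T = 0
            if root_key in ledger.fixed_root:
                if ledger.fixed_root[root_key] != act:
                    raise OptionConflictError(
                        f"task {task_id} root parameter at {v!r} already fixed "
                        f"to {ledger.fixed_root[root_key]!r}, data require {act!r}"
                    )
            else:
                ledger.fixed_root[root_key] = act
                I_T = 1
            records.append(
                ConstraintRecord(
                    element_index=i,
                    task_id=task_id,
                    state=v,
                    action=act,
                    I_T=I_T,
                    I_O=0,
                    n_i=graph.degree(v),
                    m_i=graph.degree(v) + q,
                    option_id=None,
                )
            )
            i += 1
    return records


def _task_ids(ensemble: EnsembleData) -> List[int]:
    """Stable id per distinct (start, goal); recurring tasks share an id."""
    ids: Dict[Tuple[str, str], int] = {}
    out = []
    for t in ensemble.tasks:
        if t not in ids:
            ids[t] = len(ids)
        out.append(ids[t])
    return out


def log_evidence(
    graph: StateGraph,
    partition: Partition,
    ensemble: EnsembleData,
) -> EvidenceResult:
    """Exact model evidence of a partition given an ensemble.

    log2 P(D|M) = -sum_i log2 k_i over the constraint records obtained by
    parsing the tasks in ensemble order with a shared ledger.  The product
    of the integer k_i is accumulated exactly; the log is taken last.

    Raises :class:`OptionConflictError` (log-evidence -inf in spirit) with
    diagnostics if the ensemble is inconsistent with shared deterministic
    option policies.
    """
    partition = validate_partition(graph, partition)
    ctx = _PartitionContext(graph, partition)
    ledger = ConstraintLedger()
    ids = _task_ids(ensemble)
    all_records: List[ConstraintRecord] = []
    per_task_K: Dict[Tuple[str, str], int] = {}
    per_option_K: Dict[OptionId, int] = {o.option_id: 1 for o in ctx.options}
    K_total = 1
    offset = 0
    for (task, tid, traj) in zip(ensemble.tasks, ids, ensemble.trajectories):
        start, goal = task
        recs = parse_trajectory(
            graph, partition, ctx.options, (tid, start, goal), traj, ledger,
            _ctx=ctx,
        )
        tK = per_task_K.get(task, 1)
        for r in recs:
            all_records.append(
                ConstraintRecord(
                    element_index=offset + r.element_index,
                    task_id=r.task_id,
                    state=r.state,
                    action=r.action,
                    I_T=r.I_T,
                    I_O=r.I_O,
                    n_i=r.n_i,
                    m_i=r.m_i,
                    option_id=r.option_id,
                )
            )
            K_total *= r.k_i
            if r.I_T:
                tK *= r.m_i
            if r.I_O:
                per_option_K[r.option_id] *= r.n_i
        per_task_K[task] = tK
        offset += len(traj)
    bits = _log2_int(K_total)
    T = len(per_task_K)
    O = len(ctx.options)
    geomean = 2.0 ** (bits / (T + O)) if (T + O) > 0 else 1.0
    return EvidenceResult(
        log2_evidence=-bits,
        codelength_bits=bits,
        search_time_geomean=geomean,
        records=all_records,
        per_task_attempts={t: float(k) for t, k in per_task_K.items()},
        per_option_attempts={o: float(k) for o, k in per_option_K.items()},
        num_tasks=T,
        num_options=O,
    )


def _log2_int(n: int) -> float:
    """log2 of an arbitrarily large positive integer."""
    if n <= 0:
        raise ValueError("positive integer required")
    return math.log2(n)  # handles arbitrarily large ints


def codelength(result: EvidenceResult) -> float:
    """Bits to encode the data under the hierarchy's Shannon code."""
    if math.isinf(result.codelength_bits):
        raise ValueError("codelength is infinite for evidence-zero data")
    return result.codelength_bits


def search_time(
    result: EvidenceResult,
    num_tasks: Optional[int] = None,
    num_options: Optional[int] = None,
) -> float:
    """Geometric-mean trial-and-error attempts over tasks and subtasks.

    Per task t the expected number of uniform random policy draws to hit
    the target policy is A_t = prod of m_i over t's root-constrained
    records; per option o it is A_o = prod of n_i over o's constrained
    records (never-constrained options get A_o = 1).  The geometric mean
    over the T + O policies equals 2**(codelength / (T + O)).
    """
    T = result.num_tasks if num_tasks is None else num_tasks
    O = result.num_options if num_options is None else num_options
    if T + O == 0:
        return 1.0
    log_sum = sum(math.log2(a) for a in result.per_task_attempts.values())
    log_sum += sum(math.log2(a) for a in result.per_option_attempts.values())
    return 2.0 ** (log_sum / (T + O))


# ---------------------------------------------------------------------------
# Fast scorer (search fitness): same segmentation, minimal bookkeeping.
# ---------------------------------------------------------------------------


class EnsembleIndex:
    """Integer-indexed view of graph + ensemble, reusable across partitions."""

    def __init__(self, graph: StateGraph, ensemble: EnsembleData):
        self.graph = graph
        self.verts = graph.sorted_vertices()
        self.vid = {v: i for i, v in enumerate(self.verts)}
        self.deg = [graph.degree(v) for v in self.verts]
        self.log2deg = [math.log2(d) for d in self.deg]
        self.adj = [
            sorted(self.vid[u] for u in graph.neighbors(v)) for v in self.verts
        ]
        # trajectories as integer state sequences (start..goal)
        self.tasks: List[Tuple[int, ...]] = []
        for traj in ensemble.trajectories:
            states = [self.vid[traj[0][0]]] + [self.vid[a] for (_, a) in traj]
            self.tasks.append(tuple(states))
        self.num_edges = len(graph.edges)
        self.edge_list = [
            (self.vid[u], self.vid[v]) for u, v in graph.sorted_edges()
        ]


def codelength_bits_fast(index: EnsembleIndex, labels: Sequence[int]) -> float:
    """Codelength of the ensemble under the partition given as a label array.

    ``labels[i]`` is the region of vertex i (any integer labelling).
    Assumes the ensemble's tasks are distinct and its trajectories come
    from a consistent path set (no option conflicts, no recurring tasks) --
    the conditions of the all-pairs construction.  Agrees with
    :func:`log_evidence` exactly (tested).
    """
    deg = index.deg
    log2deg = index.log2deg
    adj = index.adj
    nv = len(deg)
    # per-region option count = number of distinct exit vertices;
    # entrance flag per vertex = has a neighbor with a different label
    nopts: Dict[int, Set[int]] = {}
    entrance = [False] * nv
    for (u, v) in index.edge_list:
        lu, lv = labels[u], labels[v]
        if lu != lv:
            nopts.setdefault(lu, set()).add(v)
            nopts.setdefault(lv, set()).add(u)
            entrance[u] = True
            entrance[v] = True
    n_opt_region = {r: len(s) for r, s in nopts.items()}
    log2 = math.log2
    bits = 0.0
    fixed: Set[Tuple[int, int, int]] = set()  # (region, exit, state)
    for states in index.tasks:
        start = states[0]
        last = len(states) - 1
        i = 0
        while i < last:
            v = states[i]
            r = labels[v]
            q = n_opt_region.get(r, 0)
            if q and not (entrance[v] or v == start):
                q = 0
            j = i + 1
            while j <= last and labels[states[j]] == r:
                j += 1
            if q and j <= last:
                e = states[j]
                bits += log2(deg[v] + q)  # root fixes the option choice
                for k in range(i, j):
                    key = (r, e, states[k])
                    if key not in fixed:
                        fixed.add(key)
                        bits += log2deg[states[k]]
                i = j
            else:
                bits += log2(deg[v] + q)
                i += 1
    return bits


# ---------------------------------------------------------------------------
# Brute-force oracle: explicit enumeration of deterministic parameterizations.
# ---------------------------------------------------------------------------


def brute_force_evidence(
    graph: StateGraph,
    partition: Partition,
    ensemble: EnsembleData,
    guard: int = 10_000_000,
) -> Fraction:
    """Exact evidence by enumerating deterministic parameterizations.

    Enumerates every joint setting of the option policy tables (one value
    per (option, in-region state), each ranging over the state's
    neighbors).  For each setting, every task is simulated under the
    mandatory-option-use execution rule: at root control the single root
    value able to reproduce the data is forced (the option reaching the
    first vertex outside the current region when the continuation leaves
    it -- choosing the atomic action instead would ignore an applicable
    option -- otherwise the atomic action taken); invoked options execute
    their table step by step and must terminate at their own subgoal.
    Root parameters never visited are free and contribute their full value
    counts.  Returns N_compatible / Z as an exact rational.

    Guarded: raises if the enumeration would exceed ``guard`` table
    settings.
    """
    partition = validate_partition(graph, partition)
    ctx = _PartitionContext(graph, partition)
    verts = graph.sorted_vertices()

    # distinct tasks (recurring tasks share a root table)
    seen: Dict[Tuple[str, str], Tuple[str, ...]] = {}
    for (task, traj) in zip(ensemble.tasks, ensemble.trajectories):
        states = tuple([traj[0][0]] + [a for (_, a) in traj]) if traj else ()
        if task in seen and seen[task] != states:
            return Fraction(0)  # recurring task with contradictory data
        seen[task] = states

    # m(task, v) = degree + options initiable at v for this task's start
    def m_of(start: str, v: str) -> int:
        return graph.degree(v) + ctx.n_initiable(v, start)

    Z_root = 1
    for (start, goal) in seen:
        for v in verts:
            Z_root *= m_of(start, v)

    # option parameter table: one slot per (option, in-region state)
    slots: List[Tuple[OptionId, str, List[str]]] = []
    Z_opt = 1
    for o in ctx.options:
        for v in sorted(o.policy_domain):
            choices = sorted(graph.neighbors(v))
            slots.append((o.option_id, v, choices))
            Z_opt *= len(choices)
    if Z_opt > guard:
        raise ValueError(
            f"option parameter space {Z_opt} exceeds guard {guard}"
        )

    region_of = ctx.region_of

    def simulate(start: str, states: Tuple[str, ...], theta: Dict) -> Optional[int]:
        """Root-parameter multiplicity if theta reproduces the task, else None."""
        last = len(states) - 1
        visited_root: Set[str] = set()
        i = 0
        while i < last:
            v = states[i]
            r = region_of[v]
            q = ctx.n_initiable(v, start)
            j = i + 1
            while j <= last and region_of[states[j]] == r:
                j += 1
            if q and j <= last:
                # mandatory option use; execute the option's table
                e = states[j]
                oid = (r, e)
                if oid not in ctx.option_by_exit:
                    return None
                visited_root.add(v)
                u = v
                pos = i
                while region_of[u] == r:
                    a = theta[(oid, u)]
                    if a != states[pos + 1]:
                        return None
                    u = a
                    pos += 1
                if u != e:  # terminated at a different exit
                    return None
                i = j
            else:
                visited_root.add(v)
                i += 1
        mult = 1
        for v in verts:
            if v not in visited_root:
                mult *= m_of(start, v)
        return mult

    N = 0
    task_items = list(seen.items())
    for values in iproduct(*(choices for (_, _, choices) in slots)):
        theta = {
            (oid, v): a for (oid, v, _), a in zip(slots, values)
        }
        total = 1
        for (start, goal), states in task_items:
            mult = simulate(start, states, theta)
            if mult is None:
                total = 0
                break
            total *= mult
        N += total
    return Fraction(N, Z_root * Z_opt)
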