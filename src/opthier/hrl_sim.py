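"""Tabular flat Q-learning vs. option-equipped SMDP Q-learning.

Illustrates how the quality of a decomposition affects learning speed: an
agent furnished with options driving to useful subgoals (doorways) reaches
shortest-path behavior faster than a flat agent, while an agent carrying
misleading options (room corners) learns more slowly.

Agents are tabular and epsilon-greedy.  The hierarchical agent's root
action set at a state is the atomic actions plus the options initiable
there (the option's region entrances, plus the task start); options
execute a fixed pretrained policy (the in-region shortest path to the
option's subgoal) and the root value update uses standard SMDP discounting
of the reward accumulated over the option's duration.  Intra-option
learning is not used: options arrive pretrained and frozen.

Rewards are sparse by default (``goal_reward`` on reaching the goal, zero
per step, discount < 1), the standard scheme for gridworld learning
demonstrations: values stay flat until the goal is first found and then
propagate backwards, through option-length jumps in a single backup for
the hierarchical agent.  A per-step cost can be configured instead, but
under optimistic-zero initialization it turns pre-equipped options into
pure exploration distractors and masks the effect of hierarchy quality on
convergence speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from opthier.graph_domain import OptionSpec, StateGraph
from opthier.task_ensemble import EdgeWeights


@dataclass(frozen=True)
class AgentConfig:
    """Hyperparameters for one learning run.

    Reaching the goal yields ``goal_reward`` and ends the episode; every
    other step yields ``step_reward`` (0 by default: sparse rewards).
    Defaults are standard tabular-gridworld settings.
    """

    kind: str = "flat"  # "flat" | "hierarchical"
    learning_rate: float = 0.1
    epsilon: float = 0.1
    discount: float = 0.9
    episodes: int = 300
    max_steps_per_episode: int = 1000
    seed: int = 0
    goal_reward: float = 1.0
    step_reward: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 <= self.epsilon <= 1):
            raise ValueError("epsilon must be in [0, 1]")
        if not (0 < self.discount <= 1):
            raise ValueError("discount must be in (0, 1]")


@dataclass
class LearningCurve:
    """Steps per episode plus the first episode meeting the criterion."""

    steps_per_episode: List[int]
    episodes_to_criterion: Optional[int] = None


def pretrain_option_policies(
    graph: StateGraph,
    options: Sequence[OptionSpec],
    weights: EdgeWeights,
) -> Dict[Tuple[Tuple[int, str], str], str]:
    """Deterministic option policies: in-region shortest path to the subgoal.

    For each option, every state of its region maps to the next step of the
    unique shortest path (under ``weights``) that stays inside the region
    until the final step into the subgoal.
    """
    policies: Dict[Tuple[Tuple[int, str], str], str] = {}
    gnx = graph.to_networkx()
    for u, v in gnx.edges:
        gnx[u][v]["length"] = weights.length(u, v)
    for o in options:
        sub = gnx.subgraph(set(o.policy_domain) | {o.subgoal})
        try:
            paths = nx.single_source_dijkstra_path(sub, o.subgoal, weight="length")
        except nx.NetworkXError as err:  # pragma: no cover - guarded upstream
            raise ValueError(f"subgoal {o.subgoal!r} unreachable: {err}")
        for v in o.policy_domain:
            if v not in paths:  # pragma: no cover - regions are connected
                raise ValueError(
                    f"state {v!r} cannot reach subgoal {o.subgoal!r} in-region"
                )
            policies[(o.option_id, v)] = paths[v][-2]
    return policies


def _execute_option(
    graph: StateGraph,
    option: OptionSpec,
    policies: Dict[Tuple[Tuple[int, str], str], str],
    state: str,
    goal: str,
    config: AgentConfig,
    step_budget: int,
) -> Tuple[str, float, int, bool]:
    """Run an option policy to termination (or budget/goal).

    Returns (final state, accumulated discounted reward, steps used,
    goal reached).
    """
    total = 0.0
    gamma = 1.0
    steps = 0
    v = state
    while v in option.policy_domain and steps < step_budget:
        v = policies[(option.option_id, v)]
        steps += 1
        if v == goal:
            total += gamma * config.goal_reward
            return v, total, steps, True
        total += gamma * config.step_reward
        gamma *= config.discount
    return v, total, steps, False


def run_agent(
    graph: StateGraph,
    task: Tuple[str, str],
    config: AgentConfig,
    options: Optional[Sequence[OptionSpec]] = None,
    option_policies: Optional[Dict[Tuple[Tuple[int, str], str], str]] = None,
) -> LearningCurve:
    """Learn one fixed (start, goal) task; returns per-episode step counts.

    ``kind="flat"``: epsilon-greedy tabular Q-learning over atomic actions.
    ``kind="hierarchical"``: SMDP Q-learning whose root actions are the
    atomic actions plus the options initiable at the current state
    (pretrained policies required).
    """
    start, goal = task
    if start not in graph.adjacency or goal not in graph.adjacency:
        raise ValueError(f"task endpoints {task!r} must be graph vertices")
    hierarchical = config.kind == "hierarchical"
    if hierarchical and (options is None or option_policies is None):
        raise ValueError("hierarchical agent requires pretrained options")
    rng = np.random.default_rng(config.seed % (2**31))
    options = list(options) if (options and hierarchical) else []

    # action menus per state: atomic successors then initiable options
    atomic: Dict[str, List[str]] = {
        v: sorted(graph.neighbors(v)) for v in graph.adjacency
    }
    initiable: Dict[str, List[int]] = {v: [] for v in graph.adjacency}
    for oi, o in enumerate(options):
        init_set = o.initiation_core | (
            {start} if start in o.policy_domain else set()
        )
        for v in init_set:
            initiable[v].append(oi)
    q: Dict[str, np.ndarray] = {
        v: np.zeros(len(atomic[v]) + len(initiable[v])) for v in graph.adjacency
    }

    steps_per_episode: List[int] = []
    for _ in range(config.episodes):
        v = start
        steps = 0
        while v != goal and steps < config.max_steps_per_episode:
            menu_len = len(q[v])
            if rng.random() < config.epsilon:
                a = int(rng.integers(menu_len))
            else:
                row = q[v]
                a = int(rng.choice(np.flatnonzero(row == row.max())))
            n_atomic = len(atomic[v])
            if a < n_atomic:
                nxt = atomic[v][a]
                tau = 1
                r = config.goal_reward if nxt == goal else config.step_reward
            else:
                o = options[initiable[v][a - n_atomic]]
                nxt, r, tau, _ = _execute_option(
                    graph, o, option_policies, v, goal, config,
                    config.max_steps_per_episode - steps,
                )
            target = r
            if nxt != goal:
                target += (config.discount ** tau) * float(q[nxt].max())
            q[v][a] += config.learning_rate * (target - q[v][a])
            v = nxt
            steps += tau
        steps_per_episode.append(steps)
    return LearningCurve(steps_per_episode=steps_per_episode)


def episodes_to_criterion(
    curve: LearningCurve,
    optimal_steps: int,
    slack: int = 0,
    window: int = 5,
) -> Optional[int]:
    """First episode from which the windowed median is near-optimal.

    Returns the first index i such that episode i itself and the median of
    episodes [i, i+window) are both at most ``optimal_steps + slack``;
    None if never.
    """
    if optimal_steps < 1:
        raise ValueError("optimal_steps must be >= 1")
    steps = curve.steps_per_episode
    threshold = optimal_steps + slack
    for i in range(len(steps) - window + 1):
        if steps[i] <= threshold and (
            float(np.median(steps[i : i + window])) <= threshold
        ):
            return i
    return None
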