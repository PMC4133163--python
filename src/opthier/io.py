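"""File formats and run provenance.

Graphs travel as two-column edge-list TSV (header optional, ``#`` comments
ignored); partitions as a JSON object mapping vertex id to region label;
edge weights as three-column TSV; trajectories as JSONL (one record per
task); reports and manifests as JSON.  All formats are plain text so runs
diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Dict, List, Optional, Union

from opthier import __version__
from opthier.graph_domain import (
    GraphError,
    Partition,
    StateGraph,
    validate_partition,
)
from opthier.task_ensemble import EdgeWeights, EnsembleData

PathLike = Union[str, Path]


def read_graph(path: PathLike) -> StateGraph:
    """Edge-list TSV -> StateGraph (duplicates, self-loops, disconnection
    all rejected with descriptive errors)."""
    edges = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            if first_data_line:
                first_data_line = False
                if parts[0].lower() in {"vertex_a", "source", "from"}:
                    continue  # optional header
            edges.append((parts[0], parts[1]))
    if not edges:
        raise GraphError(f"{path}: no edges found")
    return StateGraph.from_edges(edges)


def write_graph(graph: StateGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# vertex_a\tvertex_b\n")
        for u, v in graph.sorted_edges():
            fh.write(f"{u}\t{v}\n")


def read_partition(path: PathLike, graph: Optional[StateGraph] = None) -> Partition:
    """JSON {vertex: label} -> canonicalized Partition (validated against
    ``graph`` when given)."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a JSON object of vertex -> label")
    p = Partition.from_assignment(raw)
    if graph is not None:
        p = validate_partition(graph, p)
    return p


def write_partition(partition: Partition, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {v: partition.assignment[v] for v in sorted(partition.assignment)},
            fh,
            indent=0,
            sort_keys=True,
        )
        fh.write("\n")


def write_weights(weights: EdgeWeights, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# vertex_a\tvertex_b\tcost\n")
        for (u, v), c in sorted(weights.cost.items()):
            fh.write(f"{u}\t{v}\t{c!r}\n")


def read_weights(path: PathLike, seed: int = -1) -> EdgeWeights:
    cost = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, c = line.split("\t")
            cost[(u, v) if u <= v else (v, u)] = float(c)
    return EdgeWeights(cost=cost, seed=seed)


def write_trajectories(ensemble: EnsembleData, path: PathLike) -> None:
    """JSONL: one {task_id, start, goal, states, actions} record per task."""
    with open(path, "w") as fh:
        for i, ((s, g), traj) in enumerate(
            zip(ensemble.tasks, ensemble.trajectories)
        ):
            states = [traj[0][0]] + [a for (_, a) in traj] if traj else [s]
            rec = {
                "task_id": i,
                "start": s,
                "goal": g,
                "states": states,
                "actions": [a for (_, a) in traj],
            }
            fh.write(json.dumps(rec) + "\n")


def read_trajectories(path: PathLike) -> EnsembleData:
    tasks: List = []
    trajectories: List = []
    boundaries: List[int] = []
    pos = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            states = rec["states"]
            traj = tuple(zip(states, states[1:]))
            tasks.append((rec["start"], rec["goal"]))
            boundaries.append(pos)
            trajectories.append(traj)
            pos += len(traj)
    return EnsembleData(
        tasks=tuple(tasks),
        trajectories=tuple(trajectories),
        boundaries=tuple(boundaries),
    )


def file_digest(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: PathLike,
    command: str,
    config: Dict,
    seeds: Dict[str, int],
    inputs: Dict[str, str],
) -> Path:
    """Run manifest: command, config snapshot, seeds, input digests."""
    manifest = {
        "tool": "opthier",
        "version": __version__,
        "command": command,
        "argv": sys.argv[1:],
        "config": config,
        "seeds": seeds,
        "input_digests": {k: file_digest(p) for k, p in inputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
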