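"""Programmatic generators for the study domains and their canonical
decompositions.

Every experiment in this package runs on generated graphs; no downloads.
The classic illustrations of these domains fix only structural constraints
(degrees, bottleneck placement, community sizes), so these fixtures are
documented reconstructions of those constraints.  Tests assert properties
of the generated graphs, not identity with any particular drawing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Tuple

from opthier.graph_domain import Partition, StateGraph, validate_partition


@dataclass(frozen=True)
class FixtureBundle:
    """A graph plus its named candidate partitions and provenance notes."""

    graph: StateGraph
    named_partitions: Dict[str, Partition]
    notes: str

    def partition(self, name: str) -> Partition:
        return self.named_partitions[name]


def _validate_bundle(bundle: FixtureBundle) -> FixtureBundle:
    for name, p in bundle.named_partitions.items():
        validate_partition(bundle.graph, p)
    return bundle


# ---------------------------------------------------------------------------
# Rooms gridworld
# ---------------------------------------------------------------------------


def make_rooms(room_w: int = 3, room_h: int = 3) -> FixtureBundle:
    """2x2 arrangement of room_w x room_h grid rooms joined by 4 doorways.

    Rooms are 4-neighbor lattices named NW, NE, SW, SE.  Each doorway is a
    separate vertex adjacent to one mid-wall boundary cell in each of the
    two rooms it joins (top doorway between NW and NE, right between NE and
    SE, bottom between SE and SW, left between SW and NW).  Total vertices:
    ``4 * room_w * room_h + 4``.

    Named partitions:

    * ``flat`` -- one region.
    * ``doorways`` -- one region per room, each doorway grouped with the
      room clockwise of it (top -> NE, right -> SE, bottom -> SW,
      left -> NW); the tie in doorway assignment is symmetric.
    * ``corners`` -- the four inner-corner cells (each room's cell nearest
      the center of the layout) as singleton regions, remainder one region
      (only for rooms at least 3x3; in 2-wide rooms the corner coincides
      with a doorway attachment cell).
    """
    if room_w < 2 or room_h < 2:
        raise ValueError("room_w and room_h must both be >= 2")
    w, h = room_w, room_h

    def cell(room: str, x: int, y: int) -> str:
        return f"{room}_{x}_{y}"

    edges: List[Tuple[str, str]] = []
    rooms = ("NW", "NE", "SW", "SE")
    for room in rooms:
        for x in range(w):
            for y in range(h):
                if x + 1 < w:
                    edges.append((cell(room, x, y), cell(room, x + 1, y)))
                if y + 1 < h:
                    edges.append((cell(room, x, y), cell(room, x, y + 1)))
    # doorways: D_top between NW|NE, D_right NE|SE, D_bottom SE|SW, D_left SW|NW
    my, mx = h // 2, w // 2
    doors = {
        "D_top": (cell("NW", w - 1, my), cell("NE", 0, my)),
        "D_right": (cell("NE", mx, h - 1), cell("SE", mx, 0)),
        "D_bottom": (cell("SE", 0, my), cell("SW", w - 1, my)),
        "D_left": (cell("SW", mx, 0), cell("NW", mx, h - 1)),
    }
    for d, (a, b) in doors.items():
        edges.append((d, a))
        edges.append((d, b))
    graph = StateGraph.from_edges(edges)

    room_cells = {
        room: [cell(room, x, y) for x in range(w) for y in range(h)]
        for room in rooms
    }
    # fixed clockwise rule: each doorway joins the room clockwise of it
    clockwise = {"D_top": "NE", "D_right": "SE", "D_bottom": "SW", "D_left": "NW"}
    doorway_regions = {room: list(cells) for room, cells in room_cells.items()}
    for d, room in clockwise.items():
        doorway_regions[room].append(d)
    # inner corners: the corner cell of each room facing the layout center
    inner = {
        "NW": cell("NW", w - 1, h - 1),
        "NE": cell("NE", 0, h - 1),
        "SW": cell("SW", w - 1, 0),
        "SE": cell("SE", 0, 0),
    }
    corner_rest = [v for v in graph.sorted_vertices() if v not in inner.values()]
    named = {
        "flat": Partition.flat(graph),
        "doorways": Partition.from_regions(doorway_regions.values()),
    }
    if w >= 3 and h >= 3:
        # for 2-wide/2-tall rooms the inner corner coincides with a doorway
        # attachment cell and carving it out disconnects the remainder
        named["corners"] = Partition.from_regions(
            [corner_rest] + [[v] for v in inner.values()]
        )
    notes = (
        f"Rooms gridworld: 2x2 rooms of {w}x{h} 4-neighbor cells, four "
        "doorway vertices at mid-walls; doorway-room assignment ties broken "
        "by a fixed clockwise rule."
    )
    return _validate_bundle(FixtureBundle(graph, named, notes))


def rooms_inner_corners(room_w: int = 3, room_h: int = 3) -> List[str]:
    """The four inner-corner cell ids used by the 'corners' partition."""
    w, h = room_w, room_h
    return [
        f"NW_{w - 1}_{h - 1}",
        f"NE_0_{h - 1}",
        f"SW_{w - 1}_0",
        f"SE_0_0",
    ]


# ---------------------------------------------------------------------------
# Tower of Hanoi
# ---------------------------------------------------------------------------


def make_toh(n_disks: int = 3) -> FixtureBundle:
    """State-transition graph of the n-disk Tower of Hanoi puzzle.

    States are the 3**n legal configurations (a peg per disk; stacking
    order is forced by size, with disk indices 1..n from smallest to
    largest: no disk may rest on a smaller one).  Edges are single legal
    moves: the top (smallest) disk of a peg may move to any peg whose top
    disk is larger (or which is empty).

    Named partitions: ``flat`` and ``largest_disk`` (three regions, one per
    position of the largest disk).
    """
    if n_disks < 2:
        raise ValueError("n_disks must be >= 2")

    def name(cfg: Tuple[int, ...]) -> str:
        return "T" + "".join(str(p) for p in cfg)

    from itertools import product as iproduct

    states = list(iproduct(range(3), repeat=n_disks))  # cfg[d] = peg of disk d
    edges = []
    for cfg in states:
        for peg in range(3):
            on_peg = [d for d in range(n_disks) if cfg[d] == peg]
            if not on_peg:
                continue
            top = min(on_peg)  # smallest disk on the peg moves
            for dest in range(3):
                if dest == peg:
                    continue
                dest_disks = [d for d in range(n_disks) if cfg[d] == dest]
                if dest_disks and min(dest_disks) < top:
                    continue  # smaller disk already on destination
                new = list(cfg)
                new[top] = dest
                if cfg < tuple(new):  # add each undirected edge once
                    edges.append((name(cfg), name(tuple(new))))
    graph = StateGraph.from_edges(edges)
    largest = Partition.from_regions(
        [
            [name(cfg) for cfg in states if cfg[n_disks - 1] == peg]
            for peg in range(3)
        ]
    )
    named = {"flat": Partition.flat(graph), "largest_disk": largest}
    notes = (
        f"Tower of Hanoi with {n_disks} disks: {3 ** n_disks} legal "
        "configurations, edges are single legal moves; the largest_disk "
        "partition has one region per position of the largest disk."
    )
    return _validate_bundle(FixtureBundle(graph, named, notes))


def toh_peg_relabel(vertex: str, perm: Tuple[int, int, int]) -> str:
    """Apply a peg permutation to a Tower of Hanoi vertex id."""
    return "T" + "".join(str(perm[int(c)]) for c in vertex[1:])


# ---------------------------------------------------------------------------
# Three-cluster sequence-learning graph
# ---------------------------------------------------------------------------


def make_schapiro15() -> FixtureBundle:
    """15-vertex ring of three 5-vertex clusters (all degrees 4).

    Within a cluster every pair is adjacent except the two connector
    vertices; each connector links to a connector of the neighboring
    cluster, closing a ring of clusters.  Named partitions: ``flat`` and
    ``clusters`` (the three 5-vertex communities).
    """
    clusters = []
    edges = []
    for c in range(3):
        vs = [f"c{c}v{i}" for i in range(5)]
        clusters.append(vs)
        # v0 and v4 are the connectors; all within-cluster pairs adjacent
        # except (v0, v4)
        for a, b in combinations(range(5), 2):
            if (a, b) == (0, 4):
                continue
            edges.append((vs[a], vs[b]))
    for c in range(3):
        edges.append((clusters[c][4], clusters[(c + 1) % 3][0]))
    graph = StateGraph.from_edges(edges)
    named = {
        "flat": Partition.flat(graph),
        "clusters": Partition.from_regions(clusters),
    }
    notes = (
        "Three 5-vertex clusters (complete minus the connector-connector "
        "edge) joined connector-to-connector in a ring; every vertex has "
        "degree 4."
    )
    return _validate_bundle(FixtureBundle(graph, named, notes))


# ---------------------------------------------------------------------------
# Bottleneck towns
# ---------------------------------------------------------------------------


def _town10_community(prefix: str) -> Tuple[List[Tuple[str, str]], str]:
    """Five vertices with degrees (2,3,3,3,3); 'b' is the bottleneck."""
    b, p, q, r, s = (f"{prefix}{x}" for x in "bpqrs")
    edges = [
        (b, p), (b, q),
        (p, r), (p, s),
        (q, r), (q, s),
        (r, s),
    ]
    return edges, b


def make_town(size: int) -> FixtureBundle:
    """Bottleneck towns of 10 or 19 locations.

    ``size=10``: two 5-vertex communities joined by a single cross edge
    between the two designated bottleneck vertices; every vertex has
    exactly three neighbors (the bottleneck vertices have in-community
    degree 2 plus the bridge).

    ``size=19``: two structurally identical 9-vertex communities (complete
    graphs K9, so all intra-community shortest paths are unique) joined
    through one central bottleneck vertex ``C`` attached to one gateway
    vertex per side.  Named partitions include both ``two_sides`` tie
    variants, with the central vertex assimilated to either side; the
    mirror symmetry and path uniqueness make their model evidence exactly
    equal.
    """
    if size == 10:
        left, bl = _town10_community("L")
        right, br = _town10_community("R")
        edges = left + right + [(bl, br)]
        graph = StateGraph.from_edges(edges)
        named = {
            "flat": Partition.flat(graph),
            "two_sides": Partition.from_regions(
                [
                    [v for v in graph.sorted_vertices() if v.startswith("L")],
                    [v for v in graph.sorted_vertices() if v.startswith("R")],
                ]
            ),
        }
        notes = (
            "Ten locations, all of degree 3: two 5-vertex communities "
            "bridged by the single edge between the bottleneck vertices "
            "Lb and Rb."
        )
        return _validate_bundle(FixtureBundle(graph, named, notes))
    if size == 19:
        lefts = [f"L{i}" for i in range(9)]
        rights = [f"R{i}" for i in range(9)]
        edges = [(a, b) for a, b in combinations(lefts, 2)]
        edges += [(a, b) for a, b in combinations(rights, 2)]
        edges += [("C", "L0"), ("C", "R0")]
        graph = StateGraph.from_edges(edges)
        named = {
            "flat": Partition.flat(graph),
            "two_sides_left": Partition.from_regions([lefts + ["C"], rights]),
            "two_sides_right": Partition.from_regions([lefts, rights + ["C"]]),
        }
        notes = (
            "Nineteen locations: two identical 9-vertex communities joined "
            "through the single central bottleneck vertex C (gateways L0 "
            "and R0).  The two two_sides variants assimilate C to either "
            "side and receive equal model evidence by symmetry."
        )
        return _validate_bundle(FixtureBundle(graph, named, notes))
    raise ValueError(f"unsupported town size {size!r}; expected 10 or 19")


def town_bottlenecks(size: int) -> List[str]:
    """The designated bottleneck vertices of a town fixture."""
    if size == 10:
        return ["Lb", "Rb"]
    if size == 19:
        return ["C"]
    raise ValueError(f"unsupported town size {size!r}")
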