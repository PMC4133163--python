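import random

import pytest
from hypothesis import given, settings, strategies as st

from opthier.graph_domain import (
    GraphError,
    Partition,
    PartitionError,
    StateGraph,
    induce_options,
    partition_from_edge_mask,
    region_boundary,
    validate_partition,
)


def triangle():
    return StateGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


class TestStateGraph:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphError, match="self-loop"):
            StateGraph.from_edges([("A", "A")])

    def test_rejects_duplicate_edge(self):
        with pytest.raises(GraphError, match="duplicate"):
            StateGraph.from_edges([("A", "B"), ("B", "A")])

    def test_rejects_disconnected(self):
        with pytest.raises(GraphError, match="not connected"):
            StateGraph.from_edges([("A", "B"), ("C", "D")])

    def test_degrees_and_edges(self, path3):
        assert path3.degree("B") == 2
        assert path3.degree("A") == 1
        assert path3.edges == {("A", "B"), ("B", "C")}


class TestValidatePartition:
    def test_connected_regions_pass(self, path3):
        p = validate_partition(path3, Partition.from_regions([["A", "B"], ["C"]]))
        assert p.num_regions == 2

    def test_disconnected_region_rejected(self, path3):
        with pytest.raises(PartitionError, match="not induce a connected"):
            validate_partition(path3, Partition.from_regions([["A", "C"], ["B"]]))

    def test_flat_partition_valid(self, path3):
        p = validate_partition(path3, Partition.flat(path3))
        assert p.num_regions == 1

    def test_missing_vertex_rejected(self, path3):
        with pytest.raises(PartitionError, match="missing"):
            validate_partition(path3, Partition.from_regions([["A", "B"]]))

    def test_unknown_vertex_rejected(self, path3):
        with pytest.raises(PartitionError, match="unknown"):
            validate_partition(
                path3, Partition.from_regions([["A", "B"], ["C"], ["Z"]])
            )

    def test_labels_canonicalized_by_smallest_vertex(self, path3):
        p = Partition.from_assignment({"A": "y", "B": "y", "C": "x"})
        assert p.assignment == {"A": 0, "B": 0, "C": 1}


class TestRegionBoundary:
    @pytest.mark.parametrize(
        "region_sets, region, entrances, exits",
        [
            ([["A", "B"], ["C"]], 0, {"B"}, {"C"}),
            ([["A", "B"], ["C"]], 1, {"C"}, {"B"}),
        ],
    )
    def test_path3_boundaries(self, path3, region_sets, region, entrances, exits):
        p = validate_partition(path3, Partition.from_regions(region_sets))
        ent, ext = region_boundary(path3, p, region)
        assert ent == entrances and ext == exits

    def test_triangle_singleton(self):
        g = triangle()
        p = validate_partition(g, Partition.from_regions([["A"], ["B", "C"]]))
        ent, ext = region_boundary(g, p, 0)
        assert ent == {"A"} and ext == {"B", "C"}

    def test_flat_has_empty_boundary(self, path3):
        p = Partition.flat(path3)
        assert region_boundary(path3, p, 0) == (frozenset(), frozenset())

    def test_unknown_region_errors(self, path3):
        with pytest.raises(PartitionError, match="unknown region"):
            region_boundary(path3, Partition.flat(path3), 5)


class TestInduceOptions:
    def test_path3_two_options(self, path3):
        opts = induce_options(path3, Partition.from_regions([["A", "B"], ["C"]]))
        assert len(opts) == 2
        first, second = opts
        assert first.subgoal == "C" and first.initiation_core == {"B"}
        assert first.policy_domain == {"A", "B"}
        assert second.subgoal == "B" and second.initiation_core == {"C"}

    def test_flat_induces_no_options(self, path3):
        assert induce_options(path3, Partition.flat(path3)) == []

    def test_rooms_doorway_partition_two_options_per_room(self, rooms_bundle):
        opts = induce_options(
            rooms_bundle.graph, rooms_bundle.partition("doorways")
        )
        per_region = {}
        for o in opts:
            per_region[o.region] = per_region.get(o.region, 0) + 1
        assert per_region == {0: 2, 1: 2, 2: 2, 3: 2}

    def test_option_count_equals_total_exits(self, town10_bundle):
        g = town10_bundle.graph
        p = town10_bundle.partition("two_sides")
        opts = induce_options(g, p)
        total_exits = sum(
            len(region_boundary(g, p, r)[1]) for r in p.regions
        )
        assert len(opts) == total_exits


class TestEdgeMask:
    def test_all_on_gives_flat(self):
        g = triangle()
        p = partition_from_edge_mask(g, {e: True for e in g.edges})
        assert p == Partition.flat(g)

    def test_all_off_gives_singletons(self):
        g = triangle()
        p = partition_from_edge_mask(g, {e: False for e in g.edges})
        assert p.num_regions == 3

    def test_partial_mask(self, path3):
        mask = {("A", "B"): True, ("B", "C"): False}
        p = partition_from_edge_mask(path3, mask)
        assert p == Partition.from_regions([["A", "B"], ["C"]])

    def test_missing_edge_key_rejected(self, path3):
        with pytest.raises(PartitionError, match="missing"):
            partition_from_edge_mask(path3, {("A", "B"): True})


def _random_connected_graph(rng, n):
    verts = [f"v{i}" for i in range(n)]
    edges = [
        (verts[i], verts[rng.randrange(i)]) for i in range(1, n)
    ]  # random spanning tree
    extra = [
        (a, b)
        for i, a in enumerate(verts)
        for b in verts[i + 1 :]
        if (a, b) not in edges and (b, a) not in edges and rng.random() < 0.3
    ]
    return StateGraph.from_edges(edges + extra)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_partition_invariants_on_random_graphs(seed):
    """Entrances lie inside their region, exits outside; regions tile the
    vertex set; option count equals the total exit count."""
    rng = random.Random(seed)
    g = _random_connected_graph(rng, rng.randint(3, 9))
    mask = {e: rng.random() < 0.5 for e in g.edges}
    p = partition_from_edge_mask(g, mask)
    p = validate_partition(g, p)
    regions = p.regions
    assert sum(len(vs) for vs in regions.values()) == len(g)
    seen = set()
    for vs in regions.values():
        assert not (vs & seen)
        seen |= vs
    n_opts = 0
    for r, vs in regions.items():
        ent, ext = region_boundary(g, p, r)
        assert ent <= vs
        assert not (ext & vs)
        n_opts += len(ext)
    assert len(induce_options(g, p)) == n_opts
    # mask -> partition -> region-interior mask is idempotent at partition level
    mask2 = {
        (u, v): p.region_of(u) == p.region_of(v) for (u, v) in g.edges
    }
    assert partition_from_edge_mask(g, mask2) == p
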