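import math
from fractions import Fraction

import numpy as np
import pytest

from opthier.evidence import (
    ConstraintLedger,
    EnsembleIndex,
    OptionConflictError,
    brute_force_evidence,
    codelength,
    codelength_bits_fast,
    log_evidence,
    parse_trajectory,
    search_time,
)
from opthier.graph_domain import Partition, StateGraph, induce_options
from opthier.task_ensemble import (
    EnsembleData,
    all_pairs_unique_paths,
    build_ensemble,
    sample_edge_costs,
)


def ensemble_from_paths(paths):
    """Hand-built ensemble from explicit vertex sequences."""
    tasks, trajectories, boundaries = [], [], []
    pos = 0
    for p in paths:
        tasks.append((p[0], p[-1]))
        traj = tuple(zip(p, p[1:]))
        trajectories.append(traj)
        boundaries.append(pos)
        pos += len(traj)
    return EnsembleData(
        tasks=tuple(tasks),
        trajectories=tuple(trajectories),
        boundaries=tuple(boundaries),
    )


class TestParseTrajectory:
    def test_flat_all_root(self, path3):
        p = Partition.flat(path3)
        recs = parse_trajectory(
            path3, p, [], (0, "A", "C"), [("A", "B"), ("B", "C")],
            ConstraintLedger(),
        )
        assert [(r.state, r.action, r.I_T, r.I_O, r.m_i, r.k_i) for r in recs] == [
            ("A", "B", 1, 0, 1, 1),
            ("B", "C", 1, 0, 2, 2),
        ]

    def test_option_invocation_first_step_constrains_both(self, path3):
        p = Partition.from_regions([["A", "B"], ["C"]])
        opts = induce_options(path3, p)
        recs = parse_trajectory(
            path3, p, opts, (0, "A", "C"), [("A", "B"), ("B", "C")],
            ConstraintLedger(),
        )
        first, second = recs
        # start state: root chooses among deg(A)+1 option = 2; option policy
        # at A has deg(A)=1 value
        assert (first.I_T, first.I_O, first.m_i, first.n_i, first.k_i) == (
            1, 1, 2, 1, 2,
        )
        assert first.option_id == (0, "C")
        # in-option element at B: only the option parameter (deg 2) is fixed
        assert (second.I_T, second.I_O, second.n_i, second.k_i) == (0, 1, 2, 2)

    def test_already_fixed_option_parameter_frees_element(self, path3):
        p = Partition.from_regions([["A", "B"], ["C"]])
        opts = induce_options(path3, p)
        ledger = ConstraintLedger()
        ledger.fixed_option[((0, "C"), "B")] = "C"
        recs = parse_trajectory(
            path3, p, opts, (0, "A", "C"), [("A", "B"), ("B", "C")], ledger
        )
        assert recs[1].k_i == 1

    def test_non_edge_rejected(self, path3):
        with pytest.raises(ValueError, match="not an edge"):
            parse_trajectory(
                path3, Partition.flat(path3), [], (0, "A", "C"),
                [("A", "C")], ConstraintLedger(),
            )

    def test_option_conflict_is_evidence_zero_signal(self):
        """Two tasks demanding different actions from one shared option
        parameter cannot both be encoded by a deterministic policy."""
        g = StateGraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]
        )
        p = Partition.from_regions([["A", "B", "C"], ["D"]])
        ens = ensemble_from_paths([
            ["A", "B", "C", "D"],  # fixes option param at B -> C
            ["B", "A", "D"],       # demands option param at B -> A
        ])
        with pytest.raises(OptionConflictError, match="already fixed"):
            log_evidence(g, p, ens)


class TestLogEvidence:
    def test_k3_flat_closed_form(self, k3, k3_ensemble):
        res = log_evidence(k3, Partition.flat(k3), k3_ensemble)
        assert res.log2_evidence == pytest.approx(-6.0, abs=1e-12)

    def test_path3_flat_closed_form(self, path3, path3_ensemble):
        res = log_evidence(path3, Partition.flat(path3), path3_ensemble)
        assert res.log2_evidence == pytest.approx(-4.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_flat_evidence_is_product_of_inverse_degrees(self, seed):
        """With no options every element is root-constrained with k = deg."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        verts = [f"v{i}" for i in range(n)]
        edges = [(verts[i], verts[int(rng.integers(0, i))]) for i in range(1, n)]
        for i in range(n):
            for j in range(i + 1, n):
                e = (verts[i], verts[j])
                if e not in edges and (e[1], e[0]) not in edges and rng.random() < 0.3:
                    edges.append(e)
        g = StateGraph.from_edges(edges)
        ps = all_pairs_unique_paths(g, sample_edge_costs(g, seed))
        ens = build_ensemble(ps, seed)
        expected = -sum(
            math.log2(g.degree(s))
            for traj in ens.trajectories
            for (s, _) in traj
        )
        res = log_evidence(g, Partition.flat(g), ens)
        assert res.log2_evidence == pytest.approx(expected, abs=1e-9)

    def test_oracle_equivalence_small_graphs(self, path3, path3_ensemble):
        for regions in ([["A", "B", "C"]], [["A", "B"], ["C"]],
                        [["A"], ["B", "C"]], [["A"], ["B"], ["C"]]):
            p = Partition.from_regions(regions)
            got = log_evidence(path3, p, path3_ensemble).log2_evidence
            want = math.log2(brute_force_evidence(path3, p, path3_ensemble))
            assert got == pytest.approx(want, abs=1e-9)

    def test_k3_brute_force_value(self, k3, k3_ensemble):
        assert brute_force_evidence(
            k3, Partition.flat(k3), k3_ensemble
        ) == Fraction(1, 64)

    def test_task_order_invariance(self, town10_bundle, town10_ensemble):
        g = town10_bundle.graph
        p = town10_bundle.partition("two_sides")
        base = log_evidence(g, p, town10_ensemble).log2_evidence
        rng = np.random.default_rng(0)
        items = list(zip(town10_ensemble.tasks, town10_ensemble.trajectories))
        for _ in range(5):
            order = rng.permutation(len(items))
            shuffled = [items[i] for i in order]
            ens2 = EnsembleData(
                tasks=tuple(t for t, _ in shuffled),
                trajectories=tuple(tr for _, tr in shuffled),
                boundaries=town10_ensemble.boundaries,
            )
            assert log_evidence(g, p, ens2).log2_evidence == pytest.approx(
                base, abs=1e-9
            )

    def test_carving_out_regions_here_lowers_evidence(self, k3, k3_ensemble):
        """On the triangle every non-flat partition adds option parameters
        that the data must also fix, so evidence can only drop."""
        flat = log_evidence(k3, Partition.flat(k3), k3_ensemble).log2_evidence
        for regions in ([["A", "B"], ["C"]], [["A"], ["B"], ["C"]]):
            carved = log_evidence(
                k3, Partition.from_regions(regions), k3_ensemble
            ).log2_evidence
            assert carved < flat

    def test_evidence_in_unit_interval(self, town19_bundle, town19_ensemble):
        res = log_evidence(
            town19_bundle.graph,
            town19_bundle.partition("two_sides_left"),
            town19_ensemble,
        )
        assert res.log2_evidence <= 0
        assert res.codelength_bits >= 0

    def test_ranking_by_evidence_equals_ranking_by_codelength(
        self, rooms_bundle, rooms_ensemble
    ):
        results = [
            log_evidence(rooms_bundle.graph, rooms_bundle.partition(n),
                         rooms_ensemble)
            for n in ("flat", "doorways", "corners")
        ]
        by_ev = sorted(range(3), key=lambda i: results[i].log2_evidence)
        by_cl = sorted(
            range(3), key=lambda i: -results[i].codelength_bits
        )
        assert by_ev == by_cl


class TestMetrics:
    def test_codelength_is_negated_log_evidence(self, k3, k3_ensemble):
        res = log_evidence(k3, Partition.flat(k3), k3_ensemble)
        assert codelength(res) == pytest.approx(6.0, abs=1e-12)
        assert codelength(res) == -res.log2_evidence

    def test_k3_flat_geomean_two(self, k3, k3_ensemble):
        res = log_evidence(k3, Partition.flat(k3), k3_ensemble)
        assert res.per_task_attempts == {t: 2.0 for t in k3_ensemble.tasks}
        assert search_time(res) == pytest.approx(2.0, abs=1e-12)

    def test_single_edge_world_zero_bits(self):
        g = StateGraph.from_edges([("A", "B")])
        ps = all_pairs_unique_paths(g, sample_edge_costs(g, 0))
        ens = build_ensemble(ps, 0)
        res = log_evidence(g, Partition.flat(g), ens)
        assert res.codelength_bits == 0.0
        assert search_time(res) == 1.0

    def test_geomean_identity_random_instances(self, town10_bundle,
                                               town10_ensemble):
        for name in ("flat", "two_sides"):
            res = log_evidence(
                town10_bundle.graph, town10_bundle.partition(name),
                town10_ensemble,
            )
            T, O = res.num_tasks, res.num_options
            assert search_time(res) == pytest.approx(
                2.0 ** (res.codelength_bits / (T + O)), rel=1e-9
            )


class TestFastScorer:
    @pytest.mark.parametrize("fixture_name, part_names", [
        ("town10_bundle", ("flat", "two_sides")),
        ("toh_bundle", ("flat", "largest_disk")),
        ("schapiro_bundle", ("flat", "clusters")),
    ])
    def test_matches_full_scorer(self, request, fixture_name, part_names):
        bundle = request.getfixturevalue(fixture_name)
        g = bundle.graph
        ps = all_pairs_unique_paths(g, sample_edge_costs(g, 4))
        ens = build_ensemble(ps, 4)
        index = EnsembleIndex(g, ens)
        sv = g.sorted_vertices()
        for name in part_names:
            p = bundle.partition(name)
            fast = codelength_bits_fast(index, [p.assignment[v] for v in sv])
            full = log_evidence(g, p, ens).codelength_bits
            assert fast == pytest.approx(full, abs=1e-6)
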