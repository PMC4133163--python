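import pytest

from opthier.graph_domain import StateGraph
from opthier.task_ensemble import (
    all_pairs_unique_paths,
    build_ensemble,
    sample_edge_costs,
    select_path_set,
)
from opthier import fixtures as fixmod


@pytest.fixture(scope="session")
def path3():
    return StateGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def k3():
    return StateGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def path3_ensemble(path3):
    ps = all_pairs_unique_paths(path3, sample_edge_costs(path3, 0))
    return build_ensemble(ps, 0)


@pytest.fixture(scope="session")
def k3_ensemble(k3):
    ps = all_pairs_unique_paths(k3, sample_edge_costs(k3, 0))
    return build_ensemble(ps, 0)


@pytest.fixture(scope="session")
def rooms_bundle():
    return fixmod.make_rooms(3, 3)


@pytest.fixture(scope="session")
def rooms_ensemble(rooms_bundle):
    ps = select_path_set(rooms_bundle.graph, 200, 7)
    return build_ensemble(ps, 7)


@pytest.fixture(scope="session")
def toh_bundle():
    return fixmod.make_toh(3)


@pytest.fixture(scope="session")
def toh_ensemble(toh_bundle):
    ps = select_path_set(toh_bundle.graph, 30, 11)
    return build_ensemble(ps, 11)


@pytest.fixture(scope="session")
def town10_bundle():
    return fixmod.make_town(10)


@pytest.fixture(scope="session")
def town10_ensemble(town10_bundle):
    ps = select_path_set(town10_bundle.graph, 100, 3)
    return build_ensemble(ps, 3)


@pytest.fixture(scope="session")
def town19_bundle():
    return fixmod.make_town(19)


@pytest.fixture(scope="session")
def town19_ensemble(town19_bundle):
    ps = select_path_set(town19_bundle.graph, 20, 5)
    return build_ensemble(ps, 5)


@pytest.fixture(scope="session")
def schapiro_bundle():
    return fixmod.make_schapiro15()
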