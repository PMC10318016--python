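import itertools

import networkx as nx
import numpy as np
import pytest

from hillswitch.combinatorics import (
    RegularityError,
    assign_signature_indices,
    build_stg,
    domains,
    enumerate_parameter_graph,
    morse_graph,
    predicted_repertoire,
    representative_parameters,
    signature,
    signature_index,
    target_point,
    threshold_rank,
)
from hillswitch.parameters import SwitchingParameterSet, switching_set_from_row
from hillswitch.switching import switching_rhs

from conftest import random_regular_switching, symmetric_bistable_ts


def brute_force_production(network, q, alpha):
    """Independent oracle: production = rhs + gamma*x at a point inside D(alpha)."""
    from hillswitch.combinatorics import sorted_thresholds

    ths = sorted_thresholds(network, q)
    x = np.empty(len(network.nodes))
    for idx, k in enumerate(network.nodes):
        walls = [t for t, _ in ths[k]]
        bounds = [0.0] + walls + [2 * (walls[-1] if walls else 1.0) + 1.0]
        x[idx] = 0.5 * (bounds[alpha[idx]] + bounds[alpha[idx] + 1])
    gamma = np.array([q.degradation[k] for k in network.nodes])
    return switching_rhs(network, q, x) + gamma * x


def test_target_point_ts_both_above(ts, ts_symmetric):
    q = ts_symmetric
    t = target_point(ts, q, (1, 1))
    np.testing.assert_allclose(t, [0.5, 0.5])  # (L/gamma, L/gamma)


def test_target_point_single_input_activation_below_threshold(da):
    q = SwitchingParameterSet(
        degradation={"A": 2.0, "B": 1.0},
        low={("A", "B"): 1.0, ("B", "A"): 0.5},
        high={("A", "B"): 4.0, ("B", "A"): 5.0},
        threshold={("A", "B"): 2.0, ("B", "A"): 2.0},
    )
    t = target_point(da, q, (0, 0))  # both sources below thresholds
    np.testing.assert_allclose(t, [1.0 / 2.0, 0.5 / 1.0])  # L/gamma each


@pytest.mark.parametrize("netname", ["TS", "DA", "NF", "TT"])
def test_target_point_matches_brute_force(netname, request):
    from hillswitch.networks import builtin_network

    net = builtin_network(netname)
    rng = np.random.default_rng(17)
    for _ in range(5):
        if netname == "TT":
            low = {k: rng.uniform(0.05, 1.0) for k in net.edge_keys}
            q = SwitchingParameterSet(
                degradation={k: rng.uniform(0.2, 1.0) for k in net.nodes},
                low=low,
                high={k: low[k] * rng.uniform(2, 20) for k in net.edge_keys},
                threshold={k: rng.uniform(0.1, 10.0) for k in net.edge_keys},
            )
        else:
            q = random_regular_switching(net, rng)
        for alpha in domains(net):
            expected = brute_force_production(net, q, alpha)
            gamma = np.array([q.degradation[k] for k in net.nodes])
            np.testing.assert_allclose(target_point(net, q, alpha) * gamma, expected, rtol=1e-12)


def test_tt_domain_200_production(tt):
    q = SwitchingParameterSet(
        degradation={k: 2.0 for k in tt.nodes},
        low={k: 1.0 for k in tt.edge_keys},
        high={("A", "B"): 3.0, ("A", "C"): 5.0, ("B", "A"): 4.0,
              ("B", "C"): 4.0, ("C", "A"): 4.0, ("C", "B"): 4.0},
        threshold={k: 1.5 + 0.1 * i for i, k in enumerate(tt.edge_keys)},
    )
    # A at top level, B and C at 0: both repressors of A are off -> U_AB * U_AC
    t = target_point(tt, q, (2, 0, 0))
    assert t[0] == pytest.approx(3.0 * 5.0 / 2.0)


def test_stg_central_ts(ts, ts_symmetric):
    stg = build_stg(ts, ts_symmetric)
    assert stg.number_of_nodes() == 4
    assert stg.has_edge((0, 1), (0, 1)) and stg.has_edge((1, 0), (1, 0))
    assert not stg.has_edge((0, 0), (0, 0)) and not stg.has_edge((1, 1), (1, 1))
    # exactly one directed edge across every wall
    for a, b in [((0, 0), (0, 1)), ((0, 0), (1, 0)), ((1, 1), (0, 1)), ((1, 1), (1, 0))]:
        assert stg.has_edge(a, b) != stg.has_edge(b, a)


def test_global_attractor_stg_is_in_tree(ts):
    # gamma*theta above U on both factors: every target in domain (0, 0)
    q = representative_parameters(ts, (2, 2))
    stg = build_stg(ts, q)
    assert stg.has_edge((0, 0), (0, 0))
    for alpha in stg.nodes:
        assert nx.has_path(stg, alpha, (0, 0))


def test_morse_predictions_for_central_node(ts, da, nf):
    for net, expected in ((ts, "01-10"), (da, "00-11"), (nf, "cycle")):
        q = representative_parameters(net, (1, 1))
        assert predicted_repertoire(net, q) == expected


def test_nf_central_recurrent_component_is_four_cycle(nf):
    q = representative_parameters(nf, (1, 1))
    stg = build_stg(nf, q)
    assert not any(stg.has_edge(a, a) for a in stg.nodes)
    mg = morse_graph(stg)
    assert mg.attractors == ("cycle",)
    sinks = [n for n in mg.graph.nodes if mg.graph.out_degree(n) == 0]
    members = mg.graph.nodes[sinks[0]]["members"]
    assert sorted(members) == [(0, 0), (0, 1), (1, 0), (1, 1)]


def test_parameter_graph_structure(ts):
    pg = enumerate_parameter_graph(ts)
    assert pg.number_of_nodes() == 9
    degs = sorted(d for _, d in pg.degree())
    assert degs == [2, 2, 2, 2, 3, 3, 3, 3, 4]
    bistable = [n for n, d in pg.nodes(data=True)
                if d["repertoire"].count("-") == 1 and "cycle" not in d["repertoire"]]
    assert bistable == [4]
    assert pg.nodes[4]["repertoire"] == "01-10"
    # corner nodes are monostable
    for corner in (0, 2, 6, 8):
        assert "-" not in pg.nodes[corner]["repertoire"]


def test_parameter_graph_requires_single_input_output(tt):
    with pytest.raises(ValueError):
        enumerate_parameter_graph(tt)


def test_signature_index_center(ts, ts_symmetric):
    assert signature_index(ts, signature(ts, ts_symmetric)) == 4


def test_signature_scaling_invariance(ts):
    rng = np.random.default_rng(3)
    q = random_regular_switching(ts, rng)
    idx0 = signature_index(ts, signature(ts, q))
    c = 11.0
    scaled = SwitchingParameterSet(
        degradation={k: c * v for k, v in q.degradation.items()},
        low={k: c * v for k, v in q.low.items()},
        high={k: c * v for k, v in q.high.items()},
        threshold=q.threshold,
    )
    assert signature_index(ts, signature(ts, scaled)) == idx0


def test_signature_rejects_degenerate_parameters(ts):
    q = SwitchingParameterSet(
        degradation={"A": 1.0, "B": 1.0},
        low={("A", "B"): 1.0, ("B", "A"): 1.0},
        high={("A", "B"): 2.0, ("B", "A"): 3.0},
        threshold={("A", "B"): 2.0, ("B", "A"): 2.0},
    )
    with pytest.raises(RegularityError):
        signature(ts, q)


@pytest.mark.parametrize("netname", ["TS", "DA", "NF"])
def test_signature_route_matches_direct_morse_route(netname):
    """Per-sample Morse repertoire equals the enumerated graph's tabulated one."""
    from hillswitch.networks import builtin_network

    net = builtin_network(netname)
    pg = enumerate_parameter_graph(net)
    rng = np.random.default_rng(29)
    for _ in range(200):
        q = random_regular_switching(net, rng)
        idx = signature_index(net, signature(net, q))
        assert predicted_repertoire(net, q) == pg.nodes[idx]["repertoire"]


def test_stg_no_stuck_domains_and_dag_morse(ts, da, nf):
    rng = np.random.default_rng(31)
    for net in (ts, da, nf):
        for _ in range(20):
            q = random_regular_switching(net, rng)
            stg = build_stg(net, q)
            for alpha in stg.nodes:
                assert stg.out_degree(alpha) >= 1  # self-edge or a way out
            mg = morse_graph(stg)
            assert nx.is_directed_acyclic_graph(mg.graph)
            assert len(mg.attractors) >= 1


def test_vectorized_assignment_matches_scalar(ts, ts_ensemble):
    params, sw = ts_ensemble
    idx = assign_signature_indices(ts, sw)
    for pos in range(0, 60, 7):
        q = switching_set_from_row(ts, sw.iloc[pos])
        assert signature_index(ts, signature(ts, q)) == idx[pos]


def test_brute_force_ode_oracle_two_node(ts, da):
    """Exhaustive Euler integration from a grid recovers exactly the Morse FPs."""
    for net, choices in ((ts, (1, 1)), (da, (1, 1)), (ts, (0, 2))):
        q = representative_parameters(net, choices)
        stg = build_stg(net, q)
        mg = morse_graph(stg)
        predicted = {a for a in mg.attractors if a != "cycle"}
        reached = set()
        gamma = np.array([q.degradation[k] for k in net.nodes])
        from hillswitch.combinatorics import sorted_thresholds, level_of

        ths = sorted_thresholds(net, q)
        walls = {k: [t for t, _ in ths[k]] for k in net.nodes}
        for x0 in itertools.product(np.linspace(0.05, 6.0, 12), repeat=2):
            x = np.array(x0)
            for _ in range(4000):
                x = x + 0.01 * switching_rhs(net, q, x)
            if np.max(np.abs(switching_rhs(net, q, x))) < 1e-6:
                reached.add("".join(str(level_of(x[i], walls[k])) for i, k in enumerate(net.nodes)))
        assert reached == predicted
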