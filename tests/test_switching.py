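import numpy as np
import pytest

from hillswitch.combinatorics import build_stg, morse_graph, representative_parameters
from hillswitch.parameters import SwitchingParameterSet
from hillswitch.switching import (
    basin_report,
    classify_states,
    da_separatrix_side,
    euler_final_states,
    integrate_event_driven,
    stable_fixed_points,
    ts_separatrix_side,
    uniform_box_initial_conditions,
)

from conftest import random_regular_switching


def test_event_driven_fp_by_containment(ts, ts_symmetric):
    # domain II (x low, y high) contains FP(01): classified without any event
    trj = integrate_event_driven(ts, ts_symmetric, np.array([1.0, 3.0]))
    assert trj.classification == "FP(01)"
    assert len(trj.events) == 1


def test_event_driven_crossing_order_decides_attractor(ts, ts_symmetric):
    # domain III, x much closer to its threshold: y crosses later -> FP(10)
    trj = integrate_event_driven(ts, ts_symmetric, np.array([3.9, 2.1]))
    assert trj.classification == "FP(10)"
    trj = integrate_event_driven(ts, ts_symmetric, np.array([2.1, 3.9]))
    assert trj.classification == "FP(01)"


def test_event_driven_nf_cycle_matches_stg_recurrence(nf):
    q = representative_parameters(nf, (1, 1))
    trj = integrate_event_driven(nf, q, np.array([0.4, 0.3]))
    assert trj.classification == "cycle"
    assert set(trj.cycle_domains) == {(0, 0), (0, 1), (1, 0), (1, 1)}
    stg = build_stg(nf, q)
    mg = morse_graph(stg)
    sink = [n for n in mg.graph.nodes if mg.graph.out_degree(n) == 0][0]
    assert set(trj.cycle_domains) == set(mg.graph.nodes[sink]["members"])


def test_event_times_strictly_positive_and_domains_adjacent(ts):
    rng = np.random.default_rng(5)
    for _ in range(20):
        q = random_regular_switching(ts, rng, center_only=True)
        ic = uniform_box_initial_conditions(ts, q, 1, rng)[0]
        trj = integrate_event_driven(ts, q, ic)
        times = [t for _, t, _ in trj.events]
        assert all(b > a for a, b in zip(times, times[1:]))
        for (a, _, _), (b, _, _) in zip(trj.events, trj.events[1:]):
            assert sum(abs(x - y) for x, y in zip(a, b)) == 1


def test_separatrix_symmetric_parameters_is_diagonal(ts, ts_symmetric):
    for v in (2.2, 3.0, 3.8):
        assert ts_separatrix_side(ts, ts_symmetric, (v + 1e-6, v - 1e-6)) == "FP(10)"
        assert ts_separatrix_side(ts, ts_symmetric, (v - 1e-6, v + 1e-6)) == "FP(01)"
    assert ts_separatrix_side(ts, ts_symmetric, (3.0, 3.0)) == "ambiguous"


def test_separatrix_log_form_matches_crossing_times(ts):
    """Domain III rule equals the explicit log-difference separatrix equation."""
    rng = np.random.default_rng(6)
    for _ in range(50):
        q = random_regular_switching(ts, rng, center_only=True)
        gx, gy = q.degradation["A"], q.degradation["B"]
        Lxy, Lyx = q.low[("A", "B")], q.low[("B", "A")]
        thyx, thxy = q.threshold[("B", "A")], q.threshold[("A", "B")]
        x0 = thyx * rng.uniform(1.05, 3.0)
        y0 = thxy * rng.uniform(1.05, 3.0)
        lhs = gy * np.log(gx * thyx - Lxy) - gx * np.log(gy * thxy - Lyx)
        rhs = gy * np.log(gx * x0 - Lxy) - gx * np.log(gy * y0 - Lyx)
        expected = "FP(10)" if lhs < rhs else "FP(01)"
        assert ts_separatrix_side(ts, q, (x0, y0)) == expected


def test_separatrix_precondition_enforced(ts):
    q = representative_parameters(ts, (0, 2))  # monostable region
    with pytest.raises(Exception):
        ts_separatrix_side(ts, q, (1.0, 1.0))


@pytest.mark.parametrize("motif, side_fn", [("TS", ts_separatrix_side), ("DA", da_separatrix_side)])
def test_separatrix_agrees_with_event_driven_oracle(motif, side_fn, request):
    from hillswitch.networks import builtin_network

    net = builtin_network(motif)
    rng = np.random.default_rng(7)
    agree = total = 0
    for _ in range(40):
        q = random_regular_switching(net, rng, center_only=True)
        for ic in uniform_box_initial_conditions(net, q, 20, rng):
            analytic = side_fn(net, q, ic)
            trj = integrate_event_driven(net, q, ic)
            if "ambiguous" in (analytic, trj.classification):
                continue
            total += 1
            agree += analytic == trj.classification
    assert total > 500
    assert agree == total  # exact: both are closed-form descriptions of the same flow


def test_separatrix_classification_is_flow_invariant(ts):
    """The attractor assigned to an IC equals the one assigned after one wall
    crossing of the exact flow (basins are invariant under the dynamics)."""
    rng = np.random.default_rng(8)
    checked = 0
    for _ in range(30):
        q = random_regular_switching(ts, rng, center_only=True)
        ic = uniform_box_initial_conditions(ts, q, 1, rng)[0]
        before = ts_separatrix_side(ts, q, ic)
        trj = integrate_event_driven(ts, q, ic)
        if before == "ambiguous" or len(trj.events) < 2:
            continue
        _, _, x1 = trj.events[1]
        x1 = np.array(x1) * (1 + 1e-9)  # nudge off the wall
        after = ts_separatrix_side(ts, q, x1)
        if after == "ambiguous":
            continue
        checked += 1
        assert after == before
    assert checked > 10


def test_euler_agrees_with_event_driven_away_from_separatrix(ts, ts_symmetric):
    ics = np.array([[3.9, 2.1], [2.1, 3.9], [0.1, 1.9], [1.9, 0.1]])
    finals = euler_final_states(ts, ts_symmetric, ics, step=0.05)[0]
    labels = classify_states(ts, ts_symmetric, finals)
    expected = [integrate_event_driven(ts, ts_symmetric, ic).classification for ic in ics]
    assert labels == expected


def test_euler_agreement_improves_as_step_shrinks(ts):
    rng = np.random.default_rng(9)
    rates = []
    qs = [random_regular_switching(ts, rng, center_only=True) for _ in range(15)]
    ics = {i: uniform_box_initial_conditions(ts, q, 60, rng) for i, q in enumerate(qs)}
    for step in (0.4, 0.05):
        agree = total = 0
        for i, q in enumerate(qs):
            labels = classify_states(ts, q, euler_final_states(ts, q, ics[i], step=step)[0])
            for ic, lab in zip(ics[i], labels):
                analytic = ts_separatrix_side(ts, q, ic)
                if analytic == "ambiguous":
                    continue
                total += 1
                agree += lab == analytic
        rates.append(agree / total)
    assert rates[-1] >= rates[0]
    assert rates[-1] > 0.97


def test_stable_fixed_points_central_ts(ts, ts_symmetric):
    fps = stable_fixed_points(ts, ts_symmetric)
    assert set(fps) == {"01", "10"}
    np.testing.assert_allclose(fps["10"], [4.0, 0.5])  # (U/gamma, L/gamma)


def test_basin_report_products():
    assert basin_report(["FP(10)"] * 10).strength == pytest.approx(1.0)
    assert basin_report(["FP(10)"] * 5 + ["FP(01)"] * 5).strength == pytest.approx(0.25)
    assert basin_report(["FP(10)"] * 9 + ["FP(01)"] * 1).strength == pytest.approx(0.09)
    rep = basin_report(["FP(10)"] * 5 + ["FP(01)"] * 3 + [None] * 2)
    assert sum(rep.fractions.values()) <= 1.0
    assert rep.n_classified == 8 and rep.n_total == 10
    with pytest.raises(ValueError):
        basin_report([])
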