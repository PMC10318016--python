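import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hillswitch.combinatorics import assign_signature_indices
from hillswitch.hill import (
    DiscretizationError,
    IntegratorSettings,
    discretize,
    hill_rhs,
    shifted_hill,
    simulate_ensemble,
    verify_steady_state,
)
from hillswitch.networks import Network
from hillswitch.parameters import RacipeParameterSet, racipe_set_from_row, switching_set_from_row
from hillswitch.sampling import SamplingConfig, sample_parameters
from hillswitch.switching import stable_fixed_points
from hillswitch.translate import translate_frame, to_switching


def test_shifted_hill_anchor_values():
    assert shifted_hill(0.0, 3.0, 7.0, 0.2) == pytest.approx(1.0)
    assert shifted_hill(3.0, 3.0, 7.0, 0.2) == pytest.approx(0.6)  # (1 + lam) / 2
    assert shifted_hill(1e9, 3.0, 7.0, 0.2) == pytest.approx(0.2, abs=1e-6)
    assert shifted_hill(1e9, 3.0, 7.0, 5.0) == pytest.approx(5.0, rel=1e-6)


@given(
    x=st.floats(0.0, 1e6),
    theta=st.floats(1e-3, 1e3),
    n=st.floats(1.0, 500.0),
    lam=st.floats(0.01, 0.99),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_shifted_hill_repression_bounds_and_monotonicity(x, theta, n, lam):
    h = shifted_hill(x, theta, n, lam)
    assert lam <= h <= 1.0
    assert shifted_hill(x * 1.5 + 1e-9, theta, n, lam) <= h + 1e-12


def single_node():
    net = Network(nodes=("A",), edges=())
    p = RacipeParameterSet(
        production={"A": 6.0}, degradation={"A": 2.0}, threshold={}, hill={}, fold={}
    )
    return net, p


def test_rhs_single_node_closed_form():
    net, p = single_node()
    assert hill_rhs(net, p, np.array([1.0]))[0] == pytest.approx(6.0 - 2.0)
    with pytest.raises(ValueError):
        hill_rhs(net, p, np.array([-0.1]))


def test_verify_residual_is_linear_in_perturbation():
    net, p = single_node()
    fp = 3.0  # P / gamma
    assert verify_steady_state(net, p, np.array([fp])) == 0.0
    delta = 1e-3
    assert verify_steady_state(net, p, np.array([fp + delta])) == pytest.approx(2.0 * delta)


def test_single_node_converges_to_fixed_point_from_any_ic():
    net, p = single_node()
    frame = pd.DataFrame([{"P_A": 6.0, "gamma_A": 2.0}])
    ics = np.array([[[0.01], [1.0], [30.0]]])
    records, flags = simulate_ensemble(net, frame, initial_conditions=ics)
    assert len(records) == 1
    assert records["x_A"].iloc[0] == pytest.approx(3.0, rel=1e-3)
    assert bool(records["verified"].iloc[0])
    assert records["weight"].iloc[0] == 1.0


@pytest.fixture(scope="module")
def central_steep(ts):
    cfg = SamplingConfig(n_sets=300, seed=42, hill=(6.0, 12.0))
    params = sample_parameters(ts, cfg)
    sw = translate_frame(ts, params)
    idx = assign_signature_indices(ts, sw)
    return params[idx == 4].head(40), sw


def test_central_steep_sets_recover_switching_fixed_points(ts, central_steep):
    """At steep Hill coefficients, verified states approach the translated
    switching system's fixed points (cross-formalism consistency)."""
    sub, sw = central_steep
    records, flags = simulate_ensemble(ts, sub, n_init=100, seed=7)
    ver = records[records["verified"]]
    matched = total = 0
    for pid in sub.index:
        q = switching_set_from_row(ts, sw.loc[pid])
        fps = np.array(list(stable_fixed_points(ts, q).values()))
        g = ver[ver["param_id"] == pid]
        for _, r in g.iterrows():
            x = np.array([r["x_A"], r["x_B"]])
            rel = np.min(np.max(np.abs(np.log(x[None, :] / fps)), axis=1))
            total += 1
            matched += rel < 0.5  # within a factor e^0.5 of an exact switching FP
    assert total > 0 and matched / total > 0.9


def test_weights_sum_to_one_per_set(ts, central_steep):
    sub, _ = central_steep
    records, _ = simulate_ensemble(ts, sub, n_init=50, seed=8)
    sums = records.groupby("param_id")["weight"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_step_halving_moves_states_less_than_merge_tolerance(ts, central_steep):
    sub, _ = central_steep
    one = sub.head(5)
    from hillswitch.sampling import initial_conditions_for_frame

    ics = initial_conditions_for_frame(ts, one, 30, seed=9)
    coarse, _ = simulate_ensemble(ts, one, initial_conditions=ics,
                                  settings=IntegratorSettings(step=0.05))
    fine, _ = simulate_ensemble(ts, one, initial_conditions=ics,
                                settings=IntegratorSettings(step=0.025))
    for pid in one.index:
        a = coarse[(coarse["param_id"] == pid) & coarse["verified"]]
        b = fine[(fine["param_id"] == pid) & fine["verified"]]
        assert len(a) == len(b)
        for _, ra in a.iterrows():
            xa = np.array([ra["x_A"], ra["x_B"]])
            dists = [
                np.max(np.abs(xa - np.array([rb["x_A"], rb["x_B"]])) / (np.abs(xa) + 1e-12))
                for _, rb in b.iterrows()
            ]
            assert min(dists) < 1e-2


def test_more_initial_conditions_never_lose_attractors(ts, central_steep):
    sub, _ = central_steep
    few, _ = simulate_ensemble(ts, sub.head(15), n_init=25, seed=10)
    many, _ = simulate_ensemble(ts, sub.head(15), n_init=200, seed=10)
    n_few = few[few["verified"]].groupby("param_id").size()
    n_many = many[many["verified"]].groupby("param_id").size()
    assert (n_many.reindex(n_few.index, fill_value=0) >= n_few).all()


def test_cyclic_flagging_for_negative_feedback(nf):
    cfg = SamplingConfig(n_sets=120, seed=43, hill=(10.0, 50.0))
    params = sample_parameters(nf, cfg)
    sw = translate_frame(nf, params)
    idx = assign_signature_indices(nf, sw)
    central = params[idx == 4].head(25)
    records, flags = simulate_ensemble(nf, central, n_init=40, seed=11)
    assert flags["cyclic"].mean() > 0.5
    # at the default shallow range the same parameter sets converge and verify
    shallow = central.copy()
    rng = np.random.default_rng(12)
    for col in ("n_BA", "n_AB"):
        shallow[col] = rng.uniform(1.0, 6.0, len(shallow))
    rec2, fl2 = simulate_ensemble(nf, shallow, n_init=40, seed=13)
    assert not fl2["cyclic"].any()
    assert rec2["verified"].all()


def test_discretize_standardization_identity_and_symmetry(ts):
    records = pd.DataFrame(
        [
            {"param_id": 0, "x_A": 10.0, "x_B": 1.0, "weight": 0.5, "residual": 0.0, "verified": True},
            {"param_id": 0, "x_A": 1.0, "x_B": 10.0, "weight": 0.5, "residual": 0.0, "verified": True},
        ]
    )
    flags = pd.DataFrame([{"param_id": 0, "n_states": 2, "cyclic": False, "n_divergent": 0}])
    labeled, reps = discretize(ts, records, flags)
    for k in ts.nodes:
        z = labeled[f"z_{k}"].to_numpy()
        w = labeled["weight"].to_numpy()
        assert np.average(z, weights=w) == pytest.approx(0.0, abs=1e-12)
        assert np.sqrt(np.average(z**2, weights=w)) == pytest.approx(1.0, rel=1e-12)
    assert sorted(labeled["label"]) == ["01", "10"]
    assert reps["repertoire"].iloc[0] == "01-10"
    assert reps["class"].iloc[0] == "bistable"


def test_discretize_zero_sd_raises(ts):
    records = pd.DataFrame(
        [
            {"param_id": 0, "x_A": 5.0, "x_B": 1.0, "weight": 1.0, "residual": 0.0, "verified": True},
            {"param_id": 1, "x_A": 5.0, "x_B": 2.0, "weight": 1.0, "residual": 0.0, "verified": True},
        ]
    )
    flags = pd.DataFrame(
        [
            {"param_id": 0, "n_states": 1, "cyclic": False, "n_divergent": 0},
            {"param_id": 1, "n_states": 1, "cyclic": False, "n_divergent": 0},
        ]
    )
    with pytest.raises(DiscretizationError, match="node A"):
        discretize(ts, records, flags)


def test_adaptive_integrator_agrees_with_euler(ts, central_steep):
    sub, _ = central_steep
    one = sub.head(2)
    from hillswitch.sampling import initial_conditions_for_frame

    ics = initial_conditions_for_frame(ts, one, 10, seed=14)
    a, _ = simulate_ensemble(ts, one, initial_conditions=ics)
    b, _ = simulate_ensemble(ts, one, initial_conditions=ics,
                             settings=IntegratorSettings(adaptive=True))
    for pid in one.index:
        xa = a[(a["param_id"] == pid) & a["verified"]][["x_A", "x_B"]].to_numpy()
        xb = b[(b["param_id"] == pid) & b["verified"]][["x_A", "x_B"]].to_numpy()
        assert len(xa) == len(xb)
        for row in xa:
            assert np.min(np.max(np.abs(xb - row) / (np.abs(row) + 1e-9), axis=1)) < 1e-2
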