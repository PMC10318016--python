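"""Shifted-Hill ODE ensembles: integration, steady-state detection, discretization.

Each node k of a network evolves as

    dx_k/dt = P_k * prod_{j->k} H(x_j, theta, n, a)/a * prod_{j-|k} H(x_j, theta, n, i) - gamma_k x_k

with the shifted Hill function H(x, T, n, lam) = lam + (1-lam) T^n / (T^n + x^n),
activation fold a > 1 and repression fold i < 1.  For every sampled parameter
set, many initial conditions are integrated with fixed-step Euler (the
reference scheme for this kind of ensemble screen; an adaptive integrator is
available by flag), final states are merged into distinct candidate steady
states, each candidate is verified by requiring a small root-mean-square
derivative, and the fraction of initial conditions reaching each verified
state is its basin weight.

A parameter set whose trajectories scatter over at least ``max_states``
distinct final states, none of which verifies as a steady state, is flagged
*cyclic*: that is the fingerprint a limit cycle leaves on a steady-state
detector that records final integration points.

Discretization pools all verified states of the ensemble, z-scores each
node's (log2-transformed) expression with basin weights, and binarizes at
zero; the sorted distinct labels of a parameter set form its canonical
attractor repertoire (e.g. ``01-10``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .networks import Network
from .parameters import RacipeParameterSet, ensemble_arrays, racipe_row_from_set
from .sampling import initial_conditions_for_frame


def shifted_hill(x, threshold, n, fold):
    """Shifted Hill function lam + (1-lam) T^n / (T^n + x^n), elementwise.

    Computed via (x/T)^n so very large Hill coefficients saturate cleanly
    instead of overflowing in T^n.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        ratio_pow = (x / threshold) ** n
    return fold + (1.0 - fold) / (1.0 + ratio_pow)


def hill_rhs(network: Network, p: RacipeParameterSet, x: np.ndarray) -> np.ndarray:
    """Derivative vector of the shifted-Hill model at state ``x`` (componentwise >= 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("state must be componentwise non-negative")
    dx = np.empty(len(network.nodes))
    for idx, k in enumerate(network.nodes):
        prod = p.production[k]
        for e in network.inputs(k):
            key = (k, e.source)
            xj = x[network.node_index(e.source)]
            h = shifted_hill(xj, p.threshold[key], p.hill[key], p.fold[key])
            prod *= h / p.fold[key] if e.is_activation else h
        dx[idx] = prod - p.degradation[k] * x[idx]
    return dx


def verify_steady_state(network: Network, p: RacipeParameterSet, x: np.ndarray) -> float:
    """Root-mean-square of the derivative components at ``x``.

    A state verifies as steady when this residual is below the tolerance
    (default 1e-4 throughout the package).
    """
    dx = hill_rhs(network, p, x)
    return float(np.sqrt(np.mean(dx**2)))


@dataclass(frozen=True)
class IntegratorSettings:
    """Fixed-step Euler settings and steady-state bookkeeping tolerances.

    ``horizon=None`` integrates to 200 / gamma_min of the ensemble, i.e. at
    least twenty decay time scales of the slowest sampled node.  Trajectories
    are frozen early once their RMS derivative falls below ``freeze_tol``
    (stricter than ``verify_tol`` so freezing can never fake a verification).
    """

    step: float = 0.05
    horizon: float | None = None
    merge_rtol: float = 1e-2
    max_states: int = 10
    verify_tol: float = 1e-4
    freeze_tol: float = 1e-5
    check_every: int = 50
    adaptive: bool = False


def _edge_meta(network: Network) -> list[tuple[int, int, bool]]:
    return [
        (network.node_index(e.source), network.node_index(e.target), e.is_activation)
        for e in network.edges
    ]


def _production(X: np.ndarray, P, theta, hill, fold, meta) -> np.ndarray:
    prod = P.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for e_idx, (src, tgt, is_act) in enumerate(meta):
            ratio_pow = (X[:, src] / theta[:, e_idx]) ** hill[:, e_idx]
            lam = fold[:, e_idx]
            h = lam + (1.0 - lam) / (1.0 + ratio_pow)
            prod[:, tgt] *= h / lam if is_act else h
    return prod


def _as_frame(network: Network, params) -> pd.DataFrame:
    if isinstance(params, pd.DataFrame):
        return params
    return pd.DataFrame([racipe_row_from_set(network, params)])


def simulate_ensemble(
    network: Network,
    params: Union[pd.DataFrame, RacipeParameterSet],
    initial_conditions: np.ndarray | None = None,
    settings: IntegratorSettings | None = None,
    n_init: int = 100,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate every (parameter set, initial condition) pair to its final state.

    ``initial_conditions`` has shape (M, K, n) (or (K, n) for a single set);
    if omitted, K = ``n_init`` log-uniform conditions are drawn per set.

    Returns ``(records, flags)``:

    * ``records`` -- one row per distinct final state of each set: ``param_id``,
      one expression column ``x_<node>`` per node, ``weight`` (fraction of
      that set's convergent initial conditions), ``residual`` and ``verified``;
    * ``flags`` -- one row per set: ``param_id``, ``n_states``, ``cyclic``,
      ``n_divergent``.
    """
    settings = settings or IntegratorSettings()
    frame = _as_frame(network, params)
    arrays = ensemble_arrays(network, frame)
    M = len(frame)
    n = len(network.nodes)
    if initial_conditions is None:
        initial_conditions = initial_conditions_for_frame(network, frame, n_init, seed)
    ics = np.asarray(initial_conditions, dtype=float)
    if ics.ndim == 2:
        ics = np.broadcast_to(ics, (M,) + ics.shape)
    K = ics.shape[1]

    gamma_min = arrays["gamma"].min() if M else 1.0
    horizon = settings.horizon if settings.horizon is not None else 200.0 / gamma_min
    if settings.adaptive:
        final, residuals = _integrate_adaptive(network, frame, ics, horizon, settings)
    else:
        final, residuals = _integrate_euler_ensemble(network, arrays, ics, horizon, settings)

    return _collect_states(network, frame, final, residuals, settings)


def _integrate_euler_ensemble(network, arrays, ics, horizon, settings):
    M, K, n = ics.shape
    R = M * K
    meta = _edge_meta(network)
    rep = lambda a: np.repeat(a, K, axis=0)
    P, gamma = rep(arrays["P"]), rep(arrays["gamma"])
    theta, hill, fold = rep(arrays["theta"]), rep(arrays["hill"]), rep(arrays["fold"])

    X = ics.reshape(R, n).copy()
    final = np.full((R, n), np.nan)
    final_res = np.full(R, np.inf)
    active = np.arange(R)
    h = settings.step
    n_steps = max(1, int(np.ceil(horizon / h)))
    block = max(1, settings.check_every)
    done = 0
    while done < n_steps and active.size:
        steps = min(block, n_steps - done)
        Pa, ga = P[active], gamma[active]
        ta, na, fa = theta[active], hill[active], fold[active]
        Xa = X[active]
        for _ in range(steps):
            dX = _production(Xa, Pa, ta, na, fa, meta) - ga * Xa
            Xa += h * dX
        done += steps
        dX = _production(Xa, Pa, ta, na, fa, meta) - ga * Xa
        res = np.sqrt(np.mean(dX**2, axis=1))
        finite = np.isfinite(Xa).all(axis=1) & np.isfinite(res)
        frozen = finite & (res < settings.freeze_tol)
        diverged = ~finite
        X[active] = Xa
        stop = frozen | diverged
        if stop.any():
            idx = active[stop]
            final[idx] = np.where(np.isfinite(X[idx]), X[idx], np.nan)
            final_res[idx] = np.where(diverged[stop], np.inf, res[stop])
            active = active[~stop]
    if active.size:  # horizon reached without convergence
        Xa = X[active]
        dX = _production(Xa, P[active], theta[active], hill[active], fold[active], meta) - gamma[active] * Xa
        res = np.sqrt(np.mean(dX**2, axis=1))
        finite = np.isfinite(Xa).all(axis=1) & np.isfinite(res)
        final[active] = np.where(finite[:, None], Xa, np.nan)
        final_res[active] = np.where(finite, res, np.inf)
    return final.reshape(M, K, n), final_res.reshape(M, K)


def _integrate_adaptive(network, frame, ics, horizon, settings):
    from scipy.integrate import solve_ivp

    from .parameters import racipe_set_from_row

    M, K, n = ics.shape
    final = np.full((M, K, n), np.nan)
    residuals = np.full((M, K), np.inf)
    for s, (_, row) in enumerate(frame.iterrows()):
        p = racipe_set_from_row(network, row)
        fun = lambda t, x: hill_rhs(network, p, np.maximum(x, 0.0))
        for k in range(K):
            sol = solve_ivp(fun, (0.0, horizon), ics[s, k], method="LSODA", rtol=1e-8, atol=1e-10)
            if sol.success and np.isfinite(sol.y[:, -1]).all():
                x = np.maximum(sol.y[:, -1], 0.0)
                final[s, k] = x
                residuals[s, k] = verify_steady_state(network, p, x)
    return final, residuals


def _merge_states(states: np.ndarray, rtol: float) -> tuple[list[np.ndarray], list[int]]:
    """Greedy clustering of final states with per-coordinate relative tolerance."""
    qa = np.log(np.maximum(states, 1e-300)) / np.log1p(rtol)
    quant = np.round(qa).astype(np.int64)
    uniq, inverse, counts = np.unique(quant, axis=0, return_inverse=True, return_counts=True)
    reps: list[np.ndarray] = []
    rep_counts: list[int] = []
    assign = np.empty(len(uniq), dtype=int)
    order = np.argsort(-counts)
    for u in order:
        members = states[inverse == u]
        centroid = members.mean(axis=0)
        for r, rep in enumerate(reps):
            scale = 0.5 * (np.abs(rep) + np.abs(centroid)) + 1e-12
            if np.all(np.abs(rep - centroid) <= 2.0 * rtol * scale):
                assign[u] = r
                w_old, w_new = rep_counts[r], int(counts[u])
                reps[r] = (rep * w_old + centroid * w_new) / (w_old + w_new)
                rep_counts[r] += w_new
                break
        else:
            assign[u] = len(reps)
            reps.append(centroid)
            rep_counts.append(int(counts[u]))
    return reps, rep_counts


def _collect_states(network, frame, final, residuals, settings):
    from .parameters import racipe_set_from_row

    M, K, n = final.shape
    rec_rows = []
    flag_rows = []
    for s, (pid, row) in enumerate(zip(frame.index, frame.itertuples(index=False))):
        ok = np.isfinite(final[s]).all(axis=1)
        n_div = int(K - ok.sum())
        states = final[s][ok]
        if len(states) == 0:
            flag_rows.append({"param_id": pid, "n_states": 0, "cyclic": False, "n_divergent": n_div})
            continue
        reps, counts = _merge_states(states, settings.merge_rtol)
        p = racipe_set_from_row(network, frame.loc[pid])
        any_verified = False
        for rep, count in zip(reps, counts):
            res = verify_steady_state(network, p, rep)
            verified = res < settings.verify_tol
            any_verified |= verified
            rec = {"param_id": pid, "weight": count / len(states), "residual": res, "verified": verified}
            for idx, k in enumerate(network.nodes):
                rec[f"x_{k}"] = rep[idx]
            rec_rows.append(rec)
        cyclic = (len(reps) >= settings.max_states) and not any_verified
        flag_rows.append(
            {"param_id": pid, "n_states": len(reps), "cyclic": cyclic, "n_divergent": n_div}
        )
    cols = ["param_id"] + [f"x_{k}" for k in network.nodes] + ["weight", "residual", "verified"]
    records = pd.DataFrame(rec_rows, columns=cols) if rec_rows else pd.DataFrame(columns=cols)
    flags = pd.DataFrame(flag_rows, columns=["param_id", "n_states", "cyclic", "n_divergent"])
    return records, flags


class DiscretizationError(ValueError):
    pass


def discretize(
    network: Network,
    records: pd.DataFrame,
    flags: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binarize verified steady states and assemble per-set attractor repertoires.

    Pools all verified rows of the ensemble; per node, computes the
    basin-weighted mean and standard deviation of (by default log2) expression
    and binarizes the weighted z-score at zero (z >= 0 -> 1).  Returns
    ``(labeled_records, repertoires)`` where ``repertoires`` has one row per
    parameter set with its canonical sorted label string and class
    (monostable / bistable / ... / cyclic).
    """
    ver = records[records["verified"]].copy()
    if len(ver) < 2:
        raise DiscretizationError("need at least two verified states to standardize")
    w = ver["weight"].to_numpy(float)
    labels = np.empty((len(ver), len(network.nodes)), dtype=int)
    for idx, k in enumerate(network.nodes):
        x = ver[f"x_{k}"].to_numpy(float)
        if log_transform:
            x = np.log2(np.maximum(x, 1e-300))
        mean = np.average(x, weights=w)
        sd = np.sqrt(np.average((x - mean) ** 2, weights=w))
        if sd == 0:
            raise DiscretizationError(f"zero weighted standard deviation at node {k}")
        z = (x - mean) / sd
        ver[f"z_{k}"] = z
        labels[:, idx] = (z >= 0).astype(int)
    ver["label"] = ["".join(map(str, row)) for row in labels]

    cyclic_ids = set(flags.loc[flags["cyclic"], "param_id"])
    class_names = {1: "monostable", 2: "bistable", 3: "tristable", 4: "tetrastable"}
    rep_rows = []
    grouped = {pid: g for pid, g in ver.groupby("param_id")}
    for pid in flags["param_id"]:
        if pid in cyclic_ids:
            rep_rows.append(
                {"param_id": pid, "repertoire": "cyclic", "n_attractors": 0, "class": "cyclic"}
            )
            continue
        g = grouped.get(pid)
        if g is None:
            rep_rows.append(
                {"param_id": pid, "repertoire": "", "n_attractors": 0, "class": "unclassified"}
            )
            continue
        uniq = sorted(set(g["label"]))
        k = len(uniq)
        rep_rows.append(
            {
                "param_id": pid,
                "repertoire": "-".join(uniq),
                "n_attractors": k,
                "class": class_names.get(k, f"{k}-stable"),
            }
        )
    repertoires = pd.DataFrame(rep_rows, columns=["param_id", "repertoire", "n_attractors", "class"])
    return ver, repertoires
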