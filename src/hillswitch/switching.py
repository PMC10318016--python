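"""Switching-system trajectory simulation, analytic separatrices and basins.

Within one rectangular phase-space domain a switching system is linear:
every coordinate decays exponentially toward the domain's constant target
point.  The event-driven integrator exploits this to advance trajectories
exactly from wall crossing to wall crossing in closed form -- no
discretization error -- terminating at a stable fixed point (the target
lies inside the current domain) or at a cycle (a (domain, exit-wall) pair
repeats).  A fixed-step Euler integrator of the same vector field is also
provided: it reproduces the purely numerical basin estimation that larger
networks force, and its disagreement with the exact trajectories measures
the cost of that approximation.

For the two-node mutual-repression and mutual-activation motifs in their
bistable parameter region, the basin boundary (the stable manifold of the
saddle at the threshold crossing point) has a closed form: equating the two
wall-crossing times of the within-domain solution gives a separatrix
equation in the initial condition, so any initial condition can be assigned
to its attractor without integration.

Basin sizes are summarized by *basin strength*: the product over detected
attractors of the fractions of initial conditions converging to each
(at most 1 for monostable sets, at most 0.25 for bistable ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .combinatorics import (
    DomainIndex,
    fp_label,
    level_of,
    morse_graph,
    build_stg,
    sorted_thresholds,
    target_point,
    threshold_rank,
)
from .networks import Network
from .parameters import SwitchingParameterSet, _ek, switching_set_from_row

AMBIGUOUS = "ambiguous"


class PreconditionError(ValueError):
    """Raised when a separatrix formula is applied outside its parameter region."""


@dataclass(frozen=True)
class SwitchingTrajectory:
    """Event-driven trajectory: visited domains and terminal classification.

    ``events`` holds (domain, entry time, entry state); ``classification``
    is ``FP(<digits>)``, ``cycle`` or ``ambiguous``; for cycles,
    ``cycle_domains`` records the repeating domain sequence.
    """

    events: tuple[tuple[DomainIndex, float, tuple[float, ...]], ...]
    classification: str
    cycle_domains: tuple[DomainIndex, ...] | None = None


def switching_rhs(network: Network, q: SwitchingParameterSet, x: np.ndarray) -> np.ndarray:
    """Piecewise-constant-production vector field evaluated at state ``x``."""
    x = np.asarray(x, dtype=float)
    dx = np.empty(len(network.nodes))
    for idx, k in enumerate(network.nodes):
        edges = network.inputs(k)
        prod = q.basal[k] if not edges else 1.0
        for e in edges:
            key = (k, e.source)
            above = x[network.node_index(e.source)] > q.threshold[key]
            on = above if e.is_activation else not above
            prod *= q.high[key] if on else q.low[key]
        dx[idx] = prod - q.degradation[k] * x[idx]
    return dx


def domain_of(network: Network, q: SwitchingParameterSet, x: np.ndarray) -> DomainIndex:
    """Domain multi-index of a state (levels relative to each variable's thresholds)."""
    ths = sorted_thresholds(network, q)
    return tuple(
        level_of(x[idx], [t for t, _ in ths[k]]) for idx, k in enumerate(network.nodes)
    )


def integrate_event_driven(
    network: Network,
    q: SwitchingParameterSet,
    x0: np.ndarray,
    max_transitions: int = 1000,
    tie_rtol: float = 1e-10,
) -> SwitchingTrajectory:
    """Exact trajectory of the switching system from ``x0`` (off all thresholds).

    Within each domain the first wall-crossing time is computed in closed
    form per coordinate and the minimum taken.  Ends at ``FP`` when the
    target point lies in the current domain, at ``cycle`` when a
    (domain, exit wall) pair repeats, and at ``ambiguous`` on a crossing-time
    tie below ``tie_rtol`` or when ``max_transitions`` is exhausted.
    """
    x = np.asarray(x0, dtype=float).copy()
    ths = sorted_thresholds(network, q)
    ranks = threshold_rank(network, q)
    walls = {k: [t for t, _ in ths[k]] for k in network.nodes}
    gamma = np.array([q.degradation[k] for k in network.nodes])
    alpha = domain_of(network, q, x)
    t = 0.0
    events: list[tuple[DomainIndex, float, tuple[float, ...]]] = [(alpha, 0.0, tuple(x))]
    seen: dict[tuple, int] = {}
    for _ in range(max_transitions):
        target = target_point(network, q, alpha, ranks)
        inside = all(
            level_of(target[idx], walls[k]) == alpha[idx]
            for idx, k in enumerate(network.nodes)
        )
        if inside:
            return SwitchingTrajectory(tuple(events), f"FP({fp_label(alpha)})")
        times: list[tuple[float, int, int]] = []  # (crossing time, coordinate, direction)
        for idx, k in enumerate(network.nodes):
            wlist = walls[k]
            if target[idx] > x[idx] and alpha[idx] < len(wlist) and target[idx] > wlist[alpha[idx]]:
                wall, direction = wlist[alpha[idx]], +1
            elif target[idx] < x[idx] and alpha[idx] > 0 and target[idx] < wlist[alpha[idx] - 1]:
                wall, direction = wlist[alpha[idx] - 1], -1
            else:
                continue
            ratio = (x[idx] - target[idx]) / (wall - target[idx])
            if ratio > 1.0:
                times.append((np.log(ratio) / gamma[idx], idx, direction))
            else:  # already at/past the wall (entered exactly on it)
                times.append((0.0, idx, direction))
        if not times:
            return SwitchingTrajectory(tuple(events), AMBIGUOUS)
        times.sort()
        t_star, idx, direction = times[0]
        if len(times) > 1 and abs(times[1][0] - t_star) <= tie_rtol * max(t_star, 1e-30):
            return SwitchingTrajectory(tuple(events), AMBIGUOUS)
        key = (alpha, idx, direction)
        if key in seen:
            start = seen[key]
            cycle = tuple(ev[0] for ev in events[start:])
            return SwitchingTrajectory(tuple(events), "cycle", cycle)
        seen[key] = len(events) - 1
        x = target + (x - target) * np.exp(-gamma * t_star)
        x[idx] = walls[network.nodes[idx]][alpha[idx] if direction > 0 else alpha[idx] - 1]
        t += t_star
        alpha = tuple(a + direction if j == idx else a for j, a in enumerate(alpha))
        events.append((alpha, t, tuple(x)))
    return SwitchingTrajectory(tuple(events), AMBIGUOUS)


# --- attractor inventory ----------------------------------------------------

def stable_fixed_points(network: Network, q: SwitchingParameterSet) -> dict[str, np.ndarray]:
    """Predicted stable fixed points: label ``<digits>`` -> state (target point)."""
    stg = build_stg(network, q)
    mg = morse_graph(stg)
    ranks = threshold_rank(network, q)
    out: dict[str, np.ndarray] = {}
    for label in mg.attractors:
        if label == "cycle":
            continue
        alpha = tuple(int(c) for c in label)
        out[label] = target_point(network, q, alpha, ranks)
    return out


# --- fixed-step Euler integration ------------------------------------------

def _switching_arrays(network: Network, frame: pd.DataFrame):
    nodes = network.nodes
    gamma = np.column_stack([frame[f"gamma_{k}"].to_numpy(float) for k in nodes])
    low = np.column_stack([frame[f"L_{_ek(key)}"].to_numpy(float) for key in network.edge_keys])
    high = np.column_stack([frame[f"U_{_ek(key)}"].to_numpy(float) for key in network.edge_keys])
    theta = np.column_stack([frame[f"theta_{_ek(key)}"].to_numpy(float) for key in network.edge_keys])
    basal = {
        k: frame[f"basal_{k}"].to_numpy(float) for k in nodes if network.in_degree(k) == 0
    }
    return gamma, low, high, theta, basal


def euler_final_states(
    network: Network,
    params: Union[pd.DataFrame, SwitchingParameterSet],
    initial_conditions: np.ndarray,
    step: float = 0.05,
    horizon: float | None = None,
) -> np.ndarray:
    """Fixed-step Euler endpoints of the switching system, vectorized.

    ``initial_conditions`` has shape (M, K, n) matching the M rows of the
    parameter frame (or (K, n) with a single parameter set).  Returns final
    states of the same shape.
    """
    from .parameters import switching_row_from_set

    if isinstance(params, SwitchingParameterSet):
        params = pd.DataFrame([switching_row_from_set(network, params)])
    ics = np.asarray(initial_conditions, dtype=float)
    if ics.ndim == 2:
        ics = ics[None, :, :]
    M, K, n = ics.shape
    if M != len(params):
        raise ValueError("initial-condition block does not match parameter frame")
    gamma, low, high, theta, basal = _switching_arrays(network, params)
    rep = lambda a: np.repeat(a, K, axis=0)
    gamma, low, high, theta = rep(gamma), rep(low), rep(high), rep(theta)
    meta = [
        (network.node_index(e.source), network.node_index(e.target), e.is_activation)
        for e in network.edges
    ]
    X = ics.reshape(M * K, n).copy()
    if horizon is None:
        horizon = 200.0 / gamma.min()
    n_steps = max(1, int(np.ceil(horizon / step)))
    base = np.ones((M * K, n))
    for k, b in basal.items():
        base[:, network.node_index(k)] = np.repeat(b, K)
    for _ in range(n_steps):
        prod = base.copy()
        for e_idx, (src, tgt, is_act) in enumerate(meta):
            above = X[:, src] > theta[:, e_idx]
            on = above if is_act else ~above
            prod[:, tgt] *= np.where(on, high[:, e_idx], low[:, e_idx])
        X += step * (prod - gamma * X)
    return X.reshape(M, K, n)


def classify_states(
    network: Network,
    q: SwitchingParameterSet,
    states: np.ndarray,
    rtol: float = 0.05,
) -> list[str | None]:
    """Assign each state to the nearest predicted stable fixed point.

    Relative distance within ``rtol`` of an FP gives its label; otherwise
    ``None`` (unclassified).
    """
    fps = stable_fixed_points(network, q)
    out: list[str | None] = []
    for x in np.atleast_2d(states):
        best, best_d = None, np.inf
        for label, fp in fps.items():
            d = np.max(np.abs(x - fp) / (np.abs(fp) + 1e-12))
            if d < best_d:
                best, best_d = label, d
        out.append(f"FP({best})" if best is not None and best_d <= rtol else None)
    return out


# --- analytic separatrices for the two-node motifs --------------------------

def _ts_da_params(network: Network, q: SwitchingParameterSet):
    nx_, ny = network.nodes
    return {
        "gx": q.degradation[nx_],
        "gy": q.degradation[ny],
        "Lxy": q.low[(nx_, ny)],
        "Uxy": q.high[(nx_, ny)],
        "Lyx": q.low[(ny, nx_)],
        "Uyx": q.high[(ny, nx_)],
        "thxy": q.threshold[(nx_, ny)],  # threshold on y, regulating x
        "thyx": q.threshold[(ny, nx_)],  # threshold on x, regulating y
    }


def _check_bistable_box(p: dict) -> None:
    if not (p["Lxy"] < p["gx"] * p["thyx"] < p["Uxy"] and p["Lyx"] < p["gy"] * p["thxy"] < p["Uyx"]):
        raise PreconditionError("parameters violate the bistability inequalities")


def _crossing_time(gamma: float, target: float, x0: float, wall: float) -> float:
    """Time for x(t) = target + (x0 - target) e^(-gamma t) to reach ``wall``."""
    ratio = (x0 - target) / (wall - target)
    if ratio <= 1.0:
        return 0.0
    return float(np.log(ratio)) / gamma


def ts_separatrix_side(
    network: Network,
    q: SwitchingParameterSet,
    x0: Sequence[float],
    tie_rtol: float = 1e-12,
) -> str:
    """Attractor of an initial condition of the bistable mutual-repression motif.

    In the two transient domains (both coordinates on the same side of their
    thresholds) the basin boundary is where the two wall-crossing times of
    the within-domain exponential solution coincide; the earlier crossing
    decides the attractor.  Initial conditions in the domains that contain
    the fixed points are classified by containment.
    """
    p = _ts_da_params(network, q)
    _check_bistable_box(p)
    x, y = float(x0[0]), float(x0[1])
    x_hi, y_hi = x > p["thyx"], y > p["thxy"]
    if x_hi and not y_hi:
        return "FP(10)"
    if y_hi and not x_hi:
        return "FP(01)"
    if x_hi and y_hi:  # both decay toward the low targets
        t_yx = _crossing_time(p["gx"], p["Lxy"] / p["gx"], x, p["thyx"])
        t_xy = _crossing_time(p["gy"], p["Lyx"] / p["gy"], y, p["thxy"])
    else:  # both rise toward the high targets
        t_yx = _crossing_time(p["gx"], p["Uxy"] / p["gx"], x, p["thyx"])
        t_xy = _crossing_time(p["gy"], p["Uyx"] / p["gy"], y, p["thxy"])
    if abs(t_xy - t_yx) <= tie_rtol * max(abs(t_xy), abs(t_yx), 1e-30):
        return AMBIGUOUS
    if x_hi:  # domain III: y crossing first frees x to stay high
        return "FP(10)" if t_xy < t_yx else "FP(01)"
    # domain I: x crossing its threshold first represses y
    return "FP(10)" if t_yx < t_xy else "FP(01)"


def da_separatrix_side(
    network: Network,
    q: SwitchingParameterSet,
    x0: Sequence[float],
    tie_rtol: float = 1e-12,
) -> str:
    """Attractor of an initial condition of the bistable mutual-activation motif.

    The stable fixed points sit in the both-low domain (FP(00)) and the
    both-high domain (FP(11)); in the two mixed transient domains the rising
    coordinate races the falling one, and the earlier threshold crossing
    decides the attractor.
    """
    p = _ts_da_params(network, q)
    _check_bistable_box(p)
    x, y = float(x0[0]), float(x0[1])
    x_hi, y_hi = x > p["thyx"], y > p["thxy"]
    if not x_hi and not y_hi:
        return "FP(00)"
    if x_hi and y_hi:
        return "FP(11)"
    if y_hi:  # x rises (activator y high), y falls (activator x low)
        t_yx = _crossing_time(p["gx"], p["Uxy"] / p["gx"], x, p["thyx"])
        t_xy = _crossing_time(p["gy"], p["Lyx"] / p["gy"], y, p["thxy"])
        rising_first = t_yx < t_xy  # x reaches its threshold before y loses it
    else:  # x falls, y rises
        t_yx = _crossing_time(p["gx"], p["Lxy"] / p["gx"], x, p["thyx"])
        t_xy = _crossing_time(p["gy"], p["Uyx"] / p["gy"], y, p["thxy"])
        rising_first = t_xy < t_yx
    if abs(t_xy - t_yx) <= tie_rtol * max(abs(t_xy), abs(t_yx), 1e-30):
        return AMBIGUOUS
    # if the rising coordinate clears its threshold first, both end up high
    return "FP(11)" if rising_first else "FP(00)"


# --- basins -----------------------------------------------------------------

@dataclass(frozen=True)
class BasinReport:
    """Per-attractor convergence fractions and their product (basin strength)."""

    fractions: dict[str, float] = field(default_factory=dict)
    n_classified: int = 0
    n_total: int = 0

    @property
    def strength(self) -> float:
        s = 1.0
        for f in self.fractions.values():
            s *= f
        return s


def basin_report(labels: Sequence[str | None]) -> BasinReport:
    """Summarize classified initial conditions into a :class:`BasinReport`.

    ``None``/ambiguous labels are excluded from the fractions (which are
    taken over all initial conditions, so they sum to at most 1).
    """
    labels = list(labels)
    total = len(labels)
    if total == 0:
        raise ValueError("need at least one classified initial condition")
    counts: dict[str, int] = {}
    for lab in labels:
        if lab is None or lab == AMBIGUOUS:
            continue
        counts[lab] = counts.get(lab, 0) + 1
    fractions = {lab: c / total for lab, c in sorted(counts.items())}
    return BasinReport(fractions=fractions, n_classified=sum(counts.values()), n_total=total)


def uniform_box_initial_conditions(
    network: Network,
    q: SwitchingParameterSet,
    count: int,
    seed: Union[int, np.random.Generator] = 0,
    margin: float = 1.1,
) -> np.ndarray:
    """ICs uniform on the box (0, margin * max attainable level) per coordinate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranks = threshold_rank(network, q)
    hi = np.empty(len(network.nodes))
    for idx, k in enumerate(network.nodes):
        edges = network.inputs(k)
        if not edges:
            top = q.basal[k]
        else:
            top = 1.0
            for e in edges:
                top *= q.high[(k, e.source)]
        hi[idx] = margin * top / q.degradation[k]
    return rng.random((count, len(network.nodes))) * hi


def switching_frame_to_sets(network: Network, frame: pd.DataFrame):
    for _, row in frame.iterrows():
        yield switching_set_from_row(network, row)
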