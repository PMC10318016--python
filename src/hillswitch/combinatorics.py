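"""Combinatorial dynamics of switching systems.

For a fixed switching parameter set, phase space decomposes into rectangular
domains bounded by the thresholds of each variable; within a domain the flow
is linear decay toward a constant *target point*.  Which wall of a domain
the flow can cross is decided by inequalities between the target point and
the thresholds, giving a finite *state transition graph* (STG) on domains.
Collapsing the STG's strongly connected path components and ordering them by
reachability gives the *Morse graph*, whose sinks are the predicted
attractors: a singleton component with a self-edge is a stable fixed point
FP(beta) labeled by its domain's discrete coordinates; a nontrivial
recurrent component is reported as a cycle.

The same inequalities, read as a truth table over all input on/off
combinations (the *signature*), decompose parameter space itself: all
parameter sets with the same signature share the same STG.  For networks in
which every node has exactly one input and one output each node contributes
a three-way choice -- gamma*theta below L, between L and U, or above U --
and the full parameter graph is the product of these three-choice factors
(nine nodes for the two-node motifs).

Interaction logic is a pure product of per-edge switching terms, matching
the product form of the Hill model; general sum-of-products logic is out of
scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .networks import Network
from .parameters import SwitchingParameterSet, _ek

DomainIndex = tuple[int, ...]


class RegularityError(ValueError):
    """Raised when a switching parameter set violates the genericity assumptions."""


# --- thresholds and production values --------------------------------------

def sorted_thresholds(network: Network, q: SwitchingParameterSet) -> dict[str, list[tuple[float, str]]]:
    """Per source variable, its outgoing-edge thresholds sorted ascending.

    Returns ``{source: [(theta, target), ...]}``; the rank of an edge's
    threshold in this order is what a source's discrete level is compared to.
    """
    out: dict[str, list[tuple[float, str]]] = {}
    for i in network.nodes:
        ths = [(q.threshold[(e.target, i)], e.target) for e in network.outputs(i)]
        ths.sort()
        out[i] = ths
    return out


def threshold_rank(network: Network, q: SwitchingParameterSet) -> dict[tuple[str, str], int]:
    """Rank (0-based, ascending) of each edge's threshold among its source's thresholds."""
    ranks: dict[tuple[str, str], int] = {}
    for src, ths in sorted_thresholds(network, q).items():
        for r, (_, tgt) in enumerate(ths):
            ranks[(tgt, src)] = r
    return ranks


def production_value(
    network: Network,
    q: SwitchingParameterSet,
    node: str,
    alpha: DomainIndex,
    ranks: dict[tuple[str, str], int] | None = None,
) -> float:
    """Production Lambda of ``node`` in domain ``alpha`` (product over input edges)."""
    if ranks is None:
        ranks = threshold_rank(network, q)
    edges = network.inputs(node)
    if not edges:
        return q.basal[node]
    value = 1.0
    for e in edges:
        key = (node, e.source)
        above = alpha[network.node_index(e.source)] > ranks[key]
        on = above if e.is_activation else not above
        value *= q.high[key] if on else q.low[key]
    return value


def target_point(
    network: Network,
    q: SwitchingParameterSet,
    alpha: DomainIndex,
    ranks: dict[tuple[str, str], int] | None = None,
) -> np.ndarray:
    """Target point (Lambda_1/gamma_1, ..., Lambda_n/gamma_n) of domain ``alpha``."""
    if ranks is None:
        ranks = threshold_rank(network, q)
    return np.array(
        [production_value(network, q, k, alpha, ranks) / q.degradation[k] for k in network.nodes]
    )


def domains(network: Network) -> Iterator[DomainIndex]:
    """All domain multi-indices, component i ranging over 0..out_degree(i)."""
    ranges = [range(network.out_degree(k) + 1) for k in network.nodes]
    return itertools.product(*ranges)


def level_of(value: float, thresholds: Sequence[float]) -> int:
    """Discrete level of a concentration relative to a sorted threshold list."""
    lev = 0
    for th in thresholds:
        if value > th:
            lev += 1
    return lev


# --- regularity -------------------------------------------------------------

def _input_combinations(network: Network, q: SwitchingParameterSet, node: str) -> list[float]:
    """All values of the production product of ``node`` over input on/off combinations."""
    edges = network.inputs(node)
    if not edges:
        return [q.basal[node]]
    values = []
    for states in itertools.product((0, 1), repeat=len(edges)):
        v = 1.0
        for e, on in zip(edges, states):
            key = (node, e.source)
            v *= q.high[key] if on else q.low[key]
        values.append(v)
    return values


def regularity_violation(
    network: Network, q: SwitchingParameterSet, tolerance: float = 1e-9
) -> str | None:
    """Return a description of the first genericity violation, or None.

    A parameter set is regular when no production value Lambda_i equals any
    gamma_i * theta of an outgoing edge (within ``tolerance``) and no two
    thresholds of the same source variable coincide.
    """
    for i in network.nodes:
        ths = [q.threshold[(e.target, i)] for e in network.outputs(i)]
        ths_sorted = sorted(ths)
        for a, b in zip(ths_sorted, ths_sorted[1:]):
            if b - a <= tolerance:
                return f"coincident thresholds on outputs of {i}"
        lam_values = _input_combinations(network, q, i)
        for th in ths:
            for lam in lam_values:
                if abs(q.degradation[i] * th - lam) <= tolerance:
                    return f"gamma*theta equals a production value at node {i}"
    return None


# --- state transition graph and Morse graph ---------------------------------

def build_stg(network: Network, q: SwitchingParameterSet) -> nx.DiGraph:
    """State transition graph on domains for a regular parameter set.

    Nodes are domain multi-indices.  A domain containing its own target point
    carries a self-edge; across every wall between adjacent domains exactly
    one directed edge exists, following the flow direction of the separated
    coordinate.
    """
    violation = regularity_violation(network, q)
    if violation is not None:
        raise RegularityError(violation)
    ranks = threshold_rank(network, q)
    ths = sorted_thresholds(network, q)
    stg = nx.DiGraph()
    targets: dict[DomainIndex, np.ndarray] = {}
    for alpha in domains(network):
        t = target_point(network, q, alpha, ranks)
        targets[alpha] = t
        stg.add_node(alpha)
        inside = all(
            level_of(t[idx], [th for th, _ in ths[k]]) == alpha[idx]
            for idx, k in enumerate(network.nodes)
        )
        if inside:
            stg.add_edge(alpha, alpha)
    for alpha in targets:
        for idx, k in enumerate(network.nodes):
            if alpha[idx] >= network.out_degree(k):
                continue
            beta = tuple(a + 1 if j == idx else a for j, a in enumerate(alpha))
            wall = ths[k][alpha[idx]][0]
            if targets[alpha][idx] > wall:
                stg.add_edge(alpha, beta)
            if targets[beta][idx] < wall:
                stg.add_edge(beta, alpha)
    return stg


@dataclass(frozen=True)
class MorseGraph:
    """Condensed STG: partial order of strongly connected path components.

    ``graph`` is the acyclic condensation; node attribute ``members`` lists
    the STG domains of each component.  ``attractors`` are the labels of the
    sinks: ``FP(beta)`` written as the domain's digit string for a stable
    fixed point, ``cycle`` for a nontrivial recurrent component.
    """

    graph: nx.DiGraph
    attractors: tuple[str, ...]

    @property
    def repertoire(self) -> str:
        return "-".join(sorted(self.attractors))

    def to_dot(self) -> str:
        lines = ["digraph morse {"]
        for n, data in self.graph.nodes(data=True):
            label = data["label"]
            lines.append(f'  {n} [label="{label}"];')
        for a, b in self.graph.edges():
            lines.append(f"  {a} -> {b};")
        lines.append("}")
        return "\n".join(lines)


def fp_label(alpha: DomainIndex) -> str:
    return "".join(str(a) for a in alpha)


def morse_graph(stg: nx.DiGraph) -> MorseGraph:
    """Morse graph of an STG; sinks of the condensation are the attractors."""
    cond = nx.condensation(stg)
    attractors: list[str] = []
    for n, data in cond.nodes(data=True):
        members = sorted(data["members"])
        if len(members) == 1:
            alpha = members[0]
            if stg.has_edge(alpha, alpha):
                label = f"FP({fp_label(alpha)})"
            else:
                label = "transient"
        else:
            label = "cycle"
        cond.nodes[n]["label"] = label
        if cond.out_degree(n) == 0:
            attractors.append(fp_label(members[0]) if label.startswith("FP") else "cycle")
    return MorseGraph(graph=cond, attractors=tuple(sorted(attractors)))


def predicted_repertoire(network: Network, q: SwitchingParameterSet) -> str:
    """Attractor repertoire predicted combinatorially for one parameter set."""
    return morse_graph(build_stg(network, q)).repertoire


# --- parameter-space decomposition ------------------------------------------

@dataclass(frozen=True)
class ParameterNodeSignature:
    """Inequality signature of a regular switching parameter set.

    ``table`` holds, per network node, the truth values of
    ``Lambda(combination) > gamma * theta(output)`` over every output edge
    (in ascending threshold order) and every input on/off combination;
    ``threshold_order`` records each node's output order.  Two parameter
    sets with equal signatures share the same STG.
    """

    table: tuple[tuple[str, tuple[tuple[bool, ...], ...]], ...]
    threshold_order: tuple[tuple[str, tuple[str, ...]], ...]

    def factor_choice(self, node: str) -> int:
        """Three-way factor choice for a single-input, single-output node.

        0: gamma*theta < L < U; 1: L < gamma*theta < U; 2: L < U < gamma*theta.
        """
        rows = dict(self.table)[node]
        if len(rows) != 1 or len(rows[0]) != 2:
            raise ValueError(f"node {node} is not single-input/single-output")
        low_above, high_above = rows[0]
        if low_above:
            return 0
        return 1 if high_above else 2


def signature(network: Network, q: SwitchingParameterSet) -> ParameterNodeSignature:
    """Inequality signature (the parameter-graph node) of a regular set."""
    violation = regularity_violation(network, q)
    if violation is not None:
        raise RegularityError(violation)
    table = []
    order = []
    ths = sorted_thresholds(network, q)
    for i in network.nodes:
        lam_values = _input_combinations(network, q, i)
        rows = tuple(
            tuple(lam > q.degradation[i] * th for lam in lam_values) for th, _ in ths[i]
        )
        table.append((i, rows))
        order.append((i, tuple(tgt for _, tgt in ths[i])))
    return ParameterNodeSignature(table=tuple(table), threshold_order=tuple(order))


def signature_index(network: Network, sig: ParameterNodeSignature) -> int:
    """Grid index of a signature for all-single-input/single-output networks.

    Row-major over the per-node three-way choices in node order (first node
    most significant); for the two-node motifs this is the 0..8 numbering in
    which the central, doubly-intermediate node is index 4.
    """
    idx = 0
    for k in network.nodes:
        idx = 3 * idx + sig.factor_choice(k)
    return idx


def assign_signature_indices(network: Network, switching_frame: pd.DataFrame) -> np.ndarray:
    """Vectorized signature-index assignment for an ensemble of switching sets.

    Requires every network node to have exactly one input and one output.
    """
    for k in network.nodes:
        if network.in_degree(k) != 1 or network.out_degree(k) != 1:
            raise ValueError("vectorized assignment needs single-input/single-output nodes")
    idx = np.zeros(len(switching_frame), dtype=int)
    for k in network.nodes:
        (in_edge,) = network.inputs(k)
        (out_edge,) = network.outputs(k)
        low = switching_frame[f"L_{_ek((k, in_edge.source))}"].to_numpy(float)
        high = switching_frame[f"U_{_ek((k, in_edge.source))}"].to_numpy(float)
        gt = (
            switching_frame[f"gamma_{k}"].to_numpy(float)
            * switching_frame[f"theta_{_ek((out_edge.target, k))}"].to_numpy(float)
        )
        choice = np.where(gt < low, 0, np.where(gt < high, 1, 2))
        idx = 3 * idx + choice
    return idx


def representative_parameters(network: Network, choices: Sequence[int]) -> SwitchingParameterSet:
    """A concrete parameter set realizing the given per-node factor choices.

    Uses gamma = theta = 1 so gamma*theta = 1 and places (L, U) at (2, 4),
    (0.5, 2) or (0.25, 0.5) for choices 0, 1, 2.
    """
    levels = {0: (2.0, 4.0), 1: (0.5, 2.0), 2: (0.25, 0.5)}
    low: dict[tuple[str, str], float] = {}
    high: dict[tuple[str, str], float] = {}
    theta: dict[tuple[str, str], float] = {}
    for k, c in zip(network.nodes, choices):
        (in_edge,) = network.inputs(k)
        key = (k, in_edge.source)
        low[key], high[key] = levels[c]
    for key in network.edge_keys:
        theta[key] = 1.0
    return SwitchingParameterSet(
        degradation={k: 1.0 for k in network.nodes}, low=low, high=high, threshold=theta
    )


def enumerate_parameter_graph(network: Network) -> nx.Graph:
    """Enumerate the product parameter graph for single-input/single-output networks.

    Nodes are signature indices (0..3^n - 1) with attributes ``choices`` (the
    per-node factor choices) and ``repertoire`` (the Morse-graph prediction);
    edges join signatures differing by one inequality, i.e. grid-adjacent
    choice vectors.
    """
    for k in network.nodes:
        if network.in_degree(k) != 1 or network.out_degree(k) != 1:
            raise ValueError("parameter-graph enumeration needs single-input/single-output nodes")
    n = len(network.nodes)
    pg = nx.Graph()
    for choices in itertools.product((0, 1, 2), repeat=n):
        idx = 0
        for c in choices:
            idx = 3 * idx + c
        q = representative_parameters(network, choices)
        pg.add_node(idx, choices=choices, repertoire=predicted_repertoire(network, q))
    for idx, data in pg.nodes(data=True):
        choices = data["choices"]
        for pos in range(n):
            if choices[pos] < 2:
                neighbor = list(choices)
                neighbor[pos] += 1
                jdx = 0
                for c in neighbor:
                    jdx = 3 * jdx + c
                pg.add_edge(idx, jdx)
    return pg
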