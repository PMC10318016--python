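"""Regulatory networks: signed directed graphs and their ``.topo`` serialization.

A regulatory network is a directed graph whose nodes are genes (or other
molecular species) and whose edges carry a sign: activation (the source
up-regulates the target) or repression (the source down-regulates it).  The
network object is the single structural input consumed by every engine in
this package -- the Hill-ODE ensemble simulator, the switching-system
integrators and the combinatorial parameter-space decomposition.

The on-disk format is the whitespace-separated ``.topo`` dialect used by
circuit-perturbation tools: one edge per line, columns ``Source Target Type``
with ``1`` meaning activation and ``2`` repression (the words
``activate``/``inhibit`` are accepted on read).  An optional single header
line ``Source Target Type`` is auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

ACTIVATION = 1
REPRESSION = 2

_SIGN_TOKENS = {
    "1": ACTIVATION,
    "2": REPRESSION,
    "activate": ACTIVATION,
    "activation": ACTIVATION,
    "inhibit": REPRESSION,
    "inhibition": REPRESSION,
    "repress": REPRESSION,
    "repression": REPRESSION,
}


class TopoParseError(ValueError):
    """Raised for malformed ``.topo`` input; carries the offending line number."""


class NetworkValidationError(ValueError):
    """Raised when a network violates structural invariants."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: int  # ACTIVATION or REPRESSION

    @property
    def is_activation(self) -> bool:
        return self.sign == ACTIVATION


@dataclass(frozen=True)
class Network:
    """Signed directed regulatory network.

    ``nodes`` are kept in first-appearance order; every per-node vector and
    every discrete state label produced downstream uses this order, so the
    labeling of attractors is deterministic for a given input file.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        seen = set()
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise NetworkValidationError("duplicate node names")
        for e in self.edges:
            if e.source == e.target:
                raise NetworkValidationError(f"self-loop on node {e.source!r} is not supported")
            if e.source not in declared or e.target not in declared:
                raise NetworkValidationError(f"edge {e.source}->{e.target} references undeclared node")
            key = (e.source, e.target)
            if key in seen:
                raise NetworkValidationError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # --- structural queries -------------------------------------------------

    def inputs(self, node: str) -> tuple[Edge, ...]:
        """Edges whose target is ``node`` (the node's regulators)."""
        return tuple(e for e in self.edges if e.target == node)

    def outputs(self, node: str) -> tuple[Edge, ...]:
        """Edges whose source is ``node`` (the node's targets)."""
        return tuple(e for e in self.edges if e.source == node)

    def in_degree(self, node: str) -> int:
        return len(self.inputs(node))

    def out_degree(self, node: str) -> int:
        return len(self.outputs(node))

    def node_index(self, node: str) -> int:
        return self.nodes.index(node)

    @property
    def edge_keys(self) -> tuple[tuple[str, str], ...]:
        """Edges as (target, source) pairs, the key convention for all edge parameters."""
        return tuple((e.target, e.source) for e in self.edges)

    def edge(self, target: str, source: str) -> Edge:
        for e in self.edges:
            if e.target == target and e.source == source:
                return e
        raise KeyError((target, source))


def _node_order(edge_rows: Iterable[tuple[str, str, int]]) -> tuple[str, ...]:
    order: list[str] = []
    for src, tgt, _ in edge_rows:
        for n in (src, tgt):
            if n not in order:
                order.append(n)
    return tuple(order)


def read_topo(path: Union[str, Path]) -> Network:
    """Read a ``.topo`` edge-list file into a :class:`Network`.

    Nodes are ordered by first appearance.  Raises :class:`TopoParseError`
    naming the line number for malformed lines, and a validation error for
    duplicate edges or (unsupported) self-loops.
    """
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and [p.lower() for p in parts[:3]] == ["source", "target", "type"]:
                continue
            if len(parts) != 3:
                raise TopoParseError(f"{path.name}:{lineno}: expected 3 columns, got {len(parts)}")
            src, tgt, tok = parts
            sign = _SIGN_TOKENS.get(tok.lower())
            if sign is None:
                raise TopoParseError(f"{path.name}:{lineno}: unknown sign token {tok!r}")
            rows.append((src, tgt, sign))
    if not rows:
        raise TopoParseError(f"{path.name}: no edges")
    nodes = _node_order(rows)
    edges = tuple(Edge(s, t, sign) for s, t, sign in rows)
    return Network(nodes=nodes, edges=edges, name=path.stem)


def write_topo(network: Network, path: Union[str, Path]) -> None:
    """Write a network in the numeric ``.topo`` convention (1=activation, 2=repression)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Source Target Type\n")
        for e in network.edges:
            fh.write(f"{e.source} {e.target} {e.sign}\n")


# --- built-in motif networks ------------------------------------------------

def _net(name: str, rows: list[tuple[str, str, int]]) -> Network:
    return Network(nodes=_node_order(rows), edges=tuple(Edge(*r) for r in rows), name=name)


def builtin_network(name: str) -> Network:
    """Return one of the built-in motif networks.

    ``TS``  toggle switch: A and B mutually repressing.
    ``DA``  double activation: A and B mutually activating.
    ``NF``  negative feedback: A activates B, B represses A.
    ``TT``  toggle triad: all six pairwise repressions among A, B, C.
    ``toggle_square``  cyclic chain of four mutual-repression pairs (8 edges).
    """
    builders = {
        "TS": lambda: _net("TS", [("A", "B", REPRESSION), ("B", "A", REPRESSION)]),
        "DA": lambda: _net("DA", [("A", "B", ACTIVATION), ("B", "A", ACTIVATION)]),
        "NF": lambda: _net("NF", [("A", "B", ACTIVATION), ("B", "A", REPRESSION)]),
        "TT": lambda: _net(
            "TT",
            [
                ("A", "B", REPRESSION),
                ("B", "A", REPRESSION),
                ("B", "C", REPRESSION),
                ("C", "B", REPRESSION),
                ("A", "C", REPRESSION),
                ("C", "A", REPRESSION),
            ],
        ),
        "toggle_square": lambda: _net(
            "toggle_square",
            [
                ("A", "B", REPRESSION),
                ("B", "A", REPRESSION),
                ("B", "C", REPRESSION),
                ("C", "B", REPRESSION),
                ("C", "D", REPRESSION),
                ("D", "C", REPRESSION),
                ("D", "A", REPRESSION),
                ("A", "D", REPRESSION),
            ],
        ),
    }
    try:
        return builders[name]()
    except KeyError:
        raise KeyError(f"unknown built-in network {name!r}; valid names: {sorted(builders)}") from None
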