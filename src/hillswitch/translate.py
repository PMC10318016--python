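"""Translation between the Hill-model and switching-system parameterizations.

The shifted-Hill model and the switching system describe the same network at
finite and infinite Hill coefficient respectively.  Their parameters are in
one-to-one correspondence (up to the Hill coefficient, which the switching
system lacks):

* the map R (``to_switching``) distributes a node's basal production P_k
  evenly over its m_k input edges, U_kj = P_k^(1/m_k), and scales it down by
  the fold change for the lower level, L_kj = U_kj / a_kj (activation) or
  L_kj = U_kj * i_kj (repression); thresholds and decay rates carry over
  unchanged, and the product of upper levels over a node's inputs recovers
  P_k exactly;
* the map D (``to_racipe``) inverts R on the subset of switching parameters
  where the resulting fold changes are admissible (a > 1, i < 1 strictly);
  the returned set is a switching-limit model (Hill coefficient infinite).

D∘R is the identity; R∘D is not, and D is deliberately not used by any
pipeline stage -- it exists for completeness and for the round-trip tests.

``link_strength`` is the scalar P * n / (gamma * theta * fold) measuring the
effective impact of one edge; for activating edges 1/a replaces the
repression fold i so that stronger regulation always means larger strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .networks import Network
from .parameters import (
    EdgeKey,
    RacipeParameterSet,
    SwitchingParameterSet,
    _ek,
)


class TranslationError(ValueError):
    """Raised when the switching-to-Hill map D is undefined at the given point."""


def to_switching(network: Network, p: RacipeParameterSet) -> SwitchingParameterSet:
    """Map R: Hill-model parameters to switching-system parameters."""
    low: dict[EdgeKey, float] = {}
    high: dict[EdgeKey, float] = {}
    basal: dict[str, float] = {}
    for k in network.nodes:
        m = network.in_degree(k)
        if m == 0:
            basal[k] = p.production[k]
            continue
        u = p.production[k] ** (1.0 / m)
        for e in network.inputs(k):
            key = (k, e.source)
            high[key] = u
            low[key] = u / p.fold[key] if e.is_activation else u * p.fold[key]
    return SwitchingParameterSet(
        degradation=dict(p.degradation),
        low=low,
        high=high,
        threshold=dict(p.threshold),
        basal=basal,
    )


def to_racipe(network: Network, q: SwitchingParameterSet) -> RacipeParameterSet:
    """Map D: switching-system parameters to a switching-limit Hill model.

    Raises :class:`TranslationError` where the map is undefined (an edge with
    L equal to P^(1/m), which would force a fold change of exactly 1).
    """
    production: dict[str, float] = {}
    fold: dict[EdgeKey, float] = {}
    for k in network.nodes:
        edges = network.inputs(k)
        if not edges:
            production[k] = q.basal[k]
            continue
        prod = 1.0
        for e in edges:
            prod *= q.high[(k, e.source)]
        production[k] = prod
        u = prod ** (1.0 / len(edges))
        for e in edges:
            key = (k, e.source)
            if e.is_activation:
                a = u / q.low[key]
                if not a > 1:
                    raise TranslationError(f"edge {key}: activation fold {a} not > 1")
                fold[key] = a
            else:
                i = q.low[key] / u
                if not i < 1:
                    raise TranslationError(f"edge {key}: repression fold {i} not < 1")
                fold[key] = i
    return RacipeParameterSet(
        production=production,
        degradation=dict(q.degradation),
        threshold=dict(q.threshold),
        hill={key: np.inf for key in network.edge_keys},
        fold=fold,
        switching_limit=True,
    )


def link_strength(network: Network, p: RacipeParameterSet, target: str, source: str) -> float:
    """Nondimensional strength of the edge source -> target.

    LS = P_src * n / (gamma_src * theta * i) for repression; on activating
    edges the fold in the denominator is 1/a, so that a stronger activation
    also yields a larger strength.  Typically examined on a log scale.
    """
    e = network.edge(target, source)
    key = (target, source)
    f = 1.0 / p.fold[key] if e.is_activation else p.fold[key]
    return p.production[source] * p.hill[key] / (p.degradation[source] * p.threshold[key] * f)


# --- vectorized ensemble translation ---------------------------------------

def translate_frame(network: Network, frame: pd.DataFrame) -> pd.DataFrame:
    """Apply the map R row-wise to a Hill-model ensemble frame.

    Returns a switching ensemble frame (columns ``gamma_*``, ``L_*``, ``U_*``,
    ``theta_*``) with the same index.
    """
    out: dict[str, np.ndarray] = {}
    for k in network.nodes:
        out[f"gamma_{k}"] = frame[f"gamma_{k}"].to_numpy(float)
    for k in network.nodes:
        m = network.in_degree(k)
        if m == 0:
            out[f"basal_{k}"] = frame[f"P_{k}"].to_numpy(float)
            continue
        u = frame[f"P_{k}"].to_numpy(float) ** (1.0 / m)
        for e in network.inputs(k):
            key = (k, e.source)
            f = frame[f"fold_{_ek(key)}"].to_numpy(float)
            out[f"U_{_ek(key)}"] = u
            out[f"L_{_ek(key)}"] = u / f if e.is_activation else u * f
    for key in network.edge_keys:
        out[f"theta_{_ek(key)}"] = frame[f"theta_{_ek(key)}"].to_numpy(float)
    return pd.DataFrame(out, index=frame.index)


def link_strength_frame(network: Network, frame: pd.DataFrame) -> pd.DataFrame:
    """Link strength of every edge for every row of a Hill ensemble frame."""
    out: dict[str, np.ndarray] = {}
    for e in network.edges:
        key = (e.target, e.source)
        f = frame[f"fold_{_ek(key)}"].to_numpy(float)
        if e.is_activation:
            f = 1.0 / f
        out[f"LS_{_ek(key)}"] = (
            frame[f"P_{e.source}"].to_numpy(float)
            * frame[f"n_{_ek(key)}"].to_numpy(float)
            / (frame[f"gamma_{e.source}"].to_numpy(float) * frame[f"theta_{_ek(key)}"].to_numpy(float) * f)
        )
    return pd.DataFrame(out, index=frame.index)
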