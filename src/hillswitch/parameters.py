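"""Parameter containers for the Hill-ODE and switching formalisms.

Two in-memory representations coexist:

* scalar dataclasses (:class:`RacipeParameterSet`, :class:`SwitchingParameterSet`)
  holding one sampled point of parameter space, used by the single-trajectory
  APIs (right-hand sides, translation maps, event-driven integration);
* pandas DataFrames with one row per parameter set ("ensembles"), used by the
  vectorized engines and for TSV I/O.

Edge-level parameters are keyed by ``(target, source)``: ``theta[("B", "A")]``
is the threshold for the effect of A on B.  DataFrame columns follow the
``P_<node>``, ``gamma_<node>``, ``theta_<target><source>``,
``n_<target><source>``, ``fold_<target><source>`` convention (and ``L_``,
``U_`` for switching levels); node names are concatenated, so the tabular
form assumes names that keep the concatenation unambiguous (single letters
for the built-in motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .networks import Network

EdgeKey = tuple[str, str]  # (target, source)


@dataclass(frozen=True)
class RacipeParameterSet:
    """One point of the shifted-Hill model parameter space.

    ``fold`` is the activation fold change a > 1 on activating edges and the
    repression fold change 0 < i < 1 on repressing edges.  ``hill`` may be
    ``inf`` for sets produced by the switching-limit map D.
    """

    production: Mapping[str, float]
    degradation: Mapping[str, float]
    threshold: Mapping[EdgeKey, float]
    hill: Mapping[EdgeKey, float]
    fold: Mapping[EdgeKey, float]
    switching_limit: bool = False

    def validate(self, network: Network) -> None:
        for k in network.nodes:
            if not self.production[k] > 0 or not self.degradation[k] > 0:
                raise ValueError(f"non-positive rate at node {k}")
        for e in network.edges:
            key = (e.target, e.source)
            if not self.threshold[key] > 0:
                raise ValueError(f"non-positive threshold on {key}")
            if not self.hill[key] >= 1:
                raise ValueError(f"Hill coefficient < 1 on {key}")
            f = self.fold[key]
            if e.is_activation and not f > 1:
                raise ValueError(f"activation fold must exceed 1 on {key}")
            if not e.is_activation and not 0 < f < 1:
                raise ValueError(f"repression fold must lie in (0,1) on {key}")


@dataclass(frozen=True)
class SwitchingParameterSet:
    """One point of switching-system parameter space.

    Per edge ``(target, source)``: lower level L, upper level U (0 < L < U)
    and threshold theta; per node: decay gamma.  Nodes with no regulators
    carry a constant production term in ``basal``.
    """

    degradation: Mapping[str, float]
    low: Mapping[EdgeKey, float]
    high: Mapping[EdgeKey, float]
    threshold: Mapping[EdgeKey, float]
    basal: Mapping[str, float] = field(default_factory=dict)

    def validate(self, network: Network) -> None:
        for k in network.nodes:
            if not self.degradation[k] > 0:
                raise ValueError(f"non-positive decay at node {k}")
            if network.in_degree(k) == 0 and k not in self.basal:
                raise ValueError(f"unregulated node {k} lacks a basal production term")
        for key in network.edge_keys:
            if not 0 < self.low[key] < self.high[key]:
                raise ValueError(f"need 0 < L < U on edge {key}")
            if not self.threshold[key] > 0:
                raise ValueError(f"non-positive threshold on {key}")


# --- tabular schema ---------------------------------------------------------

def _ek(key: EdgeKey) -> str:
    target, source = key
    return f"{target}{source}"


def racipe_columns(network: Network) -> list[str]:
    cols = [f"P_{k}" for k in network.nodes] + [f"gamma_{k}" for k in network.nodes]
    for key in network.edge_keys:
        cols.append(f"theta_{_ek(key)}")
    for key in network.edge_keys:
        cols.append(f"n_{_ek(key)}")
    for key in network.edge_keys:
        cols.append(f"fold_{_ek(key)}")
    return cols


def switching_columns(network: Network) -> list[str]:
    cols = [f"gamma_{k}" for k in network.nodes]
    for key in network.edge_keys:
        cols.append(f"L_{_ek(key)}")
    for key in network.edge_keys:
        cols.append(f"U_{_ek(key)}")
    for key in network.edge_keys:
        cols.append(f"theta_{_ek(key)}")
    for k in network.nodes:
        if network.in_degree(k) == 0:
            cols.append(f"basal_{k}")
    return cols


def racipe_set_from_row(network: Network, row: Mapping[str, float]) -> RacipeParameterSet:
    return RacipeParameterSet(
        production={k: float(row[f"P_{k}"]) for k in network.nodes},
        degradation={k: float(row[f"gamma_{k}"]) for k in network.nodes},
        threshold={key: float(row[f"theta_{_ek(key)}"]) for key in network.edge_keys},
        hill={key: float(row[f"n_{_ek(key)}"]) for key in network.edge_keys},
        fold={key: float(row[f"fold_{_ek(key)}"]) for key in network.edge_keys},
    )


def racipe_row_from_set(network: Network, p: RacipeParameterSet) -> dict[str, float]:
    row: dict[str, float] = {}
    for k in network.nodes:
        row[f"P_{k}"] = p.production[k]
        row[f"gamma_{k}"] = p.degradation[k]
    for key in network.edge_keys:
        row[f"theta_{_ek(key)}"] = p.threshold[key]
        row[f"n_{_ek(key)}"] = p.hill[key]
        row[f"fold_{_ek(key)}"] = p.fold[key]
    return row


def switching_set_from_row(network: Network, row: Mapping[str, float]) -> SwitchingParameterSet:
    return SwitchingParameterSet(
        degradation={k: float(row[f"gamma_{k}"]) for k in network.nodes},
        low={key: float(row[f"L_{_ek(key)}"]) for key in network.edge_keys},
        high={key: float(row[f"U_{_ek(key)}"]) for key in network.edge_keys},
        threshold={key: float(row[f"theta_{_ek(key)}"]) for key in network.edge_keys},
        basal={k: float(row[f"basal_{k}"]) for k in network.nodes if network.in_degree(k) == 0},
    )


def switching_row_from_set(network: Network, q: SwitchingParameterSet) -> dict[str, float]:
    row: dict[str, float] = {}
    for k in network.nodes:
        row[f"gamma_{k}"] = q.degradation[k]
    for key in network.edge_keys:
        row[f"L_{_ek(key)}"] = q.low[key]
        row[f"U_{_ek(key)}"] = q.high[key]
        row[f"theta_{_ek(key)}"] = q.threshold[key]
    for k in network.nodes:
        if network.in_degree(k) == 0:
            row[f"basal_{k}"] = q.basal[k]
    return row


def frame_to_sets(network: Network, frame: pd.DataFrame, kind: str = "racipe"):
    """Iterate over the rows of an ensemble frame as parameter-set dataclasses."""
    conv = racipe_set_from_row if kind == "racipe" else switching_set_from_row
    for _, row in frame.iterrows():
        yield conv(network, row)


def ensemble_arrays(network: Network, frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dense array views of a Hill-model ensemble frame for the vectorized engines.

    Returns arrays of shape (M, n_nodes) for P and gamma and (M, n_edges) for
    theta, n and fold, with edges in ``network.edges`` order.
    """
    def stack(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.empty((len(frame), 0))
        return np.column_stack([frame[c].to_numpy(float) for c in cols])

    edge_cols = [_ek(key) for key in network.edge_keys]
    return {
        "P": stack([f"P_{k}" for k in network.nodes]),
        "gamma": stack([f"gamma_{k}" for k in network.nodes]),
        "theta": stack([f"theta_{e}" for e in edge_cols]),
        "hill": stack([f"n_{e}" for e in edge_cols]),
        "fold": stack([f"fold_{e}" for e in edge_cols]),
    }
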