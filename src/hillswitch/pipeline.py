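"""End-to-end experiment orchestration.

Thin compositions of the sampling, simulation, translation, combinatorics
and comparison layers, shared by the analysis drivers, the test suite and
the reproduction script: sample an ensemble, simulate it in the Hill model,
push the same parameter sets through the switching system, discretize both
through the identical pipeline, and compare the resulting repertoire
distributions per parameter node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combinatorics import assign_signature_indices
from .compare import ComparisonReport, nodewise_comparison
from .hill import IntegratorSettings, discretize, simulate_ensemble
from .networks import Network
from .parameters import switching_set_from_row
from .sampling import SamplingConfig, sample_parameters
from .switching import (
    integrate_event_driven,
    stable_fixed_points,
    uniform_box_initial_conditions,
)
from .translate import translate_frame


@dataclass
class EnsembleRun:
    """One simulated ensemble with its switching-side counterpart."""

    network: Network
    params: pd.DataFrame
    switching: pd.DataFrame
    records: pd.DataFrame
    flags: pd.DataFrame
    labeled: pd.DataFrame
    repertoires: pd.DataFrame  # indexed by param_id
    node_index: pd.Series | None = None

    @property
    def hill_labels(self) -> pd.Series:
        return self.repertoires["repertoire"]


def run_hill_ensemble(
    network: Network,
    config: SamplingConfig,
    seed: int | None = None,
    sim_seed: int | None = None,
    settings: IntegratorSettings | None = None,
    assign_nodes: bool = True,
) -> EnsembleRun:
    """Sample, simulate and discretize one Hill-model ensemble."""
    params = sample_parameters(network, config, seed=seed)
    switching = translate_frame(network, params)
    base = config.seed if seed is None else seed
    records, flags = simulate_ensemble(
        network,
        params,
        n_init=config.n_init,
        seed=base + 1 if sim_seed is None else sim_seed,
        settings=settings,
    )
    labeled, repertoires = discretize(network, records, flags)
    repertoires = repertoires.set_index("param_id")
    node_index = None
    if assign_nodes and all(
        network.in_degree(k) == 1 and network.out_degree(k) == 1 for k in network.nodes
    ):
        node_index = pd.Series(assign_signature_indices(network, switching), index=params.index)
    return EnsembleRun(network, params, switching, records, flags, labeled, repertoires, node_index)


def switching_reference(
    network: Network, switching_frame: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Switching-system repertoires processed through the Hill discretization.

    For every parameter set, the stable fixed points are computed exactly
    from the Morse graph (states are the domains' target points, with equal
    weights); sets whose only attractor is a cycle are flagged cyclic.  The
    rows are then binarized by the same pooled weighted-z-score rule as the
    Hill records, so the two formalisms are compared under identical
    processing.  Returns ``(labeled_records, repertoires)``.
    """
    rows = []
    flag_rows = []
    for pid, frow in switching_frame.iterrows():
        q = switching_set_from_row(network, frow)
        fps = stable_fixed_points(network, q)
        if fps:
            for _, state in fps.items():
                rec = {"param_id": pid, "weight": 1.0 / len(fps), "residual": 0.0, "verified": True}
                for idx, k in enumerate(network.nodes):
                    rec[f"x_{k}"] = state[idx]
                rows.append(rec)
        flag_rows.append(
            {"param_id": pid, "n_states": len(fps), "cyclic": not fps, "n_divergent": 0}
        )
    records = pd.DataFrame(rows)
    flags = pd.DataFrame(flag_rows)
    labeled, repertoires = discretize(network, records, flags)
    return labeled, repertoires.set_index("param_id")


def compare_hill_to_switching(run: EnsembleRun) -> ComparisonReport:
    """Node-stratified comparison of one ensemble's Hill and switching repertoires."""
    if run.node_index is None:
        raise ValueError("run has no parameter-node assignment")
    _, sw_reps = switching_reference(run.network, run.switching)
    return nodewise_comparison(
        run.hill_labels, sw_reps["repertoire"], run.node_index
    )


def verified_state_counts(run: EnsembleRun) -> pd.Series:
    """Number of distinct verified steady states per parameter set."""
    counts = (
        run.records[run.records["verified"]].groupby("param_id").size()
    )
    return counts.reindex(run.params.index, fill_value=0)


def confirmed_tristable_sets(
    network: Network,
    switching_frame: pd.DataFrame,
    n_ic: int = 200,
    seed: int = 0,
) -> list:
    """Parameter sets with three stable FPs, each reached from sampled ICs.

    The Morse graph supplies the candidate tristable sets; event-driven
    integration from ``n_ic`` box-uniform initial conditions then confirms
    that all three fixed points have non-negligible basins.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pid, row in switching_frame.iterrows():
        q = switching_set_from_row(network, row)
        fps = stable_fixed_points(network, q)
        if len(fps) != 3:
            continue
        found: set[str] = set()
        for ic in uniform_box_initial_conditions(network, q, n_ic, rng):
            tr = integrate_event_driven(network, q, ic)
            if tr.classification.startswith("FP"):
                found.add(tr.classification)
            if len(found) == 3:
                break
        if len(found) == 3:
            out.append(pid)
    return out
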