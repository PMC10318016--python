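"""Statistics comparing Hill-ensemble dynamics with switching-system predictions.

The two formalisms are compared on the level of *attractor-repertoire
frequency distributions*: for a common collection of sampled parameter
sets, each set receives a canonical repertoire label from the Hill-model
simulation and one from the switching system, and the distributions of
these labels are compared -- per parameter-graph node (stratified by the
inequality signature of the translated parameters), or pooled over the
ensemble.  Pooled distributions inherit the sampler's bias toward certain
parameter nodes; averaging the per-node distributions with equal node
weights removes that bias and is the "normalized" ensemble distribution.

Distances between distributions are Jensen-Shannon divergences (base 2 by
default, so the maximum is 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import PCA

from .networks import Network

Distribution = dict[str, float]


def distribution(labels: Sequence[str], weights: Sequence[float] | None = None) -> Distribution:
    """Normalized frequency distribution of repertoire labels."""
    labels = list(labels)
    if weights is None:
        weights = np.ones(len(labels))
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("empty or zero-weight label collection")
    out: Distribution = {}
    for lab, w in zip(labels, weights):
        out[lab] = out.get(lab, 0.0) + w / total
    return dict(sorted(out.items()))


def jsd(p: Mapping[str, float], q: Mapping[str, float], base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two label distributions.

    Symmetric, zero iff the distributions coincide, at most 1 in base 2
    (ln 2 in base e).  Labels missing from one distribution count as
    frequency zero.
    """
    support = sorted(set(p) | set(q))
    pv = np.array([p.get(s, 0.0) for s in support])
    qv = np.array([q.get(s, 0.0) for s in support])
    return float(jensenshannon(pv, qv, base=base) ** 2)


def max_abs_diff(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    support = set(p) | set(q)
    return max(abs(p.get(s, 0.0) - q.get(s, 0.0)) for s in support)


@dataclass(frozen=True)
class ComparisonReport:
    """Stratified and pooled repertoire-distribution comparison.

    ``per_node`` maps each occupied parameter-graph node index to a dict
    with the Hill and switching distributions of that stratum, their maximum
    absolute frequency difference, their JSD and the stratum size.
    """

    per_node: dict[int, dict] = field(default_factory=dict)
    pooled_hill: Distribution = field(default_factory=dict)
    pooled_switching: Distribution = field(default_factory=dict)
    occupancy: dict[int, float] = field(default_factory=dict)
    normalized_hill: Distribution = field(default_factory=dict)
    normalized_switching: Distribution = field(default_factory=dict)

    @property
    def worst_node_discrepancy(self) -> float:
        return max(d["max_abs_diff"] for d in self.per_node.values())


def _mean_distribution(dists: Sequence[Distribution]) -> Distribution:
    support = sorted({lab for d in dists for lab in d})
    return {
        lab: float(np.mean([d.get(lab, 0.0) for d in dists])) for lab in support
    }


def nodewise_comparison(
    hill_labels: pd.Series,
    switching_labels: pd.Series,
    node_index: pd.Series,
    jsd_base: float = 2.0,
) -> ComparisonReport:
    """Compare repertoire distributions per parameter-graph node and pooled.

    All three series are indexed by parameter-set id; strata with no members
    are omitted.  The switching labels are expected to come from the same
    parameter sets pushed through the switching system and the same
    discretization pipeline, so at high Hill coefficients the per-node
    discrepancy measures the finite-steepness (plus integration) error.
    """
    common = hill_labels.index.intersection(switching_labels.index).intersection(node_index.index)
    h, s, nd = hill_labels.loc[common], switching_labels.loc[common], node_index.loc[common]
    per_node: dict[int, dict] = {}
    node_h: dict[int, Distribution] = {}
    node_s: dict[int, Distribution] = {}
    for node in sorted(nd.unique()):
        mask = nd == node
        dh = distribution(h[mask])
        ds = distribution(s[mask])
        node_h[int(node)], node_s[int(node)] = dh, ds
        per_node[int(node)] = {
            "hill": dh,
            "switching": ds,
            "max_abs_diff": max_abs_diff(dh, ds),
            "jsd": jsd(dh, ds, base=jsd_base),
            "n": int(mask.sum()),
        }
    occupancy = {int(node): float((nd == node).mean()) for node in sorted(nd.unique())}
    return ComparisonReport(
        per_node=per_node,
        pooled_hill=distribution(h),
        pooled_switching=distribution(s),
        occupancy=occupancy,
        normalized_hill=_mean_distribution(list(node_h.values())),
        normalized_switching=_mean_distribution(list(node_s.values())),
    )


def ensemble_comparison(
    hill_labels: pd.Series,
    switching_labels: pd.Series,
    node_index: pd.Series,
    jsd_base: float = 2.0,
) -> ComparisonReport:
    """Alias of :func:`nodewise_comparison` emphasizing the pooled/normalized views."""
    return nodewise_comparison(hill_labels, switching_labels, node_index, jsd_base)


# --- PCA delineation --------------------------------------------------------

def pca_delineation(
    param_frame: pd.DataFrame,
    classes: pd.Series,
    n_components: int = 4,
    standardize: bool = False,
    min_class_size: int = 10,
) -> dict[str, dict]:
    """Principal components of the raw parameter matrix, per dynamics class.

    Covariance-based by default (no standardization), so parameters with the
    widest sampled ranges -- production rates and thresholds -- can dominate
    the leading components.  Returns, per class, the explained-variance
    ratios, their cumulative sum, and the loadings table (components x
    parameters).
    """
    out: dict[str, dict] = {}
    for cls in sorted(classes.unique()):
        ids = classes.index[classes == cls]
        X = param_frame.loc[ids].to_numpy(float)
        if len(X) < min_class_size:
            raise ValueError(f"class {cls!r} has fewer than {min_class_size} parameter sets")
        if standardize:
            X = (X - X.mean(axis=0)) / X.std(axis=0)
        pca = PCA(n_components=n_components)
        pca.fit(X)
        out[str(cls)] = {
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "cumulative": float(pca.explained_variance_ratio_.sum()),
            "loadings": pd.DataFrame(
                pca.components_,
                index=[f"PC{i + 1}" for i in range(n_components)],
                columns=param_frame.columns,
            ),
        }
    return out


# --- label plumbing ---------------------------------------------------------

def repertoire_label_map(label: str, network: Network) -> str:
    """Lift a binary Hill label to switching discrete levels (1 -> top level).

    Each node's digit 1 becomes its number of thresholds (out-degree), digit
    0 stays 0; applied digit-wise, and to each component of a canonical
    ``a-b-c`` repertoire string.
    """
    def lift(single: str) -> str:
        return "".join(
            str(network.out_degree(k)) if d == "1" else "0"
            for d, k in zip(single, network.nodes)
        )

    if label in ("", "cyclic"):
        return label
    return "-".join(sorted(lift(part) for part in label.split("-")))
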