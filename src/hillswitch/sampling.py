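"""Random parameter and initial-condition sampling for ensemble simulation.

The generator draws parameter sets independently and uniformly from
per-class ranges in the spirit of random circuit perturbation: production
rates U(1, 100) (so the median production is 50), degradation rates
U(0.1, 1), Hill coefficients U(1, 6) by default, activation fold changes
U(1, 100), and repression fold changes as the *reciprocal* of a U(1, 100)
magnitude -- both regulation signs share one fold-magnitude scale, and the
reciprocal convention is what concentrates repressed expression near zero
and, downstream, what concentrates sampled parameter sets in the central,
multistable region of switching-parameter space.

Thresholds follow the *half-functional rule*: the threshold of an edge is
drawn from (0.02*M, 1.98*M) where M is the median expression level of the
edge's regulator, so each regulatory link has roughly even odds of being
functional.  By default M is estimated self-consistently by Monte Carlo,
accounting for the regulator's own (randomly parameterized) regulation --
a repressed regulator has a much lower median than an unregulated one.  A
simpler proxy (M = P_mid / (2 * gamma_mid), the half-maximal level of an
unregulated node at mid-range rates) and explicit ranges are available.
All ranges are overridable.

Every sampled set must be *regular* after translation to the switching
formalism: no production value may coincide with any gamma*theta product.
Equality is a measure-zero event under continuous sampling, but offending
sets are resampled so downstream combinatorics never sees a degenerate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .combinatorics import regularity_violation
from .networks import Network
from .parameters import (
    RacipeParameterSet,
    SwitchingParameterSet,
    _ek,
    racipe_columns,
)
from .translate import translate_frame

logger = logging.getLogger(__name__)

Range = tuple[float, float]


@dataclass(frozen=True)
class SamplingConfig:
    """Uniform sampling ranges and ensemble sizing.

    ``repression_fold`` is the range of the fold-change *magnitude*; with
    ``reciprocal_repression`` (the default) the repression fold i is the
    reciprocal of a uniform draw from that range, otherwise i is drawn
    uniformly from it directly.  ``threshold=None`` derives per-edge
    half-functional ranges from the regulator's estimated median level:
    self-consistently Monte-Carlo estimated for ``threshold_mode =
    "regulated"`` (the default), or the unregulated mid-range proxy for
    ``"unregulated"``.
    """

    n_sets: int = 5000
    n_init: int = 100
    production: Range = (1.0, 100.0)
    degradation: Range = (0.1, 1.0)
    activation_fold: Range = (1.0, 100.0)
    repression_fold: Range = (1.0, 100.0)
    reciprocal_repression: bool = True
    hill: Range = (1.0, 6.0)
    integer_hill: bool = False
    threshold: Range | None = None
    threshold_mode: str = "regulated"
    seed: int = 0
    regularity_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "activation_fold", "repression_fold", "hill"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} range must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.threshold is not None:
            lo, hi = self.threshold
            if not (0 < lo < hi):
                raise ValueError(f"threshold range must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.n_sets < 0 or self.n_init < 1:
            raise ValueError("need n_sets >= 0 and n_init >= 1")

    @property
    def unregulated_scale(self) -> float:
        """Half-maximal level P_mid / (2 gamma_mid) of an unregulated node."""
        p_mid = 0.5 * (self.production[0] + self.production[1])
        g_mid = 0.5 * (self.degradation[0] + self.degradation[1])
        return p_mid / (2.0 * g_mid)

    @property
    def threshold_range(self) -> Range:
        """Explicit threshold range, or the unregulated-proxy default."""
        if self.threshold is not None:
            return self.threshold
        m = self.unregulated_scale
        return (0.02 * m, 1.98 * m)

    def with_hill(self, hill: Range) -> "SamplingConfig":
        """The same configuration with a different Hill-coefficient range."""
        return replace(self, hill=hill)


#: Hill-coefficient ranges used in the steepness-sweep experiments.
HILL_SWEEP_RANGES: tuple[Range, ...] = ((1.0, 10.0), (10.0, 50.0), (50.0, 100.0), (100.0, 1000.0))


def _draw(rng: np.random.Generator, rng_range: Range, size: int) -> np.ndarray:
    return rng.uniform(rng_range[0], rng_range[1], size)


def regulated_median_levels(
    network: Network,
    config: SamplingConfig,
    n_samples: int = 20000,
    iterations: int = 12,
) -> dict[str, float]:
    """Self-consistent Monte-Carlo estimate of each node's median expression.

    Mirrors the half-functional threshold estimation of random circuit
    perturbation: a node's level is P/gamma times one fold factor per input
    edge, applied when the (randomly parameterized) regulator clears the
    edge's threshold; thresholds in turn are drawn around the regulators'
    current median estimates, and the estimates are iterated to a fixed
    point.  Deterministic (internal fixed seed), so a given network and
    configuration always yield the same threshold ranges.
    """
    rng = np.random.default_rng(1234567)
    medians = {k: config.unregulated_scale for k in network.nodes}
    draws = {
        k: _draw(rng, config.production, n_samples) / _draw(rng, config.degradation, n_samples)
        for k in network.nodes
    }
    folds = {}
    for e in network.edges:
        if e.is_activation:
            folds[(e.target, e.source)] = 1.0 / _draw(rng, config.activation_fold, n_samples)
        elif config.reciprocal_repression:
            folds[(e.target, e.source)] = 1.0 / _draw(rng, config.repression_fold, n_samples)
        else:
            folds[(e.target, e.source)] = _draw(rng, config.repression_fold, n_samples)
    levels = dict(draws)
    shuffles = {
        key: rng.permutation(n_samples) for key in network.edge_keys
    }
    thetas_u = {key: rng.random(n_samples) for key in network.edge_keys}
    for _ in range(iterations):
        new_levels = {}
        for k in network.nodes:
            x = draws[k].copy()
            for e in network.inputs(k):
                key = (k, e.source)
                m_src = medians[e.source]
                theta = (0.02 + 1.96 * thetas_u[key]) * m_src
                src_level = levels[e.source][shuffles[key]]
                functional = src_level > theta
                # activation: factor 1/a unless the activator is functional;
                # repression: factor i when the repressor is functional
                if e.is_activation:
                    x = np.where(functional, x, x * folds[key])
                else:
                    x = np.where(functional, x * folds[key], x)
            new_levels[k] = x
        levels = new_levels
        medians = {k: float(np.median(levels[k])) for k in network.nodes}
    return medians


def threshold_ranges(network: Network, config: SamplingConfig) -> dict[tuple[str, str], Range]:
    """Per-edge threshold sampling range under the configured convention."""
    if config.threshold is not None:
        return {key: config.threshold for key in network.edge_keys}
    if config.threshold_mode == "regulated":
        medians = regulated_median_levels(network, config)
    elif config.threshold_mode == "unregulated":
        medians = {k: config.unregulated_scale for k in network.nodes}
    else:
        raise ValueError(f"unknown threshold_mode {config.threshold_mode!r}")
    return {
        (tgt, src): (0.02 * medians[src], 1.98 * medians[src])
        for tgt, src in network.edge_keys
    }


def _draw_frame(
    network: Network,
    config: SamplingConfig,
    rng: np.random.Generator,
    m: int,
    th_ranges: dict[tuple[str, str], Range] | None = None,
) -> pd.DataFrame:
    if th_ranges is None:
        th_ranges = threshold_ranges(network, config)
    cols: dict[str, np.ndarray] = {}
    for k in network.nodes:
        cols[f"P_{k}"] = _draw(rng, config.production, m)
        cols[f"gamma_{k}"] = _draw(rng, config.degradation, m)
    for e in network.edges:
        key = _ek((e.target, e.source))
        cols[f"theta_{key}"] = _draw(rng, th_ranges[(e.target, e.source)], m)
        n = _draw(rng, config.hill, m)
        if config.integer_hill:
            n = np.floor(n)
        cols[f"n_{key}"] = n
        if e.is_activation:
            cols[f"fold_{key}"] = _draw(rng, config.activation_fold, m)
        elif config.reciprocal_repression:
            cols[f"fold_{key}"] = 1.0 / _draw(rng, config.repression_fold, m)
        else:
            cols[f"fold_{key}"] = _draw(rng, config.repression_fold, m)
    return pd.DataFrame(cols, columns=racipe_columns(network))


def _irregular_rows(network: Network, frame: pd.DataFrame, tolerance: float) -> np.ndarray:
    """Boolean mask of rows whose translated switching parameters are degenerate."""
    sw = translate_frame(network, frame)
    bad = np.zeros(len(frame), dtype=bool)
    for i in network.nodes:
        out_edges = network.outputs(i)
        in_edges = network.inputs(i)
        # coincident thresholds among outputs of the same source variable
        for a in range(len(out_edges)):
            for b in range(a + 1, len(out_edges)):
                ta = sw[f"theta_{_ek((out_edges[a].target, i))}"].to_numpy()
                tb = sw[f"theta_{_ek((out_edges[b].target, i))}"].to_numpy()
                bad |= np.abs(ta - tb) <= tolerance
        # production values versus gamma * theta of each output
        if in_edges:
            combo_values = [np.ones(len(frame))]
            for e in in_edges:
                key = _ek((i, e.source))
                lows = sw[f"L_{key}"].to_numpy()
                highs = sw[f"U_{key}"].to_numpy()
                combo_values = [v * lows for v in combo_values] + [v * highs for v in combo_values]
        else:
            combo_values = [sw[f"basal_{i}"].to_numpy()]
        gamma = sw[f"gamma_{i}"].to_numpy()
        for e in out_edges:
            gt = gamma * sw[f"theta_{_ek((e.target, i))}"].to_numpy()
            for lam in combo_values:
                bad |= np.abs(gt - lam) <= tolerance
    return bad


def sample_parameters(
    network: Network, config: SamplingConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``config.n_sets`` parameter sets, resampling any degenerate ones.

    Reproducible for a given seed (``config.seed`` unless overridden); each
    marginal is uniform on its configured range.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    th_ranges = threshold_ranges(network, config)
    frame = _draw_frame(network, config, rng, config.n_sets, th_ranges)
    if len(frame) == 0:
        return frame
    for _ in range(100):
        bad = _irregular_rows(network, frame, config.regularity_tolerance)
        if not bad.any():
            break
        logger.info("resampling %d degenerate parameter sets", int(bad.sum()))
        frame.loc[bad, :] = _draw_frame(network, config, rng, int(bad.sum()), th_ranges).to_numpy()
    else:  # pragma: no cover - probability ~0 for continuous ranges
        raise RuntimeError("regularity resampling did not terminate")
    frame.index.name = "param_id"
    return frame


def regularity_screen(
    network: Network, params: SwitchingParameterSet, tolerance: float = 1e-9
) -> tuple[bool, str | None]:
    """Pass/fail genericity check; on failure, the offending inequality."""
    violation = regularity_violation(network, params, tolerance)
    return violation is None, violation


# --- initial conditions -----------------------------------------------------

def ic_envelope(network: Network, p: RacipeParameterSet) -> Range:
    """Log-uniform sampling envelope spanning all expression scales of a set.

    From two decades below the smallest unregulated level P/gamma to one
    decade above the largest, so every attractor basin is represented.
    """
    scales = [p.production[k] / p.degradation[k] for k in network.nodes]
    return (1e-2 * min(scales), 10.0 * max(scales))


def sample_initial_conditions(
    network: Network,
    p: RacipeParameterSet,
    count: int,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """``count`` strictly positive state vectors, log-uniform on the envelope."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = ic_envelope(network, p)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(count, len(network.nodes))))


def initial_conditions_for_frame(
    network: Network,
    frame: pd.DataFrame,
    count: int,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Per-row log-uniform initial conditions, shape (len(frame), count, n_nodes)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scales = np.column_stack(
        [frame[f"P_{k}"].to_numpy(float) / frame[f"gamma_{k}"].to_numpy(float) for k in network.nodes]
    )
    lo = np.log(1e-2 * scales.min(axis=1))[:, None, None]
    hi = np.log(10.0 * scales.max(axis=1))[:, None, None]
    u = rng.random((len(frame), count, len(network.nodes)))
    return np.exp(lo + (hi - lo) * u)


# --- key-value config files -------------------------------------------------

def save_config(config: SamplingConfig, path: Union[str, Path]) -> None:
    """Write a config as ``key = value`` lines (ranges as ``lo,hi``)."""
    lines = []
    for name, value in vars(config).items():
        if isinstance(value, tuple):
            value = f"{value[0]},{value[1]}"
        lines.append(f"{name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: Union[str, Path]) -> SamplingConfig:
    kwargs: dict = {}
    bools = {"reciprocal_repression", "integer_hill"}
    ints = {"n_sets", "n_init", "seed"}
    strings = {"threshold_mode"}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, _, value = line.partition("=")
        name, value = name.strip(), value.strip()
        if value == "None":
            kwargs[name] = None
        elif name in bools:
            kwargs[name] = value.lower() in ("true", "1", "yes")
        elif name in ints:
            kwargs[name] = int(value)
        elif name in strings:
            kwargs[name] = value
        elif "," in value:
            lo, hi = value.split(",")
            kwargs[name] = (float(lo), float(hi))
        else:
            kwargs[name] = float(value)
    return SamplingConfig(**kwargs)
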