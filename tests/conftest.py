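import numpy as np
import pandas as pd
import pytest

from hillswitch.networks import builtin_network
from hillswitch.parameters import SwitchingParameterSet
from hillswitch.sampling import SamplingConfig, sample_parameters
from hillswitch.translate import translate_frame


@pytest.fixture(scope="session")
def ts():
    return builtin_network("TS")


@pytest.fixture(scope="session")
def da():
    return builtin_network("DA")


@pytest.fixture(scope="session")
def nf():
    return builtin_network("NF")


@pytest.fixture(scope="session")
def tt():
    return builtin_network("TT")


@pytest.fixture(scope="session")
def ts_ensemble(ts):
    """A small sampled TS ensemble with its translated switching frame."""
    cfg = SamplingConfig(n_sets=400, seed=101)
    params = sample_parameters(ts, cfg)
    return params, translate_frame(ts, params)


def symmetric_bistable_ts() -> SwitchingParameterSet:
    """Fully symmetric central-node TS switching parameters (analytic diagonal)."""
    return SwitchingParameterSet(
        degradation={"A": 1.0, "B": 1.0},
        low={("A", "B"): 0.5, ("B", "A"): 0.5},
        high={("A", "B"): 4.0, ("B", "A"): 4.0},
        threshold={("A", "B"): 2.0, ("B", "A"): 2.0},
    )


@pytest.fixture
def ts_symmetric():
    return symmetric_bistable_ts()


def random_regular_switching(network, rng, center_only=False):
    """Random regular switching parameters for 1-input/1-output networks."""
    while True:
        gamma = {k: rng.uniform(0.1, 1.0) for k in network.nodes}
        low, high, theta = {}, {}, {}
        for key in network.edge_keys:
            lo = rng.uniform(0.05, 2.0)
            high[key] = lo * rng.uniform(1.5, 30.0)
            low[key] = lo
            theta[key] = rng.uniform(0.1, 30.0)
        q = SwitchingParameterSet(degradation=gamma, low=low, high=high, threshold=theta)
        if center_only:
            ok = True
            for k in network.nodes:
                (in_e,) = network.inputs(k)
                (out_e,) = network.outputs(k)
                gt = gamma[k] * theta[(out_e.target, k)]
                key = (k, in_e.source)
                if not (low[key] < gt < high[key]):
                    ok = False
            if not ok:
                continue
        from hillswitch.combinatorics import regularity_violation

        if regularity_violation(network, q) is None:
            return q
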