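"""Ensemble-level repertoire distributions and the sampling-bias correction.

Pooling repertoire frequencies over all sampled TS parameter sets
over-represents the bistable 01-10 repertoire relative to a uniform
weighting of the nine parameter-graph nodes, because the sampler lands in
the central node more than half the time.  Re-weighting each occupied node
equally (the node-count normalization) restores the match between the Hill
ensemble and the switching prediction at high Hill coefficients.
"""

from pathlib import Path

import pandas as pd

from hillswitch.compare import jsd
from hillswitch.networks import builtin_network
from hillswitch.pipeline import compare_hill_to_switching, run_hill_ensemble
from hillswitch.sampling import SamplingConfig

M = 2000
SEED = 2030
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

net = builtin_network("TS")
cfg = SamplingConfig(n_sets=M, seed=SEED, hill=(50.0, 100.0))
run = run_hill_ensemble(net, cfg)
report = compare_hill_to_switching(run)

rows = []
for view, hill, switching in (
    # the switching reference is always node-uniform: that is the prediction a
    # parameter-space decomposition makes with no knowledge of sampling bias
    ("raw_pooled", report.pooled_hill, report.normalized_switching),
    ("node_normalized", report.normalized_hill, report.normalized_switching),
):
    for label in sorted(set(hill) | set(switching)):
        rows.append(
            {
                "view": view,
                "repertoire": label,
                "hill_frequency": hill.get(label, 0.0),
                "switching_frequency": switching.get(label, 0.0),
            }
        )
pd.DataFrame(rows).to_csv(OUT / "TS_ensemble_distributions.tsv", sep="\t", index=False)
occ = pd.Series(report.occupancy, name="occupancy")
occ.rename_axis("parameter_node").to_csv(OUT / "TS_node_occupancy_highhill.tsv", sep="\t")

bist = report.pooled_hill.get("01-10", 0.0)
print(f"raw pooled 01-10 frequency: {bist:.3f} (uniform over 9 nodes would predict {1/9:.3f})")
print(f"central-node occupancy: {report.occupancy.get(4, 0.0):.3f}")
print(
    "JSD(Hill, node-uniform switching prediction): raw pooled "
    f"{jsd(report.pooled_hill, report.normalized_switching):.4f} bits; "
    "after node-count normalization "
    f"{jsd(report.normalized_hill, report.normalized_switching):.4f} bits"
)
print(f"wrote ensemble distribution tables to {OUT}")
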