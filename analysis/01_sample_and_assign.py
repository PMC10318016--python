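"""Sample Hill-model ensembles for the two-node motifs and locate each
parameter set in switching-parameter space.

For TS, DA and NF: draw an ensemble from the default ranges, translate every
set to switching parameters, assign it to a parameter-graph node by its
inequality signature, and tabulate the occupancy of the nine nodes.  The
striking output is the sampling bias: more than half of all sampled sets
satisfy the central node's inequalities -- the one node (per motif) whose
predicted dynamics is bistable (TS, DA) or cyclic (NF).
"""

from pathlib import Path

import pandas as pd

from hillswitch.combinatorics import assign_signature_indices, enumerate_parameter_graph
from hillswitch.networks import builtin_network
from hillswitch.sampling import SamplingConfig, sample_parameters
from hillswitch.translate import translate_frame

M = 5000
SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for name in ("TS", "DA", "NF"):
    net = builtin_network(name)
    cfg = SamplingConfig(n_sets=M, seed=SEED)
    params = sample_parameters(net, cfg)
    sw = translate_frame(net, params)
    idx = pd.Series(assign_signature_indices(net, sw), index=params.index, name="parameter_node")
    params.join(idx).to_csv(OUT / f"{name}_ensemble.tsv", sep="\t")
    sw.join(idx).to_csv(OUT / f"{name}_switching.tsv", sep="\t")
    pg = enumerate_parameter_graph(net)
    occ = idx.value_counts(normalize=True).sort_index()
    for node in pg.nodes:
        rows.append(
            {
                "network": name,
                "parameter_node": node,
                "predicted_repertoire": pg.nodes[node]["repertoire"],
                "occupancy": float(occ.get(node, 0.0)),
            }
        )
    central = float(occ.get(4, 0.0))
    print(
        f"{name}: central node holds {100 * central:.1f}% of {M} sampled sets "
        f"(predicted: {pg.nodes[4]['repertoire']}); a uniform decomposition would give 11.1%"
    )

pd.DataFrame(rows).to_csv(OUT / "parameter_node_occupancy.tsv", sep="\t", index=False)
print(f"wrote ensembles and occupancy tables to {OUT}")
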