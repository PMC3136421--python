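"""Global benchmark: F-score ensembles at the optimal cutoff, and the
F-vs-cutoff curve comparing C3NET with RN.

Runs the full pipeline on a 20-gene DAG twice (m=1000 and m=20) to expose
the sample-size sensitivity, then sweeps the MI cutoff on one dataset.
"""

import numpy as np

from grnilab import fscore_vs_cutoff, mi_matrix
from grnilab.benchmark import make_network, run_benchmark

net = make_network("dag", 20, seed=11)
print(f"true network: 20-gene DAG with {len(net.edges)} edges\n")

for m in (1000, 20):
    res = run_benchmark(net, n_datasets=30, n_samples=m, master_seed=12,
                        methods=("c3net", "aracne", "mrnet"), grid_size=30)
    print(f"sample size m = {m}: F-score summary over 30 datasets (optimal cutoffs)")
    print(res.summary.round(3).to_string(index=False))
    print()

mim = mi_matrix(run_benchmark(net, 1, 1000, 13, ("c3net",), 5).ensemble.datasets[0])
grid = np.linspace(0.0, float(mim.values.max()), 20)
curve = fscore_vs_cutoff(mim, net, ("c3net", "rn"), grid)
print("F-score vs MI cutoff (same data, both methods):")
pivot = curve.pivot(index="cutoff", columns="method", values="fscore").round(3)
print(pivot.to_string())
print(
    "\nC3NET dominates RN at low cutoffs because it keeps only each gene's "
    "maximal\nsignificant edge instead of every pair above I0."
)
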