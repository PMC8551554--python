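"""Threshold a connectivity matrix across sparsities and compute the
four global graph metrics.

Uses a synthetic 68-region PLV matrix (one planted module plus a noisy
background), sweeps proportional thresholds 0.05-0.50, and prints the
metric table plus null-normalized values at one density.
"""

import numpy as np

from plvnet.graphmetrics import (metrics_sweep, minimum_connected_sparsity,
                                 normalize_vs_random, proportional_threshold)

rng = np.random.default_rng(5)
m = 0.2 + 0.1 * rng.random((68, 68))
m = (m + m.T) / 2
module = rng.choice(68, size=10, replace=False)
for i in module:               # a tightly coupled module
    for j in module:
        if i != j:
            m[i, j] = 0.7 + 0.1 * rng.random()
np.fill_diagonal(m, 1.0)

df = metrics_sweep(m, subject_id="demo", band="beta2")
table = df.pivot_table(index="sparsity", columns="metric", values="value")
print(table.round(3).to_string())
print(f"\nminimum connected sparsity: {minimum_connected_sparsity(m)}")

g = proportional_threshold(m, 0.2)
nl, nc = normalize_vs_random(g, n_null=10, seed=1)
print(f"at sparsity 0.20: normalized L = {nl:.3f}, normalized C = {nc:.3f}")
print("\nDenser graphs are more efficient (Eglob rises with sparsity); "
      "the planted module keeps clustering above the degree-matched "
      "rewired null (normalized C > 1).")
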