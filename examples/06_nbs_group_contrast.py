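"""Find a planted connectivity difference with the network-based statistic.

Two groups of 15 synthetic PLV matrices differ by +0.2 on the 10 edges
of a 5-region clique.  NBS thresholds the edgewise t-map at edge
p = 0.05, extracts connected supra-threshold components, and compares
their intensity with a max-component permutation null.
"""

import numpy as np

from plvnet.netstats import StatSpec, edge_count_summary, nbs

rng = np.random.default_rng(11)
clique = [2, 3, 4, 5, 6]
planted = {(a, b) for i, a in enumerate(clique) for b in clique[i + 1:]}


def stack(n_subj, effect=0.0):
    out = 0.3 + rng.normal(0, 0.05, size=(n_subj, 68, 68))
    out = (out + out.transpose(0, 2, 1)) / 2
    for i, j in planted:
        out[:, i, j] += effect
        out[:, j, i] += effect
    return out


inc, dec = nbs(stack(15, effect=0.2), stack(15),
               StatSpec(n_perm_nbs=1000, seed=0,
                        component_statistic="intensity"))
found = inc.significant_edges()
print(f"edge threshold: t > {inc.threshold:.2f} (edge p = 0.05, df = 28)")
print(f"significant increase components: {len(inc.significant)}, "
      f"p = {[round(p, 4) for p in inc.p_values[:2]]}")
print(f"planted edges recovered: {len(found & planted)}/10 "
      f"(component spans {len(found)} edges in total)")
print(f"decrease direction: {len(dec.significant)} significant components")

summary = edge_count_summary({"theta": (0, 0), "beta2": (inc, dec)})
print(f"\nper-band significant edge counts: {summary['per_band']}")
print("\nThe planted clique joins the supra-threshold component and its "
      "extreme t-values make the component intensity unreachable under "
      "label permutation (p ~ 0.001); the unshifted direction is quiet.")
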