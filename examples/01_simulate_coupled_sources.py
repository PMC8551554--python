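"""Simulate phase-coupled cortical sources and verify the ground truth.

Builds a small source model with three planted beta2-band couplings of
increasing strength, then measures the phase-locking value of each pair
and compares it with the closed-form expectation I1(k)/I0(k).
"""

import numpy as np

from plvnet.bands import BETA2
from plvnet.connectivity import instantaneous_phase, plv
from plvnet.synthcohort import (SimulationSpec, expected_plv_from_kappa,
                                simulate_coupled_sources)

spec = SimulationSpec(
    n_regions=8, fs=250.0, duration=60.0,
    coupling_kappa={((0, 1), "beta2"): 1.0,
                    ((2, 3), "beta2"): 3.0,
                    ((4, 5), "beta2"): 8.0},
    seed=42)
src, truth = simulate_coupled_sources(spec)
phases = instantaneous_phase(src.data, BETA2, src.fs)

print("pair   kappa  expected PLV  measured PLV")
for (pair, band), kappa in sorted(spec.coupling_kappa.items()):
    measured = plv(phases[pair[0]], phases[pair[1]])
    print(f"{pair}  {kappa:5.1f}  {expected_plv_from_kappa(kappa):12.3f}"
          f"  {measured:12.3f}")
uncoupled = plv(phases[6], phases[7])
print(f"(6, 7)    0.0         0.000  {uncoupled:12.3f}")
print("\nMeasured PLV tracks the von Mises mean resultant I1(k)/I0(k): "
      "stronger coupling concentration -> tighter phase locking; the "
      "uncoupled pair sits at the ~0.05 finite-sample estimation floor.")
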