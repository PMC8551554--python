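"""Run the complete pipeline on a small simulated cohort.

Simulates a control / stimulation-off / stimulation-on cohort, then
executes preprocessing, wMNE source reconstruction, band power,
connectivity, graph metrics and group statistics, writing all result
tables plus a reproducibility manifest.
"""

import json
import tempfile
from pathlib import Path

from plvnet.pipeline import PipelineConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp()) / "demo"
cfg = PipelineConfig(
    output_dir=str(out_dir),
    n_per_group=4, duration=30.0, fs=250.0, n_regions=20, n_sensors=24,
    bands=("theta", "beta2"), n_perm_psd=500, n_perm_nbs=500, seed=3)
report = run_pipeline(cfg)

print(f"outputs under {report.output_dir}:")
for p in sorted(report.output_dir.iterdir()):
    print(f"  {p.name}")
print("\nband-power permutation tests (PD-off vs controls, off vs on paired):")
print(json.dumps(report.results["band_power_tests"], indent=1))
print("\npaired NBS summary per band:")
print(json.dumps(report.results["nbs"], indent=1))
print(f"\nconfig hash {report.manifest['config_hash']}: rerunning with the "
      "same seed reproduces every table byte-for-byte.")
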