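"""Solve the EEG inverse problem with wMNE on the toy forward model.

Activates one cortical source at a time, projects it to 32 sensors, and
shows that the depth-weighted minimum-norm estimate puts the power
maximum back at the true source.
"""

import numpy as np

from plvnet.inverse import InverseSpec, apply_inverse, compute_wmne_operator
from plvnet.io import Recording
from plvnet.synthcohort import make_toy_lead_field

lf = make_toy_lead_field(n_sensors=32, n_sources=68, seed=3)
op = compute_wmne_operator(lf, InverseSpec(lambda2=1 / 9, depth_gamma=0.8))

t = np.arange(500) / 250.0
wave = np.sin(2 * np.pi * 9 * t)
hits = 0
for true_idx in (0, 17, 34, 51, 67):
    rec = Recording(data=np.outer(lf.gain[:, true_idx], wave), fs=250.0,
                    channel_labels=lf.sensor_labels)
    est = apply_inverse(op, rec)
    found = int(np.argmax((est ** 2).mean(axis=1)))
    corr = np.corrcoef(est[true_idx], wave)[0, 1]
    hits += found == true_idx
    print(f"true source {true_idx:2d} -> estimated {found:2d} "
          f"(time-course corr {corr:+.3f})")
print(f"\n{hits}/5 sources localized exactly: the regularized kernel "
      "K = W G'(G W G' + lambda^2 C)^-1 with depth weighting recovers "
      "both the location and the waveform of isolated generators.")
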