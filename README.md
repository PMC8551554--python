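# plvnet

Source-space EEG brain-network analysis for group studies of
Parkinson's disease and deep-brain stimulation (DBS): weighted
minimum-norm source reconstruction, band-limited power spectra,
phase-locking-value connectivity over 68 cortical atlas regions,
graph-theoretic network characterization across proportional sparsity
thresholds, and permutation-based group statistics including the
network-based statistic (NBS). A synthetic-cohort generator with
closed-form phase-coupling ground truth stands in for clinical
recordings, so every stage of the pipeline can be validated
quantitatively.

The intended user is a researcher analyzing resting-state EEG of two
groups (e.g. patients vs. matched controls) with a paired
within-subject condition (stimulation ON vs. OFF), who wants the whole
chain — from sensor time series to corrected group statistics — as a
reproducible, testable library rather than a collection of GUI steps.

## The analysis in brief

1. **Preprocessing** — zero-phase Butterworth band-pass (1–30 Hz),
   non-overlapping 2-s epochs, rejection of epochs whose any-channel
   peak-to-peak amplitude exceeds 150 µV, inverse-distance
   interpolation of flagged bad channels.
2. **Inverse solution** — depth-weighted minimum-norm estimation
   (wMNE): `K = W Gᵀ (G W Gᵀ + λ² C)⁻¹` with `W = diag(‖gⱼ‖^(−2γ))`,
   defaults λ² = 1/9 (SNR 3 convention) and γ = 0.8; vertex series are
   parcellated to the 68 Desikan–Killiany regions by a sign-aligned
   mean.
3. **Spectra** — Welch PSD (Hann window, 4-s segments, 50 % overlap)
   on the concatenated clean recording; band power and band SNR
   (in-band / out-of-band power) in theta (4–8), alpha (8–13), beta1
   (13–20) and beta2 (20–30 Hz).
4. **Connectivity** — instantaneous phase per band (zero-phase
   band-pass + Hilbert transform, 1 s edge trim), phase-locking value
   `PLV = |⟨e^{i(φx−φy)}⟩|` for all 2,278 region pairs (phase lag
   index available as a comparator), per-2-s-epoch averaging by
   default.
5. **Graph metrics** — proportional thresholds 0.05–0.50 (step 0.05,
   weights retained); characteristic path length, global efficiency,
   Onnela weighted clustering and local efficiency; optional
   normalization against Maslov–Sneppen degree-preserving surrogates.
6. **Statistics** — label/sign-flip permutation tests for band power
   (1,000 randomizations), t-tests with Benjamini–Hochberg FDR across
   the sparsity grid for graph metrics, and NBS for edgewise contrasts
   (edge p = 0.05, component p = 0.01, 5,000 permutations by default;
   extent or intensity component statistic).

## Worked example

```python
from plvnet.bands import BETA2
from plvnet.connectivity import instantaneous_phase, plv
from plvnet.synthcohort import (SimulationSpec, expected_plv_from_kappa,
                                simulate_coupled_sources)

spec = SimulationSpec(n_regions=8, fs=250.0, duration=60.0,
                      coupling_kappa={((0, 1), "beta2"): 1.0,
                                      ((2, 3), "beta2"): 3.0,
                                      ((4, 5), "beta2"): 8.0},
                      seed=42)
src, truth = simulate_coupled_sources(spec)
phases = instantaneous_phase(src.data, BETA2, src.fs)
for (pair, band), kappa in sorted(spec.coupling_kappa.items()):
    print(pair, kappa, round(expected_plv_from_kappa(kappa), 3),
          round(plv(phases[pair[0]], phases[pair[1]]), 3))
```

prints

```
(0, 1) 1.0 0.446 0.430
(2, 3) 3.0 0.810 0.780
(4, 5) 8.0 0.935 0.921
```

— each planted pair's measured PLV tracks the closed-form expectation
I₁(κ)/I₀(κ) of its von Mises coupling concentration κ, while uncoupled
pairs sit at the ~0.05 finite-sample floor. The `examples/` directory
holds one narrative script per capability (simulation, preprocessing,
localization, band power, graph metrics, NBS, full pipeline); each
builds its own small input and prints what it computes.

A thin CLI wraps the pipeline for shell use:

```bash
plvnet run --config config.yaml --seed 1
plvnet graph connectivity.tsv --sparsity 0.05:0.5:0.05 --out metrics.tsv
```

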