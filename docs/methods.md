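# Methods

This note documents the models, parameter choices and numerical
conventions behind `plvnet`, and what the synthetic validation does and
does not establish about real EEG.

## Synthetic cohort model

Each simulated subject is a set of regional source time series, one per
cortical region (68 in the canonical atlas), sampled at `fs` for
`duration` seconds (demo scale: 250 Hz, 60 s; the pipeline accepts the
clinical-scale 1,000 Hz without change). A region's series is a sum of
four narrow-band oscillations (theta/alpha/beta1/beta2) plus a 1/f
background:

* **Coupling clusters.** Region pairs with planted coupling share a
  band-limited common carrier phase: instantaneous frequency = band
  midpoint plus a slow Ornstein–Uhlenbeck drift (SD 0.15 Hz, time
  constant 5 s, clipped to ±0.5 Hz), so signals are not pathological
  pure tones. Within a cluster, the lowest-index region is an
  un-jittered anchor; every other member adds an independent slow
  Gaussian phase jitter with variance σ²(κ) = −2 ln(I₁(κ)/I₀(κ)).
  Because the jitter is Gaussian, E[e^{iθ}] = e^{−σ²/2} = I₁(κ)/I₀(κ)
  exactly, so an anchor–member pair has closed-form expected PLV equal
  to the mean resultant of a von Mises distribution with concentration
  κ, and a member–member pair the product of the two resultants. The
  ground-truth object records these values per pair. A wrapped-normal
  jitter was chosen over literal i.i.d. von Mises draws because a
  *smooth* process survives the band-pass + Hilbert measurement chain,
  while white phase noise would be destroyed by it; the von Mises
  parameterization is kept so κ retains its conventional meaning.
* **Jitter spectra.** Coupled members' jitter occupies 0.2 Hz up to
  min(1.5 Hz, 0.3 × band width): fast enough that a 60-s record holds
  many effectively independent phasor draws (estimator SD ≈ 0.01–0.02
  at κ = 2), slow enough that the modulation sidebands stay inside the
  band. Uncoupled regions get their own oscillator — carrier drawn
  uniformly from the central half of the band plus a large jitter
  (σ² = 4, bandwidth 0.2 × band width) — making uncoupled pairs
  genuinely phase-independent; pinning every oscillator at the band
  midpoint would spuriously lock uncoupled pairs. The jitter is
  synthesized in the frequency domain (Gaussian Fourier coefficients
  on in-band bins): IIR filtering at normalized frequencies of 10⁻³
  proved numerically non-Gaussian.
* **Background.** Per-region 1/f-power noise (flattened below 1 Hz),
  SD 0.25 relative to unit oscillation amplitude, so in-band noise
  contributes ≈ 2 % of band power and planted amplitude ratios survive
  measurement within a few percent.
* **Group presets.** The control-like spec has unit amplitude in every
  band. The PD-like spec plants theta amplitude ×1.5 (power ×2.25),
  beta1/beta2 amplitude ×0.75 (power ×0.56), and a beta2-band coupled
  clique over five regions (10 edges) with κ = 6 in the
  stimulation-OFF condition weakening to κ = 1 in ON — a paired,
  condition-dependent subnetwork effect. Sample sizes are free
  parameters; the clinical-scale design is 21 controls vs. 20
  patients, the demo cohort 12 + 12.
* **Randomness.** One master seed spawns `SeedSequence` children in a
  fixed order: per band, one cluster stream then one stream per
  region; then the pink-noise stream; sensor noise is seeded
  separately. Paired OFF/ON subjects share their subject seed, so
  within-subject differences reflect only the planted κ change.
* **Forward model.** The toy lead field places sensors on an upper
  unit hemisphere (Fibonacci lattice) and one source dipole per region
  on a concentric shell of radius 0.8 restricted to the spherical cap
  z ≥ 0.15 — sources sit under the electrode array, as cortex does
  under a cap; gain = 1/distance², globally scaled so unit-amplitude
  sources produce EEG-like (~10 µV RMS) sensor signals.

What the generator does *not* emulate: realistic head geometry and
volume conduction (a 1/d² spherical toy replaces a boundary-element
model), ocular/muscle/cardiac artifacts (the artifact-rejection stage
is exercised with planted amplitude bursts instead), genuine 1/f slope
variation, cross-frequency coupling, and non-stationarity beyond slow
carrier drift. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated statistical model, not robustness to
every pathology of clinical EEG.

## Preprocessing

Zero-phase Butterworth band-pass applied forward–backward; order 5 by
default, which keeps a 50 Hz mains tone below 1 % residual amplitude
for the 1–30 Hz band and gives far more than 40 dB attenuation one
octave out. Epochs are non-overlapping, contiguous 2-s windows; the
trailing remainder is discarded. The artifact criterion is a
channel-wise peak-to-peak threshold (default 150 µV) — simple,
reproducible, and sufficient for planted artifacts; independent
component analysis is deliberately out of scope, and real data are
expected to arrive artifact-cleaned. Bad-channel repair is an
inverse-distance-weighted average of the 4 nearest good channels.
Channel-set reduction (e.g. dropping face/neck electrodes) is a
label-list exclusion in the configuration, not hard-coded.

## Inverse solution

`K = W Gᵀ (G W Gᵀ + λ² C)⁻¹`, fixed dipole orientations, with
`W = diag(‖gⱼ‖^(−2γ))`. The noise covariance C (identity by default)
is rescaled to trace parity with `G W Gᵀ`, which makes λ²
dimensionless — an inverse squared SNR — independent of lead-field
units; λ² = 1/9 encodes the common assumed SNR of 3. Depth weighting
defaults to γ = 0.8, matching mainstream minimum-norm tooling; on the
32-sensor/68-source toy this localizes ≥ 90 % of noiseless single
sources exactly, whereas γ = 0.5 under-compensates the 1/d² depth
bias (~80–87 %). γ = 0 reduces the kernel to plain MNE exactly.
Parcellation maps vertex series to regions by a sign-aligned mean:
each member vertex is flipped to correlate positively with the
region's first principal direction (left singular vector), so
anti-phase vertices reinforce instead of cancelling. This aggregation
rule is a documented package choice — mean, centroid and PCA variants
all circulate in the field.

## Spectra

Welch with Hann taper, 4-s segments, 50 % overlap, one-sided density
(power per Hz), computed on the concatenated artifact-free recording —
a 4-s window cannot fit a single 2-s epoch, so surviving epochs are
re-concatenated first. Band power is the trapezoidal integral of the
density over the band; adjacent canonical bands share an edge
frequency, which enters both integrals as a boundary, so band powers
add exactly over a partition and nothing is double-counted. Band SNR
is within-band over out-of-band power inside 1–30 Hz. Absolute power
is the default for group tests; relative power is also computed.

## Connectivity

Phase extraction: 4th-order zero-phase Butterworth band-pass to the
band, analytic signal, argument; 1 s trimmed per side for filter and
Hilbert edge effects. PLV is the modulus of the time-averaged unit
phasor of the phase difference; PLI the modulus of the mean sign of
its sine, kept as a comparator for volume-conduction-sensitive
analyses. The default scheme computes the measure per 2-s epoch and
averages — matching the epoch structure of the analysis, at the cost
of a higher estimator floor (≈ 0.3 at 500 samples/epoch for
independent phases) — while the whole-recording scheme is retained for
validation against the closed forms, whose finite-sample floor at 60 s
is ≈ 0.03–0.05. The matrix diagonal is stored as 1 and excluded from
thresholding and statistics.

## Graph metrics

Proportional thresholding keeps the `round(s·n(n−1)/2)` strongest
off-diagonal weights (weights retained; binarized variants behind a
flag), ties broken by stable (row, col) order. Distances are 1/w;
shortest paths via Dijkstra. Global efficiency is the mean of inverse
shortest-path distances (unreachable pairs contribute 0) — the
standard efficiency form — with the literal inverse of the
characteristic path length exposed separately as
`inverse_path_length_efficiency`, since both readings of "inverse of
the average shortest path length" circulate. Clustering is Onnela's
weighted form (cube root of triangle weight products, weights rescaled
by the graph maximum); local efficiency is the global efficiency of
each node's neighbor-induced subgraph. Normalization divides L and C
by their means over 20 degree-sequence-preserving Maslov–Sneppen
surrogates (10 × edge-count swap attempts each, original weights
shuffled onto the rewired topology); surrogates that fail to stay
connected within the retry budget are skipped with a warning.

## Statistics

Permutation tests use difference of group means with label shuffling,
or mean within-pair difference with random sign flips (paired), with
the add-one convention p = (1 + #{|T*| ≥ |T|})/(1 + n_perm) — p is
never zero and the attainable minimum is 1/(n_perm+1). Graph metrics
are tested per (sparsity, metric) cell with Student t (pooled for
independent, one-sample on differences for paired) and
Benjamini–Hochberg FDR across the 40 cells within each band. The NBS
thresholds edgewise t-maps at the Student quantile for one-sided edge
p = 0.05, finds connected supra-threshold components, and compares the
component statistic against the max-component permutation null,
separately per contrast direction.

**Extent vs. intensity.** The component statistic defaults to extent
(edge count), the canonical choice. For *small planted effects at
edge p = 0.05 on 68 nodes*, extent is structurally blind: ~114
supra-threshold background edges arise under every permutation and
percolate into a giant component of ~110–140 edges, and because a
planted clique's edges are perfectly correlated under label
permutation, contaminated permutations carry the whole plant into the
null. A 10-edge planted clique therefore cannot reach component
p < 0.01 by extent (measured p ≈ 0.02–0.6). The intensity statistic
(sum of t minus threshold over the component) weights the plant's
extreme t-values and separates cleanly (p at the permutation floor in
every repetition). The planted-effect power validation accordingly
uses intensity; broad empirical effects spanning hundreds of edges —
the regime the clinical analysis reports — remain detectable by
extent.

## Validation suite and problem sizes

The validation routines (`plvnet.validation`) run at sizes chosen for
single-CPU execution: closed-form PLV recovery with 8 disjoint pairs
per κ ∈ {0, 2, 10⁶} at 60 s / 250 Hz (mean absolute error ≤ 0.05;
κ = 0 is limited by the estimator floor, not by residual coupling);
permutation type-I error over 1,000 null repetitions (199 permutations
each); NBS weak familywise error over 200 null cohorts of 12 + 12
subjects at 68 nodes with 1,000 permutations; single-source
localization over 20 placements; graph-metric agreement with networkx
references on 20 random ≤ 6-node graphs; and end-to-end planted-
subnetwork recovery over 20 repetitions of the 12-pair, 60-s demo
cohort (sensor projection, preprocessing, wMNE, beta2 connectivity,
paired intensity-NBS with 1,000 permutations). The brute-force oracles
(Floyd–Warshall, exhaustive triangle enumeration, Bessel series) live
in the test suite and share no code with the implementation.

## Known limitations

* The toy forward model has one dipole per region; the parcellation
  path for many-vertices-per-region inputs is implemented and tested
  on synthetic vertex sets but not against a realistic 15,000-vertex
  mesh.
* GroundTruth's closed-form PLV holds exactly for anchor–member pairs;
  for member–member pairs inside a planted clique the recorded value
  is the product of resultants, a consequence of modelling per-region
  (rather than per-pair) jitter.
* Per-epoch PLV averaging carries a positive finite-sample bias that
  grows as epochs shorten; group contrasts are unaffected (both
  conditions share the bias), but absolute per-epoch PLV values should
  not be compared against the closed forms.
* No source-leakage correction is applied before connectivity; with
  few sensors the inverse mixes sources, and paired contrasts can show
  leakage echoes of a genuine effect at neighboring edges.
* EDF export is not implemented (reading is, via the optional mne
  extra); cohorts travel in the matrix + JSON container.
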