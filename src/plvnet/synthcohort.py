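"""Synthetic EEG cohorts with known spectral and phase-coupling ground truth.

The generator emulates the data a resting-state deep-brain-stimulation
study analyses: two groups (control-like and PD-like) plus a paired
ON/OFF condition, narrow-band oscillations in theta/alpha/beta1/beta2,
prescribed pairwise phase coupling, and a planted subnetwork whose
coupling changes between conditions.

Phase-coupling model
--------------------
Coupled regions share a common band-limited carrier phase (band
midpoint with a slow +-0.5 Hz frequency drift).  Each non-anchor member
of a coupling cluster adds a slow, band-limited Gaussian phase jitter
theta_r(t) with variance sigma^2(kappa) = -2 ln(I1(kappa)/I0(kappa)),
i.e. a wrapped-normal process matched to the mean resultant of a von
Mises distribution with concentration kappa.  Because the jitter is
Gaussian, E[exp(i theta)] = exp(-sigma^2/2) = I1(kappa)/I0(kappa)
exactly, so the expected phase-locking value of an anchor-member pair
is available in closed form, and of a member-member pair it is the
product of the two member resultants.  The jitter is slow (<= ~1.5 Hz
bandwidth) so it survives the band-pass + Hilbert measurement chain
that later estimates PLV.

Uncoupled regions get their own oscillator: an independent carrier
drawn uniformly from the band interior plus a large-variance jitter,
which makes uncoupled pairs genuinely phase-independent (kappa = 0
means independent phases, expected PLV ~ 0).

Random-number discipline: a single master seed spawns per-subject and
per-stream ``numpy.random.SeedSequence`` children in a fixed order
(clusters, regions, pink noise, sensor noise), so the paired ON/OFF
conditions of one subject share every noise realization and differ only
through planted parameter changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import special

from .bands import CANONICAL_BANDS, BandDefinition
from .io import Recording, SourceActivity

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "LeadField",
    "CohortStudy",
    "expected_plv_from_kappa",
    "simulate_coupled_sources",
    "make_toy_lead_field",
    "project_to_sensors",
    "simulate_group_study",
    "pd_like_spec",
    "control_spec",
]

# jitter bandwidth: slow relative to the band width so the phase
# modulation stays inside the band and survives the measurement filter
_JITTER_F_LO = 0.2
_JITTER_BW_FRACTION = 0.2  # f_hi of uncoupled jitter = fraction of band width
# phase-jitter variance assigned to uncoupled oscillators (rad^2);
# carrier separation supplies most of the independence, the jitter
# covers accidentally close carriers (residual locking exp(-4) ~ 0.02)
_UNCOUPLED_SIGMA2 = 4.0
# carrier frequency drift: OU process, clipped
_DRIFT_SD_HZ = 0.15
_DRIFT_TAU_S = 5.0
_DRIFT_CLIP_HZ = 0.5


def expected_plv_from_kappa(kappa: float) -> float:
    """Closed-form expected PLV I1(kappa)/I0(kappa) of a von Mises jitter.

    Uses exponentially-scaled Bessel functions so the ratio is stable
    for arbitrarily large concentration.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def _sigma2_from_kappa(kappa: float) -> float:
    """Jitter variance reproducing the von Mises mean resultant."""
    r = expected_plv_from_kappa(kappa)
    if r >= 1.0:
        return 0.0
    if r == 0.0:
        return np.inf
    return -2.0 * np.log(r)


def _norm_pair(pair: tuple[int, int]) -> tuple[int, int]:
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError(f"coupling pair must join two distinct regions, got {pair}")
    return (i, j) if i < j else (j, i)


@dataclass
class SimulationSpec:
    """Parameters of one simulated subject/condition.

    Parameters
    ----------
    n_regions : number of cortical regions (canonical atlas: 68).
    fs : sampling rate, Hz.
    duration : recording length, seconds (>= 10).
    band_amplitudes : band name -> oscillation amplitude (arbitrary
        units; band power of a region scales with amplitude squared).
    coupling_kappa : (region pair, band name) -> von Mises concentration
        kappa >= 0.  Symmetric in the pair; kappa = 0 means independent.
    noise_sd : standard deviation of the 1/f background per region.
    planted_subnetwork : region pairs whose coupling is the planted,
        condition-dependent effect (bookkeeping; their kappas live in
        ``coupling_kappa`` like any others).
    seed : master seed; fully determines the output.
    """

    n_regions: int = 68
    fs: float = 1000.0
    duration: float = 60.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {b.name: 1.0 for b in CANONICAL_BANDS})
    coupling_kappa: dict[tuple[tuple[int, int], str], float] = field(default_factory=dict)
    noise_sd: float = 0.25
    planted_subnetwork: frozenset[tuple[int, int]] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        norm: dict[tuple[tuple[int, int], str], float] = {}
        for (pair, band), kappa in self.coupling_kappa.items():
            if kappa < 0:
                raise ValueError(f"kappa must be >= 0, got {kappa} for {pair}/{band}")
            p = _norm_pair(pair)
            if max(p) >= self.n_regions:
                raise ValueError(f"pair {p} outside 0..{self.n_regions - 1}")
            norm[(p, band)] = float(kappa)
        self.coupling_kappa = norm
        self.planted_subnetwork = frozenset(_norm_pair(p) for p in self.planted_subnetwork)


@dataclass
class GroundTruth:
    """What the generator actually planted, in measurement units."""

    #: (pair, band name) -> closed-form expected PLV in [0, 1]
    expected_plv: dict[tuple[tuple[int, int], str], float]
    #: band name -> planted group band-power ratio (amplitude ratio squared)
    expected_band_power_ratio: dict[str, float]
    #: planted (condition-dependent) region pairs
    planted_edges: frozenset[tuple[int, int]]

    def to_json_dict(self) -> dict:
        return {
            "expected_plv": [
                {"pair": list(pair), "band": band, "plv": plv}
                for (pair, band), plv in sorted(self.expected_plv.items())
            ],
            "expected_band_power_ratio": self.expected_band_power_ratio,
            "planted_edges": sorted(list(p) for p in self.planted_edges),
        }


@dataclass
class LeadField:
    """Forward gain matrix from source dipoles to sensors."""

    gain: np.ndarray  # (n_sensors, n_sources)
    sensor_labels: list[str]
    sensor_positions: np.ndarray  # (n_sensors, 3)
    source_positions: np.ndarray  # (n_sources, 3)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (sensors x sources)")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("lead field has an all-zero column (invisible source)")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class CohortStudy:
    """A simulated study: recordings per subject/condition plus truth."""

    #: condition name ("HC", "PD_OFF", "PD_ON") -> list of Recording
    recordings: dict[str, list[Recording]]
    #: condition name -> list of SourceActivity (pre-projection truth)
    sources: dict[str, list[SourceActivity]]
    ground_truth: GroundTruth
    lead_field: LeadField


# ---------------------------------------------------------------------------
# elementary processes
# ---------------------------------------------------------------------------

def _ou_drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slow Ornstein-Uhlenbeck frequency drift, clipped to +-0.5 Hz."""
    dt = 1.0 / fs
    a = np.exp(-dt / _DRIFT_TAU_S)
    innov_sd = _DRIFT_SD_HZ * np.sqrt(1.0 - a * a)
    x = rng.normal(0.0, innov_sd, size=n)
    drift = sps.lfilter([1.0], [1.0, -a], x)
    drift[0] += rng.normal(0.0, _DRIFT_SD_HZ)
    return np.clip(drift, -_DRIFT_CLIP_HZ, _DRIFT_CLIP_HZ)


def _slow_gaussian(rng: np.random.Generator, n: int, fs: float,
                   f_hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian process in [0.2, f_hi] Hz.

    Synthesized in the frequency domain (i.i.d. Gaussian Fourier
    coefficients on the in-band bins, zero elsewhere), so the path is
    exactly Gaussian and exactly band-limited; IIR filtering at such
    low normalized frequencies would be numerically fragile.
    """
    f_hi = max(f_hi, _JITTER_F_LO * 1.5)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= _JITTER_F_LO) & (freqs <= f_hi)
    if not mask.any():  # pathological short series
        return np.zeros(n)
    coeff = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    coeff[mask] = rng.normal(size=k) + 1j * rng.normal(size=k)
    x = np.fft.irfft(coeff, n=n)
    sd = x.std()
    if sd < 1e-12:
        return np.zeros(n)
    return x / sd


def _jitter_phase(rng: np.random.Generator, sigma2: float, n: int, fs: float,
                  band_width: float, coupled: bool = True) -> np.ndarray:
    """Slow Gaussian phase jitter with variance sigma2.

    Coupled members use a 0.3-1.5 Hz jitter (their sigma is modest, so
    the modulation sidebands stay inside the band and the 60-s record
    holds many effectively independent phasor draws).  Uncoupled
    oscillators carry a large sigma, so their jitter is slowed to a
    fraction of the band width to keep the spectral smear in-band.
    """
    if sigma2 == 0.0:
        return np.zeros(n)
    if not np.isfinite(sigma2):
        sigma2 = _UNCOUPLED_SIGMA2
    if coupled:
        f_hi = min(1.5, 0.3 * band_width)
    else:
        f_hi = _JITTER_BW_FRACTION * band_width
    return np.sqrt(sigma2) * _slow_gaussian(rng, n, fs, f_hi)


def _carrier_phase(rng: np.random.Generator, f0: float, n: int, fs: float) -> np.ndarray:
    drift = _ou_drift(rng, n, fs)
    inst_f = f0 + drift
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(inst_f) / fs


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """1/f-power background, flattened below 1 Hz, scaled to given SD."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    amp[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * amp, n=n)
    return sd * shaped / shaped.std()


# ---------------------------------------------------------------------------
# main operations
# ---------------------------------------------------------------------------

def _coupling_clusters(spec: SimulationSpec, band: str) -> list[dict]:
    """Connected clusters of coupled (kappa > 0) pairs for one band.

    Each cluster dict holds: ``members`` (sorted region list, first is
    the un-jittered anchor), ``kappa`` per non-anchor member (its edge
    kappa to the anchor if present, else the max of its edges), and the
    original ``edges``.
    """
    edges = {pair: k for (pair, b), k in spec.coupling_kappa.items()
             if b == band and k > 0}
    if not edges:
        return []
    # union-find over regions appearing in coupled edges
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for x in parent:
        groups.setdefault(find(x), []).append(x)
    clusters = []
    for members in groups.values():
        members = sorted(members)
        anchor = members[0]
        kappa_of: dict[int, float] = {}
        for m in members[1:]:
            direct = edges.get((anchor, m) if anchor < m else (m, anchor))
            if direct is not None:
                kappa_of[m] = direct
            else:
                kappa_of[m] = max(k for (i, j), k in edges.items() if m in (i, j))
        cluster_edges = {p: k for p, k in edges.items()
                         if p[0] in members and p[1] in members}
        clusters.append({"members": members, "anchor": anchor,
                         "kappa": kappa_of, "edges": cluster_edges})
    return clusters


def _ground_truth_plv(spec: SimulationSpec) -> dict[tuple[tuple[int, int], str], float]:
    out: dict[tuple[tuple[int, int], str], float] = {}
    for band in {b for (_, b) in spec.coupling_kappa}:
        for cluster in _coupling_clusters(spec, band):
            anchor = cluster["anchor"]
            resultant = {m: expected_plv_from_kappa(k)
                         for m, k in cluster["kappa"].items()}
            resultant[anchor] = 1.0
            for (i, j) in cluster["edges"]:
                out[((i, j), band)] = resultant[i] * resultant[j]
    for (pair, band), k in spec.coupling_kappa.items():
        if k == 0.0:
            out[(pair, band)] = 0.0
    return out


def simulate_coupled_sources(spec: SimulationSpec) -> tuple[SourceActivity, GroundTruth]:
    """Simulate region time courses with planted spectra and phase coupling.

    Each region's series is a sum over bands of an amplitude-scaled
    cosine of a drifting carrier phase plus slow phase jitter, plus a
    1/f background.  Coupled pairs share the carrier; the ground truth
    records the closed-form expected PLV of every coupled pair.
    """
    if spec.duration < 10:
        raise ValueError("duration must be >= 10 s for stable band estimates")
    n = int(round(spec.duration * spec.fs))
    ss = np.random.SeedSequence(spec.seed)
    # fixed stream order: one child per band for clusters, one per
    # (band, region) for independent oscillators/jitters, one for noise
    band_names = [b.name for b in CANONICAL_BANDS if b.name in spec.band_amplitudes]
    extra = [name for name in spec.band_amplitudes if name not in band_names]
    band_names += sorted(extra)
    n_streams = len(band_names) * (1 + spec.n_regions) + 1
    children = ss.spawn(n_streams)
    data = np.zeros((spec.n_regions, n))

    bands_by_name = {b.name: b for b in CANONICAL_BANDS}
    stream = 0
    for band_name in band_names:
        amp = spec.band_amplitudes[band_name]
        band = bands_by_name.get(band_name)
        if band is None:
            raise ValueError(f"unknown band {band_name!r} in band_amplitudes")
        cluster_rng = np.random.Generator(np.random.PCG64(children[stream]))
        stream += 1
        region_rngs = [np.random.Generator(np.random.PCG64(children[stream + r]))
                       for r in range(spec.n_regions)]
        stream += spec.n_regions

        clusters = _coupling_clusters(spec, band_name)
        in_cluster: set[int] = set()
        for cluster in clusters:
            psi = _carrier_phase(cluster_rng, band.midpoint, n, spec.fs)
            for m in cluster["members"]:
                in_cluster.add(m)
                if m == cluster["anchor"]:
                    theta = np.zeros(n)
                else:
                    sigma2 = _sigma2_from_kappa(cluster["kappa"][m])
                    theta = _jitter_phase(region_rngs[m], sigma2, n, spec.fs,
                                          band.width, coupled=True)
                data[m] += amp * np.cos(psi + theta)
        if amp == 0.0:
            continue
        lo = band.f_lo + 0.25 * band.width
        hi = band.f_hi - 0.25 * band.width
        for r in range(spec.n_regions):
            if r in in_cluster:
                continue
            rng = region_rngs[r]
            f0 = rng.uniform(lo, hi)
            psi = _carrier_phase(rng, f0, n, spec.fs)
            theta = _jitter_phase(rng, _UNCOUPLED_SIGMA2, n, spec.fs,
                                  band.width, coupled=False)
            data[r] += amp * np.cos(psi + theta)

    noise_rng = np.random.Generator(np.random.PCG64(children[stream]))
    for r in range(spec.n_regions):
        data[r] += _pink_noise(noise_rng, n, spec.fs, spec.noise_sd)

    truth = GroundTruth(
        expected_plv=_ground_truth_plv(spec),
        expected_band_power_ratio={},
        planted_edges=spec.planted_subnetwork,
    )
    labels = [f"region{r:02d}" for r in range(spec.n_regions)]
    return SourceActivity(data=data, fs=spec.fs, region_labels=labels), truth


def make_toy_lead_field(n_sensors: int, n_sources: int, seed: int = 0) -> LeadField:
    """Spherical toy forward model with distance-decaying sensitivity.

    Sensors sit on the upper unit hemisphere, sources on a concentric
    shell of radius 0.8 (one dipole per region in the toy geometry).
    The gain is 1/d^2 in sensor-source distance, which is generically
    full column rank when ``n_sensors >= n_sources``.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if n_sources < 2:
        raise ValueError("need at least 2 sources")
    rng = np.random.default_rng(seed)

    def fibonacci_cap(count: int, radius: float, z_lo: float) -> np.ndarray:
        k = np.arange(count)
        golden = (1.0 + np.sqrt(5.0)) / 2.0
        z = z_lo + (1.0 - z_lo) * (k + 0.5) / count  # spherical cap z in (z_lo, 1)
        phi = 2.0 * np.pi * k / golden
        s = np.sqrt(1.0 - z ** 2)
        pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        return radius * pts

    sensors = fibonacci_cap(n_sensors, 1.0, 0.0)
    # sources sit under the sensor cap (no equatorial dipoles outside
    # coverage, mimicking cortex under an electrode array)
    sources = fibonacci_cap(n_sources, 0.8, 0.15)
    sources = sources + rng.normal(0.0, 0.01, size=sources.shape)

    diff = sensors[:, None, :] - sources[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-6):
        raise ValueError("degenerate geometry: coincident sensor and source")
    gain = 1.0 / dist ** 2
    # single global scale: unit-amplitude sources yield EEG-like sensor
    # RMS (~10 microvolts), keeping peak-to-peak below artifact limits
    gain *= 5.0 / np.linalg.norm(gain, axis=1).mean()
    labels = [f"S{i:03d}" for i in range(n_sensors)]
    return LeadField(gain=gain, sensor_labels=labels,
                     sensor_positions=sensors, source_positions=sources)


def project_to_sensors(src: SourceActivity, lf: LeadField,
                       sensor_noise_sd: float = 0.0,
                       seed: int | None = None,
                       meta: dict | None = None) -> Recording:
    """Forward-project source activity: sensors = gain @ sources + noise."""
    if src.n_regions != lf.n_sources:
        raise ValueError(
            f"source count mismatch: activity has {src.n_regions} regions, "
            f"lead field expects {lf.n_sources} sources")
    sensor = lf.gain @ src.data
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        sensor = sensor + rng.normal(0.0, sensor_noise_sd, size=sensor.shape)
    return Recording(
        data=sensor,
        fs=src.fs,
        channel_labels=list(lf.sensor_labels),
        sensor_positions=np.asarray(lf.sensor_positions),
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# group-study presets and driver
# ---------------------------------------------------------------------------

#: default planted beta2 subnetwork: a 5-region clique (10 edges)
DEFAULT_PLANTED_REGIONS = (10, 11, 12, 13, 14)
DEFAULT_KAPPA_OFF = 6.0   # strong beta2 coupling in the untreated state
DEFAULT_KAPPA_ON = 1.0    # stimulation weakens the planted coupling


def _clique_edges(regions: tuple[int, ...]) -> frozenset[tuple[int, int]]:
    return frozenset((a, b) for idx, a in enumerate(regions)
                     for b in regions[idx + 1:])


def control_spec(n_regions: int = 68, fs: float = 1000.0, duration: float = 60.0,
                 seed: int = 0) -> SimulationSpec:
    """Control-like subject: flat unit band amplitudes, no planted coupling."""
    return SimulationSpec(n_regions=n_regions, fs=fs, duration=duration, seed=seed)


def pd_like_spec(condition: str = "OFF", n_regions: int = 68, fs: float = 1000.0,
                 duration: float = 60.0, seed: int = 0,
                 theta_ratio: float = 1.5, beta_ratio: float = 0.75,
                 planted_regions: tuple[int, ...] = DEFAULT_PLANTED_REGIONS,
                 kappa_off: float = DEFAULT_KAPPA_OFF,
                 kappa_on: float = DEFAULT_KAPPA_ON) -> SimulationSpec:
    """PD-like subject: theta power up, beta down, planted beta2 subnetwork.

    ``condition`` selects the planted subnetwork's coupling strength
    (OFF: strong kappa, ON: weakened kappa); everything else is shared,
    so paired OFF/ON specs with equal seeds differ only in the plant.
    """
    if condition not in ("OFF", "ON"):
        raise ValueError("condition must be 'OFF' or 'ON'")
    amps = {"theta": theta_ratio, "alpha": 1.0,
            "beta1": beta_ratio, "beta2": beta_ratio}
    edges = _clique_edges(planted_regions)
    kappa = kappa_off if condition == "OFF" else kappa_on
    coupling = {(pair, "beta2"): kappa for pair in edges}
    return SimulationSpec(
        n_regions=n_regions, fs=fs, duration=duration,
        band_amplitudes=amps, coupling_kappa=coupling,
        planted_subnetwork=edges, seed=seed)


def simulate_group_study(spec_hc: SimulationSpec, spec_pd_off: SimulationSpec,
                         spec_pd_on: SimulationSpec, n_per_group: int,
                         lead_field: LeadField | None = None,
                         sensor_noise_sd: float = 0.0,
                         sources_only: bool = False,
                         include_hc: bool = True) -> CohortStudy:
    """Simulate a two-group study with a paired ON/OFF condition.

    Subject-level seeds are spawned from each spec's master seed; the
    PD-OFF and PD-ON conditions of one subject reuse the *same* subject
    seed (the two specs must share their master seed), so within-subject
    differences reflect only the planted parameter changes.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group statistics impossible)")
    if spec_pd_off.seed != spec_pd_on.seed:
        raise ValueError("paired design: PD-OFF and PD-ON specs must share their seed")
    if lead_field is None and not sources_only:
        lead_field = make_toy_lead_field(
            n_sensors=max(32, spec_hc.n_regions // 2), n_sources=spec_hc.n_regions,
            seed=spec_hc.seed)

    hc_seeds = np.random.SeedSequence(spec_hc.seed).spawn(n_per_group)
    pd_seeds = np.random.SeedSequence(spec_pd_off.seed + 1).spawn(n_per_group)

    recordings: dict[str, list[Recording]] = {"HC": [], "PD_OFF": [], "PD_ON": []}
    sources: dict[str, list[SourceActivity]] = {"HC": [], "PD_OFF": [], "PD_ON": []}

    def run(spec: SimulationSpec, subj_seed: np.random.SeedSequence,
            cond: str, idx: int) -> None:
        sub = replace(spec, seed=int(subj_seed.generate_state(1)[0] % (2 ** 31)))
        src, _ = simulate_coupled_sources(sub)
        sources[cond].append(src)
        meta = {"subject": f"{cond}{idx:02d}", "group": cond.split("_")[0],
                "condition": cond, "seed": sub.seed}
        if not sources_only:
            rec = project_to_sensors(src, lead_field, sensor_noise_sd,
                                     seed=sub.seed + 7, meta=meta)
            recordings[cond].append(rec)

    if include_hc:
        for i, s in enumerate(hc_seeds):
            run(spec_hc, s, "HC", i)
    for i, s in enumerate(pd_seeds):
        run(spec_pd_off, s, "PD_OFF", i)
        run(spec_pd_on, s, "PD_ON", i)

    ratios = {}
    for band_name, a_hc in spec_hc.band_amplitudes.items():
        a_pd = spec_pd_off.band_amplitudes.get(band_name, a_hc)
        ratios[band_name] = (a_pd / a_hc) ** 2 if a_hc else np.inf
    truth = GroundTruth(
        expected_plv=_ground_truth_plv(spec_pd_off),
        expected_band_power_ratio=ratios,
        planted_edges=spec_pd_off.planted_subnetwork,
    )
    return CohortStudy(recordings=recordings, sources=sources,
                       ground_truth=truth, lead_field=lead_field)
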