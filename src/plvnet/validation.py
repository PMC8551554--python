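"""Self-validation routines: closed-form recovery, statistical calibration,
and end-to-end planted-effect power.

These run the package's own machinery against independent references —
Bessel-ratio closed forms, Monte-Carlo null distributions, and the
library-independent networkx graph algorithms — and return the measured
rates/errors.  They back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .bands import get_band
from .connectivity import connectivity_matrix, instantaneous_phase, plv
from .graphmetrics import (ThresholdedGraph, characteristic_path_length,
                           clustering_coefficient, global_efficiency,
                           local_efficiency)
from .inverse import InverseSpec, apply_inverse, compute_wmne_operator
from .io import Recording
from .netstats import StatSpec, nbs, permutation_test
from .preprocess import concatenate_epochs, preprocess_recording
from .synthcohort import (SimulationSpec, expected_plv_from_kappa,
                          make_toy_lead_field, pd_like_spec,
                          simulate_coupled_sources, simulate_group_study)

__all__ = [
    "plv_recovery",
    "permutation_type1_rate",
    "nbs_weak_fwer",
    "planted_subnetwork_recovery",
    "localization_rate",
    "graph_metric_crosscheck",
]


def plv_recovery(kappas=(0.0, 2.0, 1e6), n_pairs: int = 8, fs: float = 250.0,
                 duration: float = 60.0, band_name: str = "beta2",
                 seed: int = 0) -> dict[float, dict[str, float]]:
    """Measured vs closed-form PLV for planted coupling strengths.

    Simulates ``n_pairs`` disjoint coupled pairs per concentration and
    compares the mean measured whole-recording PLV with I1(k)/I0(k).
    """
    band = get_band(band_name)
    out = {}
    for k_idx, kappa in enumerate(kappas):
        pairs = [(2 * i, 2 * i + 1) for i in range(n_pairs)]
        spec = SimulationSpec(
            n_regions=2 * n_pairs, fs=fs, duration=duration,
            coupling_kappa={(p, band_name): kappa for p in pairs},
            seed=seed + 101 * k_idx)
        src, _ = simulate_coupled_sources(spec)
        phases = instantaneous_phase(src.data, band, src.fs)
        measured = float(np.mean([plv(phases[i], phases[j]) for i, j in pairs]))
        expected = expected_plv_from_kappa(kappa)
        out[kappa] = {"expected": expected, "measured": measured,
                      "abs_error": abs(measured - expected)}
    return out


def permutation_type1_rate(n_reps: int = 1000, n: int = 10, n_perm: int = 199,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of null-data permutation tests rejecting at ``alpha``."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        p = permutation_test(a, b, paired=False, n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
        rejections += p < alpha
    return rejections / n_reps


def nbs_weak_fwer(n_reps: int = 200, n_per_group: int = 12, n_nodes: int = 68,
                  n_perm: int = 1000, component_alpha: float = 0.01,
                  seed: int = 0) -> float:
    """Fraction of null simulations where NBS reports any significant
    component (weak familywise error control under the global null)."""
    rng = np.random.default_rng(seed)
    false_positives = 0
    for rep in range(n_reps):
        stacks = []
        for _ in range(2):
            m = 0.3 + rng.normal(0, 0.05, size=(n_per_group, n_nodes, n_nodes))
            m = (m + m.transpose(0, 2, 1)) / 2
            stacks.append(m)
        spec = StatSpec(n_perm_nbs=n_perm, component_alpha=component_alpha,
                        seed=int(rng.integers(2 ** 31)))
        inc, dec = nbs(stacks[0], stacks[1], spec)
        false_positives += bool(inc.significant or dec.significant)
    return false_positives / n_reps


def planted_subnetwork_recovery(n_reps: int = 20, n_pairs: int = 12,
                                fs: float = 250.0, duration: float = 60.0,
                                n_perm: int = 1000, seed: int = 0) -> dict:
    """End-to-end power: simulate the paired demo cohort, run the full
    sensor -> source -> connectivity chain, and check that paired NBS
    (intensity statistic) recovers the planted beta2 subnetwork.

    A repetition counts as a hit when the significant component
    contains >= 90% of the planted edges with component p < 0.01.
    """
    hits = 0
    edge_fractions = []
    for rep in range(n_reps):
        rep_seed = seed + 1000 * rep
        off = pd_like_spec("OFF", fs=fs, duration=duration, seed=rep_seed)
        on = pd_like_spec("ON", fs=fs, duration=duration, seed=rep_seed)
        lf = make_toy_lead_field(64, 68, seed=rep_seed)
        study = simulate_group_study(off, off, on, n_per_group=n_pairs,
                                     lead_field=lf, sensor_noise_sd=0.05,
                                     include_hc=False)
        planted = set(study.ground_truth.planted_edges)
        stacks = {}
        for cond in ("PD_OFF", "PD_ON"):
            mats = []
            for rec in study.recordings[cond]:
                ep = preprocess_recording(rec)
                clean = concatenate_epochs(ep)
                op = compute_wmne_operator(lf, InverseSpec())
                from .io import SourceActivity
                src = SourceActivity(data=apply_inverse(op, clean), fs=clean.fs,
                                     region_labels=[f"region{i:02d}"
                                                    for i in range(68)])
                mats.append(connectivity_matrix(src, get_band("beta2")).values)
            stacks[cond] = np.stack(mats)
        spec = StatSpec(paired=True, n_perm_nbs=n_perm,
                        component_statistic="intensity", seed=rep_seed)
        inc, _ = nbs(stacks["PD_OFF"], stacks["PD_ON"], spec)
        found = inc.significant_edges()
        frac = len(found & planted) / len(planted)
        edge_fractions.append(frac)
        hits += frac >= 0.9 and bool(inc.p_values) and inc.p_values[0] < 0.01
    return {"recovery_rate": hits / n_reps,
            "mean_planted_edge_fraction": float(np.mean(edge_fractions)),
            "n_reps": n_reps}


def localization_rate(n_trials: int = 20, lambda2: float = 1.0 / 9.0,
                      seed: int = 0) -> float:
    """Fraction of noiseless single-source toy simulations localized
    exactly (argmax of estimated source power at the true index)."""
    lf = make_toy_lead_field(32, 68, seed=seed)
    op = compute_wmne_operator(lf, InverseSpec(lambda2=lambda2))
    rng = np.random.default_rng(seed)
    t = np.arange(500) / 250.0
    wave = np.sin(2 * np.pi * 9 * t)
    hits = 0
    for true_idx in rng.choice(68, size=n_trials, replace=False):
        rec = Recording(data=np.outer(lf.gain[:, true_idx], wave), fs=250.0,
                        channel_labels=lf.sensor_labels)
        est = apply_inverse(op, rec)
        hits += int(np.argmax((est ** 2).mean(axis=1))) == true_idx
    return hits / n_trials


def graph_metric_crosscheck(n_graphs: int = 20, max_nodes: int = 6,
                            seed: int = 0, atol: float = 1e-10) -> float:
    """Agreement rate of all four graph metrics with networkx references
    on small random weighted graphs (1.0 = every metric on every graph
    matches)."""
    rng = np.random.default_rng(seed)
    checked = 0
    agreed = 0
    while checked < n_graphs:
        n = int(rng.integers(4, max_nodes + 1))
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.7:
                    w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
        gx = nx.from_numpy_array(w)
        for u, v, d in gx.edges(data=True):
            d["dist"] = 1.0 / d["weight"]
        g = ThresholdedGraph(weights=w, sparsity=1.0,
                             connected=nx.is_connected(gx))
        ok = True
        # clustering: networkx implements the same weighted (Onnela) form
        ours_c, _ = clustering_coefficient(g)
        ref_c = nx.clustering(gx, weight="weight")
        ok &= np.allclose(ours_c, [ref_c[i] for i in range(n)], atol=atol)
        # efficiency and path length from networkx shortest paths
        sp = dict(nx.all_pairs_dijkstra_path_length(gx, weight="dist"))
        inv = [1.0 / sp[i][j] for i in range(n) for j in range(n)
               if i != j and j in sp[i] and sp[i][j] > 0]
        ref_eglob = sum(inv) / (n * (n - 1))
        ok &= abs(global_efficiency(g) - ref_eglob) < atol
        if g.connected:
            ref_l = np.mean([sp[i][j] for i in range(n) for j in range(n) if i != j])
            ok &= abs(characteristic_path_length(g) - ref_l) < atol
        # local efficiency via neighbor-subgraph reference
        ours_e, _ = local_efficiency(g)
        for i in range(n):
            nbrs = [j for j in range(n) if w[i, j] > 0]
            if len(nbrs) < 2:
                ok &= ours_e[i] == 0.0
                continue
            sub = w[np.ix_(nbrs, nbrs)]
            sg = ThresholdedGraph(weights=sub, sparsity=1.0, connected=True)
            ok &= abs(ours_e[i] - global_efficiency(sg)) < atol
        agreed += bool(ok)
        checked += 1
    return agreed / n_graphs
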