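"""End-to-end pipeline orchestration from a structured config.

Stages: (optional) simulate -> preprocess -> inverse -> spectral ->
connectivity -> graph metrics -> group statistics.  Every stage writes
its outputs (TSV/JSON) under the output directory, and a manifest
records package versions, the master seed and a hash of the resolved
config, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import CANONICAL_BANDS, get_band
from .connectivity import connectivity_matrix
from .graphmetrics import ThresholdSpec, metrics_sweep, minimum_connected_sparsity
from .inverse import InverseSpec, source_activity_from_recording
from .io import (Recording, SourceActivity, load_recording,
                 save_connectivity_tsv, save_recording)
from .netstats import (StatSpec, edge_count_summary, graph_metric_group_tests,
                       nbs, permutation_test)
from .preprocess import concatenate_epochs, preprocess_recording
from .spectral import band_power, band_snr, save_psd_tsv, welch_psd
from .synthcohort import (control_spec, make_toy_lead_field, pd_like_spec,
                          simulate_group_study)

logger = logging.getLogger("plvnet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str = "plvnet_output"
    cohort_dir: str | None = None      # None -> simulate a demo cohort
    # demo-cohort geometry/size (used only when simulating)
    n_per_group: int = 12
    duration: float = 60.0
    fs: float = 250.0
    n_regions: int = 68
    n_sensors: int = 64
    sensor_noise_sd: float = 0.05
    # analysis parameters
    bands: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    f_lo: float = 1.0
    f_hi: float = 30.0
    epoch_s: float = 2.0
    p2p_limit: float = 150.0
    lambda2: float = 1.0 / 9.0
    depth_gamma: float = 0.8
    measure: str = "PLV"
    epoch_scheme: str = "per-epoch"
    sparsity_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
    n_perm_psd: int = 1000
    n_perm_nbs: int = 1000
    edge_alpha: float = 0.05
    component_alpha: float = 0.01
    fdr_q: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bands", "sparsity_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Paths and headline results of a completed run."""

    output_dir: Path
    manifest: dict
    results: dict = field(default_factory=dict)


def _simulate_stage(cfg: PipelineConfig, cohort_dir: Path) -> None:
    logger.info("stage simulate: %d+%d subjects, %.0f s at %.0f Hz",
                cfg.n_per_group, cfg.n_per_group, cfg.duration, cfg.fs)
    hc = control_spec(n_regions=cfg.n_regions, fs=cfg.fs,
                      duration=cfg.duration, seed=cfg.seed)
    off = pd_like_spec("OFF", n_regions=cfg.n_regions, fs=cfg.fs,
                       duration=cfg.duration, seed=cfg.seed)
    on = pd_like_spec("ON", n_regions=cfg.n_regions, fs=cfg.fs,
                      duration=cfg.duration, seed=cfg.seed)
    lf = make_toy_lead_field(cfg.n_sensors, cfg.n_regions, seed=cfg.seed)
    study = simulate_group_study(hc, off, on, cfg.n_per_group, lead_field=lf,
                                 sensor_noise_sd=cfg.sensor_noise_sd)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    np.save(cohort_dir / "leadfield_gain.npy", lf.gain)
    (cohort_dir / "leadfield.json").write_text(json.dumps({
        "sensor_labels": lf.sensor_labels,
        "sensor_positions": lf.sensor_positions.tolist(),
        "source_positions": lf.source_positions.tolist()}))
    (cohort_dir / "ground_truth.json").write_text(
        json.dumps(study.ground_truth.to_json_dict(), indent=1))
    for cond, recs in study.recordings.items():
        for rec in recs:
            save_recording(rec, cohort_dir / rec.meta["subject"])


def _load_cohort(cohort_dir: Path) -> dict[str, list[Recording]]:
    recs: dict[str, list[Recording]] = {}
    for npy in sorted(cohort_dir.glob("*.npy")):
        if npy.stem.startswith("leadfield"):
            continue
        rec = load_recording(npy)
        cond = rec.meta.get("condition", "unknown")
        recs.setdefault(cond, []).append(rec)
    if not recs:
        raise FileNotFoundError(f"no recordings found under {cohort_dir}")
    return recs


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline; see module docstring for the stages."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        cohort_dir = Path(cfg.cohort_dir) if cfg.cohort_dir else out / "cohort"
        if cfg.cohort_dir is None:
            stage = "simulate"
            _simulate_stage(cfg, cohort_dir)
        stage = "load"
        cohort = _load_cohort(cohort_dir)
        from .synthcohort import LeadField
        lf_json = json.loads((cohort_dir / "leadfield.json").read_text())
        lead_field = LeadField(
            gain=np.load(cohort_dir / "leadfield_gain.npy"),
            sensor_labels=lf_json["sensor_labels"],
            sensor_positions=np.asarray(lf_json["sensor_positions"]),
            source_positions=np.asarray(lf_json["source_positions"]))

        stage = "preprocess/inverse"
        sources: dict[str, list[SourceActivity]] = {}
        for cond, recs in cohort.items():
            for rec in recs:
                ep = preprocess_recording(rec, cfg.f_lo, cfg.f_hi,
                                          cfg.epoch_s, cfg.p2p_limit)
                clean = concatenate_epochs(ep)
                src = source_activity_from_recording(
                    clean, lead_field,
                    InverseSpec(lambda2=cfg.lambda2, depth_gamma=cfg.depth_gamma))
                sources.setdefault(cond, []).append(src)
            logger.info("preprocess+inverse done for %s (%d subjects)",
                        cond, len(recs))

        stage = "spectral"
        psd_rows = []
        band_power_by_cond: dict[str, dict[str, list[float]]] = {}
        for cond, srcs in sources.items():
            for s_idx, src in enumerate(srcs):
                psd = welch_psd(src.data, src.fs)
                save_psd_tsv(psd, out / "psd" / f"{cond}{s_idx:02d}.tsv",
                             row_labels=src.region_labels)
                for band_name in cfg.bands:
                    band = get_band(band_name)
                    bp = float(band_power(psd, band).mean())
                    snr = float(band_snr(psd, band).mean())
                    psd_rows.append({"condition": cond, "subject": s_idx,
                                     "band": band_name, "band_power": bp,
                                     "band_snr": snr})
                    band_power_by_cond.setdefault(cond, {}).setdefault(
                        band_name, []).append(bp)
        pd.DataFrame(psd_rows).to_csv(out / "band_power.tsv", sep="\t", index=False)

        stage = "connectivity"
        conn: dict[tuple[str, str], list[np.ndarray]] = {}
        conn_dir = out / "connectivity"
        for cond, srcs in sources.items():
            for s_idx, src in enumerate(srcs):
                for band_name in cfg.bands:
                    cm = connectivity_matrix(src, get_band(band_name),
                                             measure=cfg.measure,
                                             epoch_scheme=cfg.epoch_scheme,
                                             epoch_s=cfg.epoch_s,
                                             subject_id=f"{cond}{s_idx:02d}")
                    conn.setdefault((cond, band_name), []).append(cm.values)
                    save_connectivity_tsv(
                        cm, conn_dir / f"{cond}{s_idx:02d}_{band_name}.tsv",
                        region_labels=src.region_labels)
            logger.info("connectivity done for %s", cond)

        stage = "graphmetrics"
        metric_frames = []
        for (cond, band_name), mats in conn.items():
            for s_idx, m in enumerate(mats):
                df = metrics_sweep(m, subject_id=f"{cond}{s_idx:02d}",
                                   band=band_name,
                                   spec=ThresholdSpec(sparsity_grid=cfg.sparsity_grid))
                df.insert(0, "condition", cond)
                metric_frames.append(df)
        metrics = pd.concat(metric_frames, ignore_index=True)
        metrics.to_csv(out / "graph_metrics.tsv", sep="\t", index=False)

        stage = "netstats"
        results: dict = {"band_power_tests": {}, "nbs": {}}
        rng = np.random.default_rng(cfg.seed + 1)
        for band_name in cfg.bands:
            bp = band_power_by_cond
            if {"HC", "PD_OFF"} <= set(bp):
                p_ind = permutation_test(
                    np.array(bp["PD_OFF"][band_name]),
                    np.array(bp["HC"][band_name]),
                    paired=False, n_perm=cfg.n_perm_psd,
                    seed=int(rng.integers(2 ** 31)))
            else:
                p_ind = None
            if {"PD_OFF", "PD_ON"} <= set(bp):
                p_pair = permutation_test(
                    np.array(bp["PD_OFF"][band_name]),
                    np.array(bp["PD_ON"][band_name]),
                    paired=True, n_perm=cfg.n_perm_psd,
                    seed=int(rng.integers(2 ** 31)))
            else:
                p_pair = None
            results["band_power_tests"][band_name] = {
                "PD_OFF_vs_HC_p": p_ind, "PD_OFF_vs_PD_ON_paired_p": p_pair}

        conds = set(c for c, _ in conn)
        if {"PD_OFF", "PD_ON"} <= conds:
            spec_paired = StatSpec(n_perm_nbs=cfg.n_perm_nbs,
                                   edge_alpha=cfg.edge_alpha,
                                   component_alpha=cfg.component_alpha,
                                   paired=True, seed=cfg.seed + 2)
            nbs_by_band = {}
            for band_name in cfg.bands:
                inc, dec = nbs(np.stack(conn[("PD_OFF", band_name)]),
                               np.stack(conn[("PD_ON", band_name)]),
                               spec_paired)
                nbs_by_band[band_name] = (inc, dec)
                results["nbs"][band_name] = {
                    "increase_significant_edges": len(inc.significant_edges()),
                    "decrease_significant_edges": len(dec.significant_edges()),
                    "increase_p": inc.p_values[:3],
                    "decrease_p": dec.p_values[:3]}
            if len(nbs_by_band) >= 2:
                results["edge_count_summary"] = edge_count_summary(nbs_by_band)
            edge_rows = []
            region_labels = next(iter(sources.values()))[0].region_labels
            for band_name, pair in nbs_by_band.items():
                for res in pair:
                    for (i, j) in sorted(res.significant_edges()):
                        edge_rows.append({"region_a": region_labels[i],
                                          "region_b": region_labels[j],
                                          "direction": res.direction,
                                          "band": band_name})
            pd.DataFrame(edge_rows, columns=["region_a", "region_b",
                                             "direction", "band"]).to_csv(
                out / "nbs_edges.tsv", sep="\t", index=False)
        if {"HC", "PD_OFF"} <= conds:
            hc_metrics = metrics[metrics.condition == "HC"]
            off_metrics = metrics[metrics.condition == "PD_OFF"]
            gtests = graph_metric_group_tests(off_metrics, hc_metrics,
                                              paired=False, q=cfg.fdr_q)
            gtests.to_csv(out / "graph_metric_tests.tsv", sep="\t", index=False)
            results["graph_metric_tests_file"] = "graph_metric_tests.tsv"
        results["minimum_connected_sparsity"] = {
            f"{cond}/{band}": float(np.median([
                minimum_connected_sparsity(m, grid=cfg.sparsity_grid)
                for m in mats]))
            for (cond, band), mats in conn.items()}

        (out / "stats.json").write_text(json.dumps(results, indent=1, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "plvnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete; outputs under %s", out)
    return PipelineReport(output_dir=out, manifest=manifest, results=results)
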