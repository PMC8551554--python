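"""Core data containers and on-disk formats.

Recordings travel as a numeric matrix (channels x samples, ``.npy``)
plus a JSON sidecar carrying sampling rate, channel labels, sensor
positions and provenance (group, condition, seed).  Connectivity
matrices and metric tables are written as TSV so results stay
human-readable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


def dk68_labels() -> list[str]:
    """The canonical 68 Desikan-Killiany cortical region labels (lh then rh)."""
    text = resources.files("plvnet.data").joinpath("desikan_killiany_68.txt").read_text()
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    assert len(labels) == 68
    return labels


@dataclass
class Recording:
    """Sensor-space multichannel time series (microvolts).

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.  Must exceed twice the upper analysis band
        edge (30 Hz) for the band-limited pipeline to be valid.
    channel_labels : list of str
    bad_channels : set of str
        Channels flagged for interpolation (detection is upstream).
    sensor_positions : ndarray (n_channels, 3) or None
        Cartesian sensor coordinates; required for bad-channel
        interpolation.
    meta : dict
        Free-form provenance (subject id, group, condition, seed).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    bad_channels: set[str] = field(default_factory=set)
    sensor_positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epochs:
    """Non-overlapping, contiguous fixed-length epochs cut from a Recording."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    epoch_length: float  # seconds
    channel_labels: list[str]
    kept_mask: np.ndarray  # boolean per *original* epoch index

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class SourceActivity:
    """Region-by-time course after inverse solution and parcellation."""

    data: np.ndarray  # (n_regions, n_samples)
    fs: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SourceActivity.data must be 2-D")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region_labels length must match data rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region phase-synchronization matrix for one band.

    Entries lie in [0, 1]; the diagonal is fixed at 1 for PLV
    (self-synchrony) and is excluded from thresholding and statistics.
    """

    values: np.ndarray
    band: "object"  # BandDefinition; kept loose to avoid import cycle
    subject_id: str = ""
    measure: str = "PLV"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# matrix + JSON sidecar container
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.npy`` + ``<path>.json`` for one recording."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "bad_channels": sorted(rec.bad_channels),
        "sensor_positions": None if rec.sensor_positions is None
        else np.asarray(rec.sensor_positions).tolist(),
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def load_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pos = sidecar.get("sensor_positions")
    return Recording(
        data=data,
        fs=sidecar["fs"],
        channel_labels=list(sidecar["channel_labels"]),
        bad_channels=set(sidecar.get("bad_channels", [])),
        sensor_positions=None if pos is None else np.asarray(pos, float),
        meta=sidecar.get("meta", {}),
    )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install plvnet[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def save_connectivity_tsv(cm: ConnectivityMatrix, path: str | Path,
                          region_labels: list[str] | None = None) -> Path:
    """Write one connectivity matrix as TSV with region-label headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = region_labels or [f"r{i}" for i in range(cm.n_regions)]
    df = pd.DataFrame(cm.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.6f")
    return path


def load_connectivity_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
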