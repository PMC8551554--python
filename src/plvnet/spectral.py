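"""Power spectral density and band summaries.

Welch's method with a Hann taper, 4-s segments and 50% overlap, on the
concatenated artifact-free recording (a 4-s window cannot fit a 2-s
analysis epoch, so surviving epochs are re-concatenated upstream).
Densities are one-sided, power per Hz, so the integral over the full
grid matches the series variance.  Band power integrates the density
over the band by the trapezoidal rule; adjacent canonical bands share
an edge frequency, which contributes as an integration boundary to
both — band powers over a partition therefore add up exactly to the
total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import TOTAL_RANGE, BandDefinition

__all__ = ["PSDResult", "welch_psd", "band_power", "band_snr",
           "relative_band_power", "save_psd_tsv"]


@dataclass
class PSDResult:
    freqs: np.ndarray          # strictly increasing Hz grid
    psd: np.ndarray            # (n_series, n_freqs), power per Hz, >= 0
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        self.freqs = np.asarray(self.freqs, dtype=float)


def welch_psd(ts: np.ndarray, fs: float, window_s: float = 4.0,
              overlap: float = 0.5) -> PSDResult:
    """One-sided Welch PSD with Hann taper and overlapping segments."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    nperseg = int(round(window_s * fs))
    if ts.shape[1] < nperseg:
        raise ValueError(
            f"series ({ts.shape[1]} samples) shorter than one {window_s}-s window "
            f"({nperseg} samples)")
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(ts, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, detrend="constant",
                           scaling="density", axis=1)
    return PSDResult(freqs=freqs, psd=psd, window_s=window_s, overlap=overlap)


def band_power(psd: PSDResult, band: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of the density over [f_lo, f_hi], per series."""
    f = psd.freqs
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ValueError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) outside the "
            f"frequency grid ({f[0]}-{f[-1]} Hz)")
    mask = (f >= band.f_lo) & (f <= band.f_hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} narrower than the frequency resolution")
    return np.trapezoid(psd.psd[:, mask], f[mask], axis=1)


def band_snr(psd: PSDResult, band: BandDefinition,
             total_range: BandDefinition = TOTAL_RANGE) -> np.ndarray:
    """Within-band to out-of-band power ratio inside the analysis range."""
    if not (total_range.f_lo <= band.f_lo and band.f_hi <= total_range.f_hi):
        raise ValueError(f"band {band.name} must lie inside the total range")
    inside = band_power(psd, band)
    total = band_power(psd, total_range)
    out = total - inside
    if np.any(out <= 0):
        raise ZeroDivisionError(
            "zero out-of-band power: SNR ratio undefined (all power inside band)")
    return inside / out


def relative_band_power(psd: PSDResult, band: BandDefinition,
                        total_range: BandDefinition = TOTAL_RANGE) -> np.ndarray:
    """Band power as a fraction of total power in the analysis range."""
    return band_power(psd, band) / band_power(psd, total_range)


def save_psd_tsv(psd: PSDResult, path, row_labels=None):
    """Write the density as TSV: rows = regions/channels, columns = Hz bins."""
    import pandas as pd
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = row_labels or [f"r{i}" for i in range(psd.psd.shape[0])]
    df = pd.DataFrame(psd.psd, index=labels,
                      columns=[f"{f:g}" for f in psd.freqs])
    df.to_csv(path, sep="\t", float_format="%.6g")
    return path
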