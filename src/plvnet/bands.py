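"""Frequency-band definitions for resting-state EEG analysis.

The canonical band set spans 4-30 Hz in four bands: theta (4-8), alpha
(8-13), beta1 (13-20) and beta2 (20-30 Hz).  Band intervals are treated
as half-open ``[f_lo, f_hi)`` so shared edges are never double-counted
when summing band powers over a partition.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA1 = BandDefinition("beta1", 13.0, 20.0)
BETA2 = BandDefinition("beta2", 20.0, 30.0)

#: Canonical analysis bands, in ascending frequency order.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (THETA, ALPHA, BETA1, BETA2)

#: Overall analysis range (band-pass limits of the preprocessing stage).
TOTAL_RANGE = BandDefinition("total", 1.0, 30.0)


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name."""
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; canonical bands are "
                   f"{[b.name for b in CANONICAL_BANDS]}")
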