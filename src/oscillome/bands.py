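"""Canonical frequency-band definitions.

Six bands cover 2–90 Hz: delta (2–4), theta (5–7), alpha (8–12),
beta (13–29), low-gamma (30–59) and high-gamma (60–90 Hz).  They are
non-overlapping, so band-power integration uses each PSD bin at most
once per band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: f_lo ({self.f_lo}) must be < f_hi ({self.f_hi})"
            )

    @property
    def center(self) -> float:
        """Geometric-center frequency, the default envelope carrier."""
        return float((self.f_lo * self.f_hi) ** 0.5)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 4.0),
    BandSpec("theta", 5.0, 7.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 13.0, 29.0),
    BandSpec("low_gamma", 30.0, 59.0),
    BandSpec("high_gamma", 60.0, 90.0),
)


def get_band(name: str, bands: Sequence[BandSpec] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
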