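"""Canonical EEG frequency band definitions.

The five bands partition 1-45 Hz with half-open intervals [f_low, f_high),
so every spectral bin belongs to exactly one band. Gamma is capped at 45 Hz,
inside the analysis passband.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of the bins falling in [f_low, f_high)."""
        freqs = np.asarray(freqs, dtype=float)
        return (freqs >= self.f_low) & (freqs < self.f_high)

    def check_nyquist(self, fs: float) -> None:
        if self.f_high > fs / 2:
            raise ConfigurationError(
                f"band {self.name!r} upper edge {self.f_high} Hz exceeds "
                f"Nyquist {fs / 2} Hz"
            )


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 45.0)

CANONICAL_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)
BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def get_band(name: str) -> BandDefinition:
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise ConfigurationError(f"unknown band {name!r}; known: {BAND_NAMES}")
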