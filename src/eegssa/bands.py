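"""Named EEG frequency bands.

The bandwidth ``fb = f_high - f_low`` of the rhythm of interest is what
drives the embedding-dimension rule ``L = ceil(fs / fb)``: each reconstructed
component of an SSA decomposition has spectral width about ``fs / L``, so the
window must be at least ``fs / fb`` samples long for a single component to
fit inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RhythmBand", "DELTA", "THETA", "ALPHA", "BETA", "CANONICAL_BANDS", "parse_band"]


@dataclass(frozen=True)
class RhythmBand:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"need 0 <= f_low < f_high, got [{self.f_low}, {self.f_high}]"
            )

    @property
    def fb(self) -> float:
        """Bandwidth f_high - f_low in Hz."""
        return self.f_high - self.f_low

    def contains(self, freq: float) -> bool:
        """Whether ``freq`` lies in the closed interval [f_low, f_high]."""
        return self.f_low <= freq <= self.f_high


DELTA = RhythmBand("delta", 1.0, 4.0)
THETA = RhythmBand("theta", 4.0, 8.0)
ALPHA = RhythmBand("alpha", 8.0, 13.0)
BETA = RhythmBand("beta", 13.0, 30.0)

CANONICAL_BANDS = {b.name: b for b in (DELTA, THETA, ALPHA, BETA)}


def parse_band(spec: str) -> RhythmBand:
    """Parse a band from a name (``"alpha"``) or edge pair (``"8:13"``)."""
    key = spec.strip().lower()
    if key in CANONICAL_BANDS:
        return CANONICAL_BANDS[key]
    if ":" in key:
        lo, hi = key.split(":", 1)
        return RhythmBand("custom", float(lo), float(hi))
    raise ValueError(
        f"unknown band {spec!r}: use one of {sorted(CANONICAL_BANDS)} or 'low:high' in Hz"
    )
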