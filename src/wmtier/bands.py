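"""Frequency-band definitions and the canonical (band, electrode-pair) feature index.

The filter bank decomposes EEG into the five canonical bands

    delta 1-4 Hz, theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz, gamma 30-45 Hz.

All feature vectors in this package (relative power, coherence, PLI) are
indexed band-major, then by electrode pair (i, j) with i < j in stored
channel order.  The ordering is fixed so that feature ``k`` means the same
(band, pair) for every participant and state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

__all__ = ["BandSpec", "DEFAULT_BANDS", "TOTAL_BAND", "FeatureIndex", "n_pairs"]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: half-open interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, freqs) -> "object":
        """Boolean mask of frequencies in [lo, hi)."""
        import numpy as np

        f = np.asarray(freqs)
        return (f >= self.lo) & (f < self.hi)


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)

#: Broadband range used as denominator of relative band power.
TOTAL_BAND = BandSpec("total", 1.0, 45.0)


def n_pairs(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2


class FeatureIndex:
    """Canonical ordering of (band, ch_i, ch_j) feature identities.

    Band-major, pairs lexicographic by stored channel order, i < j.  With
    30 channels and 5 bands this yields 5 * 30*29/2 = 2175 entries.
    """

    def __init__(self, bands: Sequence[BandSpec], channels: Sequence[str]):
        if len(set(channels)) != len(channels):
            raise ValueError("channel labels must be unique")
        self.bands = tuple(bands)
        self.channels = tuple(channels)
        self.pairs = tuple(combinations(range(len(channels)), 2))
        self.entries = tuple(
            (b.name, channels[i], channels[j]) for b in self.bands for (i, j) in self.pairs
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureIndex) and self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.entries)

    def band_of(self, k: int) -> str:
        """Band name of feature ``k``."""
        return self.entries[k][0]

    def pair_of(self, k: int) -> tuple[str, str]:
        """Channel labels of feature ``k``."""
        return self.entries[k][1], self.entries[k][2]

    def to_frame(self):
        """Tidy DataFrame with columns band, ch1, ch2."""
        import pandas as pd

        return pd.DataFrame(self.entries, columns=["band", "ch1", "ch2"])
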