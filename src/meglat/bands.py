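"""Canonical frequency bands, cortical regions, and group labels.

The analysis partitions resting-state activity into seven bands from delta
to high-frequency oscillations (HFO) and summarizes source power within four
lobar regions per hemisphere. The delta band's lower edge is 0.3 Hz, the
hardware high-pass of the recording chain, since a true 0-Hz edge cannot be
realized by a bandpass filter.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo ({self.lo}) must be < hi ({self.hi})")


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.3, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("low_gamma", 26.0, 40.0),
    BandDefinition("high_gamma", 41.0, 80.0),
    BandDefinition("hfo", 81.0, 120.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

REGIONS: tuple[str, ...] = ("frontal", "temporal", "parietal", "occipital")
HEMISPHERES: tuple[str, ...] = ("L", "R")

#: Group labels, serialized exactly in this spelling in all tables.
GROUP_LT = "LtMTLE"
GROUP_RT = "RtMTLE"
GROUP_CTR = "CTR"
GROUPS: tuple[str, ...] = (GROUP_LT, GROUP_RT, GROUP_CTR)

#: Utility (power-line) frequencies supported by the notch filter.
UTILITY_FREQUENCIES: tuple[int, ...] = (50, 60)


def feature_names(
    bands: tuple[str, ...] = BAND_NAMES, regions: tuple[str, ...] = REGIONS
) -> list[str]:
    """Band-major ordering of the 28 laterality features (delta..hfo x regions)."""
    return [f"{b}_{r}" for b in bands for r in regions]
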