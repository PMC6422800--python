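"""Frequency band definitions for band-limited connectivity analysis."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz.

    Invariant: 0 < low < high.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: need 0 < low < high, "
                             f"got [{self.low}, {self.high}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


#: Canonical six analysis bands (Hz).
DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha1", 8.0, 10.0),
        BandDefinition("alpha2", 10.0, 13.0),
        BandDefinition("beta", 13.0, 25.0),
        BandDefinition("gamma", 25.0, 49.0),
    )
}

#: Broadband pre-filter applied to the continuous recording before any
#: band-specific analysis (excludes very slow drift and line noise).
BROADBAND = BandDefinition("broadband", 0.5, 50.0)


def get_band(band: "str | BandDefinition | tuple[float, float]") -> BandDefinition:
    """Coerce a band name, (low, high) pair, or BandDefinition to a BandDefinition."""
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            return DEFAULT_BANDS[band]
        except KeyError as exc:
            raise KeyError(f"unknown band {band!r}; known: {sorted(DEFAULT_BANDS)}") from exc
    low, high = band
    return BandDefinition(f"{low:g}-{high:g}Hz", float(low), float(high))
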