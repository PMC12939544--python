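"""Canonical EEG frequency-band table."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band [{self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: delta 0.5-3, theta 4-7, alpha 8-13, beta 14-30, gamma >30 (up to Nyquist at 128 Hz).
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

ALPHA = BANDS["alpha"]
BETA = BANDS["beta"]
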