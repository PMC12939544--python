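"""Core data containers: epochs, labeled cohort samples, rated trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CANONICAL_CHANNELS, EPOCH_SAMPLES, FS

#: Class labels: depression is the positive class.
DEPRESSION = 1
NEGATIVE_EMOTION = 0
LABEL_NAMES = {DEPRESSION: "depression", NEGATIVE_EMOTION: "negative_emotion"}


@dataclass
class Epoch:
    """One fixed-length multichannel EEG segment.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Channel labels, row-aligned with ``data``.
    """

    data: np.ndarray
    fs: float = FS
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def is_standard(self) -> bool:
        """True iff this epoch is in the canonical analysis format
        (8 canonical channels, 128 Hz, 960 samples)."""
        return (
            self.fs == FS
            and self.n_samples == EPOCH_SAMPLES
            and self.channel_names == CANONICAL_CHANNELS
        )


@dataclass
class CohortSample:
    """An epoch with its class label and provenance tag."""

    epoch: Epoch
    label: int
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.label not in (DEPRESSION, NEGATIVE_EMOTION):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.source:
            raise ValueError("source tag must be non-empty")


@dataclass
class RatedTrial:
    """A continuous multichannel trial with SAM valence/arousal ratings in [1, 9]."""

    signal: np.ndarray
    valence: float
    arousal: float
    fs: float = FS
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("trial signal must be 2-D (channels x samples)")
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"{name} {v!r} outside the SAM scale [1, 9]")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.signal.shape[0])
            )

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs
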