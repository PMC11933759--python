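"""Shared domain containers used across the pipeline.

Units convention: EEG samples and amplitudes in microvolts (µV), power
spectral densities in µV²/Hz, frequencies in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel labels of the 2-electrode prefrontal montage (10–20 positions).
PREFRONTAL_CHANNELS = ("FP1", "FP2")

CONDITIONS = ("open", "closed")


@dataclass
class Recording:
    """One resting-state EEG segment for a participant-month-condition.

    samples is a (n_channels, n_samples) float array in µV; channels are
    ordered to match the ``channels`` tuple.
    """

    participant_id: str
    month: int
    condition: str
    fs: float
    samples: np.ndarray
    channels: tuple[str, ...] = PREFRONTAL_CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"got {self.samples.shape[0]} sample rows for "
                f"{len(self.channels)} channels"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.month, self.condition)


@dataclass
class PSQIRecord:
    """Pittsburgh Sleep Quality Index scores for one participant-month.

    Seven component scores (0–3 each) summing to the 0–21 total; a higher
    total indicates poorer sleep.
    """

    participant_id: str
    month: int
    components: tuple[int, ...]
    total: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.components = tuple(int(c) for c in self.components)
        if len(self.components) != 7:
            raise ValueError("PSQI has 7 component scores")
        for c in self.components:
            if not 0 <= c <= 3:
                raise ValueError(f"component score {c} outside 0-3")
        if self.total is None:
            self.total = sum(self.components)
        elif self.total != sum(self.components):
            raise ValueError(
                f"total {self.total} != sum of components "
                f"{sum(self.components)} for {self.participant_id} "
                f"month {self.month}"
            )
        if not 0 <= self.total <= 21:
            raise ValueError(f"total {self.total} outside 0-21")


@dataclass(frozen=True)
class BandDefinition:
    """A closed frequency interval [f_lo, f_hi] named after its role."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")


#: Sub-alpha bands used throughout: low, medium and high alpha, plus the
#: traditional 8–13 Hz alpha band.
LOW_ALPHA = BandDefinition("LA", 7.0, 8.5)
MEDIUM_ALPHA = BandDefinition("MA", 9.0, 10.5)
HIGH_ALPHA = BandDefinition("HA", 11.0, 13.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)

DEFAULT_BANDS = (LOW_ALPHA, MEDIUM_ALPHA, HIGH_ALPHA, ALPHA)
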