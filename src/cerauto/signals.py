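"""Core in-memory containers for physiological time series.

Two shapes cover everything downstream: uniformly sampled waveforms
(:class:`UniformSignal`, e.g. a 200 Hz arterial pressure trace) and
event-indexed beat-to-beat series (:class:`BeatSeries`, e.g. RR intervals
anchored at detected beats).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class NoBeatsError(ValueError):
    """Raised when beat/breath detection finds no events."""


class InsufficientDataError(ValueError):
    """Raised when a signal or series is too short for the requested analysis."""


class InsufficientBeatsError(InsufficientDataError):
    """Raised when a beat series has too few beats for the requested analysis."""


@dataclass
class UniformSignal:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array_like
        Sample values in the channel's physical units.
    fs : float
        Sampling frequency in Hz (must be positive).
    t0 : float, optional
        Time of the first sample in seconds.
    label, units : str, optional
        Channel name (e.g. ``"abp"``) and unit string (e.g. ``"mmHg"``).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("UniformSignal values must be 1-D")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (``n / fs``)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice(self, start_s: float, end_s: float) -> "UniformSignal":
        """Return the sub-signal on ``[start_s, end_s)`` (absolute times)."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise InsufficientDataError("empty slice requested")
        return replace(self, values=self.values[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass
class BeatSeries:
    """An event-indexed beat-to-beat series (times strictly increasing)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n >= 2 else 0.0


@dataclass
class Recording:
    """A set of synchronized uniformly sampled channels.

    Channels are keyed by canonical short names: ``abp`` (mmHg), ``cbv``
    (cm/s), ``ecg`` (mV), ``etco2`` (mmHg). Only ``abp`` is mandatory for
    analysis; missing channels gate the corresponding downstream metrics.
    """

    channels: dict = field(default_factory=dict)
    fs: float = 200.0

    def __getitem__(self, key: str) -> UniformSignal:
        return self.channels[key]

    def __contains__(self, key: str) -> bool:
        return key in self.channels

    def get(self, key: str):
        return self.channels.get(key)

    @property
    def duration(self) -> float:
        return min(ch.duration for ch in self.channels.values())

    def slice(self, start_s: float, end_s: float) -> "Recording":
        return Recording(
            channels={k: v.slice(start_s, end_s) for k, v in self.channels.items()},
            fs=self.fs,
        )
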