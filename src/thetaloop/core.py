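"""Shared containers for continuous signals and stimulation pulse trains.

Amplitudes are microvolts throughout; times are seconds on a common clock
(``t0`` anchors a trace on that clock).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("peak", "trough")


@dataclass
class SignalTrace:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples : array of float
        Amplitude series in µV.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (must lie inside the trace)."""
        i = int(round((t - self.t0) * self.fs))
        if i < 0 or i >= self.samples.size:
            raise ValueError(f"time {t} s outside trace span")
        return i


@dataclass
class PulseTrain:
    """Light-pulse onsets produced by the closed-loop detector.

    ``onsets`` are pulse start times; ``trigger_times`` are the sample times
    at which the extremum was confirmed (onset = trigger + processing
    latency).  All pulses share one fixed width.
    """

    onsets: np.ndarray
    mode: str
    width_ms: float = 10.0
    trigger_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.width_ms <= 0:
            raise ValueError("pulse width must be positive")
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if self.trigger_times is not None:
            self.trigger_times = np.asarray(self.trigger_times, dtype=np.float64)
            if self.trigger_times.shape != self.onsets.shape:
                raise ValueError("trigger_times must match onsets in length")

    def __len__(self) -> int:
        return self.onsets.size

    @classmethod
    def empty(cls, mode: str = "peak", width_ms: float = 10.0) -> "PulseTrain":
        return cls(onsets=np.empty(0), mode=mode, width_ms=width_ms,
                   trigger_times=np.empty(0))
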