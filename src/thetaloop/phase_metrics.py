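"""Offline (acausal) theta phase estimation and circular pulse statistics.

Offline phase comes from a zero-phase forward-backward Butterworth bandpass
followed by the analytic-signal angle, so 0° sits on filtered theta maxima,
±180° on minima, and phase increases through the falling half-cycle.  On
top of that phase series the module characterises a closed-loop session:
the circular distribution of stimulation phases, the delay between each
true extremum and the pulse it triggered, and the within-cycle high-gamma
power landmark used as an absolute phase reference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

from .core import MODES, PulseTrain, SignalTrace

__all__ = [
    "PhaseSeries", "CircularSummary", "DelayStats", "LandmarkResult",
    "offline_phase", "circular_summary", "pulse_phases", "true_extrema_times",
    "pulse_delays", "highgamma_landmark", "wrap_degrees",
]

THETA_BAND = (4.0, 12.0)
HIGH_GAMMA_BAND = (60.0, 80.0)


def wrap_degrees(angles) -> np.ndarray:
    """Wrap angles to (−180, 180] degrees."""
    a = np.asarray(angles, dtype=np.float64)
    w = ((a + 180.0) % 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return w


@dataclass
class PhaseSeries:
    """Per-sample theta phase in degrees (−180, 180], 0° = peak."""

    phase_deg: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.phase_deg = np.asarray(self.phase_deg, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.phase_deg <= -180.0) or np.any(self.phase_deg > 180.0):
            raise ValueError("phase values must lie in (-180, 180]")

    def __len__(self) -> int:
        return self.phase_deg.size

    def at_times(self, times) -> np.ndarray:
        """Phase at the nearest sample to each time (times must be covered)."""
        t = np.asarray(times, dtype=np.float64)
        idx = np.round((t - self.t0) * self.fs).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.phase_deg.size):
            raise ValueError("requested times outside the phase series span")
        return self.phase_deg[idx]


@dataclass
class CircularSummary:
    """Circular mean/dispersion of a set of angles (degrees).

    ``sd_deg`` is the Mardia circular standard deviation
    sqrt(−2 ln R) expressed in degrees; ``resultant`` is the mean resultant
    length R in [0, 1].
    """

    mean_deg: float
    sd_deg: float
    n: int
    resultant: float


@dataclass
class DelayStats:
    """Extremum-to-pulse delays in milliseconds with a histogram."""

    mean_ms: float
    sd_ms: float
    n: int
    bin_edges_ms: np.ndarray
    counts: np.ndarray


@dataclass
class LandmarkResult:
    """High-gamma power landmark within the theta cycle.

    ``landmark_deg`` is the centre of the theta-phase bin with maximal mean
    high-gamma envelope on baseline (pulse-free) data.  ``modulated`` is
    False when the envelope shows no phasic modulation above the flatness
    threshold, in which case the landmark is not meaningful.
    ``relative_hist[mode]`` holds (bin_centers, counts, circ_mean_deg) of
    pulse phases re-expressed relative to the landmark.
    """

    landmark_deg: float
    bin_centers_deg: np.ndarray
    envelope_by_bin: np.ndarray
    modulated: bool
    relative_hist: dict


def _zero_phase_band(trace: SignalTrace, band, order: int = 2) -> np.ndarray:
    b, a = sps.butter(order, list(band), btype="bandpass", fs=trace.fs)
    return sps.filtfilt(b, a, trace.samples)


def _analytic(x: np.ndarray) -> np.ndarray:
    n = x.size
    return sps.hilbert(x, N=spfft.next_fast_len(n))[:n]


def offline_phase(trace: SignalTrace, band=THETA_BAND, order: int = 2) -> PhaseSeries:
    """Zero-phase 4–12 Hz filter + analytic-signal angle, in degrees.

    Requires at least three cycles of the slowest band frequency so the
    forward-backward filter has room to settle.
    """
    min_len = int(np.ceil(3.0 * trace.fs / band[0]))
    if len(trace) < min_len:
        raise ValueError(
            f"trace too short for offline phase: need >= {min_len} samples")
    filtered = _zero_phase_band(trace, band, order)
    phase = np.degrees(np.angle(_analytic(filtered)))
    return PhaseSeries(phase_deg=wrap_degrees(phase), fs=trace.fs, t0=trace.t0)


def circular_summary(angles_deg) -> CircularSummary:
    """Circular mean, resultant length and sqrt(−2 ln R) dispersion."""
    a = np.radians(np.asarray(angles_deg, dtype=np.float64))
    if a.size == 0:
        raise ValueError("no angles to summarise")
    z = np.exp(1j * a).mean()
    r = min(np.abs(z), 1.0)
    mean = float(wrap_degrees(np.degrees(np.angle(z))))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(r)))) if r > 0 else float("inf")
    return CircularSummary(mean_deg=mean, sd_deg=sd, n=a.size, resultant=float(r))


def pulse_phases(pulses: PulseTrain, phase: PhaseSeries) -> CircularSummary:
    """Circular summary of the offline theta phase at each pulse onset."""
    if len(pulses) == 0:
        raise ValueError("empty pulse train")
    return circular_summary(phase.at_times(pulses.onsets))


def true_extrema_times(phase: PhaseSeries, mode: str) -> np.ndarray:
    """Times of true theta extrema from the offline phase series.

    A peak is the sample where phase crosses 0° from below (within a
    continuous sweep, not a wrap); a trough is the ±180° wrap.  Ties (an
    exact 0° or 180° sample) resolve to the earlier sample.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ph = phase.phase_deg
    d = np.diff(ph)
    if mode == "peak":
        # sign change − → + without wrapping
        cross = np.where((ph[:-1] < 0) & (ph[1:] >= 0) & (d > 0) & (d < 180.0))[0] + 1
        tie = ph[cross - 1] == 0.0
        cross = cross - tie.astype(int)
    else:
        cross = np.where(d < -180.0)[0] + 1
        tie = ph[cross - 1] == 180.0
        cross = cross - tie.astype(int)
    return phase.t0 + cross / phase.fs


def pulse_delays(pulses: PulseTrain, phase: PhaseSeries,
                 bin_width_ms: float = 2.0) -> DelayStats:
    """Delay from the nearest preceding matching extremum to each pulse onset."""
    if len(pulses) == 0:
        raise ValueError("empty pulse train")
    extrema = true_extrema_times(phase, pulses.mode)
    if extrema.size == 0:
        raise ValueError("no extrema found in the phase series")
    pos = np.searchsorted(extrema, pulses.onsets, side="right") - 1
    if np.any(pos < 0):
        raise ValueError("pulse occurs before the first extremum")
    delays_ms = (pulses.onsets - extrema[pos]) * 1000.0
    upper = max(60.0, float(np.ceil(delays_ms.max() / bin_width_ms + 1) * bin_width_ms))
    edges = np.arange(0.0, upper + bin_width_ms / 2, bin_width_ms)
    counts, edges = np.histogram(delays_ms, bins=edges)
    return DelayStats(mean_ms=float(delays_ms.mean()),
                      sd_ms=float(delays_ms.std()),
                      n=delays_ms.size, bin_edges_ms=edges, counts=counts)


def _baseline_mask(n: int, fs: float, t0: float, baseline_intervals) -> np.ndarray:
    if baseline_intervals is None:
        return np.ones(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    for start, end in baseline_intervals:
        i = max(0, int(np.floor((start - t0) * fs)))
        j = min(n, int(np.ceil((end - t0) * fs)))
        mask[i:j] = True
    return mask


def highgamma_landmark(trace: SignalTrace, phase: PhaseSeries,
                       pulses_by_mode: dict | None = None,
                       baseline_intervals=None,
                       band=HIGH_GAMMA_BAND,
                       bin_width_deg: float = 20.0,
                       flatness_threshold: float = 0.15) -> LandmarkResult:
    """Locate the theta phase of maximal high-gamma power on baseline data.

    The trace must be baseline (pulse-free) signal — stimulation evokes
    deflections that contaminate the envelope.  The 60–80 Hz zero-phase
    envelope (analytic-signal magnitude) is averaged in ``bin_width_deg``
    theta-phase bins, restricted to ``baseline_intervals`` when given; the
    landmark is the centre of the maximal bin.  If the envelope's relative
    modulation depth (max−min)/mean falls below ``flatness_threshold`` the
    result is flagged unmodulated.  When pulse trains are given, histograms
    of (pulse phase − landmark), wrapped to (−180, 180], are returned per
    mode.
    """
    if len(trace) != len(phase):
        raise ValueError("trace and phase series must be sample-aligned")
    mask = _baseline_mask(len(trace), trace.fs, trace.t0, baseline_intervals)
    min_baseline_s = 20.0 / 8.0  # ~20 theta cycles
    if mask.sum() < min_baseline_s * trace.fs:
        raise ValueError("insufficient baseline (pulse-free) signal for the landmark")

    env = np.abs(_analytic(_zero_phase_band(trace, band)))
    edges = np.arange(-180.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(phase.phase_deg[mask], edges) - 1
    which = np.clip(which, 0, centers.size - 1)
    sums = np.bincount(which, weights=env[mask], minlength=centers.size)
    counts = np.bincount(which, minlength=centers.size)
    mean_env = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    valid = np.isfinite(mean_env)
    depth = (np.nanmax(mean_env) - np.nanmin(mean_env)) / max(np.nanmean(mean_env), 1e-12)
    modulated = bool(depth >= flatness_threshold)
    landmark = float(centers[np.nanargmax(np.where(valid, mean_env, -np.inf))])

    relative = {}
    if pulses_by_mode:
        for mode, train in pulses_by_mode.items():
            if len(train) == 0:
                continue
            rel = wrap_degrees(phase.at_times(train.onsets) - landmark)
            hist, _ = np.histogram(rel, bins=edges)
            relative[mode] = {
                "bin_centers_deg": centers,
                "counts": hist,
                "circ_mean_deg": circular_summary(rel).mean_deg,
            }
    return LandmarkResult(landmark_deg=landmark, bin_centers_deg=centers,
                          envelope_by_bin=mean_env, modulated=modulated,
                          relative_hist=relative)
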