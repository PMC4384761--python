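"""Synthetic hippocampal LFP with the structure the analysis chain assumes.

The generator produces a theta rhythm (4–12 Hz band, default 8 Hz) whose
cycles are asymmetric — the falling phase lasts longer than the rising phase,
as observed in rodent hippocampus — plus high-gamma (60–80 Hz) bursts locked
to a fixed theta phase, broadband 1/f background noise, and a stereotyped
stimulus-evoked deflection added at each light-pulse onset.

Theta asymmetry is produced by a monotone, piecewise-linear warp of the
phase of a cosine: the instantaneous phase advances more slowly on the
falling half-cycle by the factor ``asym``, which keeps the 0° = peak
convention and makes the true phase available in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import PulseTrain, SignalTrace

__all__ = ["LfpGenConfig", "generate_lfp", "theta_phase_deg", "evoked_kernel"]


@dataclass
class LfpGenConfig:
    """Parameters of the synthetic LFP.

    Amplitudes are µV.  ``asym`` is the falling/rising duration ratio of a
    theta cycle (≥ 1).  ``hg_phase`` is the theta phase (degrees, 0° = peak)
    at which high-gamma bursts are centred; ``hg_kappa`` sets how sharply the
    von-Mises-like burst envelope is concentrated around that phase.
    ``evoked_tau`` (ms) sets the decay of the biphasic evoked deflection,
    whose total extent is about 5·tau (~60 ms at the default).
    """

    theta_freq: float = 8.0
    theta_amp: float = 350.0
    asym: float = 1.3
    hg_freq: float = 70.0
    hg_phase: float = 180.0
    hg_amp: float = 30.0
    hg_kappa: float = 4.0
    noise_exponent: float = 1.0
    noise_amp: float = 80.0
    evoked_amp: float = 300.0
    evoked_tau: float = 12.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asym < 1:
            raise ValueError("asym must be >= 1 (falling phase is the longer one)")
        if not (60.0 <= self.hg_freq <= 80.0):
            raise ValueError("hg_freq must lie in the 60-80 Hz high-gamma band")
        for name in ("theta_amp", "hg_amp", "noise_amp", "evoked_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.theta_freq <= 0 or self.fs <= 0:
            raise ValueError("theta_freq and fs must be positive")
        if self.evoked_tau <= 0:
            raise ValueError("evoked_tau must be positive")

    def with_(self, **kwargs) -> "LfpGenConfig":
        """Copy of this config with fields replaced."""
        return replace(self, **kwargs)


def _warped_phase_rad(config: LfpGenConfig, n: int) -> np.ndarray:
    """Instantaneous theta phase in radians in [0, 2π) per sample.

    Phase 0 is the cycle peak; (0, π) is the falling half, (π, 2π) the
    rising half.  The falling half occupies the fraction asym/(1+asym) of
    each cycle, so falling/rising duration = asym.
    """
    t = np.arange(n) / config.fs
    u = (config.theta_freq * t) % 1.0  # linear cycle fraction
    a = config.asym / (1.0 + config.asym)
    phi = np.where(u < a, np.pi * u / a, np.pi + np.pi * (u - a) / (1.0 - a))
    return phi


def theta_phase_deg(config: LfpGenConfig, duration: float) -> np.ndarray:
    """Generator-truth theta phase in degrees (−180, 180], 0° = peak."""
    n = int(round(duration * config.fs))
    phi = np.degrees(_warped_phase_rad(config, n))
    wrapped = ((phi + 180.0) % 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    return wrapped


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, amp: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, std = amp."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mag = np.zeros_like(freqs)
    mag[1:] = freqs[1:] ** (-exponent / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(mag * z, n)
    sd = x.std()
    if sd > 0 and amp > 0:
        x *= amp / sd
    else:
        x = np.zeros(n)
    return x


def evoked_kernel(fs: float, amp: float, tau_ms: float) -> np.ndarray:
    """Biphasic light-evoked deflection, negative lobe first.

    Each lobe is a difference of exponentials (rise tau/4, decay tau); the
    rebound is delayed by 1.5·tau and scaled to 45%.  The kernel is
    normalised so its peak magnitude equals ``amp`` (µV).
    """
    tau = tau_ms / 1000.0
    t = np.arange(0.0, 5.0 * tau, 1.0 / fs)
    d1 = np.exp(-t / tau) - np.exp(-4.0 * t / tau)
    lag = 1.5 * tau
    ts = t - lag
    d2 = np.where(ts >= 0, np.exp(-ts / tau) - np.exp(-4.0 * ts / tau), 0.0)
    k = -(d1 - 0.45 * d2)
    peak = np.max(np.abs(k))
    if peak > 0 and amp > 0:
        k = amp * k / peak
    else:
        k = np.zeros_like(k)
    return k


def generate_lfp(config: LfpGenConfig, duration: float,
                 pulses: PulseTrain | None = None) -> SignalTrace:
    """Generate an LFP trace; identical inputs give byte-identical output.

    Parameters
    ----------
    config : LfpGenConfig
    duration : float
        Trace length in seconds (> 0).
    pulses : PulseTrain, optional
        Stimulation pulses; each onset (within [0, duration)) adds the
        evoked kernel to the trace.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * config.fs))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")

    phi = _warped_phase_rad(config, n)
    trace = config.theta_amp * np.cos(phi)

    if config.hg_amp > 0:
        # Bursts are centred where the *instantaneous* theta phase (the
        # analytic-signal angle of the band-limited theta component, the
        # standard convention for phase-amplitude coupling) equals
        # hg_phase, so the configured phase is directly recoverable by the
        # offline analysis.
        from .phase_metrics import offline_phase
        inst = np.radians(
            offline_phase(SignalTrace(trace.copy(), config.fs)).phase_deg)
        t = np.arange(n) / config.fs
        envelope = config.hg_amp * np.exp(
            config.hg_kappa * (np.cos(inst - np.radians(config.hg_phase)) - 1.0))
        trace = trace + envelope * np.cos(2.0 * np.pi * config.hg_freq * t)

    if config.noise_amp > 0:
        rng = np.random.default_rng(config.seed)
        trace = trace + _one_over_f_noise(rng, n, config.fs,
                                          config.noise_exponent, config.noise_amp)

    if pulses is not None and len(pulses) > 0:
        if np.any(pulses.onsets < 0) or np.any(pulses.onsets >= duration):
            raise ValueError("pulse onsets must lie within [0, duration)")
        kernel = evoked_kernel(config.fs, config.evoked_amp, config.evoked_tau)
        for onset in pulses.onsets:
            i = int(round(onset * config.fs))
            j = min(n, i + kernel.size)
            trace[i:j] += kernel[: j - i]

    return SignalTrace(samples=trace, fs=config.fs, t0=0.0)
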