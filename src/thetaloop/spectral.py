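"""Multitaper power spectra and stimulus-aligned evoked averages.

Spectra use DPSS (Slepian) tapers with time-bandwidth product 2 and 3
tapers by default, the standard setting for short LFP segments; taper
eigenspectra are averaged, then segment estimates are averaged.  Evoked
averages align LFP snippets to pulse onsets (or, in dummy mode, to the
times the detector would have fired on a pulse-free trace) and report the
mean ± SEM across pulses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .closed_loop import DetectorConfig, run_closed_loop
from .core import SignalTrace

__all__ = ["SpectralEstimate", "EvokedAverage", "multitaper_psd", "evoked_average"]


@dataclass
class SpectralEstimate:
    """One-sided multitaper PSD in µV²/Hz on a common frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray
    tw: float
    k: int
    n_segments: int


@dataclass
class EvokedAverage:
    """Pulse-aligned mean LFP (µV) with SEM across pulses."""

    lags_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def multitaper_psd(segments, tw: float = 2.0, k: int = 3,
                   nfft: int | None = None) -> SpectralEstimate:
    """Average DPSS eigenspectra over tapers, then over segments.

    All segments must share one sampling rate and length.  ``k`` must not
    exceed 2·tw − 1 (higher-order tapers have poor concentration).  The FFT
    length defaults to the next power of two above the segment length.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments given")
    if k > 2 * tw - 1:
        raise ValueError(f"k={k} exceeds 2*tw-1={2 * tw - 1:g}")
    fs = segments[0].fs
    n = len(segments[0])
    for seg in segments:
        if seg.fs != fs:
            raise ValueError("segments have mixed sampling rates")
        if len(seg) != n:
            raise ValueError("segments must share one length")
    if nfft is None:
        nfft = 1 << int(np.ceil(np.log2(n)))
    tapers = dpss(n, tw, Kmax=k)  # rows are unit-energy tapers

    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    acc = np.zeros(freqs.size)
    for seg in segments:
        x = seg.samples - seg.samples.mean()
        spec = np.fft.rfft(tapers * x, n=nfft, axis=1)
        acc += (np.abs(spec) ** 2).mean(axis=0) / fs
    psd = acc / len(segments)
    # one-sided scaling (DC and Nyquist appear once)
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    return SpectralEstimate(freqs=freqs, psd=psd, tw=tw, k=k,
                            n_segments=len(segments))


def evoked_average(trace: SignalTrace, onsets,
                   window_ms=(-100.0, 200.0),
                   dummy: bool = False,
                   detector_config: DetectorConfig | None = None) -> EvokedAverage:
    """Mean ± SEM of LFP snippets aligned to pulse onsets.

    With ``dummy=True`` the given onsets are ignored and alignment times
    are recomputed by running the closed-loop detector on the (pulse-free)
    trace, which yields the average waveform that *would* have surrounded a
    stimulus.  Onsets whose window extends past the trace are dropped; it
    is an error if none remain.
    """
    if dummy:
        if detector_config is None:
            raise ValueError("dummy alignment needs a detector_config")
        onsets = run_closed_loop(trace, detector_config).onsets
    onsets = np.asarray(onsets, dtype=np.float64)
    pre = int(round(-window_ms[0] * trace.fs / 1000.0))
    post = int(round(window_ms[1] * trace.fs / 1000.0))
    if pre < 0 or post < 0:
        raise ValueError("window must bracket lag 0: (-pre, +post)")
    idx = np.round((onsets - trace.t0) * trace.fs).astype(int)
    idx = idx[(idx - pre >= 0) & (idx + post < len(trace))]
    if idx.size == 0:
        raise ValueError("no onsets with a full window inside the trace")
    offsets = np.arange(-pre, post + 1)
    snippets = trace.samples[idx[:, None] + offsets[None, :]]
    mean = snippets.mean(axis=0)
    if idx.size > 1:
        sem = snippets.std(axis=0, ddof=1) / np.sqrt(idx.size)
    else:
        sem = np.zeros_like(mean)
    return EvokedAverage(lags_ms=offsets * 1000.0 / trace.fs,
                         mean=mean, sem=sem, n=int(idx.size))
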