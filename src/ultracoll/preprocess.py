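"""Filtering, spike-snippet extraction, and the analog multi-unit measure.

All filters are 4th-order Butterworth applied forward-backward
(:func:`scipy.signal.sosfiltfilt`), i.e. zero-phase, so detection and
latency measurements are not biased by group delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import ParameterError, Trace

log = logging.getLogger(__name__)

#: Spike band used before snippet detection (Hz).
SPIKE_BAND_HZ = (500.0, 5000.0)
#: Band used for the analog multi-unit activity envelope (Hz).
AMUA_BAND_HZ = (300.0, 6000.0)
AMUA_LOWPASS_HZ = 300.0


@dataclass
class SnippetSet:
    """Threshold-crossing waveform snippets from one channel."""

    snippets: np.ndarray  # [n_snippets x n_samples], volts
    times_ms: np.ndarray  # trigger times, session clock
    window_ms: tuple[float, float]  # (pre, post) extents around the trigger
    channel: str

    def __len__(self) -> int:
        return self.snippets.shape[0]


@dataclass
class AmuaTrace:
    """Non-negative envelope of the spike-band signal (spike-power proxy)."""

    samples: np.ndarray
    sample_rate_hz: float
    channel: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        assert np.all(self.samples >= 0.0)


def _butter_sos(kind: str, edges, fs: float):
    nyq = fs / 2.0
    e = np.atleast_1d(np.asarray(edges, dtype=float))
    if np.any(e <= 0) or np.any(e >= nyq):
        raise ParameterError(f"filter edges {edges} outside (0, Nyquist={nyq}) Hz")
    wn = e if e.size > 1 else float(e[0])
    return signal.butter(4, wn, btype=kind, fs=fs, output="sos")


def bandpass(trace: Trace, lo_hz: float, hi_hz: float) -> Trace:
    """Zero-phase band-pass filter of every channel; same length and rate."""
    if not lo_hz < hi_hz:
        raise ParameterError("need lo_hz < hi_hz")
    sos = _butter_sos("bandpass", (lo_hz, hi_hz), trace.sample_rate_hz)
    filtered = signal.sosfiltfilt(sos, trace.samples, axis=1)
    return Trace(filtered, trace.sample_rate_hz, list(trace.channel_ids), trace.start_time_ms)


def robust_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD estimate: median(|x|)/0.6745 (Gaussian-consistent)."""
    return float(np.median(np.abs(x)) / 0.6745)


def extract_snippets(
    trace: Trace,
    threshold_sd: float = 4.0,
    dead_time_ms: float = 0.7,
    window_ms: tuple[float, float] = (0.4, 0.8),
    align_ms: float = 0.6,
    channel: int = 0,
) -> SnippetSet:
    """Detect putative spikes as absolute-value threshold crossings.

    The trace must already be band-passed to the spike band.  Triggers are
    upward crossings of ``threshold_sd`` times the robust noise SD by |x|,
    aligned to the |x| extremum within ``align_ms`` after the crossing (a
    raw crossing time jitters with the waveform phase); crossings closer
    than ``dead_time_ms`` to the previous accepted trigger are discarded
    (the earlier one is kept).  Snippets span ``window_ms[0]`` before to
    ``window_ms[1]`` after the trigger; triggers whose window exceeds the
    trace bounds are dropped with a logged count.
    """
    x = trace.samples[channel]
    fs = trace.sample_rate_hz
    thr = threshold_sd * robust_noise_sd(x)
    above = np.abs(x) >= thr
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    align_n = int(round(align_ms / 1000.0 * fs))
    aligned = [
        c + int(np.argmax(np.abs(x[c : c + align_n + 1]))) for c in crossings
    ]
    dead_n = dead_time_ms / 1000.0 * fs
    keep = []
    last = -np.inf
    for c in aligned:
        if c - last >= dead_n:
            keep.append(c)
            last = c
    pre_n = int(round(window_ms[0] / 1000.0 * fs))
    post_n = int(round(window_ms[1] / 1000.0 * fs))
    snippets, times = [], []
    dropped = 0
    for c in keep:
        if c - pre_n < 0 or c + post_n > x.size:
            dropped += 1
            continue
        snippets.append(x[c - pre_n : c + post_n])
        times.append(trace.start_time_ms + c / fs * 1000.0)
    if dropped:
        log.warning("dropped %d snippet(s) whose window exceeded the trace", dropped)
    arr = np.array(snippets) if snippets else np.empty((0, pre_n + post_n))
    return SnippetSet(
        snippets=arr,
        times_ms=np.asarray(times, dtype=float),
        window_ms=window_ms,
        channel=trace.channel_ids[channel],
    )


def compute_amua(trace: Trace, channel: int = 0) -> AmuaTrace:
    """Analog multi-unit activity: band-pass 300-6000 Hz, full-wave rectify,
    low-pass below 300 Hz.  Filter undershoot is clipped at zero."""
    fs = trace.sample_rate_hz
    sos_bp = _butter_sos("bandpass", AMUA_BAND_HZ, fs)
    sos_lp = _butter_sos("lowpass", AMUA_LOWPASS_HZ, fs)
    x = signal.sosfiltfilt(sos_bp, trace.samples[channel])
    env = signal.sosfiltfilt(sos_lp, np.abs(x))
    return AmuaTrace(np.clip(env, 0.0, None), fs, trace.channel_ids[channel])
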