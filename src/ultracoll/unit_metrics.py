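"""Per-unit response statistics and the auditory-nerve-fiber gate.

Auditory nerve fibers recorded through the cochlear nucleus are separated
from cochlear nucleus neurons by three response statistics measured from
repeated presentations of the CF tone at 30 dB above threshold:

* the coefficient of variation (CV) of within-trial interspike intervals
  (AN fibers fire irregularly: CV >= 0.5),
* the mode of the first-spike latency histogram (AN fibers respond fast:
  FSL <= 5 ms), and
* the shape class of the peristimulus time histogram (AN fibers are
  primary-like; chopper, pri-N, and onset shapes indicate cochlear nucleus
  cell types).

PSTH shape classification — visual in practice — is implemented here as a
deterministic rule set over the histogram (peak position, sustained-to-peak
ratio, a post-peak notch, and autocorrelation regularity), with every
threshold exposed as a parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import InsufficientDataError, ParameterError, Schedule, UnitSpikes

log = logging.getLogger(__name__)


@dataclass
class PSTH:
    """Trial-averaged firing rate versus time after stimulus onset."""

    bin_edges_ms: np.ndarray  # len n_bins + 1, relative to event onset
    rate_hz: np.ndarray  # spikes/s averaged over trials
    n_trials: int
    bin_width_ms: float

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])

    def total_count(self) -> float:
        """Total spike count across trials (conservation identity)."""
        return float(np.sum(self.rate_hz) * self.bin_width_ms / 1000.0 * self.n_trials)


@dataclass
class UnitMetrics:
    unit_id: str
    cv_isi: float | None
    fsl_mode_ms: float | None
    psth_class: str | None
    is_an_fiber: bool = False


def _onsets(events) -> np.ndarray:
    if isinstance(events, Schedule):
        return events.onsets_ms()
    return np.asarray([getattr(e, "onset_ms", e) for e in events], dtype=float)


def compute_psth(
    unit: UnitSpikes,
    events,
    window_ms: tuple[float, float] = (0.0, 50.0),
    bin_width_ms: float = 1.0,
) -> PSTH:
    """Peristimulus time histogram over repeated events.

    Per-bin rate is count / (n_trials * bin width in s); the conservation
    identity sum(rate) * bin_width * n_trials == total in-window count
    holds exactly.
    """
    onsets = _onsets(events)
    if onsets.size == 0:
        raise InsufficientDataError("PSTH requires at least one event")
    t0, t1 = window_ms
    span = t1 - t0
    n_bins = round(span / bin_width_ms)
    if n_bins < 1 or abs(n_bins * bin_width_ms - span) > 1e-9:
        raise ParameterError("bin width must divide the window length")
    edges = t0 + bin_width_ms * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for on in onsets:
        rel = unit.spike_times_ms - on
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (onsets.size * bin_width_ms / 1000.0)
    return PSTH(edges, rate, n_trials=onsets.size, bin_width_ms=bin_width_ms)


def isi_cv(unit: UnitSpikes, events, window_ms: tuple[float, float] = (0.0, 50.0)) -> float:
    """CV of interspike intervals pooled within trials.

    Intervals never span trial boundaries.  Needs >= 3 pooled intervals.
    CV is the sample SD (n-1 denominator) over the mean.
    """
    isis = []
    for on in _onsets(events):
        rel = unit.spike_times_ms - on
        inwin = rel[(rel >= window_ms[0]) & (rel < window_ms[1])]
        if inwin.size >= 2:
            isis.append(np.diff(inwin))
    if not isis:
        raise InsufficientDataError("no within-trial interspike intervals")
    pooled = np.concatenate(isis)
    if pooled.size < 3:
        raise InsufficientDataError(f"need >= 3 ISIs, got {pooled.size}")
    return float(np.std(pooled, ddof=1) / np.mean(pooled))


def first_spike_latency_mode(
    unit: UnitSpikes,
    events,
    max_latency_ms: float = 30.0,
    bin_ms: float = 0.5,
) -> float:
    """Mode of the first-spike-latency histogram (0.5 ms bins).

    Returns the center of the maximal bin; ties go to the earliest bin.
    Needs first spikes on >= 10 trials.
    """
    firsts = []
    for on in _onsets(events):
        rel = unit.spike_times_ms - on
        cand = rel[(rel > 0.0) & (rel <= max_latency_ms)]
        if cand.size:
            firsts.append(cand[0])
    if len(firsts) < 10:
        raise InsufficientDataError(
            f"first spikes on only {len(firsts)} trials (need >= 10)"
        )
    edges = np.arange(0.0, max_latency_ms + bin_ms / 2, bin_ms)
    counts = np.histogram(firsts, bins=edges)[0]
    i = int(np.argmax(counts))  # argmax returns the earliest maximal bin
    return float(edges[i] + bin_ms / 2.0)


def classify_psth(
    psth: PSTH,
    sustained_last_ms: float = 25.0,
    sustained_frac: float = 0.2,
    peak_window_ms: float = 10.0,
    notch_window_ms: tuple[float, float] = (2.0, 6.0),
    notch_frac: float = 0.5,
    notch_recovery_frac: float = 0.25,
    chop_ac_window_ms: float = 25.0,
    chop_ac_min: float = 0.3,
) -> str:
    """Classify a CF-tone PSTH as primary / chopper / pri-N / onset.

    Rules, applied in order:

    * onset — sustained rate (mean over the last ``sustained_last_ms``)
      below ``sustained_frac`` of the peak;
    * chopper — the mean-removed autocorrelation of the first
      ``chop_ac_window_ms`` has a local maximum at a non-zero lag short
      enough for >= 3 regular peaks, with normalized height above
      ``chop_ac_min``;
    * pri-N — primary-shaped but with a notch: some bin within
      ``notch_window_ms`` after the peak falls below ``notch_frac`` of the
      peak and the rate then recovers by ``notch_recovery_frac`` of the
      peak;
    * primary — peak within the first ``peak_window_ms`` and sustained rate
      at least ``sustained_frac`` of the peak;
    * otherwise ``"unclassified"`` (a valid label, not an error).
    """
    r = psth.rate_hz
    centers = psth.bin_centers_ms
    peak = float(r.max(initial=0.0))
    if peak <= 0.0:
        return "unclassified"
    i_peak = int(np.argmax(r))
    t_peak = centers[i_peak]
    t_last = centers[-1]
    sustained = float(np.mean(r[centers > t_last - sustained_last_ms]))

    if sustained < sustained_frac * peak:
        return "onset"

    # chopper: regular oscillation in the early response
    early = r[centers <= centers[0] + chop_ac_window_ms]
    x = early - early.mean()
    if x.size >= 6 and np.any(x != 0):
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        ac = ac / ac[0]
        max_lag = int(round(chop_ac_window_ms / 3.0 / psth.bin_width_ms))
        best = 0.0
        for lag in range(2, min(max_lag + 1, ac.size - 1)):
            if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1]:
                best = max(best, float(ac[lag]))
        if best > chop_ac_min:
            return "chopper"

    primary_shaped = (t_peak <= psth.bin_edges_ms[0] + peak_window_ms) and (
        sustained >= sustained_frac * peak
    )
    if primary_shaped:
        lo, hi = notch_window_ms
        in_notch = (centers > t_peak + lo) & (centers <= t_peak + hi)
        idx = np.nonzero(in_notch)[0]
        for j in idx:
            if r[j] < notch_frac * peak and np.max(r[j:], initial=0.0) >= r[j] + notch_recovery_frac * peak:
                return "pri-N"
        return "primary"
    return "unclassified"


def an_fiber_gate(
    metrics: UnitMetrics,
    cv_min: float = 0.5,
    fsl_max_ms: float = 5.0,
) -> bool:
    """Auditory-nerve-fiber gate: CV >= 0.5 and FSL <= 5 ms (both
    inclusive) and a primary-like PSTH.  Undefined metrics fail the gate
    with a logged reason."""
    for name in ("cv_isi", "fsl_mode_ms", "psth_class"):
        if getattr(metrics, name) is None:
            log.info("unit %s: %s undefined; gate fails", metrics.unit_id, name)
            return False
    return (
        metrics.cv_isi >= cv_min
        and metrics.fsl_mode_ms <= fsl_max_ms
        and metrics.psth_class == "primary"
    )


def compute_unit_metrics(
    unit: UnitSpikes,
    events,
    window_ms: tuple[float, float] = (0.0, 50.0),
    bin_width_ms: float = 1.0,
) -> UnitMetrics:
    """Convenience chain: PSTH class, ISI CV, FSL mode, and the AN gate,
    from responses to repeated CF-tone presentations."""

    def _try(fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except InsufficientDataError as exc:
            log.info("unit %s: %s", unit.unit_id, exc)
            return None

    psth = _try(compute_psth, unit, events, window_ms, bin_width_ms)
    metrics = UnitMetrics(
        unit_id=unit.unit_id,
        cv_isi=_try(isi_cv, unit, events, window_ms),
        fsl_mode_ms=_try(first_spike_latency_mode, unit, events),
        psth_class=classify_psth(psth) if psth is not None else None,
    )
    metrics.is_an_fiber = an_fiber_gate(metrics)
    return metrics
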