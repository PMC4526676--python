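"""Vocalization responsiveness: driven-vs-spontaneous tests and the SNR.

A unit's response to each call is tested by comparing per-trial spike
counts in a driven window (call duration, shifted by a response-latency
offset) with counts in equal-duration windows immediately preceding each
onset, using the two-sided Wilcoxon rank-sum test.  A unit is responsive
when at least 3 of the 9 calls yield p < 0.05.

Response reliability is summarized by a signal-to-noise ratio: the
variance across time bins of the trial-averaged PSTH divided by the
average across trials of the variance of each trial's deviation from the
PSTH.  SNR is averaged across the 9 calls for population scatter plots
against F_max.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_io import (
    InsufficientDataError,
    Schedule,
    UnitSpikes,
    ValidationError,
)

log = logging.getLogger(__name__)

ALPHA = 0.05
N_CALLS_CRITERION = 3


@dataclass
class CallResponse:
    """One unit's test against one call."""

    unit_id: str
    call_id: str
    driven_counts: np.ndarray
    spont_counts: np.ndarray
    p_value: float
    snr: float  # may be math.inf when trial deviations vanish


@dataclass
class ResponsivenessSummary:
    unit_id: str
    n_significant_calls: int
    responsive: bool
    mean_snr: float


def count_windows(
    unit: UnitSpikes,
    call_events,
    latency_offset_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial driven and spontaneous spike counts for one call.

    Driven window: [onset + offset, onset + offset + duration); spontaneous
    window: the same duration immediately before onset.  Windows of
    adjacent events must not overlap.
    """
    events = list(call_events)
    if not events:
        raise InsufficientDataError("no call events")
    prev_end = -np.inf
    driven, spont = [], []
    t = unit.spike_times_ms
    for ev in events:
        dur = ev.duration_ms
        d0 = ev.onset_ms + latency_offset_ms
        s0 = ev.onset_ms - dur
        if s0 < prev_end:
            raise ValidationError(
                f"count windows overlap across events near {ev.onset_ms} ms"
            )
        prev_end = d0 + dur
        driven.append(np.count_nonzero((t >= d0) & (t < d0 + dur)))
        spont.append(np.count_nonzero((t >= s0) & (t < ev.onset_ms)))
    return np.asarray(driven), np.asarray(spont)


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration when both samples have n <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("rank-sum test needs non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def binned_trial_responses(
    unit: UnitSpikes,
    call_events,
    latency_offset_ms: float = 5.0,
    bin_width_ms: float = 2.0,
) -> np.ndarray:
    """Per-trial binned rates (Hz) over the driven window: [n_trials x n_bins]."""
    events = list(call_events)
    if not events:
        raise InsufficientDataError("no call events")
    dur = events[0].duration_ms
    n_bins = max(2, int(math.floor(dur / bin_width_ms)))
    rows = []
    for ev in events:
        t0 = ev.onset_ms + latency_offset_ms
        edges = t0 + bin_width_ms * np.arange(n_bins + 1)
        counts = np.histogram(unit.spike_times_ms, bins=edges)[0]
        rows.append(counts / (bin_width_ms / 1000.0))
    return np.asarray(rows, dtype=float)


def response_snr(trial_responses: np.ndarray) -> float:
    """SNR of a binned response: Var_bins(PSTH) over the mean across trials
    of Var_bins(trial - PSTH), both population-style (divide by n_bins).

    Returns ``math.inf`` (flagged infinite) when the trial deviations have
    zero variance but the PSTH does not, and 0 when both vanish.
    """
    trials = np.asarray(trial_responses, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 2:
        raise InsufficientDataError("SNR needs >= 2 trials of binned responses")
    if trials.shape[1] < 2:
        raise InsufficientDataError("SNR needs >= 2 time bins")
    psth = trials.mean(axis=0)
    num = float(np.var(psth))
    dev = trials - psth
    den = float(np.mean(np.var(dev, axis=1)))
    if den == 0.0:
        return math.inf if num > 0.0 else 0.0
    return num / den


def assess_call(
    unit: UnitSpikes,
    call_events,
    latency_offset_ms: float = 5.0,
    snr_bin_ms: float = 2.0,
) -> CallResponse:
    """Test one unit against repeated presentations of one call."""
    events = list(call_events)
    driven, spont = count_windows(unit, events, latency_offset_ms)
    p = rank_sum_test(driven, spont)
    snr = response_snr(
        binned_trial_responses(unit, events, latency_offset_ms, snr_bin_ms)
    )
    return CallResponse(
        unit_id=unit.unit_id,
        call_id=events[0].call_id or "",
        driven_counts=driven,
        spont_counts=spont,
        p_value=p,
        snr=snr,
    )


def summarize_responsiveness(
    call_responses: list[CallResponse],
    alpha: float = ALPHA,
    n_required: int = N_CALLS_CRITERION,
    n_calls_expected: int = 9,
) -> ResponsivenessSummary:
    """Aggregate per-call tests: responsive iff >= 3 of 9 calls significant.

    With fewer than the expected 9 calls the criterion is scaled as
    ceil(n/3) with a logged warning.  Flagged-infinite SNRs are excluded
    from the mean with a logged count.
    """
    if not call_responses:
        raise InsufficientDataError("no call responses to summarize")
    n = len(call_responses)
    required = n_required
    if n < n_calls_expected:
        required = math.ceil(n / 3)
        log.warning(
            "only %d calls tested; scaling responsiveness criterion to >= %d",
            n,
            required,
        )
    n_sig = sum(1 for r in call_responses if r.p_value < alpha)
    snrs = [r.snr for r in call_responses if math.isfinite(r.snr)]
    n_inf = n - len(snrs)
    if n_inf:
        log.info("excluded %d infinite SNR value(s) from the mean", n_inf)
    return ResponsivenessSummary(
        unit_id=call_responses[0].unit_id,
        n_significant_calls=n_sig,
        responsive=n_sig >= required,
        mean_snr=float(np.mean(snrs)) if snrs else 0.0,
    )


def assess_unit(
    unit: UnitSpikes,
    schedule: Schedule,
    latency_offset_ms: float = 5.0,
    snr_bin_ms: float = 2.0,
) -> ResponsivenessSummary:
    """Run the full responsiveness chain for one unit over a schedule's
    call events, grouped by call id."""
    calls = schedule.subset(kind="call")
    ids = sorted({e.call_id for e in calls})
    if not ids:
        raise InsufficientDataError("schedule contains no call events")
    responses = [
        assess_call(unit, calls.subset(call_id=cid).events, latency_offset_ms, snr_bin_ms)
        for cid in ids
    ]
    return summarize_responsiveness(responses)
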