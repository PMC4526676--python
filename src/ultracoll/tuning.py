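"""Frequency response areas, characteristic frequency, and F_max.

The FRA maps baseline-subtracted response strength over a tone
frequency x level grid (2-90 kHz in 0.2 or 0.15 octave steps, 15-100 dB
SPL in 5 dB steps).  Characteristic frequency (CF) is the frequency at
which the response threshold is lowest; F_max is the highest frequency at
which tone responses (pooled across levels) significantly exceed
spontaneous activity under a one-sided Wilcoxon rank-sum test — the same
test family used for vocalization responsiveness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_io import Schedule, UnitSpikes
from .vocal_response import rank_sum_test

log = logging.getLogger(__name__)


@dataclass
class FRA:
    """Frequency x level response grid for one unit or recording site."""

    freqs_khz: np.ndarray  # ascending
    levels_db: np.ndarray  # ascending
    response: np.ndarray  # [n_freq x n_level] mean evoked-minus-baseline rate (Hz)
    spont_hz: float  # mean baseline rate
    spont_sd_hz: float  # SD of single-trial baseline rates
    n_reps: np.ndarray  # [n_freq x n_level] repetition counts

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.freqs_khz) > 0)
        assert np.all(np.diff(self.levels_db) > 0)

    @property
    def missing(self) -> np.ndarray:
        """Cells with zero repetitions, flagged rather than imputed."""
        return self.n_reps == 0


@dataclass
class TuningSummary:
    unit_id: str
    cf_khz: float | None
    threshold_db: float | None
    fmax_khz: float | None


def build_fra(
    unit: UnitSpikes,
    schedule: Schedule,
    count_window_ms: tuple[float, float] | None = None,
    baseline_ms: float = 50.0,
) -> FRA:
    """Build an FRA from a unit's responses to the tone-pip grid.

    Cell value = mean over repetitions of (evoked rate - mean baseline
    rate); the baseline is estimated from the ``baseline_ms`` window
    preceding every tone onset, pooled over all tones.  The default count
    window is (0, stimulus duration + 10] ms.
    """
    tones = schedule.subset(kind="tone").events
    freqs = np.array(sorted({e.freq_khz for e in tones}))
    levels = np.array(sorted({e.level_db_spl for e in tones}))
    fi = {f: i for i, f in enumerate(freqs)}
    li = {l: i for i, l in enumerate(levels)}
    t = unit.spike_times_ms

    base_rates = []
    for ev in tones:
        c = np.count_nonzero((t >= ev.onset_ms - baseline_ms) & (t < ev.onset_ms))
        base_rates.append(c / (baseline_ms / 1000.0))
    base_rates = np.asarray(base_rates)
    spont = float(base_rates.mean()) if base_rates.size else 0.0
    spont_sd = float(base_rates.std(ddof=1)) if base_rates.size > 1 else 0.0

    sums = np.zeros((freqs.size, levels.size))
    reps = np.zeros((freqs.size, levels.size), dtype=int)
    for ev in tones:
        w0, w1 = count_window_ms if count_window_ms else (0.0, ev.duration_ms + 10.0)
        win_s = (w1 - w0) / 1000.0
        c = np.count_nonzero((t >= ev.onset_ms + w0) & (t < ev.onset_ms + w1))
        i, j = fi[ev.freq_khz], li[ev.level_db_spl]
        sums[i, j] += c / win_s - spont
        reps[i, j] += 1
    with np.errstate(invalid="ignore"):
        response = np.where(reps > 0, sums / np.maximum(reps, 1), np.nan)
    if np.any(reps == 0):
        log.warning("FRA for %s has %d empty grid cells", unit.unit_id, int((reps == 0).sum()))
    return FRA(freqs, levels, response, spont, spont_sd, reps)


def _significant_cells(fra: FRA, alpha: float) -> np.ndarray:
    """One-sided significance of each FRA cell against the baseline.

    With >= 5 repetitions, a z-test of the cell's mean excess against the
    single-trial baseline SD scaled by sqrt(reps); with fewer repetitions,
    the cruder criterion mean excess > 2 baseline SDs.
    """
    z_crit = stats.norm.ppf(1.0 - alpha)
    sd = max(fra.spont_sd_hz, 1e-12)
    with np.errstate(invalid="ignore"):
        z = fra.response / (sd / np.sqrt(np.maximum(fra.n_reps, 1)))
        sig_few = fra.response > 2.0 * sd
    sig = np.where(fra.n_reps >= 5, z > z_crit, sig_few)
    sig[fra.missing] = False
    return sig


def estimate_cf(fra: FRA, alpha: float = 0.05) -> tuple[float, float] | None:
    """Characteristic frequency and threshold from the FRA tip.

    Per frequency, the threshold is the lowest level whose cell is
    significant and remains significant at the next two tested levels
    (fewer near the top of the grid).  CF is the frequency of minimal
    threshold; exact ties resolve to the grid frequency nearest the
    geometric mean of the tied frequencies.  Returns ``None`` when no cell
    is significant (undefined tuning).
    """
    sig = _significant_cells(fra, alpha)
    n_f, n_l = sig.shape
    thresholds = np.full(n_f, np.nan)
    for i in range(n_f):
        for j in range(n_l):
            upper = sig[i, j : min(j + 3, n_l)]
            if upper.all():
                thresholds[i] = fra.levels_db[j]
                break
    if np.all(np.isnan(thresholds)):
        return None
    t_min = np.nanmin(thresholds)
    tied = fra.freqs_khz[thresholds == t_min]
    if tied.size == 1:
        return float(tied[0]), float(t_min)
    geo = float(np.exp(np.mean(np.log(tied))))
    cf = float(fra.freqs_khz[np.argmin(np.abs(np.log(fra.freqs_khz / geo)))])
    return cf, float(t_min)


def estimate_fmax(
    unit: UnitSpikes,
    schedule: Schedule,
    alpha: float = 0.05,
    count_window_ms: tuple[float, float] | None = None,
    correct_family: bool = True,
) -> float | None:
    """Highest frequency with responses significantly above spontaneous.

    Per grid frequency, per-trial evoked counts pooled across all levels
    are compared with equal-duration baseline counts preceding each onset
    (one-sided Wilcoxon rank-sum).  Because the grid spans ~30
    frequencies, the per-frequency level is Bonferroni-corrected by
    default so a unit with no tone response reports an undefined F_max
    rather than the highest of its false positives.  Returns ``None``
    when no frequency is significant.
    """
    tones = schedule.subset(kind="tone").events
    t = unit.spike_times_ms
    by_freq: dict[float, tuple[list, list]] = {}
    for ev in tones:
        w0, w1 = count_window_ms if count_window_ms else (0.0, ev.duration_ms + 10.0)
        span = w1 - w0
        driven = np.count_nonzero((t >= ev.onset_ms + w0) & (t < ev.onset_ms + w1))
        base = np.count_nonzero((t >= ev.onset_ms - span) & (t < ev.onset_ms))
        d, s = by_freq.setdefault(ev.freq_khz, ([], []))
        d.append(driven)
        s.append(base)
    a = alpha / len(by_freq) if (correct_family and by_freq) else alpha
    fmax = None
    for f in sorted(by_freq):
        d, s = by_freq[f]
        p = rank_sum_test(d, s, alternative="greater")
        if p < a:
            fmax = float(f)
    return fmax


def summarize_tuning(
    unit: UnitSpikes, schedule: Schedule, alpha: float = 0.05
) -> TuningSummary:
    """Full tuning chain: FRA, CF/threshold, F_max for one unit."""
    fra = build_fra(unit, schedule)
    cf_thr = estimate_cf(fra, alpha)
    fmax = estimate_fmax(unit, schedule, alpha)
    if cf_thr is None:
        log.info("unit %s: tuning undefined (no significant FRA cell)", unit.unit_id)
        return TuningSummary(unit.unit_id, None, None, fmax)
    return TuningSummary(unit.unit_id, cf_thr[0], cf_thr[1], fmax)
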