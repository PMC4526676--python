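"""Synthetic stimuli, spike trains, extracellular traces, and ABR sweeps.

The generator provides ground truth for every downstream stage of the
pipeline.  Its response model is deliberately phenomenological:

* Frequency tuning is a symmetric V in log-frequency.  A neuron with
  characteristic frequency ``cf_khz`` and threshold ``threshold_db``
  responds to a tone of frequency f at level L with driven-rate excess

      r(f, L) = max_rate * max(0, 1 - |log2(f/CF)| / w(L)),

  where the octave half-width ``w(L) = q_sharpness * (L - threshold)/20``
  grows linearly with level above threshold, i.e. the effective threshold
  rises away from CF with slope ``20/q_sharpness`` dB per octave.

* Temporal response shape follows the classic peristimulus-histogram
  classes of the cochlear nucleus literature: primary-like (exponential
  adaptation to a sustained plateau), pri-N (primary with a brief notch
  after the onset peak), chopper (regular intrinsic oscillation), and
  onset (transient only).

* Spike trains are time-rescaled gamma-renewal processes.  The gamma order
  k sets the asymptotic interspike-interval CV to 1/sqrt(k); an absolute
  refractory period is imposed as integration dead time.

* Vocalizations are synthesized as single-component log-linear FM sweeps
  confined to the 60-90 kHz band that mouse ultrasonic calls occupy; the
  only property downstream analyses rely on is that spectral energy stays
  in that band.

* ABR sweeps are sums of five biphasic bumps (trough preceding peak, a
  difference of Gaussians) at increasing latencies plus white noise.  The
  wave-I and wave-V bump amplitudes depend on tone frequency through
  user-supplied maps, emulating the peripheral-versus-midbrain amplitude
  trends the pipeline is designed to recover.

Every stochastic operation takes a seed or :class:`numpy.random.Generator`
and is exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import (
    ParameterError,
    Schedule,
    StimulusEvent,
    Trace,
    UnitSpikes,
    ValidationError,
)

log = logging.getLogger(__name__)

PSTH_CLASSES = ("primary", "chopper", "pri-N", "onset")
CALL_BAND_KHZ = (60.0, 90.0)

#: Full-scale amplitude 1.0 corresponds to 94 dB SPL (1 Pa RMS convention).
LEVEL_REF_DB = 94.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated unit."""

    cf_khz: float
    threshold_db: float = 35.0
    q_sharpness: float = 0.3  # octave half-width gained per 20 dB above threshold
    max_rate_hz: float = 300.0
    spont_rate_hz: float = 8.0
    psth_class: str = "primary"
    adaptation_tau_ms: float = 5.0
    gamma_order: float = 1.0
    refractory_ms: float = 0.8
    fsl_ms: float = 3.0
    responds_to_calls: bool = False

    def __post_init__(self) -> None:
        if self.psth_class not in PSTH_CLASSES:
            raise ValidationError(f"unknown psth_class {self.psth_class!r}")
        if self.spont_rate_hz > self.max_rate_hz:
            raise ValidationError("spont_rate_hz must not exceed max_rate_hz")
        for name in ("cf_khz", "q_sharpness", "max_rate_hz", "adaptation_tau_ms",
                     "gamma_order", "fsl_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.refractory_ms < 0 or self.spont_rate_hz < 0:
            raise ValidationError("rates and refractory period must be non-negative")


@dataclass
class PopulationSpec:
    """Parameters of a simulated recording population at one station."""

    n_units: int
    station: str
    cf_log_mean_khz: float = 25.0
    cf_log_sd_oct: float = 0.8
    fraction_high_f: float = 0.075
    n_animals: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_high_f <= 1.0:
            raise ValidationError("fraction_high_f must be in [0, 1]")
        if not self.n_units >= self.n_animals >= 1:
            raise ValidationError("need n_units >= n_animals >= 1")


@dataclass
class CallSpec:
    """A synthetic single-component ultrasonic vocalization."""

    call_id: str
    duration_ms: float = 40.0
    f_start_khz: float = 70.0
    f_end_khz: float = 80.0
    level_db_spl: float = 80.0
    am_depth: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = CALL_BAND_KHZ
        if not (lo <= self.f_start_khz <= hi and lo <= self.f_end_khz <= hi):
            raise ParameterError(
                f"call frequency trajectory must stay within {lo}-{hi} kHz"
            )
        if not 30.0 <= self.duration_ms <= 60.0:
            raise ValidationError("call duration must be 30-60 ms")
        if self.level_db_spl not in (80.0, 90.0):
            raise ValidationError("calls are presented at 80 or 90 dB SPL")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValidationError("am_depth must be in [0, 1]")

    def to_event(self, onset_ms: float) -> StimulusEvent:
        return StimulusEvent(
            onset_ms=onset_ms,
            kind="call",
            level_db_spl=self.level_db_spl,
            duration_ms=self.duration_ms,
            call_id=self.call_id,
        )


def default_call_bank(n_calls: int = 9, seed: int = 1234) -> list[CallSpec]:
    """Nine representative synthetic calls spanning the 60-90 kHz band.

    Durations 30-60 ms, levels alternating 80/90 dB SPL, mixed upward and
    downward sweeps.
    """
    rng = _rng(seed)
    calls = []
    for i in range(n_calls):
        f0, f1 = sorted(rng.uniform(62.0, 88.0, size=2))
        if i % 2:
            f0, f1 = f1, f0  # downward sweep
        calls.append(
            CallSpec(
                call_id=f"call{i + 1:02d}",
                duration_ms=float(rng.uniform(30.0, 60.0)),
                f_start_khz=float(f0),
                f_end_khz=float(f1),
                level_db_spl=80.0 if i % 2 == 0 else 90.0,
                am_depth=float(rng.uniform(0.0, 0.4)),
            )
        )
    return calls


@dataclass
class ABRSpec:
    """Parameters of the synthetic auditory brainstem response.

    Wave-I amplitude falls and wave-V amplitude rises with tone frequency
    in the default maps, the signature of a midbrain overrepresentation of
    high ultrasonic frequencies.
    """

    wave_latencies_ms: tuple = (1.5, 2.5, 3.5, 4.6, 5.7)
    waveI_amp_vs_freq: dict = field(
        default_factory=lambda: {8: 1.20, 16: 1.00, 32: 0.75, 64: 0.50, 80: 0.35}
    )
    waveV_amp_vs_freq: dict = field(
        default_factory=lambda: {8: 0.35, 16: 0.50, 32: 0.70, 64: 1.00, 80: 1.20}
    )
    mid_wave_amps_uv: tuple = (0.5, 0.45, 0.4)  # waves II-IV, frequency-independent
    noise_sd_uv: float = 2.0
    n_sweeps: int = 500
    sample_rate_hz: float = 25000.0
    window_ms: float = 10.0
    bump_sigma_ms: float = 0.15
    bump_sep_ms: float = 0.35  # trough precedes peak by this much

    def __post_init__(self) -> None:
        lat = list(self.wave_latencies_ms)
        if len(lat) != 5 or any(b <= a for a, b in zip(lat, lat[1:])):
            raise ValidationError("wave latencies must be 5 strictly increasing values")
        if not all(0.0 < t < self.window_ms for t in lat):
            raise ValidationError("wave latencies must lie within the analysis window")
        if self.noise_sd_uv < 0:
            raise ValidationError("noise_sd_uv must be non-negative")


# ---------------------------------------------------------------------------
# Stimulus waveforms
# ---------------------------------------------------------------------------


def level_to_amplitude(level_db_spl: float) -> float:
    """Peak amplitude for a given level (94 dB SPL == 1.0 full scale)."""
    return 10.0 ** ((level_db_spl - LEVEL_REF_DB) / 20.0)


def make_tone_pip(
    freq_khz: float,
    level_db_spl: float,
    duration_ms: float = 50.0,
    ramp_ms: float = 2.0,
    sample_rate_hz: float = 192000.0,
) -> np.ndarray:
    """Synthesize a tone pip with raised-cosine on/off ramps.

    The waveform is exactly zero at its first and last sample.
    """
    f_hz = freq_khz * 1000.0
    if sample_rate_hz < 2.2 * f_hz:
        raise ParameterError(
            f"sample rate {sample_rate_hz} Hz too low for a {freq_khz} kHz tone"
        )
    if 2 * ramp_ms > duration_ms:
        raise ParameterError("ramps longer than the pip itself")
    n = int(round(duration_ms / 1000.0 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    t_end = (n - 1) / sample_rate_hz
    env = np.ones(n)
    ramp_s = ramp_ms / 1000.0
    if ramp_s > 0:
        on = t < ramp_s
        env[on] = 0.5 * (1.0 - np.cos(np.pi * t[on] / ramp_s))
        off = t > t_end - ramp_s
        env[off] = 0.5 * (1.0 - np.cos(np.pi * (t_end - t[off]) / ramp_s))
    amp = level_to_amplitude(level_db_spl)
    return amp * env * np.sin(2.0 * np.pi * f_hz * t)


def make_call(spec: CallSpec, sample_rate_hz: float = 192000.0) -> np.ndarray:
    """Synthesize a call as a log-linear FM sweep with optional AM.

    Instantaneous frequency runs from ``f_start_khz`` to ``f_end_khz`` and
    never leaves the 60-90 kHz band (enforced by :class:`CallSpec`).
    """
    f_hi = max(spec.f_start_khz, spec.f_end_khz) * 1000.0
    if sample_rate_hz < 2.2 * f_hi:
        raise ParameterError(
            f"sample rate {sample_rate_hz} Hz too low for a {f_hi / 1000.0} kHz call"
        )
    n = int(round(spec.duration_ms / 1000.0 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    T = spec.duration_ms / 1000.0
    f0 = spec.f_start_khz * 1000.0
    f1 = spec.f_end_khz * 1000.0
    if abs(f1 - f0) < 1e-9:
        phase = 2.0 * np.pi * f0 * t
    else:
        k = math.log(f1 / f0) / T
        phase = 2.0 * np.pi * f0 * (np.exp(k * t) - 1.0) / k
    env = np.ones(n)
    if spec.am_depth > 0:
        env *= 1.0 - 0.5 * spec.am_depth * (1.0 - np.cos(2.0 * np.pi * 100.0 * t))
    # 1 ms raised-cosine gates to avoid spectral splatter outside the band
    ramp_s = 1e-3
    t_end = (n - 1) / sample_rate_hz
    on = t < ramp_s
    env[on] *= 0.5 * (1.0 - np.cos(np.pi * t[on] / ramp_s))
    off = t > t_end - ramp_s
    env[off] *= 0.5 * (1.0 - np.cos(np.pi * (t_end - t[off]) / ramp_s))
    return level_to_amplitude(spec.level_db_spl) * env * np.sin(phase)


def call_frequency_trajectory(spec: CallSpec, n_points: int = 64) -> np.ndarray:
    """Instantaneous frequency (kHz) of the call at n evenly spaced times."""
    u = np.linspace(0.0, 1.0, n_points)
    if abs(spec.f_end_khz - spec.f_start_khz) < 1e-9:
        return np.full(n_points, spec.f_start_khz)
    return spec.f_start_khz * (spec.f_end_khz / spec.f_start_khz) ** u


# ---------------------------------------------------------------------------
# Rate model
# ---------------------------------------------------------------------------


def driven_excess_hz(neuron: NeuronSpec, freq_khz: float, level_db_spl: float):
    """Driven-rate excess (Hz above spontaneous) of the V-shaped response area.

    Vectorized over ``freq_khz``.
    """
    dl = level_db_spl - neuron.threshold_db
    f = np.asarray(freq_khz, dtype=float)
    if dl <= 0:
        return np.zeros_like(f) if f.ndim else 0.0
    w = neuron.q_sharpness * dl / 20.0
    d = np.abs(np.log2(f / neuron.cf_khz))
    out = neuron.max_rate_hz * np.clip(1.0 - d / w, 0.0, None)
    return out if f.ndim else float(out)


def call_drives(neuron: NeuronSpec, call: CallSpec) -> bool:
    """True iff the call's frequency trajectory enters the neuron's
    response area at the call's presentation level."""
    traj = call_frequency_trajectory(call)
    return bool(np.any(driven_excess_hz(neuron, traj, call.level_db_spl) > 0.0))


def _class_envelope(neuron: NeuronSpec, tau_ms: np.ndarray) -> np.ndarray:
    """Unit-scale temporal envelope of the driven response, by PSTH class.

    ``tau_ms`` is time since response onset (stimulus onset + latency).
    """
    tau = np.asarray(tau_ms, dtype=float)
    cls = neuron.psth_class
    if cls == "onset":
        return np.exp(-tau / 1.5)
    if cls == "chopper":
        # regular intrinsic oscillation, ~4 ms chopping period
        return 0.5 * (1.0 + 0.9 * np.cos(2.0 * np.pi * tau / 4.0))
    env = 0.4 + 0.6 * np.exp(-tau / neuron.adaptation_tau_ms)
    if cls == "pri-N":
        env = env * (1.0 - 0.85 * np.exp(-0.5 * ((tau - 4.0) / 1.0) ** 2))
    return env


def rate_function(
    neuron: NeuronSpec,
    stim: StimulusEvent | CallSpec,
    dt_ms: float = 0.25,
    pre_ms: float = 0.0,
    post_ms: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate profile (Hz) of a neuron in response to one stimulus.

    Returns ``(t_ms, rate_hz)`` with t relative to stimulus onset, covering
    ``[-pre_ms, duration + post_ms]``.  Outside the driven epoch the rate
    equals the spontaneous rate; after stimulus offset the driven component
    decays with a 2 ms time constant.
    """
    if isinstance(stim, CallSpec):
        dur = stim.duration_ms
        level = stim.level_db_spl
        traj_fn = lambda tt: np.interp(
            tt / dur, np.linspace(0, 1, 64), call_frequency_trajectory(stim)
        )
        excess_of_t = lambda tt: driven_excess_hz(neuron, traj_fn(tt), level)
    elif stim.kind == "tone":
        dur = stim.duration_ms
        exc = driven_excess_hz(neuron, stim.freq_khz, stim.level_db_spl)
        excess_of_t = lambda tt: np.full_like(tt, exc, dtype=float)
    elif stim.kind == "click":
        dur = stim.duration_ms
        exc = neuron.max_rate_hz if stim.level_db_spl > neuron.threshold_db else 0.0
        excess_of_t = lambda tt: np.full_like(tt, exc, dtype=float)
    else:  # recorded call event: frequency trajectory unknown; not supported here
        raise ParameterError("rate_function needs a CallSpec for call stimuli")

    t = np.arange(-pre_ms, dur + post_ms + dt_ms / 2, dt_ms)
    rate = np.full_like(t, neuron.spont_rate_hz)
    lat = neuron.fsl_ms
    tau = t - lat
    in_resp = tau >= 0.0
    if np.any(in_resp):
        tt = np.clip(tau[in_resp], 0.0, dur)  # stimulus time for the excess
        exc = excess_of_t(tt) * _class_envelope(neuron, tau[in_resp])
        # decay after stimulus offset
        past_off = tau[in_resp] > dur
        decay = np.ones(exc.shape)
        decay[past_off] = np.exp(-(tau[in_resp][past_off] - dur) / 2.0)
        rate[in_resp] += exc * decay
    return t, rate


# ---------------------------------------------------------------------------
# Spike-train simulation
# ---------------------------------------------------------------------------


def simulate_spike_train(
    t_ms: np.ndarray,
    rate_hz: np.ndarray,
    gamma_order: float = 1.0,
    refractory_ms: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Simulate a time-rescaled gamma-renewal spike train.

    The inhomogeneous rate ``rate_hz`` (piecewise linear on the grid
    ``t_ms``) is integrated to rescaled time, where interspike intervals are
    i.i.d. Gamma(k, 1/k) with k = ``gamma_order`` (unit mean); spike times
    are mapped back through the inverse integral.  An absolute refractory
    period is imposed as dead time during which no rescaled time accrues.

    Returns spike times in ms on the same clock as ``t_ms``.
    """
    t = np.asarray(t_ms, dtype=float)
    r = np.asarray(rate_hz, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ParameterError("t_ms and rate_hz must be matching 1-D arrays")
    if np.any(r < 0):
        raise ParameterError("rates must be non-negative")
    if gamma_order <= 0:
        raise ParameterError("gamma_order must be positive")
    rng = _rng(seed)
    # cumulative expected count (trapezoid), in spikes; time in seconds
    if t.size < 2:
        return np.array([])
    dt_s = np.diff(t) / 1000.0
    seg = 0.5 * (r[:-1] + r[1:]) * dt_s
    L = np.concatenate([[0.0], np.cumsum(seg)])
    total = L[-1]
    if total <= 0:
        return np.array([])

    k = gamma_order

    def draw(n):
        return rng.gamma(k, 1.0 / k, size=n)

    if refractory_ms <= 0:
        # fully vectorized: draw more than enough intervals
        n_guess = int(total + 6.0 * math.sqrt(total / k) + 20)
        isis = draw(n_guess)
        s = np.cumsum(isis)
        while s[-1] < total:
            isis = draw(n_guess)
            s = np.concatenate([s, s[-1] + np.cumsum(isis)])
        s = s[s <= total]
        return np.interp(s, L, t)

    spikes = []
    s_cur = 0.0
    buf = draw(max(16, int(total + 6.0 * math.sqrt(total / k) + 20)))
    i_buf = 0
    while True:
        if i_buf >= buf.size:
            buf = draw(buf.size)
            i_buf = 0
        s_next = s_cur + buf[i_buf]
        i_buf += 1
        if s_next > total:
            break
        t_spk = float(np.interp(s_next, L, t))
        spikes.append(t_spk)
        t_dead_end = t_spk + refractory_ms
        if t_dead_end >= t[-1]:
            break
        s_cur = float(np.interp(t_dead_end, t, L))
    return np.asarray(spikes)


# ---------------------------------------------------------------------------
# Extracellular trace rendering
# ---------------------------------------------------------------------------


def biphasic_template(
    sample_rate_hz: float,
    duration_ms: float = 1.0,
    trough_frac: float = 0.35,
    amp_v: float = 100e-6,
    width_frac: float = 0.12,
) -> np.ndarray:
    """A canonical biphasic (negative-then-positive) action-potential shape."""
    n = int(round(duration_ms / 1000.0 * sample_rate_hz))
    u = np.linspace(0.0, 1.0, n)
    neg = np.exp(-0.5 * ((u - trough_frac) / width_frac) ** 2)
    pos = 0.55 * np.exp(-0.5 * ((u - trough_frac - 2.2 * width_frac) / (1.6 * width_frac)) ** 2)
    w = pos - neg
    return amp_v * w / np.max(np.abs(w))


def render_trace(
    units: list[UnitSpikes],
    templates: dict[str, np.ndarray],
    noise_sd: float,
    sample_rate_hz: float,
    duration_ms: float | None = None,
    gains: dict[str, float] | None = None,
    seed=None,
    channel_id: str = "ch0",
) -> Trace:
    """Render an extracellular voltage trace as spike trains convolved with
    per-unit templates plus white Gaussian noise (single channel)."""
    rng = _rng(seed)
    gains = gains or {}
    if duration_ms is None:
        last = max((u.spike_times_ms[-1] for u in units if len(u)), default=0.0)
        tmpl_ms = max(
            (len(tp) / sample_rate_hz * 1000.0 for tp in templates.values()), default=1.0
        )
        duration_ms = last + tmpl_ms + 5.0
    n = int(round(duration_ms / 1000.0 * sample_rate_hz))
    sig = np.zeros(n)
    for u in units:
        tmpl = templates[u.unit_id] * gains.get(u.unit_id, 1.0)
        if tmpl.size > n:
            raise ParameterError("template longer than the trace")
        idx = np.round(u.spike_times_ms / 1000.0 * sample_rate_hz).astype(int)
        for i in idx:
            if 0 <= i and i + tmpl.size <= n:
                sig[i : i + tmpl.size] += tmpl
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return Trace(sig[None, :], sample_rate_hz, [channel_id], start_time_ms=0.0)


# ---------------------------------------------------------------------------
# ABR simulation
# ---------------------------------------------------------------------------


def _abr_bump(t_ms: np.ndarray, latency_ms: float, sigma_ms: float, sep_ms: float) -> np.ndarray:
    """Biphasic bump: trough at ``latency - sep``, peak at ``latency``,
    normalized so (peak - antecedent trough) == 1 in continuous time."""
    peak = np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)
    trough = np.exp(-0.5 * ((t_ms - latency_ms + sep_ms) / sigma_ms) ** 2)
    b = peak - trough
    # normalization on a fine grid (shape depends only on sep/sigma)
    tf = np.linspace(-6 * sigma_ms - sep_ms, 6 * sigma_ms, 4001)
    bf = np.exp(-0.5 * (tf / sigma_ms) ** 2) - np.exp(-0.5 * ((tf + sep_ms) / sigma_ms) ** 2)
    scale = bf.max() - bf[: bf.argmax()].min()
    return b / scale


def abr_clean_waveform(spec: ABRSpec, stim_freq_khz: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free ABR waveform (µV) for one tone frequency.

    Returns ``(t_ms, waveform_uv)`` over [0, window_ms).
    """
    key = int(stim_freq_khz)
    if key not in spec.waveI_amp_vs_freq or key not in spec.waveV_amp_vs_freq:
        raise ParameterError(
            f"no wave amplitudes defined for {stim_freq_khz} kHz "
            f"(known: {sorted(spec.waveI_amp_vs_freq)})"
        )
    n = int(round(spec.window_ms / 1000.0 * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz * 1000.0
    amps = (
        spec.waveI_amp_vs_freq[key],
        *spec.mid_wave_amps_uv,
        spec.waveV_amp_vs_freq[key],
    )
    wave = np.zeros(n)
    for amp, lat in zip(amps, spec.wave_latencies_ms):
        wave += amp * _abr_bump(t, lat, spec.bump_sigma_ms, spec.bump_sep_ms)
    return t, wave


def simulate_abr(spec: ABRSpec, stim_freq_khz: float, seed=None) -> np.ndarray:
    """Simulate an ABR sweep set: [n_sweeps x n_samples] in µV."""
    rng = _rng(seed)
    _, clean = abr_clean_waveform(spec, stim_freq_khz)
    sweeps = np.tile(clean, (spec.n_sweeps, 1))
    if spec.noise_sd_uv > 0:
        sweeps = sweeps + rng.normal(0.0, spec.noise_sd_uv, size=sweeps.shape)
    return sweeps


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

_STATION_PROFILES = {
    # CF log-normal center/spread and call-band fraction by station.
    # AN and DCN tuning peaks at 20-30 kHz; ICC modes above 40 kHz with a
    # large call-band fraction.
    "AN": dict(cf_log_mean_khz=25.0, cf_log_sd_oct=0.6, fraction_high_f=0.075),
    "DCN": dict(cf_log_mean_khz=25.0, cf_log_sd_oct=0.7, fraction_high_f=0.095),
    "ICC": dict(cf_log_mean_khz=48.0, cf_log_sd_oct=0.8, fraction_high_f=0.60),
}


def station_profile(station: str, n_units: int, n_animals: int = 5, seed: int = 0) -> PopulationSpec:
    """Default population spec for a recording station."""
    return PopulationSpec(
        n_units=n_units, station=station, n_animals=n_animals, seed=seed,
        **_STATION_PROFILES[station],
    )


def make_session_schedule(
    calls: list[CallSpec] | None = None,
    n_call_reps: int = 20,
    fra_step_oct: float | None = 0.2,
    fra_n_reps: int = 2,
    level_lo_db: float = 15.0,
    level_hi_db: float = 100.0,
    level_step_db: float = 5.0,
    freq_lo_khz: float = 2.0,
    freq_hi_khz: float = 90.0,
    tone_duration_ms: float = 50.0,
    period_ms: float = 150.0,
    session_id: str = "",
    animal_id: str = "",
    seed: int = 0,
) -> Schedule:
    """Build a stimulation schedule: an interleaved tone-pip grid for the
    frequency response area (one tone every ``period_ms``) followed by
    repeated call presentations.

    Set ``fra_step_oct=None`` to omit the tone grid, or ``calls=None`` with
    ``n_call_reps=0`` to omit the calls.
    """
    rng = _rng(seed)
    events: list[StimulusEvent] = []
    onset = period_ms
    if fra_step_oct is not None:
        n_f = int(math.floor(math.log2(freq_hi_khz / freq_lo_khz) / fra_step_oct)) + 1
        freqs = freq_lo_khz * 2.0 ** (fra_step_oct * np.arange(n_f))
        levels = np.arange(level_lo_db, level_hi_db + level_step_db / 2, level_step_db)
        grid = [(f, l) for f in freqs for l in levels for _ in range(fra_n_reps)]
        order = rng.permutation(len(grid))
        for j in order:
            f, l = grid[j]
            events.append(
                StimulusEvent(
                    onset_ms=onset, kind="tone", freq_khz=float(f),
                    level_db_spl=float(l), duration_ms=tone_duration_ms,
                )
            )
            onset += period_ms
    if calls and n_call_reps > 0:
        pres = [c for c in calls for _ in range(n_call_reps)]
        order = rng.permutation(len(pres))
        for j in order:
            events.append(pres[j].to_event(onset))
            onset += period_ms
    return Schedule(events, session_id=session_id, animal_id=animal_id)


def draw_neuron_specs(spec: PopulationSpec, calls: list[CallSpec], seed=None) -> list[NeuronSpec]:
    """Draw ground-truth neurons for a station population.

    A ``fraction_high_f`` share of units get CFs inside the 60-90 kHz call
    band; the rest are drawn from the station's log-normal CF profile,
    redrawn until their response area at 80 dB SPL stays below 60 kHz (so
    ``responds_to_calls`` cleanly tracks the high-frequency group).
    """
    rng = _rng(spec.seed if seed is None else seed)
    lo, hi = CALL_BAND_KHZ
    neurons = []
    n_high = int(round(spec.fraction_high_f * spec.n_units))
    for i in range(spec.n_units):
        high = i < n_high
        threshold = float(rng.uniform(25.0, 45.0))
        q = float(rng.uniform(0.2, 0.4))
        if high:
            cf = float(lo * (hi / lo) ** rng.uniform(0.1, 0.9))
        else:
            for _ in range(1000):
                cf = float(
                    spec.cf_log_mean_khz * 2.0 ** rng.normal(0.0, spec.cf_log_sd_oct)
                )
                upper_edge = cf * 2.0 ** (q * (90.0 - threshold) / 20.0)
                if 2.0 <= cf and upper_edge < lo:
                    break
            else:  # pragma: no cover - profile too extreme to truncate
                raise ValidationError("could not draw a low-frequency CF")
        # AN-fiber-like dynamics: primary class, irregular ISIs, short latency
        neuron = NeuronSpec(
            cf_khz=cf,
            threshold_db=threshold,
            q_sharpness=q,
            max_rate_hz=float(rng.uniform(250.0, 400.0)),
            spont_rate_hz=float(rng.uniform(4.0, 15.0)),
            psth_class="primary",
            adaptation_tau_ms=float(rng.uniform(3.0, 8.0)),
            gamma_order=1.0,
            refractory_ms=0.8,
            fsl_ms=float(rng.uniform(2.0, 4.0)),
        )
        neuron.responds_to_calls = any(call_drives(neuron, c) for c in calls)
        neurons.append(neuron)
    return neurons


def simulate_unit_response(
    neuron: NeuronSpec,
    schedule: Schedule,
    calls: list[CallSpec] | None = None,
    dt_ms: float = 0.25,
    tail_ms: float = 100.0,
    seed=None,
) -> np.ndarray:
    """Simulate one unit's spike train over a whole session.

    The session rate profile is spontaneous everywhere, with each event's
    driven profile (from :func:`rate_function`) added at its onset.  Call
    events are matched to ``calls`` by ``call_id`` to recover frequency
    trajectories.  Returns spike times in ms on the session clock.
    """
    call_map = {c.call_id: c for c in (calls or [])}
    t_end = (schedule.events[-1].offset_ms + tail_ms) if len(schedule) else tail_ms
    n = int(round(t_end / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    rate = np.full(n, neuron.spont_rate_hz)
    for ev in schedule:
        stim = call_map[ev.call_id] if ev.kind == "call" else ev
        tt, rr = rate_function(neuron, stim, dt_ms=dt_ms, post_ms=30.0)
        i0 = int(round(ev.onset_ms / dt_ms))
        i1 = min(i0 + rr.size, n)
        rate[i0:i1] += rr[: i1 - i0] - neuron.spont_rate_hz
    return simulate_spike_train(
        t, rate, gamma_order=neuron.gamma_order,
        refractory_ms=neuron.refractory_ms, seed=seed,
    )


def simulate_population(
    spec: PopulationSpec,
    schedule: Schedule,
    calls: list[CallSpec] | None = None,
    dt_ms: float = 0.25,
) -> tuple[list[UnitSpikes], pd.DataFrame]:
    """Simulate a station population's responses to a stimulus schedule.

    Returns the simulated spike trains and a ground-truth table with each
    unit's CF, threshold, construction F_max (highest grid frequency inside
    the response area at the highest tested level), and whether the calls
    drive it.
    """
    rng = _rng(spec.seed)
    calls = calls if calls is not None else default_call_bank()
    neurons = draw_neuron_specs(spec, calls, seed=rng)
    tone_freqs = sorted({e.freq_khz for e in schedule if e.kind == "tone"})
    max_level = max((e.level_db_spl for e in schedule if e.kind == "tone"), default=100.0)
    units, rows = [], []
    for i, neuron in enumerate(neurons):
        animal = f"{spec.station.lower()}-a{i % spec.n_animals + 1:02d}"
        uid = f"{spec.station.lower()}-u{i + 1:04d}"
        spikes = simulate_unit_response(
            neuron, schedule, calls=calls, dt_ms=dt_ms, seed=rng
        )
        units.append(UnitSpikes(uid, animal, spec.station, spikes, source="simulated"))
        if tone_freqs:
            exc = driven_excess_hz(neuron, np.array(tone_freqs), max_level)
            driven = np.nonzero(exc > 0)[0]
            fmax_true = tone_freqs[driven[-1]] if driven.size else np.nan
        else:
            fmax_true = np.nan
        rows.append(
            {
                "unit_id": uid,
                "animal_id": animal,
                "station": spec.station,
                "cf_khz": neuron.cf_khz,
                "threshold_db": neuron.threshold_db,
                "q_sharpness": neuron.q_sharpness,
                "max_rate_hz": neuron.max_rate_hz,
                "spont_rate_hz": neuron.spont_rate_hz,
                "psth_class": neuron.psth_class,
                "gamma_order": neuron.gamma_order,
                "fsl_ms": neuron.fsl_ms,
                "fmax_true_khz": fmax_true,
                "responds_to_calls": neuron.responds_to_calls,
                "n_spikes": len(spikes),
            }
        )
    truth = pd.DataFrame(rows)
    return units, truth
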