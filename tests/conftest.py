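import numpy as np
import pytest

from ultracoll.signal_io import Schedule, StimulusEvent, UnitSpikes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_schedule(n_trials, freq_khz=20.0, level_db=65.0, duration_ms=50.0, period_ms=150.0):
    """Repeated presentations of one tone (CF-tone protocol)."""
    return Schedule(
        [
            StimulusEvent(
                onset_ms=period_ms * (i + 1),
                kind="tone",
                freq_khz=freq_khz,
                level_db_spl=level_db,
                duration_ms=duration_ms,
            )
            for i in range(n_trials)
        ]
    )


def unit_from_relative(rel_times_by_trial, schedule, unit_id="u1", station="AN"):
    """Build a UnitSpikes from per-trial spike times relative to onset."""
    times = []
    for rel, ev in zip(rel_times_by_trial, schedule.events):
        times.extend(ev.onset_ms + t for t in rel)
    return UnitSpikes(unit_id, "a1", station, np.sort(times), source="simulated")


@pytest.fixture
def tone_schedule_factory():
    return tone_schedule


@pytest.fixture
def unit_factory():
    return unit_from_relative
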