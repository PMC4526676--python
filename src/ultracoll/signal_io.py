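"""Core data model and on-disk formats.

Every stage of the pipeline consumes and produces the types defined here:
raw voltage :class:`Trace` objects, stimulus :class:`Schedule` objects, and
sorted/simulated :class:`UnitSpikes`.  Units are fixed across the package:
time in milliseconds on a single session clock, frequency in kHz, sound
level in dB SPL, voltage in volts (ABR waveforms in microvolts).

On disk, traces are float32 little-endian binary (channel-major) with a JSON
sidecar, schedules and spike tables are plain CSV, and stimulus audio is
WAV.  All readers and writers round-trip bit-exactly on valid inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

STATIONS = ("AN", "DCN", "ICC")
STIM_KINDS = ("tone", "click", "call")


class UltracollError(Exception):
    """Base class for all package errors."""


class FormatError(UltracollError):
    """A file does not conform to its declared binary/CSV layout."""


class ConfigError(UltracollError):
    """A sidecar or configuration object is missing required keys."""


class DataError(UltracollError):
    """Data values violate basic sanity (NaN/Inf, quality failures)."""


class ValidationError(UltracollError):
    """A domain-type invariant is violated."""


class ParameterError(UltracollError):
    """An operation was called with out-of-range parameters."""


class InsufficientDataError(UltracollError):
    """Not enough data to compute the requested statistic."""


class ClusteringError(UltracollError):
    """Mixture fitting failed for every candidate model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """A uniformly sampled multi-channel voltage record.

    ``samples`` is [channels x time] in volts.  ``start_time_ms`` is the
    session-clock time of sample 0, so event onsets and spike times live on
    the same axis as the raw signal.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_ids: list[str]
    start_time_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sample_rate_hz <= 0:
            raise ValidationError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValidationError(
                f"{self.samples.shape[0]} channels of data but "
                f"{len(self.channel_ids)} channel ids"
            )
        if not np.all(np.isfinite(self.samples)):
            raise DataError("trace contains NaN or Inf samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sample_rate_hz * 1000.0

    def times_ms(self) -> np.ndarray:
        """Session-clock time of each sample."""
        return self.start_time_ms + np.arange(self.n_samples) / self.sample_rate_hz * 1000.0


@dataclass
class StimulusEvent:
    """A single timed stimulus marker (tone pip, click, or vocalization)."""

    onset_ms: float
    kind: str
    level_db_spl: float
    duration_ms: float
    freq_khz: float | None = None
    call_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in STIM_KINDS:
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValidationError("duration_ms must be positive")
        if self.kind == "tone":
            if self.freq_khz is None or self.freq_khz <= 0:
                raise ValidationError("tone events require a positive freq_khz")
            if self.call_id is not None:
                raise ValidationError("tone events must not carry a call_id")
        elif self.kind == "call":
            if self.call_id is None:
                raise ValidationError("call events require a call_id")
            if self.freq_khz is not None:
                raise ValidationError("call events must not carry freq_khz")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class Schedule:
    """An ordered, non-overlapping list of stimulus events for one session."""

    events: list[StimulusEvent]
    session_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        onsets = [e.onset_ms for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("events must be sorted by onset_ms")
        for a, b in zip(self.events, self.events[1:]):
            if a.offset_ms > b.onset_ms:
                raise ValidationError(
                    f"events overlap: one ending {a.offset_ms} ms, next starting "
                    f"{b.onset_ms} ms"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def subset(self, kind: str | None = None, call_id: str | None = None) -> "Schedule":
        ev = [
            e
            for e in self.events
            if (kind is None or e.kind == kind)
            and (call_id is None or e.call_id == call_id)
        ]
        return Schedule(ev, session_id=self.session_id, animal_id=self.animal_id)

    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events], dtype=float)


@dataclass
class UnitSpikes:
    """Spike times of one unit (sorted or simulated), on the session clock."""

    unit_id: str
    animal_id: str
    station: str
    spike_times_ms: np.ndarray
    source: str = "sorted"

    def __post_init__(self) -> None:
        if self.station not in STATIONS:
            raise ValidationError(f"station must be one of {STATIONS}, got {self.station!r}")
        if self.source not in ("sorted", "simulated"):
            raise ValidationError(f"source must be 'sorted' or 'simulated', got {self.source!r}")
        t = np.asarray(self.spike_times_ms, dtype=np.float64)
        if t.size and not np.all(np.isfinite(t)):
            raise DataError("spike times contain NaN or Inf")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("spike_times_ms must be strictly increasing")
        self.spike_times_ms = t

    def __len__(self) -> int:
        return self.spike_times_ms.size


# ---------------------------------------------------------------------------
# Trace I/O: float32 binary + JSON sidecar
# ---------------------------------------------------------------------------

_SIDECAR_KEYS = ("sample_rate_hz", "channel_ids", "start_time_ms")


def read_trace(path: str | Path, sidecar: str | Path) -> Trace:
    """Read a channel-major float32 little-endian binary trace.

    The JSON sidecar must define ``sample_rate_hz``, ``channel_ids`` and
    ``start_time_ms``.
    """
    with open(sidecar) as fh:
        meta = json.load(fh)
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ConfigError(f"sidecar {sidecar} missing keys: {missing}")
    channel_ids = [str(c) for c in meta["channel_ids"]]
    n_ch = len(channel_ids)
    raw = np.fromfile(path, dtype="<f4")
    if n_ch == 0 or raw.size % n_ch:
        raise FormatError(
            f"{path}: {raw.size} float32 samples not divisible by {n_ch} channels"
        )
    samples = raw.reshape(n_ch, -1)
    if not np.all(np.isfinite(samples)):
        raise DataError(f"{path}: trace contains non-finite samples")
    return Trace(
        samples=samples,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        channel_ids=channel_ids,
        start_time_ms=float(meta["start_time_ms"]),
    )


def write_trace(trace: Trace, path: str | Path, sidecar: str | Path) -> None:
    trace.samples.astype("<f4").tofile(path)
    meta = {
        "sample_rate_hz": trace.sample_rate_hz,
        "channel_ids": list(trace.channel_ids),
        "start_time_ms": trace.start_time_ms,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Schedule I/O: CSV with a fixed header
# ---------------------------------------------------------------------------

_SCHEDULE_COLS = ["onset_ms", "kind", "freq_khz", "level_db_spl", "duration_ms", "call_id"]


def read_schedule(path: str | Path, session_id: str = "", animal_id: str = "") -> Schedule:
    """Read a stimulus schedule CSV (header required, '.' decimal, UTF-8).

    Rows out of time order are sorted with a logged warning; overlapping
    events raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype={"kind": str, "call_id": str}, float_precision="round_trip")
    missing = [c for c in _SCHEDULE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: schedule CSV missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        freq = None if pd.isna(row["freq_khz"]) else float(row["freq_khz"])
        call = None if pd.isna(row["call_id"]) else str(row["call_id"])
        try:
            events.append(
                StimulusEvent(
                    onset_ms=float(row["onset_ms"]),
                    kind=str(row["kind"]),
                    freq_khz=freq,
                    level_db_spl=float(row["level_db_spl"]),
                    duration_ms=float(row["duration_ms"]),
                    call_id=call,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
    onsets = [e.onset_ms for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        log.warning("%s: events out of time order; sorting by onset", path)
        events.sort(key=lambda e: e.onset_ms)
    return Schedule(events, session_id=session_id, animal_id=animal_id)


def write_schedule(schedule: Schedule, path: str | Path) -> None:
    rows = [
        {
            "onset_ms": e.onset_ms,
            "kind": e.kind,
            "freq_khz": "" if e.freq_khz is None else repr(float(e.freq_khz)),
            "level_db_spl": e.level_db_spl,
            "duration_ms": e.duration_ms,
            "call_id": "" if e.call_id is None else e.call_id,
        }
        for e in schedule.events
    ]
    pd.DataFrame(rows, columns=_SCHEDULE_COLS).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


# ---------------------------------------------------------------------------
# Spike table I/O
# ---------------------------------------------------------------------------


def read_spikes(path: str | Path, source: str = "sorted") -> list[UnitSpikes]:
    """Read a long-format spike CSV (unit_id,animal_id,station,spike_time_ms)."""
    df = pd.read_csv(
        path,
        dtype={"unit_id": str, "animal_id": str, "station": str},
        float_precision="round_trip",
    )
    needed = ["unit_id", "animal_id", "station", "spike_time_ms"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: spike CSV missing columns {missing}")
    units = []
    for (uid, aid, station), grp in df.groupby(
        ["unit_id", "animal_id", "station"], sort=True
    ):
        times = np.sort(grp["spike_time_ms"].to_numpy(dtype=float))
        units.append(UnitSpikes(uid, aid, station, times, source=source))
    return units


def write_spikes(units: Iterable[UnitSpikes], path: str | Path) -> None:
    frames = []
    for u in units:
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": u.unit_id,
                    "animal_id": u.animal_id,
                    "station": u.station,
                    "spike_time_ms": u.spike_times_ms,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "animal_id", "station", "spike_time_ms"])
    )
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Stimulus audio
# ---------------------------------------------------------------------------


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate_hz: float) -> None:
    """Write a stimulus waveform as 32-bit float WAV."""
    wavfile.write(path, int(round(sample_rate_hz)), np.asarray(waveform, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV stimulus; returns (waveform as float64, sample_rate_hz)."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":  # normalize PCM to full scale
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return data.astype(np.float64), float(rate)
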