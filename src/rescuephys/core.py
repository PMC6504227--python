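"""Shared domain types and error classes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

GENOTYPES = ("+/+", "+/ls", "+/-")
CRE_LEVELS = ("-", "+")
TMX_LEVELS = ("-", "+")
PHASES = ("I", "II")

WAKE = "wake"
SLEEP = "sleep"


class ParameterError(ValueError):
    """Invalid generator or analysis parameters."""


class ContractError(ValueError):
    """A precondition of an operation was violated."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information."""


class GenerationError(RuntimeError):
    """A stochastic generator could not satisfy its constraints."""


@dataclass
class Recording:
    """Multichannel fixed-rate electrophysiology recording.

    Channels are named series of equal length; ``hlfp`` is expected in mV.
    ``meta`` carries animal_id / genotype / cre / tmx / phase labels.
    """

    channels: dict[str, np.ndarray]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ContractError(f"sampling rate must be positive, got {self.fs}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ContractError(f"channels have unequal lengths: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ContractError(
                f"channel {name!r} missing (have {sorted(self.channels)})"
            )
        return self.channels[name]

    def slice(self, start_s: float, end_s: float) -> "Recording":
        i0 = max(0, int(round(start_s * self.fs)))
        i1 = min(self.n_samples, int(round(end_s * self.fs)))
        return Recording(
            channels={k: v[i0:i1].copy() for k, v in self.channels.items()},
            fs=self.fs,
            meta=dict(self.meta),
        )


@dataclass
class StateIntervals:
    """Disjoint, sorted wake/sleep intervals tiling a recording."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, state in self.intervals:
            if end <= start:
                raise ContractError(f"zero/negative-length interval ({start}, {end})")
            if state not in (WAKE, SLEEP):
                raise ContractError(f"unknown state {state!r}")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ContractError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return sum(end - start for start, end, _ in self.intervals)

    def total_time(self, state: str) -> float:
        return sum(end - start for start, end, s in self.intervals if s == state)

    def state_at(self, t: float) -> Optional[str]:
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        # a time exactly at the final boundary belongs to the last interval
        if self.intervals and abs(t - self.intervals[-1][1]) < 1e-9:
            return self.intervals[-1][2]
        return None

    def sample_labels(self, n_samples: int, fs: float) -> np.ndarray:
        """Per-sample state labels (object array of 'wake'/'sleep')."""
        labels = np.empty(n_samples, dtype=object)
        for start, end, state in self.intervals:
            i0 = int(round(start * fs))
            i1 = min(n_samples, int(round(end * fs)))
            labels[i0:i1] = state
        return labels

    @classmethod
    def from_bool(cls, is_sleep: np.ndarray, fs: float) -> "StateIntervals":
        """Build intervals from a per-sample boolean sleep mask."""
        is_sleep = np.asarray(is_sleep, dtype=bool)
        n = len(is_sleep)
        if n == 0:
            return cls(intervals=[])
        edges = np.flatnonzero(np.diff(is_sleep.astype(int))) + 1
        bounds = np.concatenate([[0], edges, [n]])
        intervals = []
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            state = SLEEP if is_sleep[i0] else WAKE
            intervals.append((i0 / fs, i1 / fs, state))
        return cls(intervals=intervals)


@dataclass
class SpikeEvent:
    peak_time_s: float
    peak_amp_mV: float
    accepted: bool = True
    reject_reason: Optional[str] = None


@dataclass
class SpikeEvents:
    """Detected high-amplitude events, sorted by peak time."""

    events: list[SpikeEvent]
    threshold_mV: float = 1.0

    def __post_init__(self) -> None:
        times = [e.peak_time_s for e in self.events]
        if times != sorted(times):
            raise ContractError("events must be sorted by peak time")

    @property
    def accepted(self) -> list[SpikeEvent]:
        return [e for e in self.events if e.accepted]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class RateByState:
    """State-resolved accepted-event rates in events/min.

    A rate is ``None`` (flagged undefined) when the state has zero time.
    """

    wake_rate: Optional[float]
    sleep_rate: Optional[float]
    wake_time_s: float
    sleep_time_s: float
    n_wake: int
    n_sleep: int


@dataclass
class AmplitudeSpectrum:
    """Time-resolved wavelet amplitude: frequencies x samples.

    ``reliable`` is False where a sample lies within one wavelet half-support
    of either trace boundary (edge effects).
    """

    freqs_hz: np.ndarray
    amp: np.ndarray
    fs: float
    reliable: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ContractError("frequencies must be strictly increasing")
        if self.amp.shape != (len(self.freqs_hz), self.amp.shape[1]):
            raise ContractError("amp must be (n_freqs, n_samples)")
        if self.reliable.shape != self.amp.shape:
            raise ContractError("reliability mask must match amp shape")

    def band_rows(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        rows = np.flatnonzero((self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz))
        if len(rows) == 0:
            raise ContractError(f"no frequencies in band ({lo_hz}, {hi_hz}) Hz")
        return rows


@dataclass(frozen=True)
class BandDefs:
    """Analysis band edges in Hz."""

    theta: tuple[float, float] = (6.0, 12.0)
    delta: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        t0, t1 = self.theta
        d0, d1 = self.delta
        if not (t1 > t0 and d1 > d0):
            raise ParameterError("band edges must be increasing")
        if max(t0, d0) < min(t1, d1):
            raise ParameterError("theta and delta bands must not overlap")


def check_tiling(states: StateIntervals, duration_s: float, tol: float = 1e-6) -> None:
    """Raise unless `states` tiles [0, duration_s] without gaps."""
    if not states.intervals:
        raise ContractError("empty state intervals cannot tile a recording")
    if abs(states.intervals[0][0]) > tol:
        raise ContractError("state intervals do not start at 0")
    prev = 0.0
    for start, end, _ in states.intervals:
        if abs(start - prev) > tol:
            raise ContractError(f"gap in state intervals at {prev:.6f}s")
        prev = end
    if abs(prev - duration_s) > tol:
        raise ContractError(
            f"state intervals end at {prev:.6f}s, recording lasts {duration_s:.6f}s"
        )
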