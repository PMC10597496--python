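"""Synthetic stimulus generation and the event-history container.

Stimuli are modeled as independent homogeneous Poisson processes, one
excitatory and one inhibitory stream, with a configurable expected
inter-event interval (default 40 ms per stream).  Fixed-length stimulus
patterns are the last ``n_events`` events of a merged pair of streams,
shifted so the pattern starts at time 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import InputError

__all__ = ["EventLabel", "EventRecord", "EventHistory",
           "poisson_stream", "make_pattern", "DEFAULT_EXPECTED_INTERVAL"]

DEFAULT_EXPECTED_INTERVAL = 40.0  # ms, per stream


class EventLabel(IntEnum):
    """Event types; the integer order is the tie-break for simultaneous
    events (EXC < INH < OUTPUT_SPIKE)."""

    EXC = 0
    INH = 1
    OUTPUT_SPIKE = 2


@dataclass(frozen=True)
class EventRecord:
    time: float  # ms
    label: EventLabel

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise InputError(f"event time must be finite and >= 0, got {self.time}")


class EventHistory:
    """Time-ordered sequence of labeled events backed by numpy arrays."""

    EXC = int(EventLabel.EXC)
    INH = int(EventLabel.INH)
    OUTPUT_SPIKE = int(EventLabel.OUTPUT_SPIKE)

    def __init__(self, times, labels, *, check: bool = True):
        self._times = np.asarray(times, dtype=float)
        self._labels = np.asarray(labels, dtype=np.int8)
        if self._times.shape != self._labels.shape or self._times.ndim != 1:
            raise InputError("times and labels must be 1-D arrays of equal length")
        if check and self._times.size:
            if not np.all(np.isfinite(self._times)) or self._times.min() < 0:
                raise InputError("event times must be finite and >= 0")
            if not self.is_sorted():
                raise InputError("event times must be non-decreasing")

    # -- constructors -------------------------------------------------------
    @classmethod
    def empty(cls) -> "EventHistory":
        return cls(np.empty(0), np.empty(0, dtype=np.int8), check=False)

    @classmethod
    def from_records(cls, records) -> "EventHistory":
        recs = list(records)
        times = np.array([r.time for r in recs], dtype=float)
        labels = np.array([int(r.label) for r in recs], dtype=np.int8)
        return cls(times, labels)

    @classmethod
    def merge(cls, *histories) -> "EventHistory":
        """Merge sorted histories; ties resolve EXC < INH < OUTPUT_SPIKE."""
        times = np.concatenate([h.times for h in histories])
        labels = np.concatenate([h.labels for h in histories])
        order = np.lexsort((labels, times))
        return cls(times[order], labels[order], check=False)

    # -- views --------------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return self._times

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    def is_sorted(self) -> bool:
        return bool(np.all(np.diff(self._times) >= 0))

    def __len__(self) -> int:
        return self._times.size

    def __getitem__(self, i):
        if isinstance(i, slice):
            return EventHistory(self._times[i], self._labels[i], check=False)
        return EventRecord(float(self._times[i]), EventLabel(int(self._labels[i])))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventHistory):
            return NotImplemented
        return (np.array_equal(self._times, other._times)
                and np.array_equal(self._labels, other._labels))

    def __repr__(self) -> str:
        return f"EventHistory(n={len(self)})"

    def tail(self, n: int) -> "EventHistory":
        """The ``n`` most recent events (all events when fewer exist)."""
        if n <= 0:
            raise InputError("window size must be >= 1")
        return self[len(self) - min(n, len(self)):]

    def shifted(self, offset: float) -> "EventHistory":
        return EventHistory(self._times + offset, self._labels, check=False)

    def appended(self, record: EventRecord) -> "EventHistory":
        if len(self) and record.time < self._times[-1]:
            raise InputError("appended event would break time ordering")
        return EventHistory(np.append(self._times, record.time),
                            np.append(self._labels, np.int8(int(record.label))),
                            check=False)

    def select(self, label) -> "EventHistory":
        mask = self._labels == int(label)
        return EventHistory(self._times[mask], self._labels[mask], check=False)


def poisson_stream(expected_interval: float, duration: float,
                   label: EventLabel = EventLabel.EXC,
                   seed=None) -> EventHistory:
    """Homogeneous Poisson event stream on [0, duration).

    Inter-event intervals are i.i.d. exponential with the given mean;
    reproducible for a fixed ``seed`` (any ``numpy.random`` seed or
    Generator).
    """
    if expected_interval <= 0 or duration <= 0:
        raise InputError("expected_interval and duration must be > 0")
    rng = np.random.default_rng(seed)
    # draw in blocks until past the horizon
    est = max(16, int(duration / expected_interval * 1.5) + 16)
    times = np.cumsum(rng.exponential(expected_interval, size=est))
    while times.size and times[-1] < duration:
        extra = np.cumsum(rng.exponential(expected_interval, size=est)) + times[-1]
        times = np.concatenate([times, extra])
    times = times[times < duration]
    return EventHistory(times, np.full(times.size, int(label), dtype=np.int8),
                        check=False)


def make_pattern(n_events: int, exc_interval: float = DEFAULT_EXPECTED_INTERVAL,
                 inh_interval: float = DEFAULT_EXPECTED_INTERVAL,
                 seed=None) -> EventHistory:
    """Fixed-length random stimulus pattern of mixed EXC/INH events.

    Two independent Poisson streams are merged, truncated to the last
    ``n_events`` events, and shifted so the first event is at t = 0.  The
    combined rate is 1/exc_interval + 1/inh_interval, so EXC events make up
    a fraction inh_interval/(exc_interval + inh_interval) in expectation.
    """
    if n_events < 1:
        raise InputError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    combined = 1.0 / (1.0 / exc_interval + 1.0 / inh_interval)
    duration = max(4.0 * combined, 1.5 * n_events * combined)
    while True:
        exc = poisson_stream(exc_interval, duration, EventLabel.EXC, rng)
        inh = poisson_stream(inh_interval, duration, EventLabel.INH, rng)
        merged = EventHistory.merge(exc, inh)
        if len(merged) >= n_events:
            break
        duration *= 2.0  # rare: streams too short, retry with a longer window
    tail = merged.tail(n_events)
    return tail.shifted(-tail.times[0])
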