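"""Frame libraries: initialization states harvested from a ground-truth run.

Three kinds of libraries are used by the on-event oracles:

* RANDOM — states sampled at uniformly random sample times of a long run,
  standing in for "unknown initial conditions";
* SPIKING — the states observed at the onset (0 mV upward crossing) of each
  output spike, used when the event window starts at an output spike;
* the median frame — the observed frame closest, in per-variable min-max
  normalized Euclidean distance, to the per-variable medians of a library;
  it represents the model's typical subthreshold state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import EmptyLibraryError, InputError
from .point_models import ModelKind, StateFrame, Trace

__all__ = ["FrameKind", "FrameLibrary", "sample_random_frames",
           "extract_spiking_frames", "median_frame"]


class FrameKind(str, Enum):
    RANDOM = "random"
    SPIKING = "spiking"
    MEDIAN = "median"


_HH_COLS = ("Vm", "m", "h", "n_gate")
_WB_COLS = ("Vm", "h", "n_gate")


@dataclass
class FrameLibrary:
    """A set of state frames stored as a (k, n_vars) array."""

    data: np.ndarray
    model_kind: ModelKind
    kind: FrameKind
    source_seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] == 0:
            raise EmptyLibraryError("frame library must be a non-empty 2-D array")
        if self.data.shape[1] != len(self.columns):
            raise InputError(
                f"expected {len(self.columns)} state variables for "
                f"{self.model_kind.value}, got {self.data.shape[1]}")
        gates = self.data[:, 1:] if self.model_kind is ModelKind.WB \
            else self.data[:, 1:]
        if gates.min() < 0.0 or gates.max() > 1.0:
            raise InputError("gating variables must lie in [0, 1]")

    @property
    def columns(self) -> tuple[str, ...]:
        return _HH_COLS if self.model_kind is ModelKind.HH else _WB_COLS

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> StateFrame:
        row = self.data[i]
        if self.model_kind is ModelKind.HH:
            return StateFrame(Vm=row[0], m=row[1], h=row[2], n_gate=row[3])
        return StateFrame(Vm=row[0], h=row[1], n_gate=row[2])

    def frames(self) -> list[StateFrame]:
        return [self.frame(i) for i in range(len(self))]

    @classmethod
    def from_frames(cls, frames, model_kind: ModelKind,
                    kind: FrameKind = FrameKind.RANDOM,
                    source_seed: int | None = None) -> "FrameLibrary":
        rows = [f.as_tuple(model_kind) for f in frames]
        if not rows:
            raise EmptyLibraryError("cannot build a library from zero frames")
        return cls(np.array(rows, dtype=float), model_kind, kind, source_seed)


def _trace_state_matrix(trace: Trace) -> np.ndarray:
    if trace.kind is ModelKind.HH:
        return np.column_stack([trace.vm, trace.gates])
    return np.column_stack([trace.vm, trace.gates[:, 1], trace.gates[:, 2]])


def sample_random_frames(trace: Trace, k: int, seed=None) -> FrameLibrary:
    """``k`` frames at uniformly random sample times of ``trace``."""
    if k <= 0:
        raise InputError("k must be >= 1")
    if trace.gates.shape[0] != trace.times.size:
        raise InputError("trace must carry gate samples (record_aux)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, trace.times.size, size=k)
    mat = _trace_state_matrix(trace)[idx]
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return FrameLibrary(mat, trace.kind, FrameKind.RANDOM, source_seed=seed_val)


def extract_spiking_frames(trace: Trace) -> FrameLibrary:
    """One frame per output spike, at the grid sample of the 0 mV crossing.

    The frame is the observed state vector at the last sample at or before
    the interpolated crossing instant, i.e. the final sub-zero sample of the
    upstroke.
    """
    if trace.spike_times.size == 0:
        raise EmptyLibraryError("trace has no spikes")
    t0 = trace.times[0]
    idx = np.floor((trace.spike_times - t0) / trace.dt + 1e-9).astype(int)
    idx = np.clip(idx, 0, trace.times.size - 1)
    mat = _trace_state_matrix(trace)[idx]
    return FrameLibrary(mat, trace.kind, FrameKind.SPIKING)


def median_frame(library: FrameLibrary) -> StateFrame:
    """The library member nearest the per-variable medians.

    Distance is Euclidean over min-max normalized variables; variables that
    are constant across the library contribute zero.  Always returns an
    observed member, never an interpolated state.
    """
    idx = median_frame_index(library)
    return library.frame(idx)


def median_frame_index(library: FrameLibrary) -> int:
    data = library.data
    lo = data.min(axis=0)
    span = data.max(axis=0) - lo
    keep = span > 0
    if not keep.any():
        return 0  # all frames identical
    norm = (data[:, keep] - lo[keep]) / span[keep]
    med = np.median(norm, axis=0)
    d2 = ((norm - med) ** 2).sum(axis=1)
    return int(np.argmin(d2))
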