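"""The on-event discrete-event simulation.

The main simulation holds no membrane state: it only schedules stimulus
events and, on each stimulus, asks an *on-event function* for the
next-spike-time (NST) given the window of recent events.  A predicted spike
is committed only if no further stimulus arrives first; otherwise it is
discarded and recomputed from the updated window.  Output spikes can
optionally join the event history, in which case the window is truncated at
the most recent output spike (no older events are presented).

The reference on-event function (:func:`conductance_oracle`) replays the
event window through a fresh conductance-based model instance initialized
from a state-frame library, which quantifies the error attributable to the
limited input encoding itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from . import point_models as pm
from ._kernels import first_crossing_after
from .errors import ContractViolationError, InputError
from .point_models import (DEFAULT_DT, PointModelSpec, StateFrame, Trace,
                           integrate_batch)
from .state_frames import FrameLibrary, median_frame
from .stimulus import EventHistory, EventLabel, EventRecord

__all__ = ["OracleMode", "run_on_event_sim", "conductance_oracle",
           "window_nsts_batch", "ground_truth_run", "SpikeTrain"]

SpikeTrain = np.ndarray  # strictly increasing spike times in ms


class OracleMode(str, Enum):
    RANDOM_FRAME = "random_frame"
    MEDIAN_FRAME = "median_frame"


def run_on_event_sim(stimuli: EventHistory,
                     fn: Callable[[EventHistory], float],
                     n: int,
                     include_output_spikes: bool = False,
                     t_end: float | None = None) -> np.ndarray:
    """Run the event-based simulation and return the recorded spike train.

    On each stimulus the window of the ``n`` most recent events (stimuli
    and, when enabled, recorded output spikes), ending with the triggering
    stimulus, is passed to ``fn``; a cold start with fewer than ``n`` known
    events uses all of them.  A pending predicted spike strictly earlier
    than the next stimulus is committed; a stimulus arriving at or before
    the predicted time invalidates it.  At most one output event exists per
    time point.
    """
    if n < 1:
        raise InputError("window size n must be >= 1")
    if not stimuli.is_sorted():
        raise InputError("stimuli must be time-sorted")
    if t_end is None:
        t_end = math.inf
    spikes: list[float] = []
    history = EventHistory.empty()
    pending: float | None = None

    def commit(t_spike: float) -> None:
        nonlocal history
        if spikes and t_spike <= spikes[-1]:
            return  # only one output event per time point
        spikes.append(t_spike)
        if include_output_spikes:
            history = history.appended(EventRecord(t_spike, EventLabel.OUTPUT_SPIKE))

    for i in range(len(stimuli)):
        rec = stimuli[i]
        if pending is not None and pending < rec.time and pending <= t_end:
            commit(pending)
        pending = None
        history = history.appended(rec)
        window = history.tail(n)
        if include_output_spikes:
            window = _truncate_at_output_spike(window)
        nst = fn(window)
        if nst is None or (not math.isinf(nst) and nst <= 0):
            raise ContractViolationError(
                f"on-event function returned NST={nst!r} for trigger at "
                f"t={rec.time} ms (must be > 0 or +inf)")
        if math.isfinite(nst):
            pending = rec.time + nst
    if pending is not None and pending <= t_end:
        commit(pending)
    return np.array(spikes)


def _truncate_at_output_spike(window: EventHistory) -> EventHistory:
    labels = window.labels
    spike_pos = np.flatnonzero(labels == EventHistory.OUTPUT_SPIKE)
    if spike_pos.size == 0:
        return window
    return window[int(spike_pos[-1]):]


# ---------------------------------------------------------------------------
# conductance-based oracle


@dataclass
class ConductanceOracle:
    """On-event function that replays the window through the full model.

    The model instance is (a) initialized from a frame — random or median
    depending on ``mode``, or a spiking frame when the window starts at an
    output spike — with synaptic conductances at zero; (b) driven by the
    window's stimulus events at their relative times; (c) integrated for the
    window span plus ``extension`` ms.  The NST is the time from the last
    (triggering) event to the first spike strictly after it, or +infinity.
    """

    model: PointModelSpec
    frame_library: FrameLibrary
    spiking_library: FrameLibrary | None
    mode: OracleMode
    extension: float = 20.0
    dt: float = DEFAULT_DT
    seed: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)
    _median: StateFrame = field(init=False, repr=False)
    _spiking_median: StateFrame | None = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.extension <= 0:
            raise InputError("extension must be > 0")
        self._rng = np.random.default_rng(self.seed)
        self._median = median_frame(self.frame_library)
        self._spiking_median = (median_frame(self.spiking_library)
                                if self.spiking_library is not None else None)

    def _pick_frame(self, window: EventHistory) -> StateFrame:
        if int(window.labels[0]) == EventHistory.OUTPUT_SPIKE:
            if self.spiking_library is None:
                raise InputError(
                    "window starts at an output spike but no spiking frame "
                    "library was provided")
            if self.mode is OracleMode.MEDIAN_FRAME:
                return self._spiking_median
            i = int(self._rng.integers(0, len(self.spiking_library)))
            return self.spiking_library.frame(i)
        if self.mode is OracleMode.MEDIAN_FRAME:
            return self._median
        i = int(self._rng.integers(0, len(self.frame_library)))
        return self.frame_library.frame(i)

    def __call__(self, window: EventHistory) -> float:
        if len(window) == 0:
            raise InputError("empty event window")
        frame = self._pick_frame(window)
        nst = window_nsts_batch(self.model, window, [frame],
                                extension=self.extension, dt=self.dt)[0]
        return nst


def conductance_oracle(model: PointModelSpec,
                       frame_library: FrameLibrary,
                       spiking_library: FrameLibrary | None = None,
                       mode: OracleMode = OracleMode.MEDIAN_FRAME,
                       extension: float = 20.0,
                       dt: float = DEFAULT_DT,
                       seed: int | None = None) -> ConductanceOracle:
    """Build the reference on-event function for ``model`` (see
    :class:`ConductanceOracle`)."""
    return ConductanceOracle(model, frame_library, spiking_library,
                             OracleMode(mode), extension, dt, seed)


def window_nsts_batch(model: PointModelSpec, window: EventHistory, frames,
                      extension: float = 20.0,
                      dt: float = DEFAULT_DT) -> np.ndarray:
    """NST of one event window under many initializations, in one pass.

    Returns an array of NSTs (ms from the triggering event; +inf where the
    replay produces no spike strictly after the trigger).  Spikes during the
    replay period are discarded.
    """
    if len(window) == 0:
        raise InputError("empty event window")
    t_first = float(window.times[0])
    t_last = float(window.times[-1])
    rel = window.shifted(-t_first)
    span = t_last - t_first
    t_end = span + extension
    times, vm, _, _ = integrate_batch(
        model.membrane, model.synapse, frames, rel, 0.0, t_end, dt)
    # first upward crossing strictly after the trigger; a crossing whose
    # bracketing interval starts at the trigger sample still counts when the
    # interpolated time exceeds the trigger time
    start_idx = int(np.floor(span / dt + 1e-9))
    out = np.empty(len(frames))
    for b in range(vm.shape[0]):
        t_cross = first_crossing_after(vm[b], start_idx, dt)
        if t_cross < 0 or t_cross <= span:
            out[b] = np.inf
        else:
            out[b] = t_cross - span
    return out


def ground_truth_run(model: PointModelSpec, stimuli: EventHistory,
                     duration: float, dt: float = DEFAULT_DT,
                     init_frame: StateFrame | None = None) -> Trace:
    """Continuous-time reference simulation under the default initialization
    (Vm = -65 mV, gates at steady state) unless a frame is supplied."""
    if duration <= 0:
        raise InputError("duration must be > 0")
    return pm.integrate(model, init_frame=init_frame, events=stimuli,
                        t0=0.0, t_end=duration, dt=dt)
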