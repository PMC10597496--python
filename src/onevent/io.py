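"""Delimited-text readers and writers for events, spike trains, traces and
frame libraries.

All formats are plain text: event files are CSV with header
``time_ms,label`` (labels ``exc``, ``inh``, ``spike``), spike trains are one
time per line, frame libraries are CSV with one frame per row plus a YAML
sidecar carrying kind and seed.  Round-trips preserve full floating-point
precision (times serialized with repr).
"""

from __future__ import annotations

import os

import numpy as np
import yaml

from .errors import InputError
from .point_models import ModelKind, Trace
from .state_frames import FrameKind, FrameLibrary
from .stimulus import EventHistory

__all__ = ["read_events", "write_events", "read_spiketrain",
           "write_spiketrain", "write_trace", "read_frame_library",
           "write_frame_library"]

_LABEL_TO_TEXT = {EventHistory.EXC: "exc", EventHistory.INH: "inh",
                  EventHistory.OUTPUT_SPIKE: "spike"}
_TEXT_TO_LABEL = {v: k for k, v in _LABEL_TO_TEXT.items()}


def write_events(history: EventHistory, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ms,label\n")
        for t, lab in zip(history.times, history.labels):
            fh.write(f"{float(t)!r},{_LABEL_TO_TEXT[int(lab)]}\n")


def read_events(path) -> EventHistory:
    times: list[float] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header and header != "time_ms,label":
            raise InputError(f"{path}: expected header 'time_ms,label', "
                             f"got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 'time,label'")
            try:
                t = float(parts[0])
            except ValueError:
                raise InputError(f"{path}:{lineno}: unparseable time "
                                 f"{parts[0]!r}") from None
            lab = parts[1].strip().lower()
            if lab not in _TEXT_TO_LABEL:
                raise InputError(f"{path}:{lineno}: unknown label {lab!r}")
            if times and t < times[-1]:
                raise InputError(f"{path}:{lineno}: events not time-sorted")
            times.append(t)
            labels.append(_TEXT_TO_LABEL[lab])
    return EventHistory(np.array(times), np.array(labels, dtype=np.int8))


def write_spiketrain(train, path) -> None:
    train = np.asarray(train, dtype=float)
    if train.size and np.any(np.diff(train) <= 0):
        raise InputError("spike train must be strictly increasing")
    with open(path, "w") as fh:
        for t in train:
            fh.write(f"{float(t)!r}\n")


def read_spiketrain(path) -> np.ndarray:
    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            t = float(line)
            if times and t <= times[-1]:
                raise InputError(
                    f"{path}:{lineno}: spike times must be strictly "
                    f"increasing (duplicate or decreasing time)")
            times.append(t)
    return np.array(times)


def write_trace(trace: Trace, path) -> None:
    """Trace as delimited text: time, Vm, gates, synaptic conductances."""
    trace.to_frame().to_csv(path, index=False)


def write_frame_library(library: FrameLibrary, path) -> None:
    header = ",".join(library.columns)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in library.data:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")
    meta = {"model_kind": library.model_kind.value,
            "kind": library.kind.value,
            "source_seed": library.source_seed}
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_frame_library(path) -> FrameLibrary:
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return FrameLibrary(data, ModelKind(meta["model_kind"]),
                        FrameKind(meta["kind"]),
                        source_seed=meta.get("source_seed"))


def _sidecar(path) -> str:
    base, _ = os.path.splitext(os.fspath(path))
    return base + ".meta.yaml"
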