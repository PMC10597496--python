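"""Conductance-based single-compartment neuron models.

Two membrane mechanisms are implemented: the classic squid-axon
Hodgkin-Huxley model (gates m, h, n) and the Wang-Buzsaki fast-spiking
interneuron model (instantaneous m, gates h and n, temperature factor
phi = 5 on the gate kinetics).  Synapses are single-exponential
conductances: each excitatory/inhibitory event increments the matching
conductance by a fixed weight and the conductance then decays with its time
constant.  An output spike is the moment the membrane potential crosses
0 mV from below, located by linear interpolation between samples.

Six shipped parameterizations (``base``, ``lw``, ``lt``, ``lwlt``,
``burst``, ``wb``) differ only in synaptic weights and time constants and
span low-rate, baseline and bursting behavior.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import yaml
from scipy.optimize import brentq

from . import _kernels
from .errors import ConfigurationError, InputError
from .stimulus import EventHistory

__all__ = [
    "ModelKind", "MembraneParams", "SynapseParams", "PointModelSpec",
    "StateFrame", "Trace", "gating_rates", "steady_state_gates",
    "resting_frame", "derivatives", "integrate", "detect_spikes",
    "load_model", "available_models", "DEFAULT_DT",
]

DEFAULT_DT = 0.025  # ms; matches the spike-timing resolution of the traces

# default compartment: 10 um x 10 um cylinder (lateral area pi*d*L)
DEFAULT_AREA_CM2 = math.pi * 10.0 * 10.0 * 1e-8


class ModelKind(str, Enum):
    HH = "hh"
    WB = "wb"


@dataclass(frozen=True)
class MembraneParams:
    """Specific membrane conductances (S/cm^2), reversals (mV), capacitance
    (uF/cm^2) and compartment area (cm^2)."""

    model_kind: ModelKind
    gNa: float
    gK: float
    gL: float
    ENa: float
    EK: float
    EL: float
    Cm: float = 1.0
    area: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        if min(self.gNa, self.gK, self.gL) < 0:
            raise ConfigurationError("conductances must be >= 0")
        if self.area <= 0 or self.Cm <= 0:
            raise ConfigurationError("area and Cm must be > 0")


@dataclass(frozen=True)
class SynapseParams:
    """Single-exponential synapse parameters.

    Weights are the peak conductance increment per event (uS), taus the
    decay constants (ms), and e_* the synaptic reversal potentials (mV).
    """

    weight_exc: float
    weight_inh: float
    tau_exc: float
    tau_inh: float
    e_exc: float = 0.0
    e_inh: float = -75.0

    def __post_init__(self) -> None:
        if self.weight_exc < 0 or self.weight_inh < 0:
            raise ConfigurationError("synaptic weights must be >= 0")
        if self.tau_exc <= 0 or self.tau_inh <= 0:
            raise ConfigurationError("synaptic time constants must be > 0")


@dataclass(frozen=True)
class PointModelSpec:
    """One named model parameterization: membrane + synapses."""

    name: str
    membrane: MembraneParams
    synapse: SynapseParams
    reference_rate_hz: float | None = None

    @property
    def kind(self) -> ModelKind:
        return self.membrane.model_kind

    def with_overrides(self, **kw) -> "PointModelSpec":
        mem_keys = {k: v for k, v in kw.items()
                    if k in MembraneParams.__dataclass_fields__ and k != "model_kind"}
        syn_keys = {k: v for k, v in kw.items()
                    if k in SynapseParams.__dataclass_fields__}
        unknown = set(kw) - set(mem_keys) - set(syn_keys)
        if unknown:
            raise ConfigurationError(f"unknown model override keys: {sorted(unknown)}")
        return replace(self, membrane=replace(self.membrane, **mem_keys),
                       synapse=replace(self.synapse, **syn_keys))


@dataclass(frozen=True)
class StateFrame:
    """Snapshot of the model state variables at one instant.

    HH frames carry (Vm, m, h, n_gate); WB frames omit m because it is an
    instantaneous function of Vm (``m`` is then None).  The K+ activation
    gate is named ``n_gate`` to keep it distinct from history lengths.
    """

    Vm: float
    h: float
    n_gate: float
    m: float | None = None

    def __post_init__(self) -> None:
        for g in (self.h, self.n_gate) + (() if self.m is None else (self.m,)):
            if not 0.0 <= g <= 1.0:
                raise ConfigurationError(f"gating variable {g} outside [0, 1]")

    def as_tuple(self, kind: ModelKind) -> tuple[float, ...]:
        if kind is ModelKind.HH:
            if self.m is None:
                raise ConfigurationError("HH frame requires an m gate")
            return (self.Vm, self.m, self.h, self.n_gate)
        return (self.Vm, self.h, self.n_gate)


@dataclass
class Trace:
    """Uniformly sampled trajectory of one integrated instance."""

    times: np.ndarray          # (S,) ms
    vm: np.ndarray             # (S,) mV
    gates: np.ndarray          # (S, 3) columns m, h, n_gate
    syn_g: np.ndarray          # (S, 2) columns g_exc, g_inh (uS)
    spike_times: np.ndarray    # (K,) ms, interpolated upward 0 mV crossings
    kind: ModelKind = ModelKind.HH
    dt: float = DEFAULT_DT

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame_at(self, index: int) -> StateFrame:
        m, h, n = self.gates[index]
        if self.kind is ModelKind.WB:
            return StateFrame(Vm=float(self.vm[index]), h=float(h), n_gate=float(n))
        return StateFrame(Vm=float(self.vm[index]), m=float(m), h=float(h),
                          n_gate=float(n))

    def to_frame(self):
        """Trace as a pandas DataFrame (time, Vm, gates, conductances)."""
        import pandas as pd
        return pd.DataFrame({
            "time_ms": self.times, "Vm": self.vm,
            "m": self.gates[:, 0], "h": self.gates[:, 1],
            "n_gate": self.gates[:, 2],
            "g_exc": self.syn_g[:, 0], "g_inh": self.syn_g[:, 1],
        })


# ---------------------------------------------------------------------------
# gating kinetics


def _vtrap(x: float, y: float) -> float:
    u = x / y
    if abs(u) < 1e-6:
        return y + 0.5 * x
    return x / (1.0 - math.exp(-u))


def gating_rates(v: float, model_kind: ModelKind) -> dict[str, tuple[float, float]]:
    """Forward/backward rates (1/ms) for each gate at potential ``v`` (mV).

    Removable singularities (e.g. the HH alpha_m at v = -40 mV) are
    evaluated by their limits.  WB rates for h and n include the phi = 5
    temperature factor; its m gate is instantaneous but the underlying
    rates are still reported.
    """
    if not np.isfinite(v):
        raise InputError(f"membrane potential must be finite, got {v}")
    if model_kind is ModelKind.HH:
        return {
            "m": (0.1 * _vtrap(v + 40.0, 10.0), 4.0 * math.exp(-(v + 65.0) / 18.0)),
            "h": (0.07 * math.exp(-(v + 65.0) / 20.0),
                  1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))),
            "n_gate": (0.01 * _vtrap(v + 55.0, 10.0),
                       0.125 * math.exp(-(v + 65.0) / 80.0)),
        }
    phi = 5.0
    return {
        "m": (0.1 * _vtrap(v + 35.0, 10.0), 4.0 * math.exp(-(v + 60.0) / 18.0)),
        "h": (phi * 0.07 * math.exp(-(v + 58.0) / 20.0),
              phi / (1.0 + math.exp(-0.1 * (v + 28.0)))),
        "n_gate": (phi * 0.01 * _vtrap(v + 34.0, 10.0),
                   phi * 0.125 * math.exp(-(v + 44.0) / 80.0)),
    }


def steady_state_gates(v: float, model_kind: ModelKind) -> dict[str, float]:
    """x_inf = alpha/(alpha+beta) for each gate at clamped potential ``v``."""
    return {g: a / (a + b) for g, (a, b) in gating_rates(v, model_kind).items()}


def _frame_at_voltage(v: float, kind: ModelKind) -> StateFrame:
    ss = steady_state_gates(v, kind)
    if kind is ModelKind.HH:
        return StateFrame(Vm=v, m=ss["m"], h=ss["h"], n_gate=ss["n_gate"])
    return StateFrame(Vm=v, h=ss["h"], n_gate=ss["n_gate"])


def _membrane_current_density(v: float, frame_gates: dict[str, float],
                              p: MembraneParams) -> float:
    kind = p.model_kind
    m = frame_gates["m"]
    h = frame_gates["h"]
    n = frame_gates["n_gate"]
    ina = 1000.0 * p.gNa * m ** 3 * h * (v - p.ENa)
    ik = 1000.0 * p.gK * n ** 4 * (v - p.EK)
    il = 1000.0 * p.gL * (v - p.EL)
    return ina + ik + il


def resting_frame(membrane: MembraneParams) -> StateFrame:
    """The model's resting fixed point: gates at steady state, net current 0."""
    kind = membrane.model_kind

    def f(v: float) -> float:
        ss = steady_state_gates(v, kind)
        return _membrane_current_density(v, ss, membrane)

    # the current-voltage curve can cross zero more than once (the upper
    # crossings are unstable); bracket the lowest crossing on a grid
    grid = np.arange(-90.0, -40.0, 0.5)
    vals = [f(v) for v in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            return _frame_at_voltage(float(lo), kind)
        if flo * fhi < 0:
            v_rest = brentq(f, lo, hi, xtol=1e-10)
            return _frame_at_voltage(float(v_rest), kind)
    raise ConfigurationError("no resting fixed point found in [-90, -40] mV")


def default_init_frame(membrane: MembraneParams) -> StateFrame:
    """Ground-truth initialization: Vm = -65 mV, gates at steady state."""
    return _frame_at_voltage(-65.0, membrane.model_kind)


def derivatives(frame: StateFrame, syn_g: tuple[float, float],
                membrane: MembraneParams, synapse: SynapseParams
                ) -> dict[str, float]:
    """Instantaneous time derivatives of Vm (mV/ms) and the gates (1/ms)."""
    kind = membrane.model_kind
    v = frame.Vm
    rates = gating_rates(v, kind)
    gates = {"h": frame.h, "n_gate": frame.n_gate}
    if kind is ModelKind.HH:
        if frame.m is None:
            raise ConfigurationError("HH frame requires an m gate")
        gates["m"] = frame.m
    else:
        am, bm = rates["m"]
        gates["m"] = am / (am + bm)
    ge, gi = syn_g
    i_mem = _membrane_current_density(v, gates, membrane)
    i_syn = (ge * (v - synapse.e_exc) + gi * (v - synapse.e_inh)) * 1e-3 / membrane.area
    out = {"Vm": -(i_mem + i_syn) / membrane.Cm}
    for g, (a, b) in rates.items():
        if kind is ModelKind.WB and g == "m":
            continue
        out[g] = a * (1.0 - gates[g]) - b * gates[g]
    return out


# ---------------------------------------------------------------------------
# integration


def _event_grid(events: EventHistory, t0: float, t_end: float, dt: float):
    times = events.times
    labels = events.labels
    if times.size and (times.min() < t0 - 1e-9 or times.max() > t_end + 1e-9):
        raise InputError("events outside the integration window [t0, t_end]")
    syn = labels != EventHistory.OUTPUT_SPIKE
    times = times[syn]
    labels = labels[syn]
    # nearest grid time at or after the event timestamp
    steps = np.ceil((times - t0) / dt - 1e-9).astype(np.int64)
    steps = np.clip(steps, 0, None)
    return steps, (labels == EventHistory.EXC).astype(np.uint8)


def _batch_arrays(frames, kind: ModelKind):
    B = len(frames)
    V = np.empty(B)
    m = np.empty(B)
    h = np.empty(B)
    n = np.empty(B)
    for i, fr in enumerate(frames):
        V[i] = fr.Vm
        h[i] = fr.h
        n[i] = fr.n_gate
        if kind is ModelKind.HH:
            if fr.m is None:
                raise ConfigurationError("HH frame requires an m gate")
            m[i] = fr.m
        else:
            ss = steady_state_gates(fr.Vm, kind)
            m[i] = ss["m"]
    return V, m, h, n


def _param_vectors(membrane: MembraneParams, synapse: SynapseParams):
    mp = np.array([membrane.gNa, membrane.gK, membrane.gL, membrane.ENa,
                   membrane.EK, membrane.EL, membrane.Cm, membrane.area])
    sp = np.array([synapse.weight_exc, synapse.weight_inh, synapse.tau_exc,
                   synapse.tau_inh, synapse.e_exc, synapse.e_inh])
    return mp, sp


def integrate_batch(membrane: MembraneParams, synapse: SynapseParams,
                    frames, events: EventHistory, t0: float, t_end: float,
                    dt: float = DEFAULT_DT, init_syn_g=(0.0, 0.0),
                    record_aux: bool = False):
    """Integrate a batch of initializations under one shared event schedule.

    Returns ``(times, vm)`` with ``vm`` of shape (B, S), plus
    ``(gates, syn_g)`` arrays of shape (B, S, 3) / (B, S, 2) when
    ``record_aux`` is set (otherwise None).
    """
    if dt <= 0:
        raise InputError("dt must be > 0")
    if t_end < t0:
        raise InputError("t_end must be >= t0")
    if not events.is_sorted():
        raise InputError("events must be time-sorted")
    kind = membrane.model_kind
    steps, exc = _event_grid(events, t0, t_end, dt)
    n_steps = int(round((t_end - t0) / dt))
    V, m, h, n = _batch_arrays(frames, kind)
    ge = np.full(V.shape, float(init_syn_g[0]))
    gi = np.full(V.shape, float(init_syn_g[1]))
    B = V.shape[0]
    vm_out = np.empty((B, n_steps + 1))
    if record_aux:
        gates_out = np.empty((B, n_steps + 1, 3))
        syn_out = np.empty((B, n_steps + 1, 2))
    else:
        gates_out = np.empty((B, 1, 3))
        syn_out = np.empty((B, 1, 2))
    mp, sp = _param_vectors(membrane, synapse)
    kkind = _kernels.HH if kind is ModelKind.HH else _kernels.WB
    _kernels.integrate_kernel(kkind, mp, sp, V, m, h, n, ge, gi,
                              steps, exc, n_steps, dt, vm_out,
                              gates_out, syn_out, record_aux)
    times = t0 + dt * np.arange(n_steps + 1)
    if record_aux:
        return times, vm_out, gates_out, syn_out
    return times, vm_out, None, None


def integrate(spec_or_membrane, synapse: SynapseParams | None = None, *,
              init_frame: StateFrame | None = None,
              init_syn_g=(0.0, 0.0), events: EventHistory | None = None,
              t0: float = 0.0, t_end: float = 1000.0,
              dt: float = DEFAULT_DT) -> Trace:
    """Integrate a single instance and return its full :class:`Trace`.

    ``spec_or_membrane`` may be a :class:`PointModelSpec` (synapse taken from
    it) or a :class:`MembraneParams` with an explicit ``synapse``.
    """
    if isinstance(spec_or_membrane, PointModelSpec):
        membrane = spec_or_membrane.membrane
        synapse = spec_or_membrane.synapse
    else:
        membrane = spec_or_membrane
        if synapse is None:
            raise ConfigurationError("synapse parameters required")
    if events is None:
        events = EventHistory.empty()
    if init_frame is None:
        init_frame = default_init_frame(membrane)
    times, vm, gates, syn = integrate_batch(
        membrane, synapse, [init_frame], events, t0, t_end, dt,
        init_syn_g=init_syn_g, record_aux=True)
    spike_times = detect_spikes(vm[0], times)
    return Trace(times=times, vm=vm[0], gates=gates[0], syn_g=syn[0],
                 spike_times=spike_times, kind=membrane.model_kind, dt=dt)


def detect_spikes(vm_samples: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Upward 0 mV crossing times, linearly interpolated between samples.

    One spike per contiguous upward crossing; consecutive spikes are
    separated by at least one sub-zero sample by construction.
    """
    vm_samples = np.asarray(vm_samples, dtype=float)
    times = np.asarray(times, dtype=float)
    if vm_samples.size < 2:
        raise InputError("need at least 2 samples to detect spikes")
    below = vm_samples[:-1] < 0.0
    above = vm_samples[1:] >= 0.0
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0)
    frac = -vm_samples[idx] / (vm_samples[idx + 1] - vm_samples[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


# ---------------------------------------------------------------------------
# shipped parameterizations


def _registry() -> dict:
    text = importlib.resources.files("onevent").joinpath("models.yaml").read_text()
    return yaml.safe_load(text)


def available_models() -> list[str]:
    return sorted(_registry())


def load_model(name: str, **overrides) -> PointModelSpec:
    """Load a shipped parameterization (base, lw, lt, lwlt, burst, wb).

    Keyword overrides update individual membrane or synapse fields, e.g.
    ``load_model("base", area=2 * DEFAULT_AREA_CM2)``.
    """
    reg = _registry()
    if name not in reg:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {available_models()}")
    entry = reg[name]
    kind = ModelKind(entry["model_kind"])
    mem = MembraneParams(model_kind=kind, **entry["membrane"])
    syn = SynapseParams(**entry["synapse"])
    spec = PointModelSpec(name=name, membrane=mem, synapse=syn,
                          reference_rate_hz=entry.get("reference_rate_hz"))
    return spec.with_overrides(**overrides) if overrides else spec
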