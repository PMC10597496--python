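# onevent

Event-based simulation of conductance-based point neurons, built to answer a
quantitative question: **how much of a neuron's recent synaptic event
history is enough to determine its next spike?**

Conventional conductance-based simulation integrates a system of ODEs — the
membrane potential `V` plus ion-channel gating variables — from known
initial conditions through the full input history. `onevent` instead runs a
*discrete-event* simulation that holds no membrane state at all: each
incoming stimulus triggers an **on-event function** that maps the window of
the `n` most recent events (excitatory/inhibitory stimuli and, optionally,
the cell's own output spikes) to a **next-spike-time (NST)** — a positive
delay, or `+inf` for "no spike". A predicted spike is committed only if no
further stimulus arrives first.

The package provides:

* **Ground-truth models** (`onevent.point_models`): single-compartment
  Hodgkin–Huxley and Wang–Buzsáki neurons with single-exponential synapses
  (`g -> g + w` on each event, `dg/dt = -g/tau`), integrated with a fixed
  0.025 ms step (exponential gate updates, semi-implicit voltage update,
  numba-accelerated batched over initializations). Output spikes are upward
  0 mV crossings, sub-step interpolated. Six shipped synaptic
  parameterizations: `base`, `lw`, `lt`, `lwlt`, `burst`, `wb`.
* **The on-event framework** (`onevent.framework`): the event scheduler and
  the reference on-event function — a *conductance oracle* that replays the
  event window through a fresh model instance initialized from a library of
  observed state frames, thereby isolating the error attributable to the
  limited input encoding itself.
* **Metrics** (`onevent.metrics`): spike prediction coherence
  `r^2 + (1-r)^2` (the probability two random initializations agree on
  spike presence), NST standard deviation, the four determinism categories,
  closed-form van Rossum spike-train distance, ISI histograms, spike
  matching, spike-triggered state variance, and category-transition
  analysis.
* **Experiments** (`onevent.experiments`): seeded determinism sweeps over
  window length, extended on-event replication versus ground truth,
  state-variable reconstruction from matched-input simulation pairs, and
  spike-triggered-variance reports.

## Worked example

```python
import numpy as np
from onevent import load_model, conductance_oracle, run_on_event_sim
from onevent.experiments import build_frame_libraries, default_stimuli
from onevent.metrics import van_rossum_distance
from onevent.framework import ground_truth_run

base = load_model("base")

# harvest initialization frames from a long reference run
trace, random_frames, spiking_frames = build_frame_libraries(
    base, duration=50_000.0, k_random=5_000, expected_interval=10.0, seed=1)

# identical Poisson stimulus stream for both simulations
stim = default_stimuli(10_000.0, expected_interval=10.0, seed=2)
truth = ground_truth_run(base, stim, 10_000.0)

# event-based run knowing only the 10 most recent events
oracle = conductance_oracle(base, random_frames, spiking_frames,
                            mode="median_frame")
train = run_on_event_sim(stim, oracle, n=10, t_end=10_000.0)

print(f"ground truth: {truth.spike_times.size} spikes")
print(f"on-event (n=10): {train.size} spikes")
print(f"van Rossum distance: "
      f"{van_rossum_distance(train, truth.spike_times, 10.0):.3f}")
```

Output:

```
ground truth: 81 spikes
on-event (n=10): 82 spikes
van Rossum distance: 0.902
```

81 reference spikes are reproduced almost one-for-one by an event-based
simulation that never sees an initial condition — only the ten most recent
event times. The van Rossum distance (exponential kernel, tau = 10 ms;
a single missed spike costs `sqrt(1/2) ~ 0.71`) quantifies the residual
timing error; it shrinks further as `n` grows.

The same machinery is scriptable from the shell:

```bash
onevent simulate-ground-truth --model base --duration 10000 --seed 3 --out spikes.txt
onevent sample-frames --model base --seed 4 --out frames
onevent run-onevent --model base --n 10 --events events.csv \
    --frames frames.random.csv --out onevent_spikes.txt
onevent metrics van-rossum spikes.txt onevent_spikes.txt
```

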