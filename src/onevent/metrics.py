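"""Statistics over response distributions and spike trains.

Covers the evaluation battery for the event-based framework: spike
prediction coherence and NST dispersion of response sets, the four
determinism categories, inter-spike-interval histograms, the van Rossum
spike-train distance (closed form over spike pairs, causal exponential
kernel), spike matching against a reference train, spike-triggered state
variance, and the bookkeeping of category transitions as the event-history
length grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InputError, InsufficientDataError
from .point_models import Trace
from .stimulus import EventHistory

__all__ = [
    "ResponseDistribution", "DeterminismCategory", "spiking_ratio",
    "spike_prediction_coherence", "nst_std", "classify_response_set",
    "van_rossum_distance", "isi_distribution", "match_spikes",
    "spike_triggered_variance", "SpikeTriggeredVariance",
    "transition_analysis", "TransitionAnalysis",
]


@dataclass(frozen=True)
class ResponseDistribution:
    """NSTs of one stimulus window across ``k`` random initializations.

    Non-spiking responses are represented as +inf entries.
    """

    nsts: np.ndarray
    pattern_id: int | None = None
    n_window: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.nsts, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InputError("nsts must be a non-empty 1-D array")
        if np.any(np.isnan(arr)) or np.any(arr <= 0):
            raise InputError("NSTs must be positive durations or +inf")
        object.__setattr__(self, "nsts", arr)

    @property
    def k(self) -> int:
        return self.nsts.size

    @property
    def finite(self) -> np.ndarray:
        return self.nsts[np.isfinite(self.nsts)]


class DeterminismCategory(str, Enum):
    DET_NONSPIKING = "det_nonspiking"
    DET_SPIKING = "det_spiking"
    NONDET_SPIKING = "nondet_spiking"
    NONDET = "nondet"


def spiking_ratio(d: ResponseDistribution) -> float:
    """Fraction of initializations that respond with a spike (finite NST)."""
    return d.finite.size / d.k


def spike_prediction_coherence(d: ResponseDistribution) -> float:
    """Probability that two random responses agree on spike presence.

    With spiking ratio r this is r^2 + (1-r)^2: 1 at full agreement,
    minimum 0.5 at r = 0.5.
    """
    r = spiking_ratio(d)
    return r * r + (1.0 - r) * (1.0 - r)


def nst_std(d: ResponseDistribution) -> float:
    """Sample standard deviation (ddof=1) of the finite NSTs.

    Returns NaN (an undefined-value signal, not an exception) when fewer
    than two finite NSTs exist; infinite responses never contribute.
    """
    fin = d.finite
    if fin.size < 2:
        return float("nan")
    return float(np.std(fin, ddof=1))


def classify_response_set(d: ResponseDistribution,
                          spike_thresh: float = 0.99,
                          std_thresh_ms: float = 0.1) -> DeterminismCategory:
    """Assign one of the four determinism categories.

    r < 1 - spike_thresh -> deterministic non-spiking; r >= spike_thresh
    with NST std < std_thresh_ms -> deterministic spiking, otherwise
    non-deterministic spiking; everything else non-deterministic.  The std
    boundary itself is non-deterministic spiking (strict '<' for
    deterministic).
    """
    r = spiking_ratio(d)
    if r < 1.0 - spike_thresh:
        return DeterminismCategory.DET_NONSPIKING
    if r >= spike_thresh:
        s = nst_std(d)
        if np.isnan(s) or s < std_thresh_ms:
            return DeterminismCategory.DET_SPIKING
        return DeterminismCategory.NONDET_SPIKING
    return DeterminismCategory.NONDET


# ---------------------------------------------------------------------------
# spike-train comparison


def van_rossum_distance(a, b, tau_vr: float = 10.0) -> float:
    """van Rossum distance between two spike trains.

    Each train is filtered with the causal exponential kernel
    e^{-t/tau} (t >= 0) and the distance is
    D = sqrt((1/tau) * integral (f_a - f_b)^2 dt), evaluated in closed form
    over spike pairs (no time discretization).  Under this normalization a
    single spike versus an empty train gives sqrt(1/2), and two single-spike
    trains offset by Delta give sqrt(1 - e^{-Delta/tau}).
    """
    if tau_vr <= 0:
        raise InputError("tau_vr must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for t in (a, b):
        if t.size and t.min() < 0:
            raise InputError("spike times must be >= 0")

    def cross(x, y):
        if x.size == 0 or y.size == 0:
            return 0.0
        # sum over all pairs of exp(-|xi - yj| / tau)
        d = np.abs(x[:, None] - y[None, :])
        return float(np.exp(-d / tau_vr).sum())

    d2 = 0.5 * (cross(a, a) + cross(b, b)) - cross(a, b)
    return float(np.sqrt(max(d2, 0.0)))


def isi_distribution(train, bin_width: float = 1.0,
                     max_isi: float | None = None):
    """Histogram of consecutive inter-spike intervals.

    Returns ``(counts, bin_edges)``; with fewer than 2 spikes both are
    empty.  Total count equals spike count minus one.
    """
    train = np.asarray(train, dtype=float)
    if bin_width <= 0:
        raise InputError("bin_width must be > 0")
    if train.size < 2:
        return np.empty(0, dtype=int), np.empty(0)
    isis = np.diff(train)
    if np.any(isis < 0):
        raise InputError("spike train must be sorted")
    hi = max_isi if max_isi is not None else float(isis.max()) + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(isis, bins=edges)
    return counts, edges


@dataclass(frozen=True)
class SpikeMatchResult:
    matched: np.ndarray      # bool per predicted spike
    n_matched: int
    n_unmatched: int


def match_spikes(pred, truth, tol: float = 1.0) -> SpikeMatchResult:
    """Flag each predicted spike that lies within ``tol`` ms of any
    reference spike."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0:
        return SpikeMatchResult(np.empty(0, dtype=bool), 0, 0)
    if truth.size == 0:
        matched = np.zeros(pred.size, dtype=bool)
    else:
        pos = np.searchsorted(truth, pred)
        left = np.clip(pos - 1, 0, truth.size - 1)
        right = np.clip(pos, 0, truth.size - 1)
        nearest = np.minimum(np.abs(pred - truth[left]),
                             np.abs(pred - truth[right]))
        matched = nearest <= tol
    return SpikeMatchResult(matched, int(matched.sum()),
                            int((~matched).sum()))


# ---------------------------------------------------------------------------
# spike-triggered variance


@dataclass
class SpikeTriggeredVariance:
    """Per-offset variance of state variables in windows centered on spikes.

    ``offsets`` are times relative to the spike; ``variance`` has one column
    per state variable (Vm first); ``baseline`` is the variance of each
    variable over the entire trace.  ``min_ratio`` is
    min_t var_Vm(t) / baseline_Vm; the peak offsets locate the maxima of the
    Vm variance curve before and after the spike.
    """

    offsets: np.ndarray
    variance: np.ndarray
    baseline: np.ndarray
    columns: tuple[str, ...]
    n_windows: int

    @property
    def min_ratio(self) -> float:
        return float(self.variance[:, 0].min() / self.baseline[0])

    @property
    def min_variance(self) -> float:
        return float(self.variance[:, 0].min())

    @property
    def peak_offset_before(self) -> float:
        pre = self.offsets < 0
        v = self.variance[pre, 0]
        return float(self.offsets[pre][np.argmax(v)])

    @property
    def peak_offset_after(self) -> float:
        post = self.offsets > 0
        v = self.variance[post, 0]
        return float(self.offsets[post][np.argmax(v)])


def spike_triggered_variance(trace: Trace, window: float = 25.0,
                             sample_dt: float | None = None,
                             min_windows: int = 100) -> SpikeTriggeredVariance:
    """Variance of state variables across windows aligned at each spike.

    Windows overlapping the trace boundary are discarded; at least
    ``min_windows`` full windows are required.  ``sample_dt`` coarsens the
    offset grid (defaults to the trace step).
    """
    if window <= 0:
        raise InputError("window must be > 0")
    dt = trace.dt
    stride = 1
    if sample_dt is not None:
        if sample_dt < dt:
            raise InputError("sample_dt cannot be finer than the trace step")
        stride = max(1, int(round(sample_dt / dt)))
    half = int(round(window / dt))
    t0 = trace.times[0]
    centers = np.round((trace.spike_times - t0) / dt).astype(int)
    centers = centers[(centers - half >= 0)
                      & (centers + half < trace.times.size)]
    if centers.size < min_windows:
        raise InsufficientDataError(
            f"only {centers.size} full spike windows; need >= {min_windows}")
    rel = np.arange(-half, half + 1, stride)
    state = np.column_stack([trace.vm, trace.gates])
    idx = centers[:, None] + rel[None, :]
    windows = state[idx]                    # (n_spikes, n_offsets, 4)
    variance = windows.var(axis=0, ddof=0)  # (n_offsets, 4)
    baseline = state.var(axis=0, ddof=0)
    return SpikeTriggeredVariance(
        offsets=rel * dt, variance=variance, baseline=baseline,
        columns=("Vm", "m", "h", "n_gate"), n_windows=int(centers.size))


# ---------------------------------------------------------------------------
# category-transition bookkeeping


@dataclass
class TransitionRecord:
    pattern_id: int
    n_from: int
    cat_from: DeterminismCategory
    cat_to: DeterminismCategory
    new_event_label: int
    pre_event_label: int
    new_event_isi: float   # interval from the newly included stimulus to the
    #                        next-most-recent one (ms)


@dataclass
class TransitionAnalysis:
    """Tallies of category transitions per history-length increment."""

    counts: dict            # (n_from, cat_from, cat_to) -> count
    transitions: list       # TransitionRecord for every category change
    conditional_isis: np.ndarray
    unconditional_isis: np.ndarray
    conditional_exc_ratio: float
    unconditional_exc_ratio: float

    def count(self, n_from: int, cat_from: DeterminismCategory,
              cat_to: DeterminismCategory) -> int:
        return self.counts.get((n_from, cat_from, cat_to), 0)


def transition_analysis(categories: dict, histories: dict,
                        n_values=None) -> TransitionAnalysis:
    """Attribute category changes to the newly included stimulus.

    ``categories`` maps pattern_id -> {n: DeterminismCategory} over
    consecutive n; ``histories`` maps pattern_id -> EventHistory (the full
    pattern, oldest first).  Growing the window from n to n+1 includes the
    (n+1)-th most recent event; for each category change the label of that
    event and its interval to the following (n-th most recent) event are
    recorded, and compared against the unconditional interval/label
    distributions pooled over all events of all patterns.
    """
    counts: dict = {}
    transitions: list[TransitionRecord] = []
    cond_isis: list[float] = []
    cond_exc = 0
    uncond_isis: list[float] = []
    uncond_exc = 0
    uncond_total = 0
    for pid, per_n in categories.items():
        ns = sorted(per_n)
        hist = histories[pid]
        times = hist.times
        labels = hist.labels
        uncond_isis.extend(np.diff(times).tolist())
        uncond_exc += int((labels == EventHistory.EXC).sum())
        uncond_total += len(hist)
        for n_from, n_to in zip(ns[:-1], ns[1:]):
            if n_to != n_from + 1:
                raise InputError("category sequences must use consecutive n")
            c0, c1 = per_n[n_from], per_n[n_to]
            key = (n_from, c0, c1)
            counts[key] = counts.get(key, 0) + 1
            if c0 is not c1 and n_to <= len(hist):
                new_idx = len(hist) - n_to      # (n+1)-th most recent
                nxt_idx = new_idx + 1
                isi = float(times[nxt_idx] - times[new_idx])
                rec = TransitionRecord(
                    pattern_id=pid, n_from=n_from, cat_from=c0, cat_to=c1,
                    new_event_label=int(labels[new_idx]),
                    pre_event_label=int(labels[nxt_idx]),
                    new_event_isi=isi)
                transitions.append(rec)
                cond_isis.append(isi)
                cond_exc += int(labels[new_idx] == EventHistory.EXC)
    n_trans = len(transitions)
    return TransitionAnalysis(
        counts=counts, transitions=transitions,
        conditional_isis=np.array(cond_isis),
        unconditional_isis=np.array(uncond_isis),
        conditional_exc_ratio=(cond_exc / n_trans) if n_trans else float("nan"),
        unconditional_exc_ratio=(uncond_exc / uncond_total)
        if uncond_total else float("nan"))
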