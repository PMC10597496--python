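"""Tests for response-distribution and spike-train metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onevent.errors import InputError, InsufficientDataError
from onevent.metrics import (DeterminismCategory, ResponseDistribution,
                             classify_response_set, isi_distribution,
                             match_spikes, nst_std,
                             spike_prediction_coherence, spiking_ratio,
                             spike_triggered_variance, transition_analysis,
                             van_rossum_distance)
from onevent.point_models import ModelKind, Trace
from onevent.stimulus import EventHistory

INF = float("inf")


def _dist(finite, infinite=0):
    vals = list(finite) + [INF] * infinite
    return ResponseDistribution(np.array(vals, dtype=float))


class TestSpikingRatioAndCoherence:
    def test_all_finite_ratio_one(self):
        assert spiking_ratio(_dist([1.0, 2.0])) == 1.0
        assert spike_prediction_coherence(_dist([1.0, 2.0])) == 1.0

    def test_all_infinite_ratio_zero(self):
        d = _dist([], infinite=10)
        assert spiking_ratio(d) == 0.0
        assert spike_prediction_coherence(d) == 1.0

    def test_670_of_1000(self):
        d = _dist([1.0] * 670, infinite=330)
        assert spiking_ratio(d) == pytest.approx(0.67)

    def test_half_split_gives_minimum(self):
        d = _dist([1.0] * 500, infinite=500)
        assert spike_prediction_coherence(d) == pytest.approx(0.5)

    def test_ratio_082(self):
        d = _dist([1.0] * 82, infinite=18)
        assert spike_prediction_coherence(d) == pytest.approx(0.7048)

    @given(st.integers(0, 200), st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_coherence_bounds_and_symmetry(self, k_spike, k_total_extra):
        k = k_spike + k_total_extra
        d = _dist([1.0] * k_spike, infinite=k - k_spike)
        c = spike_prediction_coherence(d)
        assert 0.5 <= c <= 1.0
        mirrored = _dist([1.0] * (k - k_spike), infinite=k_spike)
        assert c == pytest.approx(spike_prediction_coherence(mirrored))


class TestNstStd:
    def test_identical_values_zero(self):
        assert nst_std(_dist([2.0, 2.0, 2.0])) == 0.0

    def test_two_values_sample_std(self):
        assert nst_std(_dist([1.0, 3.0])) == pytest.approx(math.sqrt(2))

    def test_infinite_responses_ignored(self):
        assert nst_std(_dist([1.0, 3.0], infinite=5)) == pytest.approx(
            nst_std(_dist([1.0, 3.0])))

    def test_undefined_below_two_finite(self):
        assert math.isnan(nst_std(_dist([1.0], infinite=3)))


class TestClassification:
    def test_never_spiking_is_deterministic_nonspiking(self):
        d = _dist([], infinite=1000)
        assert classify_response_set(d) is DeterminismCategory.DET_NONSPIKING

    def test_tight_always_spiking_is_deterministic(self):
        d = _dist(np.full(1000, 5.0) + np.linspace(0, 0.05, 1000))
        assert classify_response_set(d) is DeterminismCategory.DET_SPIKING

    def test_loose_always_spiking_is_nondet_spiking(self):
        d = _dist(np.linspace(1.0, 10.0, 1000))
        assert classify_response_set(d) is DeterminismCategory.NONDET_SPIKING

    def test_half_split_is_nondeterministic(self):
        d = _dist([1.0] * 500, infinite=500)
        assert classify_response_set(d) is DeterminismCategory.NONDET

    def test_std_threshold_separates_spiking_categories(self):
        # sample std just above / just below the 0.1 ms threshold
        above = _dist([5.0, 5.0 + 0.15])   # std ~ 0.106 ms
        below = _dist([5.0, 5.0 + 0.13])   # std ~ 0.092 ms
        assert classify_response_set(above) is \
            DeterminismCategory.NONDET_SPIKING
        assert classify_response_set(below) is \
            DeterminismCategory.DET_SPIKING

    @given(st.integers(1, 300), st.integers(0, 300),
           st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, k_fin, k_inf, spread):
        finite = 5.0 + spread * np.linspace(0, 1, k_fin)
        d = _dist(finite, infinite=k_inf)
        assert classify_response_set(d) in DeterminismCategory


class TestVanRossum:
    def test_identical_trains_zero(self):
        t = np.array([1.0, 5.0, 9.0])
        assert van_rossum_distance(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_single_spike_versus_empty(self):
        d = van_rossum_distance([3.0], [], tau_vr=10.0)
        assert d == pytest.approx(math.sqrt(0.5), rel=1e-12)

    def test_offset_by_tau(self):
        d = van_rossum_distance([0.0], [10.0], tau_vr=10.0)
        assert d == pytest.approx(math.sqrt(1 - math.exp(-1)), rel=1e-12)

    def test_agrees_with_numerical_filtering(self):
        """Independent oracle: discretized exponential filtering + trapezoid
        integration of (f_a - f_b)^2."""
        rng = np.random.default_rng(8)
        tau = 7.0
        a = np.sort(rng.uniform(0, 100, 12))
        b = np.sort(rng.uniform(0, 100, 9))
        t = np.arange(0, 100 + 30 * tau, 0.001)

        def filtered(train):
            f = np.zeros_like(t)
            for s in train:
                mask = t >= s
                f[mask] += np.exp(-(t[mask] - s) / tau)
            return f

        d2 = np.trapezoid((filtered(a) - filtered(b)) ** 2, t) / tau
        assert van_rossum_distance(a, b, tau) == pytest.approx(
            math.sqrt(d2), rel=1e-4)

    def test_metric_axioms_on_random_trains(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            trains = [np.sort(rng.uniform(0, 50, rng.integers(0, 6)))
                      for _ in range(3)]
            a, b, c = trains
            dab = van_rossum_distance(a, b)
            dba = van_rossum_distance(b, a)
            assert dab == pytest.approx(dba, rel=1e-10)
            assert dab + van_rossum_distance(b, c) >= \
                van_rossum_distance(a, c) - 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            van_rossum_distance([1.0], [2.0], tau_vr=0.0)
        with pytest.raises(InputError):
            van_rossum_distance([-1.0], [2.0])


class TestIsiDistribution:
    def test_uniform_train_single_bin(self):
        counts, edges = isi_distribution(np.array([0.0, 10.0, 20.0]),
                                         bin_width=1.0)
        assert counts.sum() == 2
        assert counts[np.digitize(10.0, edges) - 1] == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        train = np.sort(rng.uniform(0, 1000, 200))
        counts, _ = isi_distribution(train, bin_width=0.5)
        assert counts.sum() == 199

    def test_short_train_empty(self):
        counts, edges = isi_distribution(np.array([5.0]))
        assert counts.size == 0 and edges.size == 0

    def test_poisson_train_has_exponential_isis(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        train = np.cumsum(rng.exponential(10.0, size=5000))
        isis = np.diff(train)
        _, p = stats.kstest(isis, "expon", args=(0, 10.0))
        assert p > 0.01


class TestMatchSpikes:
    def test_identical_trains_fully_matched(self):
        t = np.array([1.0, 2.0, 3.0])
        res = match_spikes(t, t, tol=1.0)
        assert res.n_matched == 3 and res.n_unmatched == 0

    def test_outside_tolerance_unmatched(self):
        res = match_spikes(np.array([5.0]), np.array([6.5]), tol=1.0)
        assert res.n_matched == 0

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            pred = np.sort(rng.uniform(0, 500, 50))
            truth = np.sort(rng.uniform(0, 500, 50))
            res = match_spikes(pred, truth, tol=1.0)
            brute = np.array([np.any(np.abs(truth - p) <= 1.0) for p in pred])
            np.testing.assert_array_equal(res.matched, brute)


class TestSpikeTriggeredVariance:
    def _trace(self, vm, dt=1.0, spikes=None):
        n = vm.size
        return Trace(times=dt * np.arange(n), vm=vm,
                     gates=np.zeros((n, 3)), syn_g=np.zeros((n, 2)),
                     spike_times=np.asarray(spikes if spikes is not None
                                            else []),
                     kind=ModelKind.HH, dt=dt)

    def test_identical_windows_have_zero_variance(self):
        wave = np.concatenate([np.zeros(20), [np.nan]])  # placeholder
        # build a periodic trace whose spike-aligned windows are copies
        period = 50
        wave = -60 + 30 * np.exp(-((np.arange(period) - 25) ** 2) / 8.0)
        vm = np.tile(wave, 40)
        spikes = 25.0 + period * np.arange(40)
        tr = self._trace(vm, dt=1.0, spikes=spikes)
        stv = spike_triggered_variance(tr, window=10.0, min_windows=10)
        assert stv.variance[:, 0].max() == pytest.approx(0.0, abs=1e-18)
        assert stv.min_ratio == pytest.approx(0.0, abs=1e-18)

    def test_agrees_with_naive_two_pass(self):
        rng = np.random.default_rng(31)
        vm = rng.normal(-65, 3, 5000)
        spikes = np.sort(rng.choice(np.arange(100, 4900), 60, replace=False)
                         ).astype(float)
        tr = self._trace(vm, dt=1.0, spikes=spikes)
        stv = spike_triggered_variance(tr, window=20.0, min_windows=50)
        # naive recomputation
        half = 20
        wins = np.array([vm[int(s) - half:int(s) + half + 1] for s in spikes])
        naive = wins.var(axis=0)
        np.testing.assert_allclose(stv.variance[:, 0], naive, rtol=1e-10)
        assert stv.baseline[0] == pytest.approx(vm.var())

    def test_boundary_windows_are_discarded(self):
        vm = np.full(1000, -65.0)
        vm[::100] = 10.0
        spikes = np.array([0.0, 500.0, 900.0])  # first/last overlap boundary
        tr = self._trace(vm, dt=1.0, spikes=spikes)
        stv = spike_triggered_variance(tr, window=150.0, min_windows=1)
        assert stv.n_windows == 1

    def test_too_few_spikes_raises(self, base_model):
        vm = np.full(100, -65.0)
        tr = self._trace(vm, dt=1.0, spikes=[50.0])
        with pytest.raises(InsufficientDataError):
            spike_triggered_variance(tr, window=10.0, min_windows=100)


class TestTransitionAnalysis:
    C = DeterminismCategory

    def _hist(self, times, labels):
        return EventHistory(times, labels)

    def test_constant_sequence_only_self_transitions(self):
        cats = {0: {3: self.C.NONDET, 4: self.C.NONDET, 5: self.C.NONDET}}
        hists = {0: self._hist([0, 10, 20, 30, 40], [0, 1, 0, 1, 0])}
        res = transition_analysis(cats, hists)
        assert res.count(3, self.C.NONDET, self.C.NONDET) == 1
        assert res.count(4, self.C.NONDET, self.C.NONDET) == 1
        assert len(res.transitions) == 0

    def test_transition_attributed_to_newly_included_stimulus(self):
        # 12 events; switching at n=9 -> 10 implicates the 10th most recent
        times = list(range(0, 120, 10))
        labels = [0, 1] * 6
        cats = {0: {9: self.C.NONDET, 10: self.C.DET_SPIKING}}
        res = transition_analysis(cats, {0: self._hist(times, labels)})
        (rec,) = res.transitions
        assert rec.n_from == 9
        # 10th most recent of 12 events is index 2
        assert rec.new_event_label == labels[2]
        assert rec.new_event_isi == pytest.approx(10.0)

    def test_tallies_match_brute_force_recount(self):
        rng = np.random.default_rng(5)
        cat_list = list(self.C)
        cats, hists = {}, {}
        for pid in range(100):
            ns = range(3, 11)
            cats[pid] = {n: cat_list[rng.integers(0, 4)] for n in ns}
            t = np.sort(rng.uniform(0, 200, 20))
            hists[pid] = self._hist(t, rng.integers(0, 2, 20))
        res = transition_analysis(cats, hists)
        # brute-force recount
        from collections import Counter
        expected = Counter()
        for pid, per_n in cats.items():
            for n in range(3, 10):
                expected[(n, per_n[n], per_n[n + 1])] += 1
        assert dict(expected) == {k: v for k, v in res.counts.items() if v}
        n_changes = sum(1 for pid, per_n in cats.items()
                        for n in range(3, 10)
                        if per_n[n] is not per_n[n + 1])
        assert len(res.transitions) == n_changes

    def test_nonconsecutive_n_rejected(self):
        cats = {0: {3: self.C.NONDET, 5: self.C.NONDET}}
        hists = {0: self._hist([0, 10, 20, 30, 40], [0] * 5)}
        with pytest.raises(InputError):
            transition_analysis(cats, hists)


class TestResponseDistributionValidation:
    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ResponseDistribution(np.array([]))

    def test_nonpositive_nst_rejected(self):
        with pytest.raises(InputError):
            ResponseDistribution(np.array([1.0, -2.0]))
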