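"""Antidromic-spike inference: quartiles, similarity kernel, both protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecollide.errors import ParameterError
from spikecollide.infer import (
    EvokedTrialSet,
    amplitude_quartile,
    build_target,
    center_spike_search,
    detect_trial_spikes,
    quartile_deviation,
    spike_similarity,
    window_search,
)
from spikecollide.pipeline import build_evoked_sets
from spikecollide.simulate import (
    Projection,
    SimConfig,
    SimNeuron,
    SynapticInput,
    make_ground_truth,
)



def _quartile_oracle(values, q):
    """Independent sort-and-interpolate quantile (linear between order stats)."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (len(v) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestQuartiles:
    @pytest.mark.parametrize(
        "values,expected",
        [([5.0, 5, 5, 5], 5.0), ([3.0], 3.0), ([8.0, 6, 4, 2], 3.5)],
    )
    def test_amplitude_quartile_examples(self, values, expected):
        assert amplitude_quartile(values) == pytest.approx(expected)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        for _ in range(100):
            v = rng.uniform(0, 10, size=rng.integers(1, 40))
            assert amplitude_quartile(v) == pytest.approx(_quartile_oracle(v, 0.25))
            if len(v) >= 2:
                qd = (_quartile_oracle(v, 0.75) - _quartile_oracle(v, 0.25)) / 2
                assert quartile_deviation(v) == pytest.approx(qd)

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            amplitude_quartile([])


class TestSpikeSimilarity:
    def test_identical_spike_is_one(self):
        z = np.array([-3.0, -1.0, 0.0, -0.2])
        assert spike_similarity(z, 7.7, z, 7.7, alpha=1.0) == 1.0

    def test_timing_alpha_equals_angle_pi_over_18(self):
        z = np.array([-2.0, -1.0, -0.5, 0.0])
        expected = math.exp(-math.sin(math.pi / 18) ** 2)
        s_time = spike_similarity(z, 5.0, z, 5.0 + 1.0, alpha=1.0)
        assert s_time == pytest.approx(expected, abs=1e-12)
        # a pattern rotated by pi/18 at zero timing difference scores the same
        theta = math.pi / 18
        a = np.array([-1.0, 0.0, 0.0, 0.0])
        b = np.array([-math.cos(theta), -math.sin(theta), 0.0, 0.0])
        s_angle = spike_similarity(a, 5.0, b, 5.0, alpha=1.0)
        assert s_angle == pytest.approx(expected, abs=1e-12)
        assert s_angle == pytest.approx(s_time, abs=1e-12)

    def test_errors(self):
        z = np.array([-1.0, 0, 0, 0])
        with pytest.raises(ParameterError):
            spike_similarity(np.zeros(4), 0.0, z, 0.0, alpha=1.0)
        with pytest.raises(ParameterError):
            spike_similarity(z, 0.0, z, 0.0, alpha=0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-50, max_value=-0.1), min_size=4, max_size=4),
        st.lists(st.floats(min_value=-50, max_value=-0.1), min_size=4, max_size=4),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-5, max_value=5),
    )
    def test_symmetric_and_bounded(self, za, zb, ta, tb):
        a, b = np.array(za), np.array(zb)
        s1 = spike_similarity(a, ta, b, tb, alpha=1.0)
        s2 = spike_similarity(b, tb, a, ta, alpha=1.0)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert 0.0 < s1 <= 1.0

    def test_strictly_decreasing_in_dt_and_angle(self):
        z = np.array([-2.0, -1.0, 0.0, 0.0])
        s = [spike_similarity(z, 0.0, z, dt, alpha=1.0) for dt in (0.0, 0.5, 1.0, 2.0)]
        assert all(x > y for x, y in zip(s, s[1:]))
        angles = [0.1, 0.3, 0.6, 1.2]
        vs = []
        for th in angles:
            b = np.array([-math.cos(th), -math.sin(th), 0.0, 0.0])
            vs.append(spike_similarity(np.array([-1.0, 0, 0, 0]), 0.0, b, 0.0, alpha=1.0))
        assert all(x > y for x, y in zip(vs, vs[1:]))


def _clean_trial_set(
    latency=10.0, jitter_sd=0.05, n_anti=80, channel_amp=(-2.0, -22.0, -8.0, -3.0), extra_neuron=None
):
    """Z-scored evoked set with one tight antidromic responder (no collisions:
    silent neuron, evoked only)."""
    neurons = [
        SimNeuron(
            id=0,
            tetrode_id=0,
            amp_pattern=np.asarray(channel_amp),
            rate=0.0,
            projections=[Projection(site=0, d=0.7, C=latency - 0.7, jitter_sd=jitter_sd)],
        )
    ]
    if extra_neuron is not None:
        neurons.append(extra_neuron)
    cfg = SimConfig(
        neurons=neurons, sites=[0], n_tetrodes=1, session_length=200.0, n_anti=n_anti
    )
    truth = make_ground_truth(cfg, seed=11)
    return build_evoked_sets(truth)[(0, 0)]


class TestWindowSearch:
    def test_pure_noise_yields_nothing(self, rng):
        es = EvokedTrialSet(
            tetrode_id=0, site=0, trials=rng.normal(size=(40, 4, 1201)), fs=20_000
        )
        assert window_search(es) == []

    def test_single_cluster_found_on_correct_channel(self):
        es = _clean_trial_set(latency=10.0)
        wins = window_search(es)
        assert len(wins) >= 1
        best = wins[0]
        assert best.channel == 1  # dominant amplitude channel
        assert best.start_ms <= 10.0 <= best.end_ms
        assert len(best.rep_trials) == math.ceil(0.75 * es.n_trials)
        assert len(set(best.rep_trials.tolist())) == len(best.rep_trials)

    def test_two_latency_clusters_two_windows(self):
        extra = SimNeuron(
            id=1,
            tetrode_id=0,
            amp_pattern=np.array([-3.0, -2.0, -25.0, -6.0]),
            rate=0.0,
            projections=[Projection(site=0, d=0.7, C=13.3, jitter_sd=0.05)],
        )
        es = _clean_trial_set(latency=8.0, extra_neuron=extra)
        wins = window_search(es)
        centers = sorted((w.start_ms + w.end_ms) / 2 for w in wins[:2])
        assert len(wins) >= 2
        assert abs(centers[0] - 8.0) < 1.0 and abs(centers[1] - 14.0) < 1.0
        # no two adopted windows overlap in time
        spans = sorted((w.start_ms, w.end_ms) for w in wins)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestCenterSpikeSearch:
    def test_no_suprathreshold_spikes_empty(self, rng):
        es = EvokedTrialSet(
            tetrode_id=0, site=0, trials=rng.normal(size=(30, 4, 1201)) * 0.5, fs=20_000
        )
        assert center_spike_search(es) == []

    def test_tight_cluster_one_dominant_center(self):
        es = _clean_trial_set(latency=10.0, n_anti=100)
        targets = center_spike_search(es, alpha=1.0, theta_aggr=0.9)
        best = targets[0]
        assert abs(best.center_t_ms - 10.0) < 0.5
        assert len(set(best.rep_trials.tolist())) >= 75
        assert best.similarity_quartile > 0.9
        # later centers are leftover spikes of the same aggregation, never a
        # spurious cluster elsewhere in the response
        assert all(abs(t.center_t_ms - 10.0) < 0.5 for t in targets)

    def test_antidromic_center_beats_diffuse_synaptic(self):
        extra = SimNeuron(
            id=1,
            tetrode_id=0,
            amp_pattern=np.array([-4.0, -3.0, -20.0, -7.0]),
            rate=0.0,
            synaptic_inputs=[SynapticInput(site=0, latency=10.0, jitter_qd=1.5)],
        )
        es = _clean_trial_set(latency=10.0, extra_neuron=extra, n_anti=100)
        targets = center_spike_search(es, alpha=1.0)
        # brute-force check: the adopted center has the maximal quartile among
        # all detected spikes
        spikes = detect_trial_spikes(es)
        best = targets[0]
        qs = []
        for k in range(spikes.n):
            per_trial = np.zeros(spikes.n_trials)
            for j, sl in enumerate(spikes.trial_slices()):
                if sl.start == sl.stop:
                    continue
                per_trial[j] = max(
                    spike_similarity(
                        spikes.z[k], spikes.t_ms[k], spikes.z[l], spikes.t_ms[l], 1.0
                    )
                    for l in range(sl.start, sl.stop)
                )
            qs.append(np.percentile(per_trial, 25))
        assert best.similarity_quartile == pytest.approx(max(qs), rel=1e-9)
        # and it is the antidromic cluster, not the diffuse synaptic one
        assert abs(best.center_t_ms - 10.0) < 0.5
        assert np.argmin(best.center_z) == 1


class TestBuildTarget:
    def test_latency_bound_algebra(self):
        es = _clean_trial_set(latency=10.0, n_anti=10)
        reps = np.array([0, 1, 2])
        times = np.array([9.8, 10.0, 10.2])
        tg = build_target(es, reps, times, "I", window=None)
        assert tg.t_min == 9.8 and tg.t_max == 10.2
        assert tg.L_min == pytest.approx(9.8 - 1.0)  # t_min - t_off (D_i = 1 ms)
        assert tg.L_max == pytest.approx(10.2)

    def test_identical_representatives(self):
        es = _clean_trial_set(latency=10.0, n_anti=10)
        tg = build_target(es, np.array([0, 1]), np.array([10.0, 10.0]), "II")
        assert tg.t_min == tg.t_max == 10.0
        assert tg.L_max - tg.L_min == pytest.approx(es.duration_ms)

    def test_empty_set_errors(self):
        es = _clean_trial_set(latency=10.0, n_anti=10)
        with pytest.raises(ParameterError):
            build_target(es, np.array([]), np.array([]), "I")

    def test_median_pattern_direction(self):
        es = _clean_trial_set(latency=10.0, n_anti=60)
        wins = window_search(es)
        tg = build_target(es, wins[0].rep_trials, wins[0].rep_times_ms, "I", window=wins[0])
        u = tg.u / np.linalg.norm(tg.u)
        truth = np.array([-2.0, -22.0, -8.0, -3.0])
        truth = truth / np.linalg.norm(truth)
        assert float(u @ truth) > 0.99


class TestProtocolAgreement:
    def test_both_protocols_agree_on_clean_projection(self):
        """One projection neuron: each protocol yields a best target whose
        bounds contain the true latency; median latencies agree < 0.1 ms."""
        es = _clean_trial_set(latency=10.0, n_anti=100)
        w = window_search(es)
        c = center_spike_search(es, alpha=1.0, theta_aggr=0.9)
        t1 = build_target(es, w[0].rep_trials, w[0].rep_times_ms, "I", window=w[0])
        t2 = build_target(es, c[0].rep_trials, c[0].rep_times_ms, "II", center=c[0])
        for tg in (t1, t2):
            assert tg.t_min <= 10.0 + 0.2 and tg.t_max >= 10.0 - 0.2
        assert abs(t1.latency_ms - t2.latency_ms) < 0.1
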