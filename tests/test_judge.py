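"""Offline judgment: trial extraction, ROC statistics, jitter, success rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecollide.errors import ParameterError
from spikecollide.infer import CollisionTarget, quartile_deviation
from spikecollide.judge import (
    extract_trials,
    judge_pair,
    latency_and_jitter,
    robust_sigma,
    roc_auc,
)

FS = 20_000.0


def _target(t_min=9.8, t_max=10.2, d_i=1.0):
    return CollisionTarget(
        tetrode_id=0,
        site=0,
        protocol="I",
        u=np.array([-10.0, -4.0, -2.0, -1.0]),
        median_waveform=np.zeros((4, 5)),
        waveform_peak_idx=2,
        t_min=t_min,
        t_max=t_max,
        d_i=d_i,
        rep_times_ms=np.array([t_min, t_max]),
    )


class TestExtractTrials:
    STIMS = np.arange(40) * 1500.0  # ms, 1.5 s apart

    def test_range_formulas(self):
        """t_stim=0, D_i=1, t_min=9.8, t_max=10.2, R_max=4: trigger range
        [-7.8, 0], no-trigger range [-14.2, 0] relative to onset."""
        tg = _target()
        stims = self.STIMS
        # spikes at -7.7 ms before every second stimulation -> trigger trials
        spikes = np.sort(np.concatenate([stims[::2] - 7.7, stims[1::2] - 14.0]))
        pair = extract_trials(spikes, stims, tg, min_triggers=1)
        assert set(pair.trigger_trials.tolist()) == set(range(0, 40, 2))
        # odd trials have a spike at -14.0, inside [-14.2, 0] -> not no-trigger
        assert not set(pair.no_trigger_trials) & set(range(1, 40, 2))

    def test_boundary_spike_just_outside_no_trigger_range(self):
        tg = _target()
        spikes = self.STIMS[1::2] - 14.3  # just before -14.2
        pair = extract_trials(
            np.sort(np.concatenate([self.STIMS[::2] - 5.0, spikes])),
            self.STIMS,
            tg,
            min_triggers=1,
        )
        assert set(range(1, 40, 2)) <= set(pair.no_trigger_trials.tolist())

    def test_refractory_confound_dropped_before_classification(self):
        tg = _target()
        # a spike at t_min - 3 ms (3 < R_max = 4) post-stimulus: dropped
        spikes = np.sort(
            np.concatenate([self.STIMS[:20] - 5.0, [self.STIMS[0] + tg.t_min - 3.0]])
        )
        pair = extract_trials(spikes, self.STIMS, tg, min_triggers=1)
        assert 0 not in pair.trigger_trials
        assert pair.excluded_refractory == 1

    def test_fewer_than_15_triggers_excludes_pair(self):
        tg = _target()
        spikes = self.STIMS[:14] - 5.0
        assert extract_trials(np.sort(spikes), self.STIMS, tg) is None
        spikes = self.STIMS[:15] - 5.0
        assert extract_trials(np.sort(spikes), self.STIMS, tg) is not None

    def test_no_trigger_cap_ten_per_trigger(self):
        """Abundant quiet candidates + 20 well-separated triggers -> exactly
        10x as many no-trigger trials."""
        stims = np.arange(400) * 1500.0
        trigger_idx = np.arange(0, 400, 20)  # 20 triggers far apart
        spikes = np.sort(stims[trigger_idx] - 5.0)
        pair = extract_trials(spikes, stims, _target(), min_triggers=15)
        assert pair.n_trigger == 20
        assert pair.n_no_trigger == 10 * pair.n_trigger
        assert not set(pair.no_trigger_trials) & set(pair.trigger_trials)

    def test_duplicates_merged_when_triggers_cluster(self):
        stims = np.arange(60) * 1500.0
        spikes = np.sort(stims[:20] - 5.0)  # 20 adjacent triggers
        pair = extract_trials(spikes, stims, _target(), min_triggers=15)
        assert pair.n_no_trigger <= 10 * pair.n_trigger
        # adjacent triggers share the same nearest candidates: union is 10
        assert pair.n_no_trigger == 10


class TestRocAuc:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1.0, 1.0], [1.0, 1.0], 0.5),
            ([2.0, 3.0], [0.5, 1.0], 1.0),
            ([3.0, 5.0], [4.0], 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert roc_auc(a, b) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n, m = rng.integers(1, 51), rng.integers(1, 51)
            x = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = np.round(rng.normal(size=m), 1)
            brute = (
                (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
            ) / (n * m)
            assert roc_auc(x, y) == pytest.approx(brute, abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=30)
        assert roc_auc(x, y) + roc_auc(y, x) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            roc_auc([], [1.0])


class TestRobustSigma:
    def test_all_equal_zero(self):
        assert robust_sigma([0.5, 0.5, 0.5]) == 0.0

    def test_hand_example(self):
        assert robust_sigma([0.4, 0.5, 0.6]) == pytest.approx(0.1 / 0.6745)

    def test_consistent_for_gaussian(self, rng):
        assert robust_sigma(rng.normal(size=10_000)) == pytest.approx(1.0, rel=0.05)

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            robust_sigma([0.5])


class TestJudgePair:
    BATCH = np.concatenate([[0.99], 0.5 + 0.05 * np.sin(np.arange(60))])

    def test_long_jitter_never_succeeds(self):
        ok, _ = judge_pair(0.99, 0.3, self.BATCH)
        assert not ok

    def test_outlier_auc_with_short_jitter_succeeds(self):
        ok, sigma = judge_pair(0.99, 0.03, self.BATCH)
        assert ok
        assert 0.99 - np.median(self.BATCH) > 5 * sigma

    def test_chance_auc_fails(self):
        ok, _ = judge_pair(0.55, 0.03, self.BATCH)
        assert not ok


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
)
def test_roc_auc_swap_property(a, b):
    assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0, abs=1e-9)


class TestLatencyAndJitter:
    def _evoked(self, latencies_ms, amp=-12.0, rng=None):
        """Trial set with one clean spike per trial at the given latencies."""
        from spikecollide.infer import EvokedTrialSet
        from spikecollide.simulate import SpikeTemplate, StimulusEvent

        fs = FS
        tpl = SpikeTemplate(0.7)
        half = 600
        trials = np.zeros((len(latencies_ms), 4, 2 * half + 1))
        if rng is not None:
            trials += rng.normal(0, 0.3, trials.shape)
        grid = np.arange(2 * half + 1) / fs * 1000.0 - half / fs * 1000.0
        for i, lat in enumerate(latencies_ms):
            w = tpl.evaluate(grid - lat)
            for c, a in enumerate((amp, amp * 0.4, amp * 0.2, amp * 0.1)):
                trials[i, c] += abs(a) * w  # template trough is -1

        stims = [StimulusEvent(site=0, t_stim=int(k * 30000), duration_ms=1.0) for k in range(len(latencies_ms))]
        return EvokedTrialSet(tetrode_id=0, site=0, trials=trials, fs=fs, stims=stims)

    def test_identical_latencies_zero_jitter(self):
        es = self._evoked([10.0] * 6)
        lat, qd = latency_and_jitter(es, np.arange(6), _target())
        assert qd == pytest.approx(0.0, abs=1e-6)
        assert lat == pytest.approx(10.0, abs=0.02)

    def test_quartile_convention_matches_oracle(self):
        lats = [9.9, 10.0, 10.1, 10.2]
        es = self._evoked(lats)
        _, qd = latency_and_jitter(es, np.arange(4), _target(t_min=9.8, t_max=10.3))
        assert qd == pytest.approx(quartile_deviation(lats), abs=0.01)

    def test_half_sample_offsets_recovered(self):
        # spikes at exact half-sample offsets: spline recovers within 0.01 ms
        lats = [10.0, 10.025, 10.05, 10.075]
        es = self._evoked(lats)
        for i, true in enumerate(lats):
            lat, _ = latency_and_jitter(
                es, np.array([i] * 4), _target(t_min=9.8, t_max=10.3), min_evoked=1
            )
            assert lat == pytest.approx(true, abs=0.01)

    def test_too_few_evoked_spikes_errors(self):
        es = self._evoked([10.0] * 3)
        with pytest.raises(ParameterError):
            latency_and_jitter(es, np.arange(3), _target(), min_evoked=4)
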