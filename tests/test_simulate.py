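"""Simulator: scheduling, collision physics, ground truth, rendering."""

import numpy as np
import pytest

from spikecollide.errors import ParameterError, SchedulingError
from spikecollide.infer import quartile_deviation
from spikecollide.simulate import (
    Projection,
    SimNeuron,
    SpikeTemplate,
    evoked_spike_outcome,
    make_ground_truth,
    render_recording,
    schedule_stimulations,
)

from conftest import single_projection_config


class TestSchedule:
    def test_single_event(self):
        ev = schedule_stimulations([7], n_anti=1, session_length=10.0, seed=0)
        assert len(ev) == 1 and ev[0].site == 7

    def test_defaults_counts_and_gaps(self):
        ev = schedule_stimulations([0, 1, 2], n_anti=100, session_length=600.0, seed=4)
        assert len(ev) == 300
        t = np.array([e.t_stim for e in ev]) / 20_000.0
        sites = np.array([e.site for e in ev])
        for s in (0, 1, 2):
            assert (sites == s).sum() == 100
            assert np.diff(np.sort(t[sites == s])).min() >= 1.0
        assert np.diff(np.sort(t)).min() >= 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_per_site_count_for_any_seed(self, seed):
        ev = schedule_stimulations([0, 1], n_anti=7, session_length=60.0, seed=seed)
        sites = [e.site for e in ev]
        assert sites.count(0) == 7 and sites.count(1) == 7

    def test_infeasible_session_errors(self):
        with pytest.raises(SchedulingError):
            schedule_stimulations([0], n_anti=100, session_length=5.0, seed=0)


class TestEvokedSpikeOutcome:
    P = {"d": 1.0, "C": 9.0, "R": 2.0, "R_prime": 1.0}

    def test_no_spontaneous_spikes_present(self):
        out = evoked_spike_outcome(self.P, 0.0, 1.0, np.array([]), "antidromic")
        assert out.present

    def test_collision_eliminates_antidromic_only(self):
        # t_spon + C + R' = -5 + 9 + 1 = 5 >= t_stim + d = 1 -> collision
        sp = np.array([-5.0])
        anti = evoked_spike_outcome(self.P, 0.0, 1.0, sp, "antidromic")
        syn = evoked_spike_outcome(self.P, 0.0, 1.0, sp, "synaptic")
        assert not anti.present and anti.cause == "collision"
        assert syn.present

    def test_missing_spike_does_not_collide(self):
        # -9.5 + 9 + 1 = 0.5 < 1: the spontaneous spike cleared the site
        out = evoked_spike_outcome(self.P, 0.0, 1.0, np.array([-9.5]), "antidromic")
        assert out.present

    def test_refractory_eliminates_both_kinds(self):
        sp = np.array([9.0])  # within R=2 before arrival at 10
        syn = evoked_spike_outcome(self.P, 0.0, 1.0, sp, "synaptic")
        assert not syn.present and syn.cause == "refractory"
        # the same spike also collides with the antidromic spike on the axon
        anti = evoked_spike_outcome(self.P, 0.0, 1.0, sp, "antidromic")
        assert not anti.present and anti.cause == "collision"

    def test_collision_takes_precedence(self):
        sp = np.array([8.5])  # collides AND leaves the soma refractory
        out = evoked_spike_outcome(self.P, 0.0, 1.0, sp, "antidromic")
        assert out.cause == "collision"


class TestGroundTruth:
    def test_zero_neurons_empty_events(self):
        from spikecollide.simulate import SimConfig

        cfg = SimConfig(neurons=[], sites=[0], n_tetrodes=1, session_length=30.0, n_anti=5)
        truth = make_ground_truth(cfg, seed=0)
        assert len(truth.events) == 0

    def test_fixed_seed_reproducible(self):
        cfg = single_projection_config(n_anti=10, session_length=30.0)
        a = make_ground_truth(cfg, seed=9)
        b = make_ground_truth(cfg, seed=9)
        assert a.events.equals(b.events)
        assert [s.t_stim for s in a.schedule] == [s.t_stim for s in b.schedule]

    def test_antidromic_vs_synaptic_jitter(self, rng):
        from spikecollide.simulate import SimConfig, SynapticInput

        proj = SimNeuron(
            id=0,
            tetrode_id=0,
            amp_pattern=np.array([-20.0, -10, -5, -2]),
            rate=0.0,
            projections=[Projection(site=0, d=0.7, C=9.3, jitter_sd=0.05)],
        )
        syn = SimNeuron(
            id=1,
            tetrode_id=0,
            amp_pattern=np.array([-15.0, -8, -4, -2]),
            rate=0.0,
            synaptic_inputs=[SynapticInput(site=0, latency=10.0, jitter_qd=1.0)],
        )
        cfg = SimConfig(
            neurons=[proj, syn], sites=[0], n_tetrodes=1, session_length=200.0, n_anti=100
        )
        truth = make_ground_truth(cfg, seed=2)
        ev = truth.events
        anti = ev[(ev.kind == "antidromic")]["t_ms"].to_numpy()
        stim = np.array([s.t_stim_ms(cfg.fs) for s in truth.schedule])
        lat_anti = anti - stim[ev[ev.kind == "antidromic"]["stim_index"].to_numpy()]
        synap = ev[ev.kind == "synaptic"]
        lat_syn = synap["t_ms"].to_numpy() - stim[synap["stim_index"].to_numpy()]
        assert quartile_deviation(lat_anti) < 0.25
        assert quartile_deviation(lat_syn) > 0.25

    def test_eliminated_events_have_cause(self):
        cfg = single_projection_config(rate=30.0, n_anti=40, session_length=120.0)
        truth = make_ground_truth(cfg, seed=5)
        ev = truth.events
        assert (ev.loc[ev.eliminated, "cause"] != "none").all()
        assert (ev.loc[~ev.eliminated, "cause"] == "none").all()
        anti = ev[ev.kind == "antidromic"]
        assert (anti["stim_index"] >= 0).all()

    def test_invalid_config_names_field(self):
        from spikecollide.simulate import SimConfig

        cfg = SimConfig(neurons=[], sites=[], n_tetrodes=1)
        with pytest.raises(ParameterError, match="sites"):
            make_ground_truth(cfg, seed=0)


class TestRendering:
    def test_no_neurons_no_noise_all_zero(self):
        from spikecollide.simulate import SimConfig

        cfg = SimConfig(
            neurons=[], sites=[0], n_tetrodes=1, session_length=5.0, n_anti=2, noise_sd=0.0
        )
        truth = make_ground_truth(cfg, seed=0)
        seg = render_recording(truth)
        assert not seg.samples.any()

    def test_noise_free_detection_matches_ground_truth(self):
        """Conservation: with no noise, detection recall and precision are 1
        against the non-eliminated events."""
        cfg = single_projection_config(
            rate=6.0, noise_sd=0.0, n_anti=5, session_length=20.0, jitter_sd=0.0
        )
        truth = make_ground_truth(cfg, seed=8)
        seg = render_recording(truth)
        # variance state seeded at a nominal noise floor of 1 (no noise in the
        # rendering, so every template crossing is supra-threshold)
        from spikecollide.signal import FilterState, online_highpass, detect_spikes

        x = seg.tetrode_samples(0)
        state = FilterState(y=x[0].copy(), v=1.0, gain_y=0.2, gain_v=1e-12)
        z = online_highpass(x, state)
        spikes = detect_spikes(z, state, theta_sp=4.0)
        live = truth.events[~truth.events.eliminated]
        expected = np.sort(live["t_ms"].to_numpy() * cfg.fs / 1000.0)
        got = np.sort([s.t for s in spikes])
        # recall 1.0: every surviving event detected at its trough (the causal
        # filter may shift the rectified peak by a sample or two)
        for t in expected:
            assert np.any(np.abs(got - t) <= 2.6)
        # precision 1.0: every detection belongs to a surviving event (the
        # causal filter's rebound after the positive lobe stays within a few
        # samples of the waveform support)
        for t in got:
            assert np.any((expected - 3 <= t) & (t <= expected + 0.003 * cfg.fs))

    def test_evoked_scale_visible_in_rendered_peaks(self):
        cfg = single_projection_config(rate=10.0, noise_sd=0.0, n_anti=40, session_length=120.0)
        cfg.neurons[0].evoked_scale = 1.2
        truth = make_ground_truth(cfg, seed=3)
        seg = render_recording(truth)
        x = seg.tetrode_samples(0)[:, 0]
        ev = truth.events[~truth.events.eliminated]
        peaks = {"spontaneous": [], "antidromic": []}
        for r in ev.itertuples():
            k = int(round(r.t_ms * cfg.fs / 1000.0))
            peaks[r.kind].append(-x[max(0, k - 2) : k + 3].min())
        ratio = np.median(peaks["antidromic"]) / np.median(peaks["spontaneous"])
        assert ratio == pytest.approx(1.2, rel=0.05)


class TestCollisionTrialInvariant:
    def test_trigger_trials_always_eliminate_no_trigger_never(self, rng):
        """Constructed per the judgment ranges: spikes inside the trigger
        range always collide; quiet no-trigger ranges never collide
        (1000 trials each)."""
        d, C, R, Rp = 0.7, 9.3, 2.8, 1.0
        proj = {"d": d, "C": C, "R": R, "R_prime": Rp}
        t_min, t_max, d_i = 9.9, 10.1, 1.0
        l_min = t_min - d_i
        for _ in range(1000):
            t_spon = rng.uniform(2 * d_i - t_min, 0.0)  # trigger range
            out = evoked_spike_outcome(proj, 0.0, d_i, np.array([t_spon]), "antidromic")
            assert not out.present and out.cause == "collision"
        for _ in range(1000):
            # spike strictly before the no-trigger range
            t_spon = -(t_max + 4.0) - rng.uniform(0.1, 50.0)
            out = evoked_spike_outcome(proj, 0.0, d_i, np.array([t_spon]), "antidromic")
            assert out.cause != "collision"


class TestTemplate:
    def test_trough_normalized(self):
        tpl = SpikeTemplate(0.7)
        assert tpl.evaluate(np.array([0.0]))[0] == pytest.approx(-1.0)

    def test_wide_narrow_duration_dichotomy(self):
        from spikecollide.metrics import trough_to_peak

        wide = trough_to_peak(SpikeTemplate(0.7).sample(20_000), 20_000)
        narrow = trough_to_peak(SpikeTemplate(0.3).sample(20_000), 20_000)
        assert wide > 0.5 > narrow

    def test_invalid_duration(self):
        with pytest.raises(ParameterError):
            SpikeTemplate(trough_to_peak_ms=-1.0)
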