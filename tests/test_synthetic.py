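"""Generator contracts: tuning model, noise statistics, determinism, stacks."""

import numpy as np
import pytest

from headvel.stimuli import make_rotation_stimulus
from headvel.synthetic import (TuningSpec, simulate_behavior_session,
                               simulate_eye_trace, simulate_population,
                               simulate_rotating_stack, simulate_vm_trial,
                               read_trials, write_trials)


class TestVmTrialModel:
    def test_zero_gain_zero_noise_gives_flat_baseline(self, stim_fast):
        spec = TuningSpec(response_class="NONE", gain_cw=0, gain_ccw=0,
                          noise_sd=0.0)
        t = simulate_vm_trial(stim_fast, spec, seed=0, insert_spikes=False)
        np.testing.assert_allclose(t.vm, spec.baseline)

    def test_noiseless_on_cell_is_exactly_linear_in_speed(self, stim_fast):
        g = 0.05
        spec = TuningSpec(gain_cw=g, gain_ccw=g, noise_sd=0.0)
        t = simulate_vm_trial(stim_fast, spec, seed=0, insert_spikes=False)
        speed = np.abs(np.interp(t.time, stim_fast.time, stim_fast.velocity))
        np.testing.assert_allclose(t.vm - spec.baseline, g * speed, atol=1e-12)

    def test_ou_noise_variance_matches_spec(self):
        # long noise-only trial: sample variance within 5% of noise_sd^2
        stim = make_rotation_stimulus(90, 80, pre_s=60.0, post_s=0.0, dt=1e-3)
        spec = TuningSpec(response_class="NONE", gain_cw=0, gain_ccw=0,
                          noise_sd=2.0, noise_tau=0.02)
        t = simulate_vm_trial(stim, spec, seed=5, insert_spikes=False)
        pre = t.vm[t.time < 60.0]
        assert np.var(pre) == pytest.approx(spec.noise_sd**2, rel=0.05)

    def test_spikes_inserted_above_threshold_and_recorded(self, stim_fast):
        spec = TuningSpec(gain_cw=0.2, gain_ccw=0.2, noise_sd=1.0,
                          spike_threshold=-52.0)
        t = simulate_vm_trial(stim_fast, spec, seed=3, insert_spikes=True)
        assert t.spike_times.size > 0
        assert t.spike_times.min() >= t.time[0]
        assert t.spike_times.max() <= t.time[-1]
        assert t.vm.max() > spec.spike_threshold + 20  # waveform overshoot

    def test_vestibulo_visual_is_exact_sum_of_components(self, stim_fast):
        spec = TuningSpec(gain_cw=0.05, gain_ccw=0.02, noise_sd=0.0)
        kw = dict(insert_spikes=False, visual_gain=0.03)
        dark = simulate_vm_trial(stim_fast, spec, seed=0, condition="dark", **kw)
        vis = simulate_vm_trial(stim_fast, spec, seed=0,
                                condition="visual_only", **kw)
        both = simulate_vm_trial(stim_fast, spec, seed=0,
                                 condition="vestibulo_visual", **kw)
        np.testing.assert_allclose(
            both.vm - spec.baseline,
            (dark.vm - spec.baseline) + (vis.vm - spec.baseline), atol=1e-10)

    def test_lesion_condition_has_no_rotation_response(self, stim_fast):
        spec = TuningSpec(gain_cw=0.1, gain_ccw=0.1, noise_sd=0.0)
        t = simulate_vm_trial(stim_fast, spec, seed=0, condition="lesion",
                              insert_spikes=False)
        np.testing.assert_allclose(t.vm, spec.baseline)

    @pytest.mark.parametrize("cls,cw,ccw", [
        ("NONE", 0.1, 0.0), ("ON", -0.1, 0.1),
        ("OFF", 0.1, -0.1), ("ON_OFF", 0.1, 0.1),
    ])
    def test_tuning_class_invariants_enforced(self, cls, cw, ccw):
        with pytest.raises(ValueError):
            TuningSpec(response_class=cls, gain_cw=cw, gain_ccw=ccw)


class TestPopulation:
    def test_default_geometry_348_trials_8_neurons(self, population348):
        assert len(population348) == 348
        assert population348.n_source_neurons == 8
        assert set(t.neuron_id for t in population348.trials) == set(range(8))
        assert set(population348.truth) == set(range(8))

    def test_all_none_mix_yields_untuned_population(self):
        pop = simulate_population(n_trials=16, n_neurons=4,
                                  class_mix={"NONE": 1.0}, seed=0)
        assert all(s.gain_cw == 0 and s.gain_ccw == 0
                   for s in pop.truth.values())

    def test_fixed_seed_regenerates_identically(self):
        a = simulate_population(n_trials=12, n_neurons=3, seed=9)
        b = simulate_population(n_trials=12, n_neurons=3, seed=9)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.vm, tb.vm)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(n_trials=8, n_neurons=2,
                                class_mix={"ON": -1.0}, seed=0)
        with pytest.raises(ValueError):
            simulate_population(n_trials=8, n_neurons=2,
                                class_mix={"BLUE": 1.0}, seed=0)

    def test_csv_json_round_trip(self, tmp_path):
        pop = simulate_population(n_trials=6, n_neurons=2, seed=1,
                                  sample_rate=250.0)
        write_trials(tmp_path / "pop", pop)
        back = read_trials(tmp_path / "pop")
        assert len(back) == len(pop)
        assert back.truth[0].response_class == pop.truth[0].response_class
        np.testing.assert_allclose(back.trials[0].vm, pop.trials[0].vm,
                                   atol=1e-5)
        np.testing.assert_allclose(
            back.stimuli["stim"].velocity, pop.stimuli["stim"].velocity,
            atol=1e-9)


class TestBehaviorSessionGenerator:
    def test_block_structure_10_plus_10(self):
        s = simulate_behavior_session(1, n_blocks=5, seed=0)
        assert len(s.trials) == 100
        for block in s.blocks():
            labels = [t.stimulus for t in block]
            assert labels.count("S+") == 10 and labels.count("S-") == 10

    def test_at_most_three_identical_consecutive_stimuli_per_block(self):
        s = simulate_behavior_session(1, n_blocks=20, seed=1)
        for block in s.blocks():
            run = 1
            for a, b in zip(block, block[1:]):
                run = run + 1 if a.stimulus == b.stimulus else 1
                assert run <= 3

    def test_perfect_observer_scores_100(self):
        from headvel.behavior import session_accuracies
        s = simulate_behavior_session(5, n_blocks=4, hit_rate=1.0,
                                      fa_rate=0.0, seed=2)
        assert session_accuracies(s) == [100.0] * 4

    def test_chance_observer_near_50(self):
        from headvel.behavior import session_accuracies
        s = simulate_behavior_session(1, n_blocks=50, hit_rate=0.5,
                                      fa_rate=0.5, seed=3)
        assert np.mean(session_accuracies(s)) == pytest.approx(50.0, abs=5.0)


class TestRotatingStack:
    def _base(self):
        yy, xx = np.mgrid[0:64, 0:64]
        return 100.0 + 300.0 * np.exp(-((xx - 30) ** 2 + (yy - 34) ** 2) / 50.0)

    def test_zero_encoder_gives_identical_frames(self):
        base = self._base()
        stack, angles, _ = simulate_rotating_stack(base, np.zeros(10), seed=0)
        assert np.all(angles == 0)
        for f in stack:
            np.testing.assert_array_equal(f, base)

    def test_encoder_channel_quantized_to_0_05_degrees(self):
        base = self._base()
        enc = np.random.default_rng(0).uniform(-30, 30, 40)
        _, angles, _ = simulate_rotating_stack(base, enc, seed=0)
        np.testing.assert_allclose(np.round(angles / 0.05) * 0.05, angles,
                                   atol=1e-9)

    def test_transient_ground_truth_returned(self):
        base = self._base()
        mask = np.zeros((64, 64), bool)
        mask[30:38, 26:34] = True
        _, _, truth = simulate_rotating_stack(
            base, np.zeros(50), seed=0, transient_rois=[mask],
            transient_times=[[5, 30]])
        np.testing.assert_array_equal(truth[0], [5, 30])

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            simulate_rotating_stack(self._base(), np.zeros(5),
                                    center=(100, 100))

    def test_encoder_slower_than_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_rotating_stack(self._base(), np.zeros(5),
                                    frame_rate=25.0, encoder_rate=10.0)


class TestEyeTrace:
    def test_injected_events_present_in_trace(self):
        time, pos, onsets, directions = simulate_eye_trace(
            duration_s=30, n_events=6, amplitude=4.0, seed=0)
        assert len(onsets) == 6 and len(directions) == 6
        assert np.all(np.diff(onsets) > 0)
        # each saccade moves the trace by about its amplitude
        i = int(onsets[0] * 120)
        assert abs(pos[i + 2] - pos[i - 2]) > 2.0


class TestOuNoise:
    def test_reference_and_filtered_implementations_agree(self):
        # the readable recursion and the lfilter-based path are the same
        # process driven by the same white-noise draw
        from headvel.synthetic import _ou_noise_fast, ou_noise

        a = ou_noise(500, 1e-3, 2.0, 0.02, np.random.default_rng(0))
        b = _ou_noise_fast(500, 1e-3, 2.0, 0.02, np.random.default_rng(0))
        np.testing.assert_allclose(a, b, atol=1e-10)
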