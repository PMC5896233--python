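"""Spike clipping, rotation-response detection, classification, eye events."""

import numpy as np
import pytest

from headvel.response_stats import (ResponseResult, classify_cell, clip_spikes,
                                    detect_eye_events, event_triggered_vm,
                                    rotation_response)
from headvel.synthetic import TuningSpec, VmTrial, simulate_vm_trial


def _result(direction, delta, p, cell="c"):
    return ResponseResult(
        cell_id=cell, direction=direction, mode="vm", mean_baseline=-60.0,
        mean_rotation=-60.0 + delta, delta=delta, p_value=p,
        significant=p < 0.05, peak_amplitude=abs(delta) if p < 0.05 else None,
        n_trials=10)


class TestClipSpikes:
    def test_trial_without_spikes_unchanged(self, stim_fast):
        t = simulate_vm_trial(stim_fast, TuningSpec(), seed=0,
                              insert_spikes=False)
        np.testing.assert_array_equal(clip_spikes(t), t.vm)

    def test_clipping_recovers_spike_free_response(self, stim_baseline):
        # paired simulation: same seed with and without spike insertion
        spec = TuningSpec(gain_cw=0.15, gain_ccw=0.1, noise_sd=1.0,
                          spike_threshold=-53.0)
        with_spk = simulate_vm_trial(stim_baseline, spec, seed=11,
                                     insert_spikes=True)
        without = simulate_vm_trial(stim_baseline, spec, seed=11,
                                    insert_spikes=False)
        assert with_spk.spike_times.size >= 5
        m0, m1 = stim_baseline.motion_window()
        sel = (with_spk.time >= m0) & (with_spk.time <= m1)
        clipped = clip_spikes(with_spk)
        err = abs(clipped[sel].mean() - without.vm[sel].mean())
        assert err < 0.1

    def test_spike_at_trace_edge_truncates_window(self):
        time = np.arange(100) / 1000.0
        vm = np.full(100, -60.0)
        vm[:3] = 0.0
        t = VmTrial(time=time, vm=vm, sample_rate=1000.0, stimulus_id="s",
                    spike_times=np.array([0.0]))
        out = clip_spikes(t)
        assert out.shape == vm.shape
        assert np.isfinite(out).all()


class TestRotationResponse:
    def test_identical_means_degenerate(self, stim_baseline):
        spec = TuningSpec(response_class="NONE", gain_cw=0, gain_ccw=0,
                          noise_sd=0.0)
        trials = [simulate_vm_trial(stim_baseline, spec, seed=i,
                                    insert_spikes=False) for i in range(6)]
        res = rotation_response(trials, stim_baseline, "CW")
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_tuned_cell_detected_with_positive_delta(self, on_trials,
                                                     stim_baseline):
        res = rotation_response(on_trials, stim_baseline, "CW")
        assert res.significant and res.delta > 0
        assert res.peak_amplitude is not None
        assert res.peak_amplitude >= abs(res.delta)

    def test_spike_mode_detects_rate_increase(self, stim_baseline):
        spec = TuningSpec(gain_cw=0.25, gain_ccw=0.25, noise_sd=1.0,
                          spike_threshold=-52.0)
        rng = np.random.default_rng(2)
        trials = [simulate_vm_trial(stim_baseline, spec, seed=rng)
                  for _ in range(8)]
        res = rotation_response(trials, stim_baseline, "CW", mode="spikes")
        assert res.delta > 0 and res.significant

    def test_fewer_than_four_trials_rejected(self, on_trials, stim_baseline):
        with pytest.raises(ValueError):
            rotation_response(on_trials[:3], stim_baseline, "CW")

    def test_null_rejection_rate_calibrated(self):
        # untuned cells: about 5% of direction tests significant at 0.05
        from headvel.stimuli import make_rotation_stimulus

        stim = make_rotation_stimulus(20, 80, pre_s=2.0, post_s=0.1, dt=4e-3)
        spec = TuningSpec(response_class="NONE", gain_cw=0, gain_ccw=0,
                          noise_sd=2.0)
        rng = np.random.default_rng(2024)
        n_cells, n_trials = 1000, 15
        hits = 0
        for _ in range(n_cells):
            trials = [simulate_vm_trial(stim, spec, seed=rng,
                                        insert_spikes=False)
                      for _ in range(n_trials)]
            hits += rotation_response(trials, stim, "CW").significant
        # attainable exact level for n=15 is 0.0479; 2 SE band around it
        rate = hits / n_cells
        se = np.sqrt(0.05 * 0.95 / n_cells)
        assert abs(rate - 0.0479) < 2 * se + 0.005


class TestClassifyCell:
    def test_on_off_cell_has_dsi_one(self):
        cls = classify_cell(_result("CW", +2.0, 0.01),
                            _result("CCW", -1.5, 0.01))
        assert cls.response_class == "ON_OFF" and cls.dsi == 1.0

    def test_two_significant_depolarizations_give_on(self):
        cls = classify_cell(_result("CW", +2.0, 0.01),
                            _result("CCW", +1.0, 0.01))
        assert cls.response_class == "ON"
        assert cls.dsi == pytest.approx((2 - 1) / (2 + 1))
        assert cls.pref_direction == "CW"

    def test_equal_deltas_give_zero_dsi(self):
        cls = classify_cell(_result("CW", -1.0, 0.01),
                            _result("CCW", -1.0, 0.01))
        assert cls.response_class == "OFF" and cls.dsi == pytest.approx(0.0)

    def test_nonsignificant_cell_unclassified(self):
        cls = classify_cell(_result("CW", +2.0, 0.4),
                            _result("CCW", -1.0, 0.6))
        assert cls.response_class == "NONE" and cls.dsi is None

    def test_argument_order_irrelevant(self):
        a = classify_cell(_result("CW", +2.0, 0.01), _result("CCW", +1.0, 0.01))
        b = classify_cell(_result("CCW", +1.0, 0.01), _result("CW", +2.0, 0.01))
        assert (a.response_class, a.dsi) == (b.response_class, b.dsi)

    def test_noiseless_on_off_cell_end_to_end(self, stim_baseline):
        spec = TuningSpec(response_class="ON_OFF", gain_cw=0.05,
                          gain_ccw=-0.04, noise_sd=0.0)
        trials = [simulate_vm_trial(stim_baseline, spec, seed=i,
                                    insert_spikes=False) for i in range(10)]
        cw = rotation_response(trials, stim_baseline, "CW")
        ccw = rotation_response(trials, stim_baseline, "CCW")
        cls = classify_cell(cw, ccw)
        assert cls.response_class == "ON_OFF" and cls.dsi == 1.0


class TestEyeEvents:
    def test_constant_position_gives_no_events(self):
        assert detect_eye_events(np.full(1000, 3.0)) == []

    def test_injected_step_detected_at_onset(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 0.02, 1200)
        pos[600:] += 5.0
        events = detect_eye_events(pos, sample_rate=120.0)
        assert len(events) == 1
        assert events[0].onset == pytest.approx(600 / 120.0, abs=1 / 120.0)
        assert events[0].direction == "temporal_to_medial"

    def test_threshold_outside_stated_range_rejected(self):
        with pytest.raises(ValueError):
            detect_eye_events(np.zeros(100), k_sd=4.0)


class TestEventTriggeredVm:
    def test_injected_step_detected(self):
        sr = 1000.0
        rng = np.random.default_rng(1)
        vm = rng.normal(-60, 0.3, 20000)
        onsets = np.arange(1.0, 19.0, 1.0)
        for t0 in onsets:
            i = int(t0 * sr)
            vm[i + 50 :] += 0.0  # no persistent shift
            vm[i + 60 : i + 110] += 1.0  # +1 mV in the post window
        pre, post, res, dropped = event_triggered_vm(onsets, vm, sr)
        assert dropped == 0
        assert (post - pre).mean() > 0.5
        assert res.p_value < 0.05

    def test_event_near_trace_end_dropped(self):
        vm = np.zeros(1000)
        _, _, _, dropped = event_triggered_vm([0.5, 0.999], vm, 1000.0)
        assert dropped == 1

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            event_triggered_vm([], np.zeros(100), 100.0)
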