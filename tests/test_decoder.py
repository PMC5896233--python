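"""Profile construction, conditional models, naive-Bayes decoding, sweeps."""

import numpy as np
import pytest

from headvel.decoder import (N_VELOCITY_BINS, ResponseProfile, build_profiles,
                             decode, decode_bins, decoding_error,
                             fit_conditional, network_sweep, profile_matrix,
                             random_baseline_error, velocity_bin_centers)


def _profile(values, cid=0):
    v = np.asarray(values, float)
    lo, hi = v.min(), v.max()
    norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return ResponseProfile(cell_id=cid, vm_vs_velocity=v, vbar=float(v.mean()),
                           sign=1, normalized=norm)


def posterior_oracle(observations, models):
    """Direct product-of-probabilities argmax, no log domain."""
    n_vel = models[0].histograms.shape[0]
    post = np.ones(n_vel)
    for obs, m in zip(observations, models):
        j = min(int(obs * m.response_bins), m.response_bins - 1)
        post = post * m.histograms[:, j]
    return float(np.argmax(post) + 0.5)


class TestBuildProfiles:
    def test_one_profile_per_trial(self, population348):
        profiles = build_profiles(population348)
        assert len(profiles) == 348
        assert all(p.normalized.shape == (N_VELOCITY_BINS,) for p in profiles)

    def test_normalization_spans_unit_interval(self, population348):
        V = profile_matrix(build_profiles(population348))
        np.testing.assert_allclose(V.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(V.max(axis=1), 1.0, atol=1e-12)

    def test_off_neurons_sign_corrected(self, population348):
        profiles = build_profiles(population348)
        off_ids = [nid for nid, spec in population348.truth.items()
                   if spec.response_class == "OFF"]
        assert off_ids, "default mix should include an OFF neuron"
        flipped = [p for p in profiles if p.neuron_id in off_ids]
        assert all(p.sign == -1 for p in flipped)
        assert all(p.vbar < 0 for p in flipped)

    def test_minmax_arithmetic(self):
        p = _profile(np.linspace(-2, 6, N_VELOCITY_BINS))
        # value 2 sits at (2 - (-2)) / (6 - (-2)) = 0.5
        idx = np.argmin(np.abs(p.vm_vs_velocity - 2.0))
        assert p.normalized[idx] == pytest.approx(0.5, abs=0.01)


class TestConditionalModel:
    def test_histograms_are_distributions(self):
        profs = [_profile(np.linspace(0, 1, 80) ** (1 + 0.1 * i), cid=i)
                 for i in range(6)]
        m = fit_conditional(profs, held_out_id=0)
        np.testing.assert_allclose(m.histograms.sum(axis=1), 1.0)

    def test_identical_others_give_near_point_mass(self):
        profs = [_profile(np.linspace(0, 1, 80), cid=i) for i in range(11)]
        m = fit_conditional(profs, held_out_id=0, B=10, alpha=1.0)
        # 10 identical cells, B=10, alpha=1: mode (10+1)/(10+10), rest 1/20
        assert m.histograms.max(axis=1) == pytest.approx(11 / 20)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_conditional([_profile(np.linspace(0, 1, 80))], held_out_id=0)


class TestDecode:
    def test_matches_direct_posterior_enumeration(self):
        rng = np.random.default_rng(0)
        profs = [_profile(np.sort(rng.random(80)), cid=i) for i in range(8)]
        models = [fit_conditional(profs, held_out_id=i) for i in range(4)]
        obs = [profs[i].normalized[33] for i in range(4)]
        assert decode(obs, models) == posterior_oracle(obs, models)

    def test_self_trained_increasing_profile_decodes_own_bin(self):
        prof = np.linspace(0, 1, 80)
        profs = [_profile(prof, cid=i) for i in range(10)]
        m = fit_conditional(profs, held_out_id=0, B=10)
        pred = decode([prof[40]], [m])
        # observation at 40 deg/s: B=10 response bins alias 8 velocity bins;
        # the lowest-tie rule picks the first bin of the aliased run
        assert pred == 40.5

    def test_uniform_conditionals_give_lowest_center(self):
        from headvel.decoder import ConditionalModel
        m = ConditionalModel(histograms=np.full((80, 10), 0.1),
                             response_bins=10, smoothing=1.0)
        assert decode([0.7], [m]) == 0.5

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            decode([], [])


class TestDecodingError:
    def test_perfect_predictions_give_zero(self):
        assert decoding_error(velocity_bin_centers()) == 0.0

    def test_constant_center_prediction_gives_20(self):
        assert decoding_error(np.full(80, 40.5)) == pytest.approx(20.0)

    def test_random_baseline_closed_form(self):
        assert random_baseline_error() == pytest.approx(26.66, abs=0.01)
        rng = np.random.default_rng(0)
        sims = [decoding_error(rng.integers(0, 80, 80) + 0.5)
                for _ in range(2000)]
        assert np.mean(sims) == pytest.approx(random_baseline_error(),
                                              rel=0.02)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decoding_error(np.zeros(79))


class TestNetworkSweep:
    def test_error_invariant_to_cell_relabeling(self, population348):
        profiles = build_profiles(population348)[:40]
        V = profile_matrix(profiles)
        perm = np.random.default_rng(0).permutation(40)
        a = decode_bins(V, B=10, alpha=1.0)
        b = decode_bins(V[perm], B=10, alpha=1.0)
        np.testing.assert_array_equal(a, b)

    def test_error_decreases_with_network_size(self, population348):
        profiles = build_profiles(population348)
        sweep = network_sweep(profiles, [6, 30, 100], n_repeats=30, seed=1)
        med = sweep.groupby("k")["error"].median()
        assert med[100] < med[30] < med[6] < random_baseline_error()

    def test_k_equal_n_collapses_to_single_subset(self, population348):
        profiles = build_profiles(population348)[:30]
        sweep = network_sweep(profiles, [30], n_repeats=50, seed=2)
        assert len(sweep) == 1

    def test_k_one_uses_each_trial_once(self, population348):
        profiles = build_profiles(population348)[:25]
        sweep = network_sweep(profiles, [1], n_repeats=10, seed=3)
        assert len(sweep) == 25

    def test_reproducible_under_fixed_seed(self, population348):
        profiles = build_profiles(population348)[:60]
        a = network_sweep(profiles, [6], n_repeats=10, seed=11)
        b = network_sweep(profiles, [6], n_repeats=10, seed=11)
        assert a.equals(b)

    def test_untuned_population_stays_at_random_baseline(self):
        from headvel.synthetic import simulate_population
        pop = simulate_population(n_trials=80, n_neurons=4,
                                  class_mix={"NONE": 1.0}, seed=6,
                                  sample_rate=500.0)
        profiles = build_profiles(pop)
        sweep = network_sweep(profiles, [20], n_repeats=40, seed=7)
        mean_err = sweep["error"].mean()
        se = sweep["error"].std() / np.sqrt(len(sweep))
        assert abs(mean_err - random_baseline_error()) < max(2 * se, 2.0)

    def test_k_out_of_range_rejected(self, population348):
        profiles = build_profiles(population348)[:10]
        with pytest.raises(ValueError):
            network_sweep(profiles, [11], n_repeats=2, seed=0)
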