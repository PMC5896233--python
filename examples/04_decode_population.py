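"""Decode angular velocity from a population of single-trial profiles.

Builds the default 348-trial / 8-neuron synthetic population, converts each
trial to a sign-corrected, normalized response profile (vm as a function of
|velocity|, 1 deg/s bins over 0-80), and sweeps naive-Bayes decoding error
versus network size.  Error should fall well below the 26.66 deg/s
random-guess baseline and shrink as cells are added.
"""

from headvel import (build_profiles, network_sweep, random_baseline_error,
                     simulate_population)

population = simulate_population(n_trials=348, n_neurons=8, seed=42)
profiles = build_profiles(population)
print(f"{len(profiles)} profiles from {population.n_source_neurons} neurons")

sweep = network_sweep(profiles, k_values=[1, 6, 25, 100], n_repeats=50,
                      seed=7)
print(f"random baseline: {random_baseline_error():.2f} deg/s")
for k, med in sweep.groupby("k")["error"].median().items():
    print(f"  k = {k:3d}: median error {med:6.2f} deg/s")
# Each error is the mean absolute deviation between the 80 decoded
# velocities and the true bin centers; ~100 cells suffice for a faithful
# estimate, single trials barely beat guessing.
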