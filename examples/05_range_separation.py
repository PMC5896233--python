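"""How well does a k-cell network separate overlapping velocity ranges?

Decodes every 1-deg/s bin of the slow (0-27 deg/s) and fast (0-80 deg/s)
stimulus ranges over many random subsets, counts estimates erroneously
above 27 deg/s, computes the area-based separation index, and runs a
Fisher exact test per iteration on the outside/inside proportions.
"""

from headvel import build_profiles, erroneous_fraction, separation_analysis
from headvel.synthetic import simulate_population

population = simulate_population(n_trials=348, n_neurons=8, seed=42)
profiles = build_profiles(population)

for k in (6, 100):
    res = separation_analysis(profiles, k=k, s_plus_range=(0, 80),
                              n_iterations=50, seed=3)
    count, frac = erroneous_fraction(res.estimates_s_minus)
    print(f"k = {k:3d}: {count}/{res.estimates_s_minus.size} slow-range "
          f"estimates erroneous ({100 * frac:.0f}%), "
          f"separation index {res.separation_index:.2f}, "
          f"Fisher significant in {100 * res.fisher_significant_fraction:.0f}% "
          f"of iterations")
# Small networks mis-assign a large share of slow-range estimates; at 100
# cells the slow range is decoded cleanly and nearly every iteration
# separates the two ranges.
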