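"""Score a go/no-go rotation-discrimination session and fit a psychometric.

Simulated observers lick in two or more of five 250-ms bins to report "go";
block accuracy, the learning criterion (first five-block window averaging
above 80%), and the accuracy-versus-range-difference sigmoid are computed.
"""

import numpy as np

from headvel import (criterion_block, fit_psychometric, session_accuracies,
                     simulate_behavior_session)
from headvel.stimuli import DISCRIMINATION_PEAKS, S_MINUS_PEAK

# a learner: early blocks near chance, later blocks proficient
rng = np.random.default_rng(0)
accs = []
for phase, (hit, fa) in enumerate([(0.6, 0.5), (0.85, 0.25), (0.95, 0.08)]):
    s = simulate_behavior_session(5, n_blocks=5, hit_rate=hit, fa_rate=fa,
                                  seed=int(rng.integers(2**31)))
    accs.extend(session_accuracies(s))
print("block accuracies:", [f"{a:.0f}" for a in accs])
print("criterion block :", criterion_block(accs))

# psychometric curve across stimulus pairs (threshold near 24 deg/s)
points = []
for pair, peak in DISCRIMINATION_PEAKS.items():
    delta = peak - S_MINUS_PEAK
    p_acc = 50 + 45 / (1 + np.exp(-(delta - 24.0) / 4.0))
    for _ in range(50):
        points.append((delta, 100 * rng.binomial(20, p_acc / 100) / 20))
fit = fit_psychometric(points)
print(f"psychometric threshold: {fit.threshold:.1f} deg/s "
      f"(floor {fit.floor:.0f}%, ceiling {fit.ceiling:.0f}%)")
# Pairs differing by >= 24 deg/s are discriminable; a 10 deg/s difference
# stays near the floor, matching the geometry of the stimulus families.
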