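"""Test whether a cell's membrane potential linearly encodes velocity.

The observed R^2 (trial-averaged vm regressed on |velocity| after
equal-representation resampling) is compared with a null built by randomly
circularly shifting each trial's velocity labels, which preserves the
temporal autocorrelation of the voltage trace.  A tuned cell beats its
null; an untuned cell does not.  The same machinery runs in the
acceleration domain, where a velocity-tuned cell scores much lower.
"""

import numpy as np

from headvel import (TuningSpec, make_rotation_stimulus, shuffle_regression_test,
                     simulate_vm_trial)

stim = make_rotation_stimulus(90, 80, pre_s=0.5, post_s=0.5, dt=1e-3)
rng = np.random.default_rng(3)

tuned = TuningSpec(gain_cw=0.035, gain_ccw=0.02)
trials = [simulate_vm_trial(stim, tuned, seed=rng, insert_spikes=False)
          for _ in range(10)]
for domain in ("velocity", "acceleration"):
    res = shuffle_regression_test(trials, stim, "CW", n_iter=1000, seed=1,
                                  domain=domain, bin_width=0.25)
    print(f"tuned cell, {domain:12s}: R^2 = {res.r2_raw:.3f}, "
          f"p = {res.p_value:.3f}")

null = TuningSpec(response_class="NONE", gain_cw=0, gain_ccw=0)
trials0 = [simulate_vm_trial(stim, null, seed=rng, insert_spikes=False)
           for _ in range(10)]
res0 = shuffle_regression_test(trials0, stim, "CW", n_iter=1000, seed=1,
                               bin_width=0.25)
print(f"untuned cell, velocity    : R^2 = {res0.r2_raw:.3f}, "
      f"p = {res0.p_value:.3f}")
# With 10,000 iterations the smallest attainable p is 1e-4 (the floor of
# the permutation null); 1,000 iterations floor at 1e-3.
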