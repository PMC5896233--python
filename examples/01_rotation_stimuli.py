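"""Build sinusoidal rotation stimuli and inspect their geometry.

A single direction sweep is a half-sine velocity profile; a sweep covering
180 degrees at a peak of 80 deg/s lasts pi*180/(2*80) = 3.53 s.
"""

import numpy as np

from headvel import make_discrimination_stimuli, make_rotation_stimulus, sweep_duration

stim = make_rotation_stimulus(amplitude_deg=90, peak_velocity=80, n_periods=1,
                              pre_s=2.0, post_s=1.0, dt=1e-4)
sweeps = [s for s in stim.direction_segments if s[2] != "stationary"]

print(f"sweep duration (closed form): {sweep_duration(180, 80):.3f} s")
print(f"sweep duration (measured):    {sweeps[0][1] - sweeps[0][0]:.3f} s")
print(f"peak |velocity|:              {np.abs(stim.velocity).max():.2f} deg/s")
print(f"position excursion:           {stim.position.min():.1f} to "
      f"{stim.position.max():.1f} deg")
print(f"sweep labels:                 {[s[2] for s in sweeps]}")

s_minus, s_plus = make_discrimination_stimuli(pair_id=2)
print(f"\ndiscrimination pair 2: S- peaks at {s_minus.peak_velocity:.0f}, "
      f"S+ at {s_plus.peak_velocity:.0f} deg/s "
      f"(range difference {s_plus.peak_velocity - s_minus.peak_velocity:.0f})")
# Both stimuli share onset, peak time and offset; only the velocity range
# differs, which is what the discrimination task manipulates.
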