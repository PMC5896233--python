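"""Sinusoidal platform-rotation stimuli.

A rotation sweep is one half-period of a sinusoidal velocity profile: the
platform accelerates from rest, reaches ``peak_velocity`` and decelerates
back to rest while turning through twice the stimulus ``amplitude`` (e.g.
-90 deg to +90 deg).  A full stimulus is a half-sine ramp into ``n_periods``
full sinusoidal periods and a half-sine ramp out, all of the same period, so
the velocity trace is a single continuous sinusoid spanning
``(n_periods + 1)`` periods, flanked by stationary padding.

For a sweep covering ``theta`` degrees at peak velocity ``V`` the sweep
duration is ``D = pi * theta / (2 V)``: a 180-degree sweep at 80 deg/s lasts
3.53 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RotationStimulus",
    "make_rotation_stimulus",
    "make_discrimination_stimuli",
    "sweep_duration",
    "DISCRIMINATION_PEAKS",
    "S_MINUS_PEAK",
]

#: Peak velocity (deg/s) of the non-rewarded stimulus; its range is 0-27 deg/s.
S_MINUS_PEAK = 27.0

#: Peak velocity (deg/s) of the rewarded stimulus for each stimulus-pair family.
#: Pair 1 is identical to the non-rewarded stimulus; pair 2 differs by 10 deg/s
#: (below the behavioral discrimination threshold); pairs 3-5 differ by at
#: least 24 deg/s, up to the full 0-80 deg/s training range.
DISCRIMINATION_PEAKS = {1: 27.0, 2: 37.0, 3: 51.0, 4: 65.0, 5: 80.0}


@dataclass
class RotationStimulus:
    """Time-indexed kinematic profile of one platform rotation.

    Attributes
    ----------
    time : ndarray
        Uniform time grid in seconds, step ``dt``.
    position, velocity, acceleration : ndarray
        Platform angle (deg), angular velocity (deg/s, clockwise positive)
        and angular acceleration (deg/s^2) on the grid.
    direction_segments : list of (float, float, str)
        ``(start, end, label)`` with label in {"CW", "CCW", "stationary"};
        the velocity is zero at every segment boundary.
    peak_velocity : float
        Nominal maximum |velocity| in deg/s.
    amplitude : float
        Half-excursion in degrees; one sweep covers ``2 * amplitude``.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    direction_segments: list = field(default_factory=list)
    peak_velocity: float = 0.0
    amplitude: float = 0.0

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def segments(self, label: str) -> list:
        """Direction segments carrying the given label."""
        return [s for s in self.direction_segments if s[2] == label]

    def motion_window(self) -> tuple:
        """(start, end) of the full rotation trajectory (non-stationary part)."""
        moving = [s for s in self.direction_segments if s[2] != "stationary"]
        if not moving:
            raise ValueError("stimulus has no motion segments")
        return moving[0][0], moving[-1][1]

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "peak_velocity": self.peak_velocity,
            "amplitude": self.amplitude,
            "direction_segments": [
                [float(a), float(b), lab] for a, b, lab in self.direction_segments
            ],
        }


def sweep_duration(sweep_degrees: float, peak_velocity: float) -> float:
    """Duration of a single half-sine sweep covering ``sweep_degrees``.

    Closed form ``D = pi * theta / (2 V)``: the sweep velocity is
    ``V sin(pi t / D)`` whose integral over [0, D] is ``2 V D / pi = theta``.
    """
    return np.pi * sweep_degrees / (2.0 * peak_velocity)


def _build(time, velocity, dt, peak, amplitude):
    position = np.concatenate(
        ([0.0], np.cumsum((velocity[1:] + velocity[:-1]) * 0.5 * dt))
    )
    acceleration = np.gradient(velocity, dt)
    return position, acceleration


def make_rotation_stimulus(
    amplitude_deg: float = 90.0,
    peak_velocity: float = 80.0,
    n_periods: int = 1,
    pre_s: float = 2.0,
    post_s: float = 1.0,
    dt: float = 1e-4,
) -> RotationStimulus:
    """Build a sinusoidal rotation stimulus.

    Parameters
    ----------
    amplitude_deg : float
        Half-excursion in degrees; a single sweep runs from
        ``-amplitude_deg`` to ``+amplitude_deg``.
    peak_velocity : float
        Maximum |velocity| in deg/s.
    n_periods : int
        Number of full sinusoidal periods between the two half-period ramps
        (1 or 2).
    pre_s, post_s : float
        Stationary padding before and after motion, seconds.
    dt : float
        Sample interval in seconds.
    """
    if amplitude_deg <= 0 or peak_velocity <= 0 or dt <= 0:
        raise ValueError("amplitude_deg, peak_velocity and dt must be positive")
    if n_periods not in (1, 2):
        raise ValueError("n_periods must be 1 or 2")
    if pre_s < 0 or post_s < 0:
        raise ValueError("padding must be non-negative")

    theta = 2.0 * amplitude_deg          # degrees covered by one sweep
    d_sweep = sweep_duration(theta, peak_velocity)
    period = 2.0 * d_sweep
    n_sweeps = 2 * (n_periods + 1)       # ramps contribute one sweep each
    motion_s = n_sweeps * d_sweep

    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    n_motion = int(round(motion_s / dt))
    n_total = n_pre + n_motion + n_post + 1

    time = np.arange(n_total) * dt
    velocity = np.zeros(n_total)
    t_m = time[n_pre : n_pre + n_motion + 1] - time[n_pre]
    velocity[n_pre : n_pre + n_motion + 1] = peak_velocity * np.sin(
        2.0 * np.pi * t_m / period
    )
    # force exact rest at the boundaries of every sweep
    for j in range(n_sweeps + 1):
        idx = n_pre + int(round(j * d_sweep / dt))
        if idx < n_total:
            velocity[idx] = 0.0

    position, acceleration = _build(time, velocity, dt, peak_velocity, amplitude_deg)
    position -= amplitude_deg  # center the excursion around 0

    # segment boundaries taken from the grid samples forced to zero above
    bidx = [min(n_pre + int(round(j * d_sweep / dt)), n_total - 1)
            for j in range(n_sweeps + 1)]
    segments = []
    if n_pre:
        segments.append((0.0, time[n_pre], "stationary"))
    for j in range(n_sweeps):
        label = "CW" if j % 2 == 0 else "CCW"
        segments.append((time[bidx[j]], time[bidx[j + 1]], label))
    if n_post:
        segments.append((segments[-1][1], time[-1], "stationary"))

    return RotationStimulus(
        time=time,
        position=position,
        velocity=velocity,
        acceleration=acceleration,
        direction_segments=segments,
        peak_velocity=peak_velocity,
        amplitude=amplitude_deg,
    )


def make_discrimination_stimuli(pair_id: int, pre_s: float = 2.0,
                                post_s: float = 1.0, dt: float = 1e-3):
    """Return the (non-rewarded, rewarded) stimulus pair for a behavior task.

    The non-rewarded stimulus spans velocities 0-27 deg/s; the rewarded peak
    depends on the pair family (identical for pair 1, +10 deg/s for pair 2,
    >= +24 deg/s for pairs 3-5 up to 0-80 deg/s).  Both stimuli are single
    clockwise sweeps with identical onset, peak time and offset: the common
    sweep duration is set by the 45-degree training rotation at 80 deg/s, and
    the turn amplitude scales with peak velocity.
    """
    if pair_id not in DISCRIMINATION_PEAKS:
        raise ValueError(f"unknown pair_id {pair_id!r}; expected 1..5")
    d_common = sweep_duration(45.0, 80.0)  # common sweep duration, s

    def single_sweep(peak):
        theta = 2.0 * peak * d_common / np.pi   # degrees covered in d_common
        n_pre = int(round(pre_s / dt))
        n_post = int(round(post_s / dt))
        n_motion = int(round(d_common / dt))
        n_total = n_pre + n_motion + n_post + 1
        time = np.arange(n_total) * dt
        velocity = np.zeros(n_total)
        t_m = time[n_pre : n_pre + n_motion + 1] - time[n_pre]
        velocity[n_pre : n_pre + n_motion + 1] = peak * np.sin(np.pi * t_m / d_common)
        velocity[n_pre] = 0.0
        velocity[n_pre + n_motion] = 0.0
        position, acceleration = _build(time, velocity, dt, peak, theta / 2.0)
        segments = []
        if n_pre:
            segments.append((0.0, time[n_pre], "stationary"))
        segments.append((time[n_pre], time[n_pre] + d_common, "CW"))
        if n_post:
            segments.append((segments[-1][1], time[-1], "stationary"))
        return RotationStimulus(
            time=time, position=position, velocity=velocity,
            acceleration=acceleration, direction_segments=segments,
            peak_velocity=peak, amplitude=theta / 2.0,
        )

    s_minus = single_sweep(S_MINUS_PEAK)
    s_plus = single_sweep(DISCRIMINATION_PEAKS[pair_id])
    return s_minus, s_plus
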