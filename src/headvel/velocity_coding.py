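"""Shuffle-based test for linear velocity (or acceleration) encoding.

Does the membrane potential of a cell carry more linear information about
angular velocity than its temporal autocorrelation alone would produce?
Each trial is re-sampled so that every velocity value is equally
represented (one vm sample per velocity bin, default 0.008 deg/s; one per
0.007 deg/s^2 in the acceleration domain).  The observed statistic is the
R^2 of an ordinary least-squares fit of the trial-averaged vm against the
kinematic variable.  The null preserves each trial's temporal structure:
per iteration every trial's velocity labels are circularly rotated by an
independent uniform random shift, trials are averaged, and the R^2 is
recorded.  The p-value is the fraction of null R^2 values at or above the
observed one, floored at 1/n_iter, so with 10,000 iterations the smallest
attainable p is 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import RotationStimulus
from .synthetic import VmTrial

__all__ = [
    "VelocityResampled",
    "ShuffleTestResult",
    "resample_by_velocity",
    "circular_shuffle",
    "shuffle_regression_test",
    "VELOCITY_BIN",
    "ACCELERATION_BIN",
]

VELOCITY_BIN = 0.008       # deg/s
ACCELERATION_BIN = 0.007   # deg/s^2


@dataclass
class VelocityResampled:
    """One trial re-sampled onto an equal-representation kinematic grid.

    ``bins`` holds the kinematic value (|velocity| or acceleration) of each
    re-sampled point, ``vm`` the matching membrane-potential sample, both in
    temporal order (monotone phases concatenated).
    """

    bins: np.ndarray
    vm: np.ndarray
    direction: str
    domain: str = "velocity"
    bin_width: float = VELOCITY_BIN

    def __len__(self):
        return self.bins.size


@dataclass
class ShuffleTestResult:
    r2_raw: float
    r2_null: np.ndarray
    p_value: float
    n_iter: int
    domain: str
    direction: str
    significant: bool
    degenerate: bool = False
    dropped_bins: int = 0


def _monotone_runs(x):
    """Index ranges [i0, i1) over which x is strictly monotone."""
    d = np.sign(np.diff(x))
    runs = []
    start = 0
    for i in range(1, d.size):
        if d[i] != 0 and d[i - 1] != 0 and d[i] != d[i - 1]:
            runs.append((start, i + 1))
            start = i
    runs.append((start, x.size))
    return [(a, b) for a, b in runs if b - a >= 2]


def resample_by_velocity(
    trial: VmTrial,
    stimulus: RotationStimulus,
    direction: str,
    bin_width: float | None = None,
    domain: str = "velocity",
    phases: str = "both",
) -> VelocityResampled:
    """Re-sample a trial so every kinematic bin holds one vm data point.

    Within each of the direction's sweeps the kinematic variable is split
    into monotone phases (|velocity| rises then falls over a half-sine
    sweep); for each bin center crossed by a phase the vm sample nearest in
    time to the crossing is taken.  ``phases='rising'`` keeps only the
    first monotone phase of each sweep.  Bins never visited by the stimulus
    are simply absent from the output.
    """
    if domain not in ("velocity", "acceleration"):
        raise ValueError("domain must be 'velocity' or 'acceleration'")
    if bin_width is None:
        bin_width = VELOCITY_BIN if domain == "velocity" else ACCELERATION_BIN
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sweeps = stimulus.segments(direction)
    if not sweeps:
        raise ValueError(f"stimulus has no {direction!r} segments")

    # kinematic series on the trial's own grid
    if domain == "velocity":
        kin_full = np.abs(np.interp(trial.time, stimulus.time, stimulus.velocity))
    else:
        kin_full = np.interp(trial.time, stimulus.time, stimulus.acceleration)

    out_bins, out_vm = [], []
    for a, b, _ in sweeps:
        i0 = int(np.searchsorted(trial.time, a, side="left"))
        i1 = int(np.searchsorted(trial.time, b, side="right"))
        kin = kin_full[i0:i1]
        runs = _monotone_runs(kin)
        if phases == "rising":
            runs = runs[:1]
        for r0, r1 in runs:
            seg = kin[r0:r1]
            idx = np.arange(r0, r1, dtype=float)
            lo, hi = float(seg.min()), float(seg.max())
            k0 = int(np.ceil((lo - bin_width / 2) / bin_width))
            k1 = int(np.floor((hi - bin_width / 2) / bin_width))
            if k1 < k0:
                continue
            centers = (np.arange(k0, k1 + 1) + 0.5) * bin_width
            if seg[0] > seg[-1]:
                pos = np.interp(centers, seg[::-1], idx[::-1])
            else:
                pos = np.interp(centers, seg, idx)
            sample = np.rint(pos).astype(int) + i0
            out_bins.append(centers if seg[0] <= seg[-1] else centers[::-1])
            out_vm.append(trial.vm[sample if seg[0] <= seg[-1] else sample[::-1]])

    if not out_bins:
        raise ValueError("no monotone kinematic phases found for this direction")
    return VelocityResampled(
        bins=np.concatenate(out_bins), vm=np.concatenate(out_vm),
        direction=direction, domain=domain, bin_width=bin_width,
    )


def circular_shuffle(resampled: VelocityResampled, shift: int) -> VelocityResampled:
    """Rotate the kinematic labels circularly against the vm samples.

    The vm series keeps its temporal order; the label sequence is rolled by
    ``shift`` positions.  ``shift`` must lie in [1, n-1]: shift 0 (or n) is
    the identity and is excluded from null generation.
    """
    n = len(resampled)
    if not 1 <= shift <= n - 1:
        raise ValueError(f"shift must lie in [1, {n - 1}]")
    return VelocityResampled(
        bins=np.roll(resampled.bins, shift), vm=resampled.vm.copy(),
        direction=resampled.direction, domain=resampled.domain,
        bin_width=resampled.bin_width,
    )


def _r2_rows(avg, x_centered, x_ss):
    """R^2 of OLS (with intercept) of each row of ``avg`` on x."""
    a = avg - avg.mean(axis=-1, keepdims=True)
    num = (a * x_centered).sum(axis=-1) ** 2
    den = (a * a).sum(axis=-1) * x_ss
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, 0.0)
    return r2


def shuffle_regression_test(
    trials: list,
    stimulus: RotationStimulus,
    direction: str,
    n_iter: int = 10_000,
    seed=None,
    domain: str = "velocity",
    bin_width: float | None = None,
    phases: str = "both",
    alpha: float = 0.05,
    chunk: int = 250,
) -> ShuffleTestResult:
    """Circular-shuffle significance test of linear kinematic encoding.

    The observed R^2 comes from the OLS fit (with intercept) of the
    trial-averaged re-sampled vm on the kinematic variable; the null
    distribution from ``n_iter`` iterations of independent per-trial
    circular shifts.  p = max(#{null >= raw}/n_iter, 1/n_iter).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    rs = [resample_by_velocity(t, stimulus, direction, bin_width, domain, phases)
          for t in trials]
    n_bins = len(rs[0])
    if any(len(r) != n_bins for r in rs):
        raise ValueError("trials resampled to different lengths")
    x = rs[0].bins
    M = np.stack([r.vm for r in rs])          # (n_trials, n_bins)
    n_trials = M.shape[0]

    x_c = x - x.mean()
    x_ss = float((x_c * x_c).sum())
    raw_avg = M.mean(axis=0)
    r2_raw = float(_r2_rows(raw_avg[None, :], x_c, x_ss)[0])
    degenerate = bool(np.ptp(raw_avg) == 0)

    rng = np.random.default_rng(seed)
    r2_null = np.empty(n_iter)
    col = np.arange(n_bins)
    done = 0
    while done < n_iter:
        c = min(chunk, n_iter - done)
        shifts = rng.integers(1, n_bins, size=(n_trials, c))
        acc = np.zeros((c, n_bins))
        for i in range(n_trials):
            # rolling vm forward by s is equivalent to rolling the labels
            idx = (col[None, :] - shifts[i][:, None]) % n_bins
            acc += M[i][idx]
        acc /= n_trials
        r2_null[done : done + c] = _r2_rows(acc, x_c, x_ss)
        done += c

    count = int(np.sum(r2_null >= r2_raw))
    p = max(count / n_iter, 1.0 / n_iter)
    return ShuffleTestResult(
        r2_raw=r2_raw, r2_null=r2_null, p_value=p, n_iter=n_iter,
        domain=domain, direction=direction,
        significant=bool(p < alpha) and not degenerate, degenerate=degenerate,
    )
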