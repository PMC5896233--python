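"""Go/no-go rotation-discrimination scoring and open-field turning metrics.

A session is a sequence of 20-trial blocks, each holding 10 rewarded (S+)
and 10 non-rewarded (S-) rotations in pseudo-random order.  The animal
reports by licking in five 250-ms bins starting 2750 ms after stimulus
onset: licking in two or more bins is a "go".  A go on S+ is a hit, a go on
S- a false alarm; block accuracy is the percentage of correct trials.
Learning criterion is an average accuracy of 80% over five consecutive
blocks; the first block of that window is the criterion block.  Accuracy
versus the velocity-range difference of the stimulus pair is summarized by
a four-parameter logistic psychometric curve.

Vestibular-lesion phenotypes are quantified from open-field centroid
tracks: the signed change in heading over consecutive frame triples
measures circling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BehaviorTrial",
    "BehaviorSession",
    "PsychometricPoint",
    "PsychometricFit",
    "score_trial",
    "block_accuracy",
    "session_accuracies",
    "criterion_block",
    "fit_psychometric",
    "turning_metric",
    "simulate_behavior_session",
    "BLOCK_SIZE",
    "LICK_BINS",
]

BLOCK_SIZE = 20
LICK_BINS = 5
LICK_BIN_S = 0.250
LICK_WINDOW_START_S = 2.750
CRITERION_ACCURACY = 80.0
CRITERION_WINDOW = 5


@dataclass
class BehaviorTrial:
    stimulus: str                  # "S+" or "S-"
    lick_bins: tuple               # 5 booleans


@dataclass
class BehaviorSession:
    trials: list                   # ordered BehaviorTrials
    pair_id: int = 1

    def blocks(self):
        """Consecutive 20-trial blocks; a trailing partial block is kept."""
        return [self.trials[i : i + BLOCK_SIZE]
                for i in range(0, len(self.trials), BLOCK_SIZE)]


@dataclass
class PsychometricPoint:
    pair_id: int
    velocity_range_delta: float    # deg/s
    accuracy: float                # percent
    block_index: int = 0


@dataclass
class PsychometricFit:
    floor: float
    ceiling: float
    threshold: float               # range delta at the curve midpoint
    slope: float
    converged: bool
    degenerate: bool
    residuals: np.ndarray | None = None

    def predict(self, delta):
        delta = np.asarray(delta, float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-(delta - self.threshold) / self.slope))


def score_trial(stimulus: str, lick_bins) -> bool:
    """Correctness of one trial: go (>= 2 lick bins) is correct on S+ only."""
    if stimulus not in ("S+", "S-"):
        raise ValueError("stimulus must be 'S+' or 'S-'")
    bins = list(lick_bins)
    if len(bins) != LICK_BINS:
        raise ValueError(f"expected {LICK_BINS} lick bins")
    go = sum(bool(b) for b in bins) >= 2
    return go if stimulus == "S+" else not go


def block_accuracy(block) -> float:
    """Percentage of correct trials in one complete 20-trial block."""
    if len(block) != BLOCK_SIZE:
        raise ValueError(f"incomplete block: {len(block)} trials, "
                         f"expected {BLOCK_SIZE}")
    correct = sum(score_trial(t.stimulus, t.lick_bins) for t in block)
    return 100.0 * correct / BLOCK_SIZE


def session_accuracies(session: BehaviorSession) -> list:
    """Block accuracies for every complete block of a session."""
    return [block_accuracy(b) for b in session.blocks() if len(b) == BLOCK_SIZE]


def criterion_block(accuracies, threshold: float = CRITERION_ACCURACY,
                    window: int = CRITERION_WINDOW):
    """Index of the first block opening a window performed above criterion.

    Criterion is an average accuracy strictly above 80% over five
    consecutive blocks ("above criterion": a window averaging exactly 80%
    does not qualify).  Returns None when no such window exists, including
    sessions shorter than the window.
    """
    acc = np.asarray(accuracies, float)
    if acc.size < window:
        return None
    means = np.convolve(acc, np.ones(window) / window, mode="valid")
    hits = np.flatnonzero(means > threshold)
    return int(hits[0]) if hits.size else None


def _logistic4(x, floor, ceiling, x0, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-(x - x0) / slope))


def fit_psychometric(points) -> PsychometricFit:
    """Four-parameter logistic fit of accuracy versus velocity-range delta.

    ``points`` is a list of :class:`PsychometricPoint` (or (delta, accuracy)
    pairs).  The threshold is the delta at the midpoint between floor and
    ceiling.  A flat dataset or a non-converged optimization is flagged.
    """
    deltas, accs = [], []
    for p in points:
        if isinstance(p, PsychometricPoint):
            deltas.append(p.velocity_range_delta)
            accs.append(p.accuracy)
        else:
            deltas.append(p[0])
            accs.append(p[1])
    x = np.asarray(deltas, float)
    y = np.asarray(accs, float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct velocity-range deltas")

    if np.ptp(y) < 1.0:      # essentially flat: no psychometric structure
        return PsychometricFit(floor=float(y.mean()), ceiling=float(y.mean()),
                               threshold=float("nan"), slope=float("nan"),
                               converged=True, degenerate=True)
    p0 = (max(y.min(), 0.0), min(y.max(), 100.0), float(np.median(x)), 5.0)
    bounds = ([0.0, 0.0, x.min() - 50.0, 0.1], [100.0, 100.0, x.max() + 50.0, 100.0])
    try:
        popt, _ = curve_fit(_logistic4, x, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError:
        return PsychometricFit(floor=float("nan"), ceiling=float("nan"),
                               threshold=float("nan"), slope=float("nan"),
                               converged=False, degenerate=False)
    fit = PsychometricFit(floor=float(popt[0]), ceiling=float(popt[1]),
                          threshold=float(popt[2]), slope=float(popt[3]),
                          converged=True,
                          degenerate=bool(popt[1] - popt[0] < 1.0))
    fit.residuals = y - _logistic4(x, *popt)
    return fit


def turning_metric(centroid_xy, min_step: float = 1e-9):
    """Signed heading changes over consecutive frame triples of a track.

    For frames (i, i+1, i+2) the turning angle is the signed angle between
    the two displacement vectors; triples containing a zero displacement
    (stationary frames) are skipped.  Returns a dict with the per-triple
    ``angles`` (radians), their mean (``bias``) and ``median_abs``.
    """
    xy = np.asarray(centroid_xy, float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of centroid coordinates")
    v = np.diff(xy, axis=0)
    norms = np.hypot(v[:, 0], v[:, 1])
    angles = []
    for i in range(v.shape[0] - 1):
        if norms[i] < min_step or norms[i + 1] < min_step:
            continue
        cross = v[i, 0] * v[i + 1, 1] - v[i, 1] * v[i + 1, 0]
        dot = v[i] @ v[i + 1]
        angles.append(np.arctan2(cross, dot))
    angles = np.asarray(angles)
    if angles.size == 0:
        return {"angles": angles, "bias": 0.0, "median_abs": 0.0}
    return {"angles": angles, "bias": float(angles.mean()),
            "median_abs": float(np.median(np.abs(angles)))}


def _pseudo_random_order(rng, n_plus: int = 10, n_minus: int = 10,
                         max_run: int = 3):
    """Shuffled stimulus order with at most ``max_run`` identical in a row."""
    labels = ["S+"] * n_plus + ["S-"] * n_minus
    for _ in range(1000):
        rng.shuffle(labels)
        run, ok = 1, True
        for a, b in zip(labels, labels[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return list(labels)
    return list(labels)      # pathological constraints: give up gracefully


def _draw_bins(rng, go: bool):
    """Lick-bin pattern for a go (>= 2 bins) or no-go (<= 1 bin) response."""
    if go:
        n_lick = 2 + rng.binomial(LICK_BINS - 2, 0.6)
    else:
        n_lick = rng.integers(0, 2)
    bins = np.zeros(LICK_BINS, dtype=bool)
    if n_lick:
        bins[rng.choice(LICK_BINS, size=n_lick, replace=False)] = True
    return tuple(bool(b) for b in bins)


def simulate_behavior_session(pair_id: int, n_blocks: int = 10,
                              hit_rate: float = 0.9, fa_rate: float = 0.2,
                              seed=None) -> BehaviorSession:
    """Simulate a go/no-go session with fixed hit and false-alarm rates.

    Each block holds 10 S+ and 10 S- trials in pseudo-random order (at most
    three identical stimuli in a row); on S+ the animal goes with
    probability ``hit_rate``, on S- with probability ``fa_rate``.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_blocks):
        for stim in _pseudo_random_order(rng):
            p_go = hit_rate if stim == "S+" else fa_rate
            go = rng.random() < p_go
            trials.append(BehaviorTrial(stimulus=stim,
                                        lick_bins=_draw_bins(rng, go)))
    return BehaviorSession(trials=trials, pair_id=pair_id)
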