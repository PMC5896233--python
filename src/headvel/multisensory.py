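"""Vestibulo-visual summation analysis.

Does the membrane-potential response to rotating the animal past a visual
stimulus match the arithmetic sum of the pure vestibular (rotation in
darkness) and pure visual-motion responses?  The comparison is temporal: an
odd/even-trial autocorrelation of the combined-condition response sets a
within-cell normalizer, and cross-correlograms of the combined response
against each candidate (visual-only, vestibular-only, arithmetic sum) are
normalized to that peak.  A coefficient near 1 means the candidate
reproduces the combined response's temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConditionSet",
    "arithmetic_sum",
    "odd_even_autocorrelation",
    "normalized_crosscorrelation",
    "split_eye_fields",
]


@dataclass
class ConditionSet:
    """Trial-averaged responses of one cell under the three conditions."""

    avg_vestibulo_visual: np.ndarray
    avg_visual_only: np.ndarray
    avg_vestibular_only: np.ndarray
    baseline_vestibulo_visual: float = 0.0
    baseline_visual_only: float = 0.0
    baseline_vestibular_only: float = 0.0
    odd_avg: np.ndarray | None = None
    even_avg: np.ndarray | None = None


def _baseline(series, baseline_window):
    if baseline_window is None:
        return 0.0
    if isinstance(baseline_window, slice):
        return float(np.mean(series[baseline_window]))
    i0, i1 = baseline_window
    return float(np.mean(series[i0:i1]))


def arithmetic_sum(avg_visual, avg_vestibular, baseline_window=None,
                   baseline_visual=None, baseline_vestibular=None):
    """Arithmetic sum of the two unisensory trial averages.

    Each average is referenced to its own pre-stimulus baseline (estimated
    over ``baseline_window`` unless given explicitly), the baseline-
    subtracted responses are added, and a single common baseline (the mean
    of the two) is restored.  The operation is commutative in its inputs.
    """
    a = np.asarray(avg_visual, float)
    b = np.asarray(avg_vestibular, float)
    if a.shape != b.shape:
        raise ValueError("condition averages must share the time grid")
    ba = _baseline(a, baseline_window) if baseline_visual is None else baseline_visual
    bb = _baseline(b, baseline_window) if baseline_vestibular is None else baseline_vestibular
    common = 0.5 * (ba + bb)
    return (a - ba) + (b - bb) + common


def _correlogram(a, b, max_lag):
    """Normalized cross-correlation over lags -max_lag..max_lag.

    Both series are mean-subtracted; the product sums are scaled by the
    geometric mean of the full-window sums of squares, so a self-comparison
    peaks at exactly 1 at lag 0.
    """
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        raise ValueError("constant trace: correlation undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.empty(lags.size)
    for i, L in enumerate(lags):
        if L >= 0:
            cc[i] = np.dot(a[: a.size - L], b[L:])
        else:
            cc[i] = np.dot(a[-L:], b[: b.size + L])
    return lags, cc / denom


def odd_even_autocorrelation(trials, max_lag_frac: float = 0.25):
    """Within-cell autocorrelation normalizer from odd/even trial splits.

    ``trials`` is an (n_trials, n_samples) array of combined-condition
    responses; the average of odd trials is cross-correlated with the
    average of even trials (mean-subtracted, lags up to a quarter of the
    window) and the peak magnitude returned.
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    if trials.shape[0] < 4:
        raise ValueError("need at least 4 trials for an odd/even split")
    odd = trials[0::2].mean(axis=0)
    even = trials[1::2].mean(axis=0)
    max_lag = max(1, int(trials.shape[1] * max_lag_frac))
    _, cc = _correlogram(odd, even, max_lag)
    return float(np.max(np.abs(cc)))


def normalized_crosscorrelation(avg_condition, reference, auto_peak,
                                max_lag_frac: float = 0.25) -> float:
    """Peak cross-correlation against the reference, scaled by ``auto_peak``.

    ``auto_peak`` is the odd/even autocorrelation peak of the reference
    condition; a coefficient of 1 means the candidate matches the reference
    as well as the reference matches itself across trial splits.
    """
    if auto_peak <= 0:
        raise ValueError("auto_peak must be positive")
    a = np.asarray(avg_condition, float)
    max_lag = max(1, int(a.size * max_lag_frac))
    _, cc = _correlogram(a, reference, max_lag)
    return float(np.max(np.abs(cc)) / auto_peak)


def split_eye_fields(response, stimulus, direction: str,
                     hemisphere: str = "left", baseline: float | None = None,
                     time=None):
    """Mean |delta-Vm| in the two halves of a direction's rotation sweeps.

    During a sweep the visual field in front of the animal shifts from one
    hemifield to the other, so the first and second halves of the
    trajectory weight the ipsilateral and contralateral eye fields of the
    recorded hemisphere differently.  Convention: for a left-hemisphere
    recording, the first half of a clockwise sweep is dominated by the
    contralateral (right) eye field; labels swap with direction and with
    hemisphere.  Returns ``{"ipsi": mean, "contra": mean}``.
    """
    response = np.asarray(response, float)
    if time is None:
        time = stimulus.time
    if baseline is None:
        m0 = stimulus.motion_window()[0]
        pre = response[time < m0]
        baseline = float(pre.mean()) if pre.size else float(response.mean())

    sweeps = stimulus.segments(direction)
    if not sweeps:
        raise ValueError(f"stimulus has no {direction!r} segments")
    first, second = [], []
    for a, b, _ in sweeps:
        mid = 0.5 * (a + b)
        sel1 = (time >= a) & (time < mid)
        sel2 = (time >= mid) & (time <= b)
        first.append(np.mean(np.abs(response[sel1] - baseline)))
        second.append(np.mean(np.abs(response[sel2] - baseline)))
    first_m, second_m = float(np.mean(first)), float(np.mean(second))

    first_is_contra = (direction == "CW") == (hemisphere == "left")
    if first_is_contra:
        return {"contra": first_m, "ipsi": second_m}
    return {"contra": second_m, "ipsi": first_m}
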