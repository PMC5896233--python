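"""Detection and classification of rotation-evoked responses.

Per trial, the mean membrane potential (or spike rate) in a 2-s stationary
window immediately before motion onset is compared with the mean over the
rotation trajectory of one direction; a two-sided Wilcoxon signed-rank test
across trials decides significance at alpha = 0.05.  Cells are classified
from the signs of their significant per-direction responses as ON
(depolarizing), OFF (hyperpolarizing), ON/OFF (opposite signs in the two
directions, direction-selectivity index forced to 1) or unresponsive.

The module also houses the eye-movement analyses: threshold detection of
rapid eye-movement events on the differentiated position trace, and
event-triggered membrane-potential averaging around those events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import paired_wilcoxon
from .stimuli import RotationStimulus
from .synthetic import VmTrial

__all__ = [
    "ResponseResult",
    "CellClassification",
    "EyeEvent",
    "clip_spikes",
    "rotation_response",
    "classify_cell",
    "detect_eye_events",
    "event_triggered_vm",
]

ALPHA = 0.05
BASELINE_WINDOW_S = 2.0
# clip window around each spike peak: covers the action potential and the
# fast after-hyperpolarization
CLIP_PRE_S = 0.002
CLIP_POST_S = 0.005


@dataclass
class ResponseResult:
    """Outcome of the stationary-vs-rotation comparison for one direction."""

    cell_id: object
    direction: str
    mode: str
    mean_baseline: float
    mean_rotation: float
    delta: float
    p_value: float
    significant: bool
    peak_amplitude: float | None   # defined only when significant
    n_trials: int
    degenerate: bool = False


@dataclass
class CellClassification:
    response_class: str           # ON / OFF / ON_OFF / NONE
    dsi: float | None             # direction-selectivity index, undefined for NONE
    pref_direction: str | None = None


@dataclass
class EyeEvent:
    onset: float
    direction: str                # temporal_to_medial / medial_to_temporal
    amplitude: float


def clip_spikes(trial: VmTrial, pre_s: float = CLIP_PRE_S,
                post_s: float = CLIP_POST_S) -> np.ndarray:
    """Remove action potentials from a membrane-potential trace.

    The trace inside ``[spike - pre_s, spike + post_s]`` is replaced by
    linear interpolation between the window edges; overlapping windows are
    merged.  Returns the subthreshold vm series (the trial is not modified).
    """
    vm = np.asarray(trial.vm, float).copy()
    if trial.spike_times.size == 0:
        return vm
    n = vm.size
    sr = trial.sample_rate
    t0 = trial.time[0]
    windows = []
    for st in np.sort(trial.spike_times):
        lo = int(np.floor((st - t0 - pre_s) * sr))
        hi = int(np.ceil((st - t0 + post_s) * sr))
        lo, hi = max(lo, 0), min(hi, n - 1)
        if windows and lo <= windows[-1][1] + 1:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    for lo, hi in windows:
        a = vm[lo - 1] if lo > 0 else vm[hi] if hi < n - 1 else vm[0]
        b = vm[hi + 1] if hi < n - 1 else a
        vm[lo : hi + 1] = np.linspace(a, b, hi - lo + 1)
    return vm


def _window_mean(trial, vm, start, end):
    i0 = int(np.searchsorted(trial.time, start, side="left"))
    i1 = int(np.searchsorted(trial.time, end, side="right"))
    return float(np.mean(vm[i0:i1]))


def _spike_rate(trial, start, end):
    st = trial.spike_times
    count = int(np.sum((st >= start) & (st < end)))
    return count / (end - start)


def rotation_response(
    trials: list,
    stimulus: RotationStimulus,
    direction: str,
    mode: str = "vm",
    cell_id=None,
    alpha: float = ALPHA,
    baseline_s: float = BASELINE_WINDOW_S,
) -> ResponseResult:
    """Stationary-vs-rotation comparison for one direction across trials.

    ``mode='vm'`` compares mean membrane potential (spikes clipped first);
    ``mode='spikes'`` compares spike rates.  The baseline is the
    ``baseline_s`` window immediately preceding motion onset; the rotation
    window is the union of the direction's sweep segments.
    """
    if mode not in ("vm", "spikes"):
        raise ValueError("mode must be 'vm' or 'spikes'")
    if len(trials) < 4:
        raise ValueError("need at least 4 trials")
    sweeps = stimulus.segments(direction)
    if not sweeps:
        raise ValueError(f"stimulus has no {direction!r} segments")
    motion_start = stimulus.motion_window()[0]
    base_start = max(stimulus.time[0], motion_start - baseline_s)

    baselines, rotations, peaks = [], [], []
    for tr in trials:
        if mode == "vm":
            vm = clip_spikes(tr)
            baselines.append(_window_mean(tr, vm, base_start, motion_start))
            seg_means, seg_peaks = [], []
            for a, b, _ in sweeps:
                i0 = int(np.searchsorted(tr.time, a, side="left"))
                i1 = int(np.searchsorted(tr.time, b, side="right"))
                seg_means.append(np.mean(vm[i0:i1]))
                seg_peaks.append(np.max(np.abs(vm[i0:i1] - baselines[-1])))
            rotations.append(float(np.mean(seg_means)))
            peaks.append(float(np.max(seg_peaks)))
        else:
            baselines.append(_spike_rate(tr, base_start, motion_start))
            rate = np.mean([_spike_rate(tr, a, b) for a, b, _ in sweeps])
            rotations.append(float(rate))
            peaks.append(abs(rotations[-1] - baselines[-1]))

    res = paired_wilcoxon(rotations, baselines)
    mean_base = float(np.mean(baselines))
    mean_rot = float(np.mean(rotations))
    significant = bool(res.p_value < alpha) and not res.degenerate
    return ResponseResult(
        cell_id=cell_id, direction=direction, mode=mode,
        mean_baseline=mean_base, mean_rotation=mean_rot,
        delta=mean_rot - mean_base, p_value=res.p_value,
        significant=significant,
        peak_amplitude=float(np.mean(peaks)) if significant else None,
        n_trials=len(trials), degenerate=res.degenerate,
    )


def classify_cell(result_cw: ResponseResult,
                  result_ccw: ResponseResult) -> CellClassification:
    """Classify a cell from its two per-direction responses.

    ON: at least one significant depolarization, no significant
    hyperpolarization; OFF: the converse; ON_OFF: one of each (the
    direction-selectivity index is then 1 by definition); NONE otherwise.
    The index is (Pref - Null)/(Pref + Null) on |delta| from baseline, where
    Pref is the direction with the larger |delta|.
    """
    results = {result_cw.direction: result_cw, result_ccw.direction: result_ccw}
    sig_pos = [r for r in results.values() if r.significant and r.delta > 0]
    sig_neg = [r for r in results.values() if r.significant and r.delta < 0]

    if sig_pos and sig_neg:
        cls = "ON_OFF"
    elif sig_pos:
        cls = "ON"
    elif sig_neg:
        cls = "OFF"
    else:
        return CellClassification(response_class="NONE", dsi=None)

    mags = {d: abs(r.delta) for d, r in results.items()}
    pref = max(mags, key=mags.get)
    null = min(mags, key=mags.get)
    if pref == null:  # single direction supplied twice
        null = [d for d in mags if d != pref][0] if len(mags) > 1 else pref
    if cls == "ON_OFF":
        dsi = 1.0
    else:
        denom = mags[pref] + mags[null]
        dsi = (mags[pref] - mags[null]) / denom if denom > 0 else 0.0
    return CellClassification(response_class=cls, dsi=dsi, pref_direction=pref)


def detect_eye_events(
    position: np.ndarray,
    sample_rate: float = 120.0,
    k_sd: float = 2.5,
    refractory_s: float = 0.05,
) -> list:
    """Detect rapid eye-movement events on a horizontal position trace.

    The position trace is differentiated; samples where |d(position)/dt|
    exceeds ``k_sd`` standard deviations of the differential mark events.
    Consecutive supra-threshold samples within ``refractory_s`` are merged
    into one event whose onset is the first crossing.  ``k_sd`` defaults to
    2.5, the midpoint of the conventional 2-3 SD range.
    """
    if not 2.0 <= k_sd <= 3.0:
        raise ValueError("k_sd must lie in [2, 3]")
    position = np.asarray(position, float)
    d = np.diff(position) * sample_rate
    sd = d.std()
    if sd == 0:
        return []
    above = np.abs(d) > k_sd * sd
    events = []
    last = -np.inf
    ref = int(round(refractory_s * sample_rate))
    idx = np.flatnonzero(above)
    for i in idx:
        if i - last <= ref:
            last = i
            continue
        last = i
        direction = "temporal_to_medial" if d[i] > 0 else "medial_to_temporal"
        # amplitude: position change over the contiguous supra-threshold run
        j = i
        while j + 1 < d.size and above[j + 1]:
            j += 1
        events.append(EyeEvent(onset=(i + 1) / sample_rate, direction=direction,
                               amplitude=float(position[j + 1] - position[i])))
        last = j
    return events


def event_triggered_vm(
    events: list,
    vm: np.ndarray,
    sample_rate: float,
    pre_window_s: float = 0.025,
    post_delay_s: float = 0.070,
    post_window_s: float = 0.025,
    time_offset: float = 0.0,
):
    """Event-triggered pre/post membrane-potential comparison.

    For each event onset, the mean vm in a 25-ms window ending at onset is
    paired with the mean in a 25-ms window starting 70 ms after onset; a
    Wilcoxon signed-rank test is run across events.  Events whose post
    window would run past the trace end are dropped.  Returns
    ``(pre_means, post_means, WilcoxonResult, n_dropped)``.
    """
    if len(events) == 0:
        raise ValueError("no events supplied")
    vm = np.asarray(vm, float)
    n = vm.size
    pre, post = [], []
    dropped = 0
    for ev in events:
        onset = ev.onset if isinstance(ev, EyeEvent) else float(ev)
        i = int(round((onset - time_offset) * sample_rate))
        i_pre0 = i - int(round(pre_window_s * sample_rate))
        i_post0 = i + int(round(post_delay_s * sample_rate))
        i_post1 = i_post0 + int(round(post_window_s * sample_rate))
        if i_pre0 < 0 or i_post1 > n:
            dropped += 1
            continue
        pre.append(vm[i_pre0:i].mean())
        post.append(vm[i_post0:i_post1].mean())
    if not pre:
        raise ValueError("all events fell outside the trace span")
    res = paired_wilcoxon(post, pre)
    return np.asarray(pre), np.asarray(post), res, dropped
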