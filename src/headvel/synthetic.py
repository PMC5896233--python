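"""Synthetic whole-cell, behavioral and imaging data with known ground truth.

The generator emulates the statistical structure the analyses assume:
velocity-tuned subthreshold membrane-potential responses riding on
membrane-like colored noise, with stereotyped spikes superimposed; trial
populations pooled across a handful of source neurons; go/no-go lick
sessions; and two-photon frame stacks acquired on a rotating platform with
the encoder angle recorded alongside.

Membrane-potential model
------------------------
``vm(t) = baseline + g_dir * |velocity(t)| + visual(t) + OU(t)`` where
``g_dir`` is the clockwise or counter-clockwise gain (mV per deg/s) and OU
is an Ornstein-Uhlenbeck process with stationary standard deviation
``noise_sd`` and correlation time ``noise_tau`` (default 20 ms, a
membrane-like timescale).  Trials in the visual-only condition carry only
the visual component; vestibulo-visual trials are the exact sum of the
vestibular and visual components, so multisensory summation analyses have
known ground truth.  Lesion trials carry no vestibular component.

The default tuning calibration targets the scale of awake deep-layer
recordings: a clockwise-preferring cell driven at 80 deg/s peak shows a mean
depolarization of about 1.8 mV over the rotation trajectory, with per-trial
absolute peaks (tuning plus noise excursions) of roughly 11 mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .stimuli import RotationStimulus, make_rotation_stimulus

__all__ = [
    "TuningSpec",
    "VmTrial",
    "SyntheticPopulation",
    "simulate_vm_trial",
    "simulate_population",
    "simulate_eye_trace",
    "simulate_rotating_stack",
    "ou_noise",
    "SPIKE_TEMPLATE_MS",
]

RESPONSE_CLASSES = ("ON", "OFF", "ON_OFF", "NONE")
CONDITIONS = ("dark", "visual_only", "vestibulo_visual", "lesion")

#: duration of the triangular spike template inserted at threshold crossings
SPIKE_TEMPLATE_MS = 2.0


@dataclass
class TuningSpec:
    """Ground-truth velocity tuning of one simulated neuron.

    Gains are in mV per deg/s and act on |velocity| per rotation direction.
    ON cells have non-negative gains, OFF cells non-positive, ON_OFF cells
    gains of opposite sign, NONE cells zero gain.
    """

    response_class: str = "ON"
    gain_cw: float = 0.035
    gain_ccw: float = 0.035
    baseline: float = -60.0
    noise_sd: float = 2.5
    noise_tau: float = 0.02
    spike_threshold: float = -50.0
    seed: int | None = None

    def __post_init__(self):
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response_class {self.response_class!r}")
        cw, ccw = self.gain_cw, self.gain_ccw
        if self.response_class == "NONE" and not (cw == 0 and ccw == 0):
            raise ValueError("NONE tuning requires zero gains")
        if self.response_class == "ON" and (cw < 0 or ccw < 0):
            raise ValueError("ON tuning requires non-negative gains")
        if self.response_class == "OFF" and (cw > 0 or ccw > 0):
            raise ValueError("OFF tuning requires non-positive gains")
        if self.response_class == "ON_OFF" and not (cw * ccw < 0):
            raise ValueError("ON_OFF tuning requires gains of opposite sign")

    def to_dict(self) -> dict:
        return {
            "response_class": self.response_class,
            "gain_cw": self.gain_cw,
            "gain_ccw": self.gain_ccw,
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
            "noise_tau": self.noise_tau,
            "spike_threshold": self.spike_threshold,
        }


@dataclass
class VmTrial:
    """One membrane-potential trial with stimulus linkage."""

    time: np.ndarray
    vm: np.ndarray
    sample_rate: float
    stimulus_id: str
    condition: str = "dark"
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_index: int = 0
    neuron_id: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        st = np.asarray(self.spike_times, float)
        if st.size and (st.min() < self.time[0] or st.max() > self.time[-1]):
            raise ValueError("spike_times outside trial time span")
        self.spike_times = st


@dataclass
class SyntheticPopulation:
    """A pool of trials from several source neurons, with retrievable truth."""

    trials: list
    n_source_neurons: int
    truth: dict                      # neuron_id -> TuningSpec
    stimuli: dict                    # stimulus_id -> RotationStimulus
    seed: int | None = None

    def __len__(self):
        return len(self.trials)

    def stimulus_for(self, trial: VmTrial) -> RotationStimulus:
        return self.stimuli[trial.stimulus_id]


def ou_noise(n: int, dt: float, sd: float, tau: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path of length ``n``."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    x = np.empty(n)
    w = rng.standard_normal(n)
    x[0] = sd * w[0]
    s = sd * np.sqrt(1.0 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + s * w[i]
    return x


def _ou_noise_fast(n, dt, sd, tau, rng):
    # recursion via scipy lfilter: x[i] = a x[i-1] + s w[i]
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    s = sd * np.sqrt(1.0 - a * a)
    w = rng.standard_normal(n)
    w[0] = w[0] * sd / s  # stationary start
    return lfilter([s], [1.0, -a], w)


def _visual_component(stimulus: RotationStimulus, gain: float,
                      latency: float, tau: float = 0.15) -> np.ndarray:
    """Visual-motion response: delayed, low-pass-filtered velocity drive.

    Visual-motion responses are slower than vestibular ones; the drive is
    |velocity| convolved with an exponential kernel (time constant ``tau``)
    and shifted by a response latency, so the visual and vestibular
    components are temporally distinct.
    """
    from scipy.signal import lfilter

    dt = 1.0 / stimulus.sample_rate
    a = np.exp(-dt / tau)
    drive = lfilter([1.0 - a], [1.0, -a], gain * np.abs(stimulus.velocity))
    shift = int(round(latency * stimulus.sample_rate))
    out = np.zeros_like(drive)
    if shift < len(drive):
        out[shift:] = drive[: len(drive) - shift]
    return out


def _insert_spikes(vm, dt, threshold, refractory=0.005, amplitude=45.0):
    """Insert triangular spike waveforms at upward threshold crossings."""
    half = max(1, int(round(SPIKE_TEMPLATE_MS / 2 * 1e-3 / dt)))
    template = amplitude * (1.0 - np.abs(np.arange(-half, half + 1)) / half)
    crossings = np.flatnonzero((vm[1:] >= threshold) & (vm[:-1] < threshold)) + 1
    spike_idx = []
    last = -np.inf
    ref = refractory / dt
    for c in crossings:
        if c - last >= ref:
            spike_idx.append(c)
            last = c
    out = vm.copy()
    for c in spike_idx:
        lo = max(0, c - half)
        hi = min(len(vm), c + half + 1)
        out[lo:hi] += template[half - (c - lo) : half + (hi - c)]
    return out, np.asarray(spike_idx, dtype=int)


def simulate_vm_trial(
    stimulus: RotationStimulus,
    tuning: TuningSpec,
    seed=None,
    condition: str = "dark",
    visual_gain: float = 0.03,
    visual_latency: float = 0.06,
    sample_rate: float | None = None,
    insert_spikes: bool = True,
    trial_index: int = 0,
    neuron_id: int = 0,
    stimulus_id: str = "stim",
) -> VmTrial:
    """Simulate one membrane-potential trial for a given stimulus and tuning.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.  With
    ``sample_rate`` set below the stimulus rate, the stimulus kinematics are
    decimated before simulation (the tuning is instantaneous, so decimation
    commutes with the response model).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    time = stimulus.time
    velocity = stimulus.velocity
    if sample_rate is not None and sample_rate < stimulus.sample_rate:
        step = int(round(stimulus.sample_rate / sample_rate))
        time = time[::step]
        velocity = velocity[::step]
        stimulus = replace(stimulus, time=time, velocity=velocity,
                           position=stimulus.position[::step],
                           acceleration=stimulus.acceleration[::step])
    dt = float(time[1] - time[0])

    vestibular = np.where(velocity > 0, tuning.gain_cw, tuning.gain_ccw) * np.abs(velocity)
    visual = _visual_component(stimulus, visual_gain, visual_latency)

    # lesioned vestibular apparatus: rotation in the dark evokes nothing,
    # while visual responses are spared (carried by visual_gain if a visual
    # stimulus is present).
    if condition == "dark":
        drive = vestibular
    elif condition == "visual_only":
        drive = visual
    elif condition == "vestibulo_visual":
        drive = vestibular + visual
    elif condition == "lesion":
        drive = np.zeros_like(vestibular)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    noise = _ou_noise_fast(len(time), dt, tuning.noise_sd, tuning.noise_tau, rng)
    vm = tuning.baseline + drive + noise

    spike_times = np.empty(0)
    if insert_spikes:
        vm, spike_idx = _insert_spikes(vm, dt, tuning.spike_threshold)
        spike_times = time[spike_idx]

    return VmTrial(
        time=time, vm=vm, sample_rate=1.0 / dt, stimulus_id=stimulus_id,
        condition=condition, spike_times=spike_times,
        trial_index=trial_index, neuron_id=neuron_id,
    )


DEFAULT_CLASS_MIX = {"ON": 0.75, "OFF": 0.125, "ON_OFF": 0.125}


def _draw_tuning(cls, rng, gain_scale=0.035, noise_sd=2.5):
    g1 = gain_scale * rng.lognormal(0.0, 0.3)
    g2 = gain_scale * rng.lognormal(0.0, 0.3)
    if cls == "ON":
        cw, ccw = g1, g2 * rng.choice([0.0, 1.0], p=[0.3, 0.7])
    elif cls == "OFF":
        cw, ccw = -g1, -g2 * rng.choice([0.0, 1.0], p=[0.3, 0.7])
    elif cls == "ON_OFF":
        cw, ccw = g1, -g2 if rng.random() < 0.5 else -g1
        if cw * ccw >= 0:
            cw, ccw = g1, -g2
    else:
        cw = ccw = 0.0
    return TuningSpec(response_class=cls, gain_cw=cw, gain_ccw=ccw,
                      noise_sd=noise_sd)


def simulate_population(
    n_trials: int = 348,
    n_neurons: int = 8,
    class_mix: dict | None = None,
    seed=None,
    stimulus: RotationStimulus | None = None,
    sample_rate: float = 1000.0,
    noise_sd: float = 2.5,
    gain_scale: float = 0.035,
    insert_spikes: bool = False,
) -> SyntheticPopulation:
    """Simulate a trial pool from ``n_neurons`` source neurons.

    Trials are partitioned as evenly as possible among neurons, each neuron
    drawing one :class:`TuningSpec` from ``class_mix`` (a mapping of response
    class to proportion).  The truth is stored per neuron for
    parameter-recovery tests.  The default 348-trial / 8-neuron geometry
    matches the pooled whole-cell dataset the decoding analyses assume.
    """
    if n_trials < n_neurons:
        raise ValueError("need at least one trial per neuron")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("class_mix proportions must be non-negative, sum > 0")
    for k in mix:
        if k not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {k!r} in class_mix")

    root = np.random.default_rng(seed)
    if stimulus is None:
        stimulus = make_rotation_stimulus(
            amplitude_deg=90.0, peak_velocity=80.0, n_periods=1,
            pre_s=2.0, post_s=1.0, dt=1.0 / sample_rate,
        )

    classes = list(mix)
    probs = np.array([mix[c] for c in classes], float)
    probs = probs / probs.sum()
    # deterministic class counts per neuron (largest remainder), then shuffle
    counts = np.floor(probs * n_neurons).astype(int)
    rem = n_neurons - counts.sum()
    order = np.argsort(-(probs * n_neurons - counts))
    for i in range(rem):
        counts[order[i % len(classes)]] += 1
    neuron_classes = [c for c, k in zip(classes, counts) for _ in range(k)]
    root.shuffle(neuron_classes)

    truth = {}
    trials = []
    base, extra = divmod(n_trials, n_neurons)
    idx = 0
    for nid in range(n_neurons):
        spec = _draw_tuning(neuron_classes[nid], root, gain_scale, noise_sd)
        truth[nid] = spec
        n_this = base + (1 if nid < extra else 0)
        for _ in range(n_this):
            trials.append(
                simulate_vm_trial(
                    stimulus, spec, seed=root, condition="dark",
                    visual_gain=0.0, insert_spikes=insert_spikes,
                    trial_index=idx, neuron_id=nid, stimulus_id="stim",
                )
            )
            idx += 1

    return SyntheticPopulation(
        trials=trials, n_source_neurons=n_neurons, truth=truth,
        stimuli={"stim": stimulus}, seed=seed if isinstance(seed, int) else None,
    )


def simulate_eye_trace(
    duration_s: float = 60.0,
    sample_rate: float = 120.0,
    n_events: int = 10,
    amplitude: float = 5.0,
    noise_sd: float = 0.05,
    seed=None,
):
    """Horizontal eye-position trace with injected saccade-like steps.

    Returns ``(time, position, event_onsets, event_directions)`` with
    directions alternating temporal-to-medial / medial-to-temporal.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    time = np.arange(n) / sample_rate
    position = rng.normal(0.0, noise_sd, n).cumsum() * 0.01
    onsets = np.sort(rng.choice(np.arange(int(2 * sample_rate), n - int(2 * sample_rate)),
                                size=n_events, replace=False))
    directions = []
    for j, i0 in enumerate(onsets):
        sign = 1.0 if j % 2 == 0 else -1.0
        position[i0:] += sign * amplitude
        directions.append("temporal_to_medial" if sign > 0 else "medial_to_temporal")
    return time, position, time[onsets], directions


def simulate_rotating_stack(
    base_image: np.ndarray,
    encoder_trace: np.ndarray,
    center: tuple | None = None,
    seed=None,
    frame_rate: float = 25.0,
    encoder_rate: float | None = None,
    noise_sd: float = 0.0,
    transient_rois: list | None = None,
    transient_times: list | None = None,
    transient_amplitude: float = 1.0,
    transient_tau: float = 0.4,
    quantization: float = 0.05,
):
    """Rotate ``base_image`` frame by frame according to an encoder trace.

    Each output frame is the base image rotated about ``center`` by the mean
    encoder angle during that frame, with optional Gaussian noise and
    exponential-decay fluorescence transients embedded in the listed ROI
    masks at the listed onset frames.  The emitted encoder channel is
    quantized to ``quantization`` degrees (0.05 by default, the precision of
    the rotary-encoder feedback).

    Returns ``(stack, encoder_per_frame, truth)`` where ``truth`` maps ROI
    index to the ground-truth transient onset frames.
    """
    from skimage.transform import rotate

    base = np.asarray(base_image, float)
    h, w = base.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("rotation center outside image bounds")

    encoder_trace = np.asarray(encoder_trace, float)
    if encoder_rate is None:
        encoder_rate = frame_rate
    if encoder_rate < frame_rate:
        raise ValueError("encoder must be sampled at >= frame rate")
    per_frame = encoder_rate / frame_rate
    n_frames = int(len(encoder_trace) // per_frame)
    angles = np.empty(n_frames)
    for f in range(n_frames):
        seg = encoder_trace[int(f * per_frame): int((f + 1) * per_frame)]
        angles[f] = seg.mean()
    angles = np.round(angles / quantization) * quantization

    rng = np.random.default_rng(seed)
    transient_rois = transient_rois or []
    transient_times = transient_times or []
    truth = {i: np.asarray(t, int) for i, t in enumerate(transient_times)}

    # per-frame fluorescence gain per ROI (exponential decay after onset)
    roi_gain = np.zeros((len(transient_rois), n_frames))
    decay = np.exp(-np.arange(n_frames) / (transient_tau * frame_rate))
    for i, onsets in enumerate(transient_times):
        for t0 in onsets:
            roi_gain[i, t0:] += transient_amplitude * decay[: n_frames - t0]

    stack = np.empty((n_frames, h, w))
    for f in range(n_frames):
        frame = base.copy()
        for i, mask in enumerate(transient_rois):
            frame = frame + mask * base * roi_gain[i, f]
        if angles[f] != 0.0:
            frame = rotate(frame, angles[f], center=center, order=1,
                           mode="constant", cval=float(np.median(base)),
                           preserve_range=True)
        if noise_sd:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        stack[f] = frame
    return stack, angles, truth


# ---------------------------------------------------------------------------
# on-disk formats: CSV trial tables with JSON sidecars

def write_trials(directory, population: SyntheticPopulation) -> None:
    """Write a population as per-trial CSV (time, vm) plus a JSON sidecar."""
    import csv
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "n_source_neurons": population.n_source_neurons,
        "stimuli": {k: s.to_dict() for k, s in population.stimuli.items()},
        "truth": {str(k): v.to_dict() for k, v in population.truth.items()},
        "trials": [],
    }
    for t in population.trials:
        name = f"trial_{t.trial_index:04d}.csv"
        with open(directory / name, "w", newline="") as fh:
            wtr = csv.writer(fh)
            wtr.writerow(["time", "vm"])
            for ti, vi in zip(t.time, t.vm):
                wtr.writerow([f"{ti:.6f}", f"{vi:.6f}"])
        sidecar["trials"].append({
            "file": name, "stimulus_id": t.stimulus_id,
            "condition": t.condition, "neuron_id": t.neuron_id,
            "trial_index": t.trial_index,
            "sample_rate": t.sample_rate,
            "spike_times": [float(s) for s in t.spike_times],
        })
    with open(directory / "trials.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trials(directory) -> SyntheticPopulation:
    """Read a population previously written by :func:`write_trials`."""
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    with open(directory / "trials.json") as fh:
        sidecar = json.load(fh)
    stimuli = {}
    for key, meta in sidecar["stimuli"].items():
        # regenerate the kinematic grids from the stored geometry
        segs = [(a, b, lab) for a, b, lab in meta["direction_segments"]]
        pre = segs[0][1] if segs[0][2] == "stationary" else 0.0
        post = (segs[-1][1] - segs[-1][0]) if segs[-1][2] == "stationary" else 0.0
        n_sweeps = sum(1 for s in segs if s[2] != "stationary")
        stimuli[key] = make_rotation_stimulus(
            amplitude_deg=meta["amplitude"], peak_velocity=meta["peak_velocity"],
            n_periods=max(1, n_sweeps // 2 - 1),
            pre_s=pre, post_s=post, dt=meta["dt"],
        )
    truth = {int(k): TuningSpec(**v) for k, v in sidecar["truth"].items()}
    trials = []
    for meta in sidecar["trials"]:
        df = pd.read_csv(directory / meta["file"])
        trials.append(VmTrial(
            time=df["time"].to_numpy(), vm=df["vm"].to_numpy(),
            sample_rate=meta["sample_rate"], stimulus_id=meta["stimulus_id"],
            condition=meta["condition"],
            spike_times=np.asarray(meta["spike_times"]),
            trial_index=meta["trial_index"], neuron_id=meta["neuron_id"],
        ))
    return SyntheticPopulation(
        trials=trials, n_source_neurons=sidecar["n_source_neurons"],
        truth=truth, stimuli=stimuli,
    )


# behavioral sessions are part of the generator surface; the scoring rules
# and session containers live in headvel.behavior
from .behavior import simulate_behavior_session  # noqa: E402,F401

__all__.append("simulate_behavior_session")
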