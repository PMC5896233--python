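"""Naive-Bayes decoding of angular velocity from membrane-potential profiles.

Each trial is reduced to a response profile: baseline-subtracted membrane
potential as a function of |velocity| on a 1-deg/s grid over 0-80 deg/s.
Profiles of hyperpolarizing (OFF) neurons are sign-corrected by the sign of
the neuron's mean response, then each profile is min-max normalized to
[0, 1].  Every trial is treated as an independent "cell".

Decoding a velocity bin: each selected cell contributes its normalized
value at the true velocity as the observation v_i; the conditional
P(v_i | velocity) is a Laplace-smoothed histogram (B equal-width response
bins on [0, 1]) fit from the other cells, leave-one-out.  With a uniform
prior the prediction is argmax_velocity prod_i P(v_i | velocity), evaluated
in the log domain over the 80 candidate bins (centers k - 1/2), ties broken
toward the lowest velocity.  The decoding error is the mean absolute
deviation between the 80 predictions and the bin centers; a decoder that
guesses uniformly at random scores (80^2 - 1)/(3*80) ~ 26.66 deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResponseProfile",
    "ConditionalModel",
    "DecodeResult",
    "build_profiles",
    "fit_conditional",
    "decode",
    "decoding_error",
    "network_sweep",
    "profile_matrix",
    "decode_bins",
    "random_baseline_error",
    "N_VELOCITY_BINS",
]

N_VELOCITY_BINS = 80
V_MAX = 80.0


@dataclass
class ResponseProfile:
    """Sign-corrected, normalized response curve of one trial ("cell")."""

    cell_id: object
    vm_vs_velocity: np.ndarray          # raw baseline-subtracted, per 1-deg/s bin
    vbar: float                         # neuron-level mean response
    sign: int                           # +1 or -1; sign(0) := +1
    normalized: np.ndarray              # in [0, 1]
    degenerate: bool = False            # flat profile normalized to zeros
    neuron_id: int | None = None


@dataclass
class ConditionalModel:
    """P(v_i | velocity) as per-velocity histograms over response bins."""

    histograms: np.ndarray              # (n_velocity_bins, B), rows sum to 1
    response_bins: int
    smoothing: float


@dataclass
class DecodeResult:
    predicted: np.ndarray               # deg/s, one per velocity bin
    error: float                        # mean |predicted_k - (k - 1/2)|
    n_cells: int
    seed: int | None = None


def velocity_bin_centers(n_bins: int = N_VELOCITY_BINS) -> np.ndarray:
    """True value of bin k is its center k - 1/2 (k = 1..n_bins)."""
    return np.arange(n_bins) + 0.5


def random_baseline_error(n_bins: int = N_VELOCITY_BINS) -> float:
    """Expected error of uniform-random predictions: (n^2 - 1) / (3 n)."""
    return (n_bins**2 - 1) / (3.0 * n_bins)


def _bin_trial(trial, stimulus, n_bins, v_max, baseline_s=2.0):
    """Baseline-subtracted mean vm per 1-deg/s |velocity| bin."""
    speed = np.abs(np.interp(trial.time, stimulus.time, stimulus.velocity))
    m0, m1 = stimulus.motion_window()
    base_start = max(trial.time[0], m0 - baseline_s)
    in_base = (trial.time >= base_start) & (trial.time < m0)
    dvm = trial.vm - trial.vm[in_base].mean()
    in_motion = (trial.time >= m0) & (trial.time <= m1)
    sp = speed[in_motion]
    dv = dvm[in_motion]
    idx = np.minimum((sp / (v_max / n_bins)).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=dv, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    prof = np.full(n_bins, np.nan)
    hit = counts > 0
    prof[hit] = sums[hit] / counts[hit]
    if not hit.all():                   # fill unvisited bins by interpolation
        centers = velocity_bin_centers(n_bins)
        prof[~hit] = np.interp(centers[~hit], centers[hit], prof[hit])
    return prof


def build_profiles(population, n_bins: int = N_VELOCITY_BINS,
                   v_max: float = V_MAX) -> list:
    """One sign-corrected, min-max-normalized profile per trial.

    The sign correction uses the mean response of the source neuron (mean
    over its trials and over all velocity bins): profiles of neurons with a
    net hyperpolarizing response are flipped before normalization, so ON and
    OFF cells contribute the same increasing-with-velocity statistics.
    """
    raw = {}
    for t in population.trials:
        stim = population.stimulus_for(t)
        raw[t.trial_index] = (t, _bin_trial(t, stim, n_bins, v_max))

    by_neuron = {}
    for t, prof in raw.values():
        by_neuron.setdefault(t.neuron_id, []).append(prof)
    vbar = {nid: float(np.mean(profs)) for nid, profs in by_neuron.items()}

    profiles = []
    for t, prof in raw.values():
        nb = vbar[t.neuron_id]
        sign = 1 if nb >= 0 else -1     # sign(0) := +1
        corrected = sign * prof
        lo, hi = corrected.min(), corrected.max()
        if hi > lo:
            norm = (corrected - lo) / (hi - lo)
            degen = False
        else:
            norm = np.zeros_like(corrected)
            degen = True
        profiles.append(ResponseProfile(
            cell_id=t.trial_index, vm_vs_velocity=prof, vbar=nb, sign=sign,
            normalized=norm, degenerate=degen, neuron_id=t.neuron_id,
        ))
    return profiles


def profile_matrix(profiles: list) -> np.ndarray:
    """Stack normalized profiles into an (n_cells, n_velocity_bins) matrix."""
    return np.stack([p.normalized for p in profiles])


def _digitize(values: np.ndarray, B: int) -> np.ndarray:
    """Map values in [0, 1] to response-bin indices 0..B-1."""
    return np.minimum((np.asarray(values) * B).astype(int), B - 1)


def _counts(D: np.ndarray, B: int) -> np.ndarray:
    """Per-velocity histogram counts: C[w, j] = #cells with bin j at velocity w."""
    n_vel = D.shape[1]
    C = np.zeros((n_vel, B), dtype=np.int64)
    for j in range(B):
        C[:, j] = (D == j).sum(axis=0)
    return C


def fit_conditional(profiles: list, held_out_id, B: int = 10,
                    alpha: float = 1.0) -> ConditionalModel:
    """Fit P(v_i | velocity) from all profiles except the held-out cell.

    Histograms use ``B`` equal-width response bins on [0, 1] with Laplace
    pseudo-count ``alpha``, normalized per velocity bin.
    """
    others = [p for p in profiles if p.cell_id != held_out_id]
    if not others:
        raise ValueError("cannot fit a conditional model from zero cells")
    D = _digitize(profile_matrix(others), B)
    C = _counts(D, B).astype(float) + alpha
    row = C.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise ValueError("empty histogram row; use alpha > 0")
    return ConditionalModel(histograms=C / row, response_bins=B, smoothing=alpha)


def decode(observations, models) -> float:
    """Maximum-posterior velocity for one set of per-cell observations.

    ``observations`` are normalized responses in [0, 1], one per cell;
    ``models`` the matching per-cell conditional models.  Log-probabilities
    are accumulated across cells; the argmax bin center is returned with
    ties broken toward the lowest velocity.
    """
    if len(observations) == 0:
        raise ValueError("empty observation set")
    if len(observations) != len(models):
        raise ValueError("one model per observation required")
    n_vel = models[0].histograms.shape[0]
    logpost = np.zeros(n_vel)
    for obs, model in zip(observations, models):
        j = int(_digitize(np.asarray([obs]), model.response_bins)[0])
        logpost += np.log(model.histograms[:, j])
    return float(np.argmax(logpost) + 0.5)


def decoding_error(predictions) -> float:
    """Mean absolute deviation between predictions and the bin centers."""
    predictions = np.asarray(predictions, float)
    if predictions.shape != (N_VELOCITY_BINS,):
        raise ValueError(f"expected {N_VELOCITY_BINS} predictions")
    return float(np.mean(np.abs(predictions - velocity_bin_centers())))


def decode_bins(
    V_sub: np.ndarray,
    t_indices=None,
    B: int = 10,
    alpha: float = 1.0,
    V_fit: np.ndarray | None = None,
) -> np.ndarray:
    """Decode the listed velocity bins from a cell-subset matrix.

    ``V_sub`` is the (k, n_velocity_bins) matrix of normalized profiles of
    the selected cells; the observation of cell i at true bin t is
    ``V_sub[i, t]``.  Conditionals are fit leave-one-out: by default from
    the other cells of the subset; with ``V_fit`` given (e.g. the full
    dataset, which must contain the subset rows) from that set minus the
    observer cell's own contribution.  Returns predicted velocities
    (bin centers) for each requested true bin.
    """
    V_sub = np.atleast_2d(V_sub)
    k, n_vel = V_sub.shape
    if t_indices is None:
        t_indices = np.arange(n_vel)
    t_indices = np.asarray(t_indices, int)

    D_sub = _digitize(V_sub, B)
    if V_fit is None:
        if k < 2:
            raise ValueError("subset leave-one-out needs at least 2 cells; "
                             "pass V_fit for single-cell decoding")
        C = _counts(D_sub, B).astype(float)
    else:
        D_fit = _digitize(np.atleast_2d(V_fit), B)
        C = _counts(D_fit, B).astype(float)

    # logpost[w, t] = sum_i log(C[w, D_sub[i,t]] - [D_sub[i,w] == D_sub[i,t]] + alpha)
    # the subtraction removes the observer cell's own contribution (leave-one-out)
    P = C[:, D_sub[:, t_indices]]                       # (n_vel, k, T)
    Eq = (D_sub[:, :, None] == D_sub[:, None, t_indices])  # (k, n_vel, T)
    L = np.log(P - Eq.transpose(1, 0, 2) + alpha).sum(axis=1)  # (n_vel, T)
    return np.argmax(L, axis=0) + 0.5


def network_sweep(
    profiles: list,
    k_values,
    n_repeats: int = 348,
    seed=None,
    B: int = 10,
    alpha: float = 1.0,
    loo: str = "subset",
) -> pd.DataFrame:
    """Decoding error versus network size.

    For each k, ``n_repeats`` random subsets of k cells are drawn without
    replacement (within a subset); each subset decodes all 80 velocity bins
    and its error is recorded.  k = 1 uses each cell exactly once with the
    conditional fit leave-one-out against the full dataset (a single cell
    has no "other cells" within its subset); k = n collapses to the single
    full subset.  Returns a long-format frame with columns k, repeat, error.
    """
    if loo not in ("subset", "full"):
        raise ValueError("loo must be 'subset' or 'full'")
    V = profile_matrix(profiles)
    n = V.shape[0]
    rng = np.random.default_rng(seed)
    centers = velocity_bin_centers(V.shape[1])
    rows = []
    for k in k_values:
        if not 1 <= k <= n:
            raise ValueError(f"k={k} outside [1, {n}]")
        if k == 1:
            for i in range(n):
                pred = decode_bins(V[i : i + 1], B=B, alpha=alpha, V_fit=V)
                rows.append((k, i, float(np.mean(np.abs(pred - centers)))))
            continue
        reps = 1 if k == n else n_repeats
        for rep in range(reps):
            sel = rng.choice(n, size=k, replace=False)
            V_fit = V if loo == "full" else None
            pred = decode_bins(V[sel], B=B, alpha=alpha, V_fit=V_fit)
            rows.append((k, rep, float(np.mean(np.abs(pred - centers)))))
    return pd.DataFrame(rows, columns=["k", "repeat", "error"])
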