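"""Separation of overlapping velocity ranges by a decoding network.

How well can a k-cell network tell a slow rotation range (the non-rewarded
stimulus, 0-27 deg/s) from a faster, overlapping one (a rewarded stimulus,
up to 0-80 deg/s)?  Per iteration a fresh random k-subset decodes every
1-deg/s bin of each range; estimates falling above the slow range's upper
bound are "erroneous" for that range.  Three summaries are computed:

* the erroneous fraction of slow-range estimates,
* a separation index: the area above the cumulative distribution of the
  fast-range estimates beyond the slow range, normalized to [0, 1] by the
  width of the beyond-range region,
* a per-iteration Fisher exact test on the 2x2 outside/inside table of the
  two estimate sets, aggregated as the fraction of significant iterations.

The separation index versus network size saturates and is summarized by a
double-exponential fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .decoder import decode_bins, profile_matrix
from .stats import fisher_exact

__all__ = [
    "SeparationResult",
    "estimate_over_range",
    "erroneous_fraction",
    "separation_index",
    "per_iteration_fisher",
    "separation_analysis",
    "fit_separation_curve",
    "S_MINUS_RANGE",
]

S_MINUS_RANGE = (0.0, 27.0)
V_MAX = 80.0


@dataclass
class SeparationResult:
    k_cells: int
    s_minus_range: tuple
    s_plus_range: tuple
    estimates_s_minus: np.ndarray      # (n_iterations, n_minus_bins)
    estimates_s_plus: np.ndarray       # (n_iterations, n_plus_bins)
    area_s_minus: float
    area_s_plus: float
    separation_index: float
    fisher_significant_fraction: float
    n_iterations: int
    seed: int | None = None


def _range_bins(velocity_range):
    lo, hi = velocity_range
    if not (0 <= lo < hi <= V_MAX):
        raise ValueError(f"range must satisfy 0 <= lo < hi <= {V_MAX}")
    return np.arange(int(round(lo)), int(round(hi)))     # true-bin indices


def estimate_over_range(
    profiles,
    k: int,
    velocity_range,
    n_iterations: int = 348,
    seed=None,
    B: int = 10,
    alpha: float = 1.0,
) -> np.ndarray:
    """Decoded velocities for each 1-deg/s bin of a range, per iteration.

    Each iteration draws a fresh random k-subset of cells and decodes every
    bin of the range; the slow 0-27 deg/s range yields 27 estimates per
    iteration.  Returns an (n_iterations, n_bins) matrix.
    """
    t_idx = _range_bins(velocity_range)
    if t_idx.size == 0:
        raise ValueError("empty velocity range")
    V = profile_matrix(profiles) if isinstance(profiles, list) else np.asarray(profiles)
    n = V.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty((n_iterations, t_idx.size))
    for it in range(n_iterations):
        sel = rng.choice(n, size=k, replace=False)
        out[it] = decode_bins(V[sel], t_idx, B=B, alpha=alpha,
                              V_fit=V if k == 1 else None)
    return out


def erroneous_fraction(estimates, s_minus_range=S_MINUS_RANGE):
    """Count and fraction of estimates above the slow range's upper bound."""
    estimates = np.asarray(estimates, float)
    upper = s_minus_range[1]
    count = int(np.sum(estimates > upper))
    return count, count / estimates.size


def separation_index(estimates_s_plus, s_minus_range=S_MINUS_RANGE,
                     v_max: float = V_MAX) -> float:
    """Area above the cumulative estimate curve beyond the slow range.

    Equals the mean exceedance of the estimates over the slow range's upper
    bound, normalized by the width of the beyond-range region, so the index
    lies in [0, 1]: 0 when every estimate falls at or below the bound, 1
    when every estimate sits at the top of the velocity axis.
    """
    est = np.asarray(estimates_s_plus, float).ravel()
    upper = s_minus_range[1]
    return float(np.mean(np.clip(est, upper, v_max) - upper) / (v_max - upper))


def per_iteration_fisher(estimates_s_minus_iter, estimates_s_plus_iter,
                         cutoff: float = S_MINUS_RANGE[1],
                         alpha: float = 0.05):
    """Fisher exact test on one iteration's outside/inside proportions.

    Builds the 2x2 table of estimates outside (> cutoff) versus inside for
    the two stimulus ranges; returns ``(p_value, significant)``.
    """
    em = np.asarray(estimates_s_minus_iter, float)
    ep = np.asarray(estimates_s_plus_iter, float)
    out_m = int(np.sum(em > cutoff))
    out_p = int(np.sum(ep > cutoff))
    table = [[out_m, em.size - out_m], [out_p, ep.size - out_p]]
    p = fisher_exact(table)
    return p, bool(p < alpha)


def separation_analysis(
    profiles,
    k: int,
    s_plus_range=(0.0, 80.0),
    s_minus_range=S_MINUS_RANGE,
    n_iterations: int = 348,
    seed=None,
    B: int = 10,
    alpha: float = 1.0,
    fisher_alpha: float = 0.05,
) -> SeparationResult:
    """Full range-separation analysis for one network size and range pair.

    The same random k-subset decodes both ranges within an iteration, so the
    per-iteration Fisher test compares matched networks.
    """
    t_minus = _range_bins(s_minus_range)
    t_plus = _range_bins(s_plus_range)
    V = profile_matrix(profiles) if isinstance(profiles, list) else np.asarray(profiles)
    n = V.shape[0]
    rng = np.random.default_rng(seed)

    est_m = np.empty((n_iterations, t_minus.size))
    est_p = np.empty((n_iterations, t_plus.size))
    n_sig = 0
    for it in range(n_iterations):
        sel = rng.choice(n, size=k, replace=False)
        V_sel = V[sel]
        fit = V if k == 1 else None
        est_m[it] = decode_bins(V_sel, t_minus, B=B, alpha=alpha, V_fit=fit)
        est_p[it] = decode_bins(V_sel, t_plus, B=B, alpha=alpha, V_fit=fit)
        _, sig = per_iteration_fisher(est_m[it], est_p[it],
                                      cutoff=s_minus_range[1], alpha=fisher_alpha)
        n_sig += sig

    return SeparationResult(
        k_cells=k, s_minus_range=tuple(s_minus_range),
        s_plus_range=tuple(s_plus_range),
        estimates_s_minus=est_m, estimates_s_plus=est_p,
        area_s_minus=separation_index(est_m, s_minus_range),
        area_s_plus=separation_index(est_p, s_minus_range),
        separation_index=separation_index(est_p, s_minus_range),
        fisher_significant_fraction=n_sig / n_iterations,
        n_iterations=n_iterations,
        seed=seed if isinstance(seed, int) else None,
    )


def _double_exp(k, a1, tau1, a2, tau2):
    return a1 * (1.0 - np.exp(-k / tau1)) + a2 * (1.0 - np.exp(-k / tau2))


def fit_separation_curve(k_values, indices, saturating: bool = True):
    """Least-squares double-exponential fit of separation index versus k.

    The saturating form ``a1 (1 - e^(-k/tau1)) + a2 (1 - e^(-k/tau2))`` is
    the default; ``saturating=False`` fits a raw sum of decaying
    exponentials instead.  Returns ``(params_dict, residuals, flagged)``
    where ``flagged`` marks non-convergence or a degenerate (constant-data)
    fit; parameters are None when the fit did not converge.
    """
    k_values = np.asarray(k_values, float)
    y = np.asarray(indices, float)
    if k_values.size < 6:
        raise ValueError("need at least 6 (k, index) points")

    if saturating:
        model = _double_exp
    else:
        def model(k, a1, tau1, a2, tau2):
            return a1 * np.exp(-k / tau1) + a2 * np.exp(-k / tau2)

    span = max(np.ptp(y), 1e-12)
    p0 = (span / 2, max(k_values.min(), 1.0), span / 2, k_values.max() / 2)
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # degenerate (e.g. constant) data is flagged below; the
            # covariance warning carries no extra information here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, k_values, y, p0=p0, maxfev=20_000)
    except RuntimeError:
        return None, None, True
    residuals = y - model(k_values, *popt)
    params = dict(zip(("a1", "tau1", "a2", "tau2"), (float(v) for v in popt)))
    flagged = bool(np.ptp(y) < 1e-9 or min(abs(params["a1"]), abs(params["a2"])) <
                   1e-6 * span)
    return params, residuals, flagged
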