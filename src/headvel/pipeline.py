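"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> response classification -> encoding
test -> decoding sweep -> range separation -> multisensory comparison on a
synthetic population, writing per-stage CSV/JSON outputs and a manifest
that records the root seed, per-stage parameters and a parameter hash, so
identical configurations reproduce identical artifacts.  All randomness
flows from a single root seed through deterministically spawned
sub-streams, one per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoder import build_profiles, network_sweep
from .multisensory import (arithmetic_sum, normalized_crosscorrelation,
                           odd_even_autocorrelation)
from .response_stats import classify_cell, rotation_response
from .separation import separation_analysis
from .synthetic import simulate_population, simulate_vm_trial
from .velocity_coding import shuffle_regression_test

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STAGES"]

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "response_stats", "velocity_coding",
                  "decode", "separate", "multisensory")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Per-stage parameter blocks override the stage defaults; unknown stage
    names or parameters are rejected up front.  The demo defaults are sized
    to finish within minutes on one CPU.
    """

    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    simulate: dict = field(default_factory=lambda: {
        "n_trials": 80, "n_neurons": 4, "sample_rate": 500.0})
    response_stats: dict = field(default_factory=lambda: {"n_trials": 10})
    velocity_coding: dict = field(default_factory=lambda: {
        "n_iter": 200, "bin_width": 0.25, "n_trials": 6})
    decode: dict = field(default_factory=lambda: {
        "k_values": (6, 25), "n_repeats": 20})
    separate: dict = field(default_factory=lambda: {
        "k": 25, "n_iterations": 30, "s_plus_range": (0.0, 80.0)})
    multisensory: dict = field(default_factory=lambda: {"n_trials": 10})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                unknown = set(val) - set(current)
                if unknown:
                    raise ValueError(
                        f"unknown parameter(s) {sorted(unknown)} for stage {key!r}")
                current.update(val)
            else:
                setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
        for st in cfg.stages:
            if st not in DEFAULT_STAGES:
                raise ValueError(f"unknown stage {st!r}")
        return cfg


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict | None = None,
                 out_dir=None) -> Path:
    """Run the configured stages and return the artifact directory."""
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out_dir = Path(out_dir if out_dir is not None else "headvel_run")
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    streams = {name: child for name, child in
               zip(DEFAULT_STAGES, ss.spawn(len(DEFAULT_STAGES)))}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "config": asdict(config),
        "stages": {},
    }

    population = None
    profiles = None
    for stage in config.stages:
        logger.info("running stage %s", stage)
        rng = np.random.default_rng(streams[stage])
        try:
            if stage == "simulate":
                p = config.simulate
                population = simulate_population(
                    n_trials=p["n_trials"], n_neurons=p["n_neurons"],
                    sample_rate=p["sample_rate"], seed=rng)
                manifest["stages"][stage] = {"n_trials": len(population)}

            elif stage == "response_stats":
                _require(population, stage, "simulate")
                stim = population.stimuli["stim"]
                n_tr = config.response_stats["n_trials"]
                rows = []
                for nid, spec in population.truth.items():
                    trials = [t for t in population.trials
                              if t.neuron_id == nid][:n_tr]
                    r_cw = rotation_response(trials, stim, "CW", cell_id=nid)
                    r_ccw = rotation_response(trials, stim, "CCW", cell_id=nid)
                    cls = classify_cell(r_cw, r_ccw)
                    rows.append({
                        "neuron": nid, "true_class": spec.response_class,
                        "called_class": cls.response_class, "dsi": cls.dsi,
                        "p_cw": r_cw.p_value, "p_ccw": r_ccw.p_value,
                        "delta_cw": r_cw.delta, "delta_ccw": r_ccw.delta,
                    })
                pd.DataFrame(rows).to_csv(out_dir / "response_stats.csv",
                                          index=False)
                manifest["stages"][stage] = {"n_cells": len(rows)}

            elif stage == "velocity_coding":
                _require(population, stage, "simulate")
                stim = population.stimuli["stim"]
                p = config.velocity_coding
                rows = []
                for nid in population.truth:
                    trials = [t for t in population.trials
                              if t.neuron_id == nid][: p["n_trials"]]
                    for direction in ("CW", "CCW"):
                        res = shuffle_regression_test(
                            trials, stim, direction, n_iter=p["n_iter"],
                            bin_width=p["bin_width"], seed=rng)
                        rows.append({"neuron": nid, "direction": direction,
                                     "r2_raw": res.r2_raw, "p": res.p_value,
                                     "n_iter": res.n_iter})
                pd.DataFrame(rows).to_csv(out_dir / "velocity_coding.csv",
                                          index=False)
                manifest["stages"][stage] = {"n_tests": len(rows)}

            elif stage == "decode":
                _require(population, stage, "simulate")
                profiles = build_profiles(population)
                p = config.decode
                sweep = network_sweep(profiles, p["k_values"],
                                      n_repeats=p["n_repeats"], seed=rng)
                sweep.to_csv(out_dir / "decode_sweep.csv", index=False)
                summary = sweep.groupby("k")["error"].median().to_dict()
                manifest["stages"][stage] = {
                    "median_error_by_k": {int(k): float(v)
                                          for k, v in summary.items()}}

            elif stage == "separate":
                _require(profiles, stage, "decode")
                p = config.separate
                res = separation_analysis(
                    profiles, k=p["k"], s_plus_range=tuple(p["s_plus_range"]),
                    n_iterations=p["n_iterations"], seed=rng)
                manifest["stages"][stage] = {
                    "separation_index": res.separation_index,
                    "fisher_significant_fraction":
                        res.fisher_significant_fraction,
                }

            elif stage == "multisensory":
                _require(population, stage, "simulate")
                stim = population.stimuli["stim"]
                spec = population.truth[0]
                n_tr = config.multisensory["n_trials"]
                conds = {}
                for cond in ("vestibulo_visual", "visual_only", "dark"):
                    conds[cond] = np.stack([
                        simulate_vm_trial(stim, spec, seed=rng, condition=cond,
                                          insert_spikes=False).vm
                        for _ in range(n_tr)])
                n_pre = int(np.searchsorted(stim.time,
                                            stim.motion_window()[0]))
                bwin = (0, n_pre)
                auto = odd_even_autocorrelation(conds["vestibulo_visual"])
                combined = conds["vestibulo_visual"].mean(axis=0)
                summed = arithmetic_sum(conds["visual_only"].mean(axis=0),
                                        conds["dark"].mean(axis=0),
                                        baseline_window=bwin)
                coeffs = {
                    name: normalized_crosscorrelation(cand, combined, auto)
                    for name, cand in (("sum", summed),
                                       ("visual", conds["visual_only"].mean(axis=0)),
                                       ("vestibular", conds["dark"].mean(axis=0)))
                }
                manifest["stages"][stage] = {"coefficients": coeffs}

        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


def _require(obj, stage, needed):
    if obj is None:
        raise RuntimeError(
            f"stage {stage!r} requires stage {needed!r} to run first")
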