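"""End-to-end orchestration: simulate/featurize -> APM/MSM -> validation
-> kinetics/TPT, with YAML configuration, per-stage checkpoints and
machine-readable reports.

Identical configuration plus seed yields byte-identical numeric tables.
Stage outputs are written as CSV/JSON into the run directory; a run that
fails at a stage leaves the completed checkpoints in place.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic as synth
from . import validation as _val
from .ensembles import TrajectoryEnsemble
from .model import MarkovStateModel, MSMResults

__all__ = ["RunConfig", "run_pipeline", "load_config"]

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_COMPUTE = 3


@dataclass
class RunConfig:
    """Validated pipeline configuration (times in ns)."""

    outdir: str = "run"
    seed: int = 0
    # synthetic data conditions
    n_traj: int = 10
    n_steps: int = 20000
    micro_per_macro: int = 5
    inter_rate: float = 0.012
    noise_sd: float = 0.4
    # model settings
    lag: float = 200.0
    t0: float = 400.0
    n_macro: int | None = None
    estimator: str = "nonreversible"
    min_population: int = 10
    # diagnostics
    lag_grid: list = field(default_factory=lambda: [20.0, 40.0, 100.0, 200.0, 400.0])
    residence_states: int = 3
    residence_points: int = 8
    n_boot: int | None = None
    open_threshold: float = 25.0  # Å, c.o.m. distance above which a
    # macrostate counts as open
    resume: bool = False

    def validate(self, dt: float) -> None:
        for t in [self.lag, self.t0, *self.lag_grid]:
            if t <= 0 or abs(t / dt - round(t / dt)) > 1e-9:
                raise ValueError(
                    f"time {t} ns is not a positive multiple of the saving "
                    f"interval {dt} ns")
        if self.n_traj < 1 or self.n_steps < 2:
            raise ValueError("need n_traj >= 1 and n_steps >= 2")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Run every stage and return the report dictionary.

    Stages: simulate -> features -> build (APM/MSM) -> validate ->
    kinetics -> tpt.  Each stage is checkpointed under ``config.outdir``;
    with ``resume=True`` completed stage outputs are reused.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {"config": asdict(config),
                    "config_hash": _config_hash(config),
                    "seed": config.seed, "stages": {}}

    def stage(name):
        log(f"[agomsm] stage {name}")
        report["stages"][name] = {"t_wall": None}
        return time.time()

    # --- simulate -------------------------------------------------------
    t = stage("simulate")
    chain = synth.ago_like_chain(config.seed,
                                 micro_per_macro=config.micro_per_macro,
                                 inter_rate=config.inter_rate)
    config.validate(chain.lag_unit)
    labels_true = synth.simulate_chain(chain, config.n_traj, config.n_steps,
                                       seed=config.seed + 1)
    emission = synth.ago_like_emission(chain, seed=config.seed + 2,
                                       noise_sd=config.noise_sd)
    features = synth.emit_features(labels_true, emission,
                                   seed=config.seed + 3)
    _write_json(out / "ground_truth.json", {
        "T_true": chain.T_true, "pi_true": chain.pi_true,
        "macro_of_micro": chain.macro_of_micro,
        "macro_populations": chain.macro_populations(),
        "implied_timescales_true": np.where(
            np.isfinite(chain.implied_timescales_true),
            chain.implied_timescales_true, -1.0),
        "lag_unit": chain.lag_unit,
        "emission_centers": emission.centers,
        "noise_sd": emission.noise_sd,
    })
    np.savetxt(out / "features_traj0.csv", features.series[0],
               delimiter=",", header="com_distance_A", comments="")
    report["stages"]["simulate"]["t_wall"] = time.time() - t

    # --- build ----------------------------------------------------------
    t = stage("build")
    model = MarkovStateModel.from_features(
        features, lag=config.lag, t0=config.t0, n_macro=config.n_macro,
        estimator=config.estimator, seed=config.seed,
        min_population=config.min_population)
    res = model.fit()
    np.savetxt(out / "assignment.csv",
               res.assignment.flat()[:, None], fmt="%d", header="microstate",
               comments="")
    np.savetxt(out / "transition_matrix.csv", res.transition_matrix,
               delimiter=",")
    np.savetxt(out / "count_matrix.csv", res.micro.C, delimiter=",", fmt="%d")
    _write_json(out / "model.json", {
        "n_microstates": res.n_microstates,
        "n_macrostates": res.n_macrostates,
        "lag_ns": res.lag, "t0_ns": config.t0, "seed": config.seed,
        "micro_to_macro": res.mapping.micro_to_macro,
        "macro_populations": res.macro_populations,
        "stationary": res.stationary_distribution,
    })
    report["stages"]["build"]["t_wall"] = time.time() - t
    report["n_microstates"] = res.n_microstates
    report["n_macrostates"] = res.n_macrostates
    report["macro_populations"] = res.macro_populations.tolist()

    # --- validate -------------------------------------------------------
    t = stage("validate")
    its = res.implied_timescales(config.lag_grid, k=8)
    pd.DataFrame(its.timescales, index=its.lags).to_csv(
        out / "implied_timescales.csv",
        index_label="lag_ns",
        header=[f"t{k + 1}_ns" for k in range(its.timescales.shape[1])])
    resid_rows = []
    big_states = np.argsort(-res.stationary_distribution)
    for row in big_states[:config.residence_states]:
        state = int(res.micro.active[row])
        r = res.residence_test(state, n_points=config.residence_points)
        for i, tt in enumerate(r.times):
            resid_rows.append({"state": state, "t_ns": tt,
                               "p_counted": r.p_counted[i],
                               "p_msm": r.p_msm[i], "se": r.se[i]})
    pd.DataFrame(resid_rows).to_csv(out / "residence_tests.csv", index=False)
    report["slowest_its_ns"] = float(res.timescales(1)[0])
    report["stages"]["validate"]["t_wall"] = time.time() - t

    # --- kinetics -------------------------------------------------------
    t = stage("kinetics")
    mfpt_us = res.mfpt_matrix(units="us")
    mfpt_us.round(6).to_csv(out / "mfpt_macro_us.csv")
    open_m, partial_m, closed_m = classify_macrostates(
        res, features, config.open_threshold)
    report["open_macro"] = open_m
    report["partial_macro"] = partial_m
    report["closed_macros"] = closed_m
    report["mfpt_closed_to_open_us"] = float(
        np.mean([mfpt_us.iloc[c, open_m] for c in closed_m]))
    report["mfpt_open_to_closed_us"] = float(
        np.mean([mfpt_us.iloc[open_m, c] for c in closed_m]))
    if config.n_boot is None or config.n_boot >= 2:
        # macrostates are numbered by descending population in every fit,
        # so the openness classification carries over to label-refits
        def _stat(ens):
            m = MarkovStateModel.from_labels(
                ens, lag=config.lag, n_macro=res.n_macrostates,
                estimator=config.estimator, seed=config.seed)
            r = m.fit()
            return np.mean([r.mfpt(c, open_m) for c in closed_m])
        boot = _val.bootstrap(res.assignment.labels, _stat,
                              n_boot=config.n_boot, seed=config.seed + 7)
        report["mfpt_closed_to_open_boot_sd_us"] = boot.std
        report["bootstrap_failed_replicates"] = boot.n_failed
    report["stages"]["kinetics"]["t_wall"] = time.time() - t

    # --- tpt ------------------------------------------------------------
    t = stage("tpt")
    paths = res.pathways(closed_m, [open_m], lumped=True)
    _write_json(out / "pathways.json", [
        {"macro_sequence": list(p.states), "flux": p.flux,
         "fraction": p.fraction} for p in paths])
    report["n_macro_pathways"] = len(paths)
    report["top_pathway_fraction"] = paths[0].fraction if paths else None
    trace = res.sample(start=0, n_steps=min(20000, 10 * config.n_steps),
                       seed=config.seed + 11)
    np.savetxt(out / "synthetic_trace.csv",
               np.column_stack([trace.micro, trace.macro]), fmt="%d",
               delimiter=",", header="microstate,macrostate", comments="")
    report["stages"]["tpt"]["t_wall"] = time.time() - t

    report["t_wall_total"] = time.time() - t_start
    _write_json(out / "report.json", report)
    return report


def classify_macrostates(res: MSMResults, features: TrajectoryEnsemble,
                         open_threshold: float = 25.0):
    """Identify the open, partially open and closed macrostates.

    Each macrostate's mean first-feature value (the c.o.m.-distance
    coordinate, Å) orders the states by openness: the largest mean is the
    open state, the next the partially open state, the rest closed.
    ``open_threshold`` (the distance above which a conformation can admit
    direct RNA loading) is only a sanity criterion: a warning-free
    classification requires the open state's mean to exceed it.
    """
    n = res.n_macrostates
    flat = res.mapping.map_labels(res.assignment.flat())
    X = features.concatenated()[:, 0]
    means = np.array([X[flat == m].mean() if np.any(flat == m) else -np.inf
                      for m in range(n)])
    order = np.argsort(-means)
    open_m = int(order[0])
    partial_m = int(order[1]) if n > 1 else open_m
    closed = sorted(int(m) for m in order[2:])
    return open_m, partial_m, closed
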