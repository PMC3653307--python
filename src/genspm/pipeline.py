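"""End-to-end analysis driver: data -> descriptives -> optimal trajectories
-> maximum-likelihood fit -> hypothesis battery -> summary report.

The pipeline is configured by a plain dict (usually loaded from YAML) and
writes only deterministic, timestamp-free artifacts so that reruns under a
fixed seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import config as config_mod
from . import estimation, hypotheses, io, trajectories
from .likelihood import pack
from .model import PARAM_FIELDS, ModelParams, TrajectoryPair

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger("genspm")

_VARIABLES = ("CH", "DBP")
_SEXES = ("F", "M")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate_config(cfg: dict) -> dict:
    if cfg.get("variable") not in _VARIABLES:
        raise ValueError(f"unknown variable {cfg.get('variable')!r}; expected one of {_VARIABLES}")
    if cfg.get("sex") not in _SEXES:
        raise ValueError(f"unknown sex {cfg.get('sex')!r}; expected one of {_SEXES}")
    if ("simulate" in cfg) == ("input" in cfg):
        raise ValueError("config must name exactly one of 'simulate' or 'input'")
    return cfg


def _get_params(cfg: dict) -> ModelParams:
    src = cfg.get("params", "reference")
    if src == "reference":
        return config_mod.reference_params(cfg["variable"], cfg["sex"])
    return config_mod.load_params(src, cfg["variable"], cfg["sex"])


def _longlived_group(sex: str) -> str:
    return "LS90+" if sex == "F" else "LS85+"


def _empirical_pair(records, sex: str):
    """Cubic optimal trajectories from long-lived averages, per stratum.

    If a stratum has too few nonempty bins for a cubic, fall back to the
    pooled long-lived fit across strata.
    """
    group = _longlived_group(sex)
    frames, fits = {}, {}
    try:
        pooled = trajectories.average_trajectory(records, group, sex)
        pooled_fit, _ = trajectories.fit_optimal_trajectory(pooled["bin_mid"], pooled["mean"])
    except ValueError as e:
        raise ValueError(
            f"cannot fit optimal trajectories from long-lived averages ({e}); "
            "set optimal_from: allostatic for cohorts without long-lived subjects"
        ) from e
    for code, name in ((1, "noncarrier"), (0, "carrier")):
        sub = [r for r in records if r.genotype == code]
        try:
            avg = trajectories.average_trajectory(sub, group, sex)
            fits[name], _ = trajectories.fit_optimal_trajectory(avg["bin_mid"], avg["mean"])
        except ValueError:
            log.warning("too little long-lived data for %s; using pooled trajectory", name)
            avg = pooled
            fits[name] = pooled_fit
        avg = avg.assign(genotype=name, group=group)
        frames[name] = avg
    table = pd.concat(frames.values(), ignore_index=True)
    return TrajectoryPair(fits["noncarrier"], fits["carrier"]), table


def _fit_yaml(result, variable, sex) -> dict:
    mp = result.params
    return {
        "variable": variable,
        "sex": sex,
        "scale": "display",
        "estimates": {
            "p1": float(mp.p1),
            "noncarrier": {k: float(v) for k, v in mp.noncarrier.to_display().items()},
            "carrier": {k: float(v) for k, v in mp.carrier.to_display().items()},
        },
        "loglik": float(result.loglik),
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "boundary": list(result.boundary),
        "seed": int(result.seed),
    }


def _marker_map(results) -> dict:
    """(row, column) -> significance marker, mirroring the summary-table
    convention: two-stratum nulls mark the noncarrier row."""
    out = {}
    for r in results:
        m = hypotheses.significance_marker(r.p_value)
        name, _, stratum = r.hypothesis.partition("[")
        stratum = stratum.rstrip("]") or "noncarrier"
        col = {
            "baseline_equal": "ln_a_mu0",
            "no_quadratic_hazard": "a_mu1",
            "age_constant_ushape": "b_mu1",
            "adaptive_equal": "a_Y",
            "no_adaptive_decline": "b_Y",
            "allostatic_equal": "a_f1",
        }.get(name)
        if col:
            out[(stratum, col)] = m
    return out


def _report_frame(cfg, result, battery_results) -> pd.DataFrame:
    markers = _marker_map(battery_results)
    mp = result.params
    rows = []
    for stratum in ("noncarrier", "carrier"):
        disp = getattr(mp, stratum).to_display()
        row = {"variable": cfg["variable"], "sex": cfg["sex"], "allele": stratum}
        for f in PARAM_FIELDS:
            val = f"{disp[f]:.4g}"
            row[f] = val + markers.get((stratum, f), "")
        row["p1"] = f"{mp.p1:.3f}" if stratum == "noncarrier" else ""
        row["ln_L"] = f"{result.loglik:.3f}" if stratum == "noncarrier" else ""
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the full analysis; return a dict of artifact paths."""
    cfg = _validate_config(dict(cfg))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    censor_lag = float(cfg.get("censor_lag", 2.0))
    artifacts = {}

    params = _get_params(cfg)

    # --- stage 1: data -----------------------------------------------------
    if "simulate" in cfg:
        design = cohort_mod.CohortDesign(sex=cfg["sex"], seed=seed, **cfg["simulate"])
        log.info("simulating cohort: n=%d seed=%d", design.n_individuals, seed)
        individuals = cohort_mod.simulate_cohort(design, params)
        records = cohort_mod.to_records(individuals)
        io.write_cohort(cohort_mod.cohort_to_frame(individuals), outdir / "cohort.tsv")
        cohort_mod.truth_to_frame(individuals).to_csv(
            outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g"
        )
        artifacts["cohort"] = outdir / "cohort.tsv"
        artifacts["truth"] = outdir / "truth.tsv"
    else:
        records = io.read_cohort(cfg["input"], schema=cfg.get("schema", "standard"),
                                 censor_lag=censor_lag)
        log.info("loaded %d records from %s", len(records), cfg["input"])

    # --- stage 2: descriptive trajectories + optimal cubic -----------------
    if cfg.get("optimal_from", "empirical") == "empirical":
        f_pair, traj_table = _empirical_pair(records, cfg["sex"])
    else:  # fall back to the generative allostatic curves
        f_pair = TrajectoryPair.from_params(params)
        traj_table = pd.DataFrame()
    if len(traj_table):
        traj_table.to_csv(outdir / "trajectories.tsv", sep="\t", index=False,
                          float_format="%.6g")
        artifacts["trajectories"] = outdir / "trajectories.tsv"
    config_mod.save_trajectories(f_pair, outdir / "optimal_trajectories.yaml")
    artifacts["optimal_trajectories"] = outdir / "optimal_trajectories.yaml"

    # --- stage 3: maximum-likelihood fit -----------------------------------
    pc = pack(records, censor_lag=censor_lag)
    fit_cfg = dict(cfg.get("fit", {}))
    warm = fit_cfg.pop("warm_start", "simulate" in cfg)
    options = estimation.FitOptions(seed=seed, **fit_cfg)
    init = params if warm else estimation.moment_init(records, censor_lag)
    log.info("fitting joint model (%d records, warm_start=%s)", pc.n, warm)
    result = estimation.fit(pc, f_pair, init, options=options, censor_lag=censor_lag)
    (outdir / "fit.yaml").write_text(
        yaml.safe_dump(_fit_yaml(result, cfg["variable"], cfg["sex"]), sort_keys=False)
    )
    artifacts["fit"] = outdir / "fit.yaml"

    # --- stage 4: hypothesis battery ---------------------------------------
    hyps = cfg.get("hypotheses", "all")
    hyps = None if hyps == "all" else list(hyps)
    log.info("running likelihood-ratio battery")
    battery_results = hypotheses.battery(pc, f_pair, result, options=options,
                                         hypotheses=hyps, censor_lag=censor_lag)
    hypotheses.battery_table(battery_results).to_csv(
        outdir / "lrt.tsv", sep="\t", index=False, float_format="%.6g"
    )
    artifacts["lrt"] = outdir / "lrt.tsv"

    # --- stage 5: summary report -------------------------------------------
    _report_frame(cfg, result, battery_results).to_csv(
        outdir / "report.tsv", sep="\t", index=False
    )
    artifacts["report"] = outdir / "report.tsv"
    log.info("pipeline complete: %s", outdir)
    return artifacts
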