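"""Declarative pipeline orchestration.

A YAML config names the stages to run (in canonical order: simulate,
rings, unpalatability, pgls, predation, mantel, trials), the seed and the
output directory.  Each stage writes its outputs under the output
directory and contributes to a summary report; all randomness is seeded
from the config so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colour, phylo, predation, spatial, trials as trials_mod
from . import unpalatability as unpal
from .simulate import SimConfig, simulate_community, simulate_gut_screen, \
    simulate_tree_bm, simulate_trials

log = logging.getLogger("goldmim")

STAGE_ORDER = ("simulate", "rings", "unpalatability", "pgls", "predation",
               "mantel", "trials")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with at least a 'seed' key")
    cfg.setdefault("stages", list(STAGE_ORDER))
    cfg.setdefault("out_dir", "goldmim_out")
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def run_pipeline(config_path) -> dict:
    """Execute the configured stages in canonical order; return the report."""
    cfg = load_config(config_path)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_params = dict(cfg.get("simulate", {}))
    sim = SimConfig(seed=int(cfg["seed"]), **sim_params)
    report: dict = {"seed": int(cfg["seed"]), "stages": {}}
    state: dict = {}
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    for stage in stages:
        log.info("running stage %s", stage)
        try:
            _STAGES[stage](sim, cfg, state, report, out_dir)
        except Exception as exc:  # halt with context
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump({**cfg, "simulate": sim.to_dict()}, fh, sort_keys=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _require(state: dict, key: str, producer: str):
    if key not in state:
        raise StageError(f"missing input {key!r}; run the {producer} stage first")
    return state[key]


def _stage_simulate(sim, cfg, state, report, out_dir):
    tree, trait, V = simulate_tree_bm(sim)
    tt, cm, u_true = simulate_community(sim)
    state.update(tree=tree, vcv=V, trait_table=tt, colour=cm, u_true=u_true)
    tree.write(path=str(out_dir / "tree.nwk"), schema="newick")
    tt.data.to_csv(out_dir / "traits.csv")
    cm.to_long().to_csv(out_dir / "colour.csv", index=False)
    report["stages"]["simulate"] = {"n_species": sim.n_species,
                                    "true_lambda": sim.true_lambda}


def _stage_rings(sim, cfg, state, report, out_dir):
    cm = _require(state, "colour", "simulate")
    feats = colour.weighted_colour_matrix(cm)
    d = colour.bray_curtis(feats.to_numpy(float))
    coords, stress = colour.nmds(d, dims=2, n_starts=cfg.get("nmds_starts", 20),
                                 seed=sim.seed)
    part = colour.kmeans_ssi_scan(feats, k_range=range(
        cfg.get("k_min", 2), cfg.get("k_max", 12) + 1), seed=sim.seed)
    out = pd.DataFrame({"ring": part.labels,
                        "nmds1": coords[:, 0], "nmds2": coords[:, 1]},
                       index=feats.index)
    out.to_csv(out_dir / "rings.csv")
    state["rings"] = part
    report["stages"]["rings"] = {"k": part.k, "stress": stress,
                                 "ssi_by_k": part.ssi_by_k}


def _stage_unpalatability(sim, cfg, state, report, out_dir):
    tt = _require(state, "trait_table", "simulate")
    models = unpal.fit_trait_interpolators(tt)
    tt = unpal.impute_missing_traits(tt, models)
    res = unpal.unpalatability_index(tt)
    pd.DataFrame({"u": res.u, "weight": res.weight}).to_csv(out_dir / "u.csv")
    state["u"] = res
    report["stages"]["unpalatability"] = {
        "n_species": int(len(res.u)), "u_mean": float(res.u.mean()),
        "u_sd": float(res.u.std())}


def _stage_pgls(sim, cfg, state, report, out_dir):
    V = _require(state, "vcv", "simulate")
    res = _require(state, "u", "unpalatability")
    cm = _require(state, "colour", "simulate")
    u = res.u.loc[V.taxa].to_numpy(float)
    area = cm.golden_area.loc[V.taxa].to_numpy(float)
    w = res.weight.loc[V.taxa].to_numpy(float)
    fit = phylo.golden_area_model(u, area, V, weights=w)
    lam, lam_fit = phylo.estimate_lambda_ml(
        np.ones((len(u), 1)), area, V, case_weights=w)
    summary = {
        "coefficients": dict(zip(fit.names, map(float, fit.coefficients))),
        "F": fit.f_statistic, "df": [fit.df_num, fit.df_den],
        "p": fit.f_pvalue, "lambda_area": lam}
    with open(out_dir / "pgls.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    report["stages"]["pgls"] = summary


def _stage_predation(sim, cfg, state, report, out_dir):
    u = state.get("u")
    u_series = u.u if u is not None else None
    gs = simulate_gut_screen(sim, u=u_series)
    kres = predation.killing_values(gs)
    kres.k.rename("K").to_csv(out_dir / "killing_values.csv")
    smooth = predation.smooth_regression(
        (u_series if u_series is not None else pd.Series(
            np.linspace(0, 7, len(kres.k)), index=kres.k.index)
         ).loc[kres.k.index].to_numpy(float),
        kres.k.to_numpy(float))
    state["killing"] = kres
    report["stages"]["predation"] = {
        "K_mean": float(kres.k.mean()), "smooth_F": smooth.f_statistic,
        "smooth_p": smooth.p_value, "edf": smooth.edf}


def _stage_mantel(sim, cfg, state, report, out_dir):
    cm = _require(state, "colour", "simulate")
    rng = sim.rng(5)
    # uniform-within-range occurrences: each species occupies a random box
    records = []
    for sp in cm.species:
        cx, cy = rng.uniform(115, 150), rng.uniform(-38, -12)
        k = rng.integers(3, 12)
        records.append(pd.DataFrame({
            "species_id": sp,
            "lon": np.clip(rng.normal(cx, 4.0, k), 113, 154),
            "lat": np.clip(rng.normal(cy, 4.0, k), -43, -10)}))
    recs = pd.concat(records, ignore_index=True)
    pm = spatial.grid_occurrences(recs, cell_km=cfg.get("cell_km", 400.0))
    d_geo, d_col = spatial.distance_matrices(pm, cm)
    r, p = spatial.mantel_test(d_col.to_numpy(), d_geo.to_numpy(),
                               n_perm=cfg.get("mantel_perms", 999),
                               seed=sim.seed)
    pm.matrix.to_csv(out_dir / "presence.csv")
    report["stages"]["mantel"] = {"r": r, "p": p,
                                  "n_cells": int(pm.matrix.shape[1])}


def _stage_trials(sim, cfg, state, report, out_dir):
    u = state.get("u")
    tt = simulate_trials(sim)
    tt.data.to_csv(out_dir / "trials.csv", index=False)
    mat = tt.capture_matrix()
    q, df, p = trials_mod.cochran_q(mat.to_numpy(float))
    freqs = trials_mod.capture_frequencies(tt)
    scores = tt.data.dropna(subset=["post_attack_rank"]).groupby(
        "prey_species")["post_attack_rank"].mean() / 2.0
    k_trial = {prey: trials_mod.trial_killing_value([freqs[prey]])
               for prey in freqs.index}
    report["stages"]["trials"] = {
        "cochran_q": q, "df": df, "p": p,
        "capture_frequencies": {k: float(v) for k, v in freqs.items()},
        "mean_postattack_score": {k: float(v) for k, v in scores.items()},
        "trial_killing_values": {k: float(v) for k, v in k_trial.items()}}


_STAGES = {
    "simulate": _stage_simulate,
    "rings": _stage_rings,
    "unpalatability": _stage_unpalatability,
    "pgls": _stage_pgls,
    "predation": _stage_predation,
    "mantel": _stage_mantel,
    "trials": _stage_trials,
}
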