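"""End-to-end orchestration: simulate/load, covariates, turnover at up to
three scales, trait-shuffle null test, ICAR fits and DIC ranking.

Every stage writes plain CSV/JSON so any stage can be re-run in isolation,
and a manifest records the seeds, versions and analysis toggles needed to
reproduce each output exactly.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (OccurrenceAtlas, aggregate, apply_exclusions,
                    block_assignment, block_id, read_atlas, write_atlas)
from .biotic import biotic_covariates
from .climate import climate_covariates
from .icar import build_design, compare_models, fit_icar, regress_rao_on_sim
from .nullmodel import (classification_counts, classify,
                        null_delta_distribution)
from .simulate import SimConfig, simulate_atlas_pair, simulate_climate, \
    simulate_traits, truth
from .traits import TraitTable, gower, read_traits
from .turnover import MEASURES, delta, neighborhood_turnover

logger = logging.getLogger("betadrift")

DEFAULTS = {
    "seed": 0,
    "scales": [10],
    "min_land": 0.5,
    "jost": True,
    "proportional": False,
    "latitude_deg": 54.0,
    "quantile_method": "linear",
    "mbv_include_focal": False,
    "nulltest": {"reps": 999, "alpha": 0.05},
    "fit": {"n_iter": 6000, "n_burn": 1000,
            "models": ["full", "biotic", "climate"],
            "responses": ["sim", "rao"]},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    merged = json.loads(json.dumps(DEFAULTS))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg.get("simulation") or {})
    sim.setdefault("seed", cfg["seed"])
    if sim.get("homog_region") is not None:
        sim["homog_region"] = tuple(sim["homog_region"])
    return SimConfig(**sim)


def simulate_to_dir(cfg: dict, outdir) -> dict:
    """Write the synthetic inputs (two atlases, traits, climate, truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = _sim_config(cfg)
    a1, a2 = simulate_atlas_pair(sc)
    traits = simulate_traits(sc)
    clim = simulate_climate(sc)
    write_atlas(a1, outdir / "atlas_period1.csv")
    write_atlas(a2, outdir / "atlas_period2.csv")
    tdf = traits.data.reset_index().rename(columns={"index": "species"})
    tdf.to_csv(outdir / "traits.csv", index=False)
    clim.to_csv(outdir / "climate.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth(sc), fh, indent=2, default=str)
    return {"atlas1": a1, "atlas2": a2, "traits": traits, "climate": clim}


def _load_inputs(cfg: dict):
    if "simulation" in cfg and cfg["simulation"] is not None:
        sc = _sim_config(cfg)
        a1, a2 = simulate_atlas_pair(sc)
        return a1, a2, simulate_traits(sc), simulate_climate(sc)
    inp = cfg["inputs"]
    a1 = read_atlas(inp["atlas1"], period=inp.get("period1", "period1"))
    a2 = read_atlas(inp["atlas2"], period=inp.get("period2", "period2"))
    traits = read_traits(inp["traits"], log_traits=tuple(
        cfg.get("log_traits", ())))
    clim = pd.read_csv(inp["climate"])
    return a1, a2, traits, clim


def _aggregate_climate(clim: pd.DataFrame, base_atlas: OccurrenceAtlas,
                       factor: int) -> pd.DataFrame:
    """Mean monthly climate over the member 10-km cells of each block."""
    g = base_atlas.grid
    keys, member = block_assignment(g, factor)
    size = g.cell_size * factor
    e0, n0 = g.easting.min(), g.northing.min()
    ids = {cid: block_id(size, keys[m][0] * size + e0, keys[m][1] * size + n0)
           for cid, m in zip(g.cell_ids, member)}
    df = clim[clim["cell_id"].isin(ids)].copy()
    df["cell_id"] = df["cell_id"].map(ids)
    return (df.groupby(["cell_id", "year", "month"], as_index=False)
            [["tmin_c", "tmean_c", "precip_mm"]].mean())


def _field_frame(atlas, t1, t2, dfield) -> pd.DataFrame:
    g = atlas.grid
    return pd.DataFrame({"site_id": list(g.cell_ids),
                         "easting_km": g.easting, "northing_km": g.northing,
                         "t1": t1.values, "t2": t2.values,
                         "delta": dfield.delta})


def _fit_to_dict(fit) -> dict:
    return {"model": fit.model_id,
            "coefficients": {c: {"median": float(fit.summary.loc[c, "median"]),
                                 "q2.5": float(fit.summary.loc[c, "q2.5"]),
                                 "q97.5": float(fit.summary.loc[c, "q97.5"]),
                                 "rhat": float(fit.rhat[c])}
                             for c in fit.columns},
            "DIC": fit.dic, "pD": fit.p_d, "n_iter": fit.n_iter,
            "n_burn": fit.n_burn, "seed": fit.seed, "settings": fit.settings}


def run_scale(a1: OccurrenceAtlas, a2: OccurrenceAtlas, traits: TraitTable,
              clim: pd.DataFrame, cfg: dict, scale_dir: Path,
              factor: int) -> dict:
    """All per-scale stages; returns the summary block for the manifest."""
    scale_dir.mkdir(parents=True, exist_ok=True)
    base = a1
    if factor > 1:
        a1 = aggregate(a1, factor, min_land=cfg["min_land"])
        a2 = aggregate(a2, factor, min_land=cfg["min_land"])
        # both periods must survive on the same block set
        common = sorted(set(a1.grid.cell_ids) & set(a2.grid.cell_ids))
        if tuple(common) != a1.grid.cell_ids:
            keep1 = [a1.grid.index_of(c) for c in common]
            keep2 = [a2.grid.index_of(c) for c in common]
            from .atlas import _subset
            a1, a2 = _subset(a1, np.array(keep1)), _subset(a2, np.array(keep2))
        clim_s = _aggregate_climate(clim, base, factor)
    else:
        clim_s = clim[clim["cell_id"].isin(a1.grid.cell_ids)]
    table = traits.reindex(a1.species)
    dmat = gower(table)

    fields = {}
    for measure in MEASURES:
        t1 = neighborhood_turnover(a1, dmat, measure, jost=cfg["jost"],
                                   proportional=cfg["proportional"])
        t2 = neighborhood_turnover(a2, dmat, measure, jost=cfg["jost"],
                                   proportional=cfg["proportional"])
        dfield = delta(t1, t2)
        fields[measure] = dfield
        _field_frame(a1, t1, t2, dfield).to_csv(
            scale_dir / f"turnover_{measure}.csv", index=False)

    nt = cfg["nulltest"]
    null = null_delta_distribution(a1, a2, table, n_reps=int(nt["reps"]),
                                   seed=int(cfg["seed"]) + 101,
                                   jost=cfg["jost"],
                                   proportional=cfg["proportional"])
    classified = classify(fields["sim"], fields["rao"], null.p_two_tailed,
                          alpha=float(nt["alpha"]))
    classified.to_csv(scale_dir / "nulltest.csv", index=False)
    counts = classification_counts(classified, alpha=float(nt["alpha"]))
    counts.to_csv(scale_dir / "classification_counts.csv")

    bio = biotic_covariates(a1, dmat, include_focal=cfg["mbv_include_focal"])
    bio.to_csv(scale_dir / "biotic_covariates.csv", index=False)
    cc = climate_covariates(clim_s, latitude_deg=cfg["latitude_deg"],
                            quantile_method=cfg["quantile_method"])
    cc.to_csv(scale_dir / "climate_covariates.csv", index=False)
    covariates = bio.merge(cc, on="cell_id", how="outer")

    fit_cfg = cfg["fit"]
    rankings = {}
    for resp_name in fit_cfg["responses"]:
        fits = {}
        for model_id in fit_cfg["models"]:
            try:
                spec = build_design(model_id, fields[resp_name], covariates)
            except ValueError as err:
                logger.warning("skipping %s fit of delta %s at this scale: %s",
                               model_id, resp_name, err)
                continue
            fit = fit_icar(spec, n_iter=int(fit_cfg["n_iter"]),
                           n_burn=int(fit_cfg["n_burn"]),
                           seed=int(cfg["seed"]) + 211)
            fits[model_id] = fit
            with open(scale_dir / f"fit_{resp_name}_{model_id}.json", "w") as fh:
                json.dump(_fit_to_dict(fit), fh, indent=2)
        if fits:
            ranking = compare_models(fits)
            ranking.insert(0, "response", f"delta_beta_{resp_name}")
            ranking.to_csv(scale_dir / f"dic_ranking_{resp_name}.csv",
                           index=False)
            rankings[resp_name] = ranking

    slope = None
    try:
        rr = regress_rao_on_sim(fields["rao"], fields["sim"],
                                n_iter=int(fit_cfg["n_iter"]),
                                n_burn=int(fit_cfg["n_burn"]),
                                seed=int(cfg["seed"]) + 307)
        with open(scale_dir / "fit_rao_on_sim.json", "w") as fh:
            json.dump(_fit_to_dict(rr), fh, indent=2)
        slope = _fit_to_dict(rr)["coefficients"]["delta_sim"]
    except ValueError as err:
        logger.warning("skipping rao-on-sim regression at this scale: %s", err)

    return {"n_cells": int(a1.grid.n_cells),
            "rejection_fraction": counts.attrs["rejection_fraction"],
            "counts": counts.to_dict(),
            "rao_on_sim_slope": slope,
            "dic_ranking": {k: v[["model", "DIC", "dDIC"]].to_dict("records")
                            for k, v in rankings.items()}}


def run_all(config, outdir) -> Path:
    """Run every stage per the config; returns the output directory."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a1, a2, traits, clim = _load_inputs(cfg)
    if "simulation" in cfg and cfg["simulation"] is not None:
        simulate_to_dir(cfg, outdir / "inputs")
    a1 = apply_exclusions(a1, min_land=cfg["min_land"])
    a2 = apply_exclusions(a2, min_land=cfg["min_land"])
    common = [c for c in a1.grid.cell_ids if c in set(a2.grid.cell_ids)]
    if tuple(common) != a1.grid.cell_ids or tuple(common) != a2.grid.cell_ids:
        from .atlas import _subset
        a1 = _subset(a1, np.array([a1.grid.index_of(c) for c in common]))
        a2 = _subset(a2, np.array([a2.grid.index_of(c) for c in common]))

    base_size = a1.grid.cell_size
    manifest = {"betadrift_version": __version__,
                "numpy_version": np.__version__,
                "config": cfg, "scales": {}}
    for scale in cfg["scales"]:
        if scale % base_size:
            raise ValueError(f"scale {scale} is not a multiple of the base "
                             f"cell size {base_size}")
        factor = scale // base_size
        logger.info("run_all: scale %d km (factor %d)", scale, factor)
        manifest["scales"][str(scale)] = run_scale(
            a1, a2, traits, clim, cfg, outdir / f"scale_{scale}km", factor)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
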