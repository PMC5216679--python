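"""End-to-end pipeline: simulate -> covariates -> fit -> evaluate -> forecast.

Runs every stage in order on one synthetic world and writes all
artifacts (landscape CSV, fit JSONs, trajectory CSV, evaluation CSV,
summary JSON) under an output directory. Every output carries the
config hash and seed; deterministic stages are bit-identical on rerun.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import colext as cx
from . import covariates as cov
from . import evaluation as ev
from . import forecast as fc
from . import io as pio
from . import occupancy as occ
from . import static_models as sm
from . import synthetic as syn
from .config import RunConfig

log = logging.getLogger("sporecast")

# generator truth for the demo world: strong spruce and connectivity
# effects, the climate covariates mildly negative (northern species)
TRUE_OCCURRENCE = {"intercept": -2.0, "spruce_volume": 1.0, "connectivity": 0.8,
                   "temperature": -0.4, "precipitation": -0.2}
TRUE_BIAS = {"log_population_density": 0.5, "dist_small_roads": -0.8}
TRUE_COLEXT = cx.ColextParams(delta2=cx.cloglog(0.25), eps2=cx.cloglog(0.3),
                              eps1=cx.cloglog(0.6), psi1=0.4,
                              beta={"forest_age": 0.8}, p=0.9)
N_TARGET_SPECIES = 4


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages and return the summary dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "models": list(config.models)}
    state: dict = {}
    for stage, fn in [("simulate", _stage_simulate), ("covariates", _stage_covariates),
                      ("fit", _stage_fit), ("evaluate", _stage_evaluate),
                      ("forecast", _stage_forecast)]:
        log.info("stage %s", stage)
        try:
            fn(config, state, outdir, summary)
        except Exception as exc:  # noqa: BLE001 - context for the operator
            raise StageError(stage, exc) from exc
    summary["runtime_s"] = round(time.time() - t_start, 2)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _stage_simulate(config: RunConfig, state, outdir, summary):
    rng_seed = config.seed
    land = syn.generate_landscape(config.grid.n_rows, config.grid.n_cols,
                                  config.grid.spatial_range, seed=rng_seed)
    state["landscape"] = land
    state["recorders"] = syn.make_recorders(config.n_recorders, n_thorough=4,
                                            seed=rng_seed + 1)


def _stage_covariates(config: RunConfig, state, outdir, summary):
    land = state["landscape"]
    cells = land.cells
    cells["connectivity"] = cov.connectivity(
        land, cov.ConnectivityConfig(mean_dispersal_km=config.dispersal_km))
    elev = land.grid("elevation")
    cells["wetness"] = cov.wetness_index(elev, land.cell_size_m).ravel()
    cells["northness"] = cov.northness(elev, land.cell_size_m).ravel()
    pio.write_landscape(land, outdir / "landscape.csv")

    occ_z, occ_p = syn.simulate_true_occurrence(land, TRUE_OCCURRENCE, seed=config.seed + 2)
    state["true_occ"] = occ_z
    rng = np.random.default_rng(config.seed + 3)
    targets = {}
    for s in range(1, N_TARGET_SPECIES + 1):
        coefs = dict(TRUE_OCCURRENCE)
        coefs["spruce_volume"] = float(rng.uniform(0.4, 1.2))
        coefs["intercept"] = float(rng.uniform(-2.2, -1.2))
        targets[s] = syn.simulate_true_occurrence(land, coefs, seed=config.seed + 10 + s)[0]
    obs = syn.simulate_citizen_science(land, occ_z, TRUE_BIAS, state["recorders"],
                                       effort=config.effort, seed=config.seed + 4,
                                       target_species_occupancy=targets)
    state["observations"] = obs
    pio.write_observations(obs, outdir / "observations")

    model_cols = ["spruce_volume", "connectivity", "temperature", "precipitation",
                  "deadwood_volume", "wetness", "northness",
                  "log_population_density", "dist_small_roads", "dist_main_roads",
                  "dist_cities", "dist_towns", "population_density"]
    scaled, scales = cov.standardize(cells, model_cols)
    state["covariate_table"] = scaled
    state["scale_factors"] = scales
    summary["n_presence_only"] = int(len(obs.presence_only))
    summary["n_presence_absence"] = int(len(obs.presence_absence))


def _stage_fit(config: RunConfig, state, outdir, summary):
    ct = state["covariate_table"]
    obs = state["observations"]
    land = state["landscape"]
    env_terms = [t for t in config.env_terms if t != "forest_age"]
    fits: dict = {}
    pa = obs.presence_absence
    po = obs.presence_only

    if "glm" in config.models:
        fits["glm"] = sm.fit_glm(pa, ct, env_terms)
    if "maxent" in config.models or "papo" in config.models:
        bg_random = sm.sample_background(land, obs, config.n_background, "random",
                                         seed=config.seed + 20)
    if "maxent" in config.models:
        fits["maxent"] = sm.fit_maxent_linear(po, bg_random, ct, env_terms,
                                              presence_absence=pa, seed=config.seed)
    if "maxent-tgb" in config.models:
        bg_tgb = sm.sample_background(land, obs, config.n_background, "TGB",
                                      target_group_records=po, seed=config.seed + 21)
        f = sm.fit_maxent_linear(po, bg_tgb, ct, env_terms, presence_absence=pa,
                                 seed=config.seed)
        f.model_kind = "maxent-tgb"
        fits["maxent-tgb"] = f
    if "papo" in config.models:
        fits["papo"] = sm.fit_papo(po, pa, bg_random, env_terms, config.bias_terms, ct)
    if "occupancy" in config.models:
        hist = occ.build_detection_histories(po, list(range(1, N_TARGET_SPECIES + 1)))
        mc = occ.MCMCConfig(n_chains=config.mcmc.n_chains, n_iter=config.mcmc.n_iter,
                            burn_in=config.mcmc.burn_in, thin=config.mcmc.thin,
                            seed=config.seed + 30)
        post = occ.fit_occupancy(hist, ct, obs.recorders, mc,
                                 occurrence_terms=["spruce_volume", "connectivity"])
        state["occupancy_posterior"] = post
        fits["occupancy"] = post
        summary["occupancy_rhat"] = {k: round(v, 3) for k, v in post.rhat.items()}
    if "colext" in config.models:
        surveys = syn.simulate_colext_surveys(config.n_colext_plots, TRUE_COLEXT,
                                              seed=config.seed + 40)
        fits["colext"] = cx.fit_colext(surveys, p_fixed=0.9, method="ml",
                                       candidate_covariates=["forest_age"],
                                       seed=config.seed + 41)
    state["fits"] = fits
    for name, fit in fits.items():
        if hasattr(fit, "to_dict"):
            fit.scale_factors = state["scale_factors"]
            pio.write_fit(fit, outdir / f"fit_{name}.json")


def _stage_evaluate(config: RunConfig, state, outdir, summary):
    ct = state["covariate_table"]
    pa = state["observations"].presence_absence
    if len(pa) == 0 or "glm" not in state["fits"]:
        summary["evaluation"] = "skipped (no presence-absence GLM)"
        return
    terms = state["fits"]["glm"].extra["terms"]

    def fit_fn(train):
        f = sm.fit_glm(train[["cell_id", "detected"]], ct, terms, start_terms=terms[:1])
        ft = f.extra["terms"]

        def score(df):
            from .results import design_matrix
            X = design_matrix(df, ft)
            return X.to_numpy() @ f.params.loc[X.columns].to_numpy()
        return score

    bs = max(min(config.grid.n_rows, config.grid.n_cols) // 3, 2)
    cfg = ev.BlockCVConfig(block_size_cells=bs, n_folds=4, seed=config.seed + 50)
    res = ev.block_cv_auc(fit_fn, pa, ct, cfg)
    res.to_csv(outdir / "evaluation_glm.csv", index=False)
    summary["glm_block_cv"] = {
        "train_auc": float(res.loc[res["fold"] == "mean", "train_auc"].iloc[0]),
        "test_auc": float(res.loc[res["fold"] == "mean", "test_auc"].iloc[0]),
    }


def _stage_forecast(config: RunConfig, state, outdir, summary):
    land = state["landscape"]
    proj = syn.simulate_forest_projection(land, config.set_aside_fraction,
                                          seed=config.seed + 60,
                                          n_plots=min(config.n_plots, len(land.cells)))
    scales = state["scale_factors"]
    trajectories = []
    rows = []
    for name, fit in state["fits"].items():
        if name == "colext":
            params = cx.params_from_fit(fit)
            long = proj.long.copy()
            sd_age = long["forest_age"].std()
            long["forest_age"] = long["forest_age"] / (sd_age if sd_age > 0 else 1.0)
            probs = cx.simulate_forward(params.psi1, syn.PlotProjection(proj.plots, long),
                                        params, n_reps=config.n_forward_reps,
                                        seed=config.seed + 61)
        else:
            probs = fc.predict_timesteps(fit, proj, scales)
        probs = fc.apply_mechanistic_filters(probs, proj, config.forecast_variant)
        traj = fc.summarize_by_class(probs, proj, model=name, variant=config.forecast_variant)
        trajectories.append(traj)
        for year in traj.values.index:
            for cls in fc.CLASSES:
                rows.append({"model": name, "variant": config.forecast_variant,
                             "class": cls, "step": int(year),
                             "value": float(traj.values.loc[year, cls])})
        summary.setdefault("relative_change", {})[name] = {
            k: round(v, 1) for k, v in traj.relative_change_2020_2110.items()}
    pio.write_trajectories(pd.DataFrame(rows), outdir / "trajectories.csv")

    csd = [t for t in trajectories if t.model != "colext"]
    if len(csd) >= 2:
        ens = fc.ensemble_average(csd)
        summary["ensemble"] = {cls: {"mean": round(d["mean_relative_change"], 1),
                                     "sd": round(d["sd_relative_change"], 1)}
                               for cls, d in ens["per_class"].items()}
    sens = fc.sensitivity_analysis(
        {n: f for n, f in state["fits"].items() if n != "colext"}, proj, scales)
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    state["projection"] = proj
    state["trajectories"] = trajectories
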