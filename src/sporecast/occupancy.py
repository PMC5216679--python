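"""Occupancy model with recorder-effort detectability, fitted by MCMC.

Detection histories are built from presence-only records of an
indicator-species group: any day on which a recorder submitted a
record of some indicator species from a cell counts as a visit to that
cell, and the visit is a detection iff the focal species was among the
records of that day. A calendar year is the closed period. The
hierarchical model is

    z_i ~ Bernoulli(psi_i),            logit(psi_i) = beta'x_i
    y_iv ~ Bernoulli(z_i * p_iv),      logit(p_iv) = a0 + a1 * log(days_v)

where ``days_v`` is the total number of recording days of the visit's
recorder — a proxy for experience and search effort. The latent z is
marginalized analytically, and the coefficient posterior is sampled
with an affine-invariant ensemble sampler under Normal(0, 10) priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy.special import expit

from .results import design_matrix

__all__ = [
    "MCMCConfig",
    "OccupancyPosterior",
    "build_detection_histories",
    "fit_occupancy",
    "predict_occupancy",
]


@dataclass
class MCMCConfig:
    """Sampler settings. Defaults are test-scale; ``paper_scale`` gives
    the long-run settings (2 chains, 80,000 iterations thinned by 2
    after a 20,000 burn-in)."""

    n_chains: int = 2
    n_iter: int = 8000
    burn_in: int = 2000
    thin: int = 2
    walkers_per_chain: int = 0  # 0 -> max(2*ndim+2, 10)
    prior_sd: float = 10.0
    seed: int = 0

    @classmethod
    def paper_scale(cls) -> "MCMCConfig":
        return cls(n_chains=2, n_iter=80_000, burn_in=20_000, thin=2)


@dataclass
class OccupancyPosterior:
    """Posterior draws shaped (chains, kept iterations) per parameter."""

    samples: dict[str, np.ndarray]
    rhat: dict[str, float]
    config: MCMCConfig
    occurrence_terms: list[str]
    scale_factors: pd.Series | None = None
    selection_trace: list[dict] = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        x = self.flat(name)
        return float(np.quantile(x, a)), float(np.quantile(x, 1 - a))


def build_detection_histories(presence_only_all_species: pd.DataFrame,
                              indicator_list: list[int], focal_species: int = 0) -> pd.DataFrame:
    """One visit row per (cell, year, day) with an indicator-group record.

    Records of species outside ``indicator_list`` (and not the focal
    species) are ignored; several records on one day collapse to one
    visit; ``detected`` is 1 iff the focal species was recorded that
    day. Returns columns cell_id, year, date, recorder_id, detected,
    n_visits (visits of that cell-year).
    """
    if not indicator_list:
        raise ValueError("indicator list must not be empty")
    po = presence_only_all_species
    keep = po["species_id"].isin(set(indicator_list) | {focal_species})
    po = po.loc[keep].copy()
    if len(po) == 0:
        return pd.DataFrame(columns=["cell_id", "year", "date", "recorder_id",
                                     "detected", "n_visits"])
    if "recorder_id" not in po.columns:
        po["recorder_id"] = -1
    grouped = po.groupby(["cell_id", "year", "date"]).agg(
        detected=("species_id", lambda s: int((s == focal_species).any())),
        recorder_id=("recorder_id", "first"),
    ).reset_index()
    n_visits = grouped.groupby(["cell_id", "year"])["date"].transform("size")
    grouped["n_visits"] = n_visits
    return grouped.sort_values(["cell_id", "year", "date"]).reset_index(drop=True)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an array shaped (chains, draws)."""
    m, n = chains.shape
    if n < 4:
        return np.nan
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m2, n2 = splits.shape
    means = splits.mean(axis=1)
    B = n2 * means.var(ddof=1)
    W = splits.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


def fit_occupancy(histories: pd.DataFrame, covariate_table: pd.DataFrame,
                  recorder_profiles, mcmc_config: MCMCConfig | None = None,
                  occurrence_terms: list[str] = ("spruce_volume",),
                  detection_effort: bool = True) -> OccupancyPosterior:
    """Sample the occupancy posterior given detection histories.

    The latent occupancy state is marginalized per cell-year:
    L_i = psi_i * prod_v Bern(y_v | p_v) + (1 - psi_i) * 1{all y_v = 0}.
    With ``detection_effort=False`` detection is intercept-only.
    Raises when any visiting recorder has non-positive recording days.
    """
    cfg = mcmc_config or MCMCConfig()
    occurrence_terms = list(occurrence_terms)
    hist = histories.copy()
    days_by_rec = {r.recorder_id: r.recording_days for r in recorder_profiles}
    if len(hist):
        hist["recording_days"] = hist["recorder_id"].map(days_by_rec)
        if hist["recording_days"].isna().any():
            raise ValueError("history references a recorder without a profile")
        if (hist["recording_days"] <= 0).any():
            raise ValueError("recording_days must be positive for all visits")
        if (hist.groupby(["cell_id", "year"])["date"].size() < 2).all():
            warnings.warn("no cell-year has repeat visits; detectability is unidentifiable")
        sites = hist.groupby(["cell_id", "year"])
        site_index = {key: i for i, key in enumerate(sites.groups)}
        n_sites = len(site_index)
        site_of_visit = hist.set_index(["cell_id", "year"]).index.map(site_index).to_numpy()
        y = hist["detected"].to_numpy(float)
        log_days = np.log(hist["recording_days"].to_numpy(float))
        site_cells = pd.DataFrame({"cell_id": [k[0] for k in site_index]})
        ct = covariate_table.set_index("cell_id")
        Xocc = design_matrix(ct.loc[site_cells["cell_id"]], occurrence_terms).to_numpy()
        all_zero = np.ones(n_sites)
        np.minimum.at(all_zero, site_of_visit, (y == 0).astype(float))
    else:
        n_sites = 0
        Xocc = np.zeros((0, 1 + len(occurrence_terms)))
        y = np.zeros(0)
        log_days = np.zeros(0)
        site_of_visit = np.zeros(0, dtype=int)
        all_zero = np.ones(0, dtype=bool)

    det_names = ["a0", "a1"] if detection_effort else ["a0"]
    names = ["const"] + occurrence_terms + det_names
    ndim = len(names)
    k_occ = 1 + len(occurrence_terms)

    def loglik(theta):
        if n_sites == 0:
            return 0.0
        beta = theta[:k_occ]
        a0 = theta[k_occ]
        a1 = theta[k_occ + 1] if detection_effort else 0.0
        psi = expit(Xocc @ beta)
        p = np.clip(expit(a0 + a1 * log_days), 1e-14, 1 - 1e-14)
        log_pv = np.where(y == 1, np.log(p), np.log1p(-p))
        site_logdet = np.zeros(n_sites)
        np.add.at(site_logdet, site_of_visit, log_pv)
        lik = psi * np.exp(site_logdet) + (1 - psi) * all_zero
        return float(np.sum(np.log(lik + 1e-300)))

    def logpost(theta):
        return -0.5 * np.sum((theta / cfg.prior_sd) ** 2) + loglik(theta)

    nwalk = cfg.walkers_per_chain or max(2 * ndim + 2, 10)
    rng = np.random.default_rng(cfg.seed)
    chains_out = {nm: [] for nm in names}
    for chain in range(cfg.n_chains):
        p0 = 0.5 * rng.standard_normal((nwalk, ndim))
        # emcee snapshots the global state at construction; pin it per chain
        np.random.seed((cfg.seed + 7919 * chain) % (2**31))
        sampler = emcee.EnsembleSampler(nwalk, ndim, logpost)
        state = sampler.run_mcmc(p0, max(cfg.n_iter // nwalk, 50), progress=False,
                                 skip_initial_state_check=True)
        discard = max(cfg.burn_in // nwalk, 10)
        chain_arr = sampler.get_chain(discard=discard, thin=cfg.thin)  # (steps, walkers, ndim)
        flat = chain_arr.reshape(-1, ndim)
        for j, nm in enumerate(names):
            chains_out[nm].append(flat[:, j])
    samples = {nm: np.stack(v) for nm, v in chains_out.items()}
    rhat = {nm: _split_rhat(samples[nm]) for nm in names}
    return OccupancyPosterior(samples=samples, rhat=rhat, config=cfg,
                              occurrence_terms=occurrence_terms)


def fit_occupancy_selected(histories, covariate_table, recorder_profiles,
                           candidate_terms: list[str], mcmc_config: MCMCConfig | None = None,
                           start_terms: tuple[str, ...] = ("spruce_volume",)) -> OccupancyPosterior:
    """Forward selection: keep a term iff its 95% credible interval excludes 0."""
    kept = list(start_terms)
    trace: list[dict] = []
    post = fit_occupancy(histories, covariate_table, recorder_profiles, mcmc_config, kept)
    for term in candidate_terms:
        if term in kept:
            continue
        trial = fit_occupancy(histories, covariate_table, recorder_profiles,
                              mcmc_config, kept + [term])
        lo, hi = trial.credible_interval(term)
        keep = lo > 0 or hi < 0
        trace.append({"term": term, "interval": [lo, hi], "kept": keep})
        if keep:
            kept.append(term)
            post = trial
    post.selection_trace = trace
    return post


def predict_occupancy(posterior: OccupancyPosterior, covariate_table: pd.DataFrame,
                      max_draws: int = 400, level: float = 0.95):
    """Posterior mean occurrence probability per cell, with quantile intervals.

    Covariates must already be scaled with the training scale factors.
    Returns (mean, lo, hi) arrays over the rows of ``covariate_table``.
    """
    terms = posterior.occurrence_terms
    X = design_matrix(covariate_table, terms).to_numpy()
    names = ["const"] + terms
    draws = np.column_stack([posterior.flat(nm) for nm in names])
    if len(draws) > max_draws:
        idx = np.linspace(0, len(draws) - 1, max_draws).astype(int)
        draws = draws[idx]
    probs = expit(X @ draws.T)  # (cells, draws)
    a = (1 - level) / 2
    return probs.mean(axis=1), np.quantile(probs, a, axis=1), np.quantile(probs, 1 - a, axis=1)
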