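"""Dynamic colonization-extinction occupancy model with cloglog offsets.

Plot occupancy between two surveys follows a two-state Markov chain.
For plot ``j`` the latent state is ``Z_{j,t} ~ Bernoulli(psi_{j,t})``
with, at the second survey,

    psi_{j,t} = (1 - Z_{j,t-1}) c*_{j,t} + Z_{j,t-1} (1 - e*_{j,t})

where the colonization and extinction probabilities carry an offset for
survey interval and plot area:

    c* = 1 - (1 - c)^(n a),   n = interval_years / 10,   a = area_ha / 0.2

(the reference scales being a decade between surveys and a 0.2 ha plot).
On uncut plots ``cloglog(c) = delta2 + sum_l beta_l X_l`` and
``cloglog(e) = eps2``; on clear-cut plots colonization is fixed at zero
(no colonizations were observed on cut sites) and ``cloglog(e) = eps1``.
Observation is imperfect: ``Y ~ Bernoulli(Z p)`` with detection
probability ``p`` fixed (default 0.9, from an intensive control study),
which implies no false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .results import FitResult

__all__ = [
    "cloglog",
    "inv_cloglog",
    "offset_probability",
    "ColextParams",
    "ColextPlotData",
    "transition_probability",
    "colext_loglik",
    "fit_colext",
    "simulate_forward",
]


def cloglog(p):
    """Complementary log-log link, ``log(-log(1-p))`` for p in (0,1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("cloglog requires p in the open interval (0, 1)")
    out = np.log(-np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def inv_cloglog(x):
    """Inverse cloglog, ``1 - exp(-exp(x))``."""
    x = np.asarray(x, dtype=float)
    out = -np.expm1(-np.exp(x))
    return float(out) if out.ndim == 0 else out


def offset_probability(prob, interval_years, area_ha):
    """Rescale a per-reference-unit probability to a survey's interval and area.

    ``prob*`` = 1 - (1-prob)^(n a) with n = interval_years/10 and
    a = area_ha/0.2. Equals ``prob`` exactly at 10 years and 0.2 ha.
    """
    prob = np.asarray(prob, dtype=float)
    interval_years = np.asarray(interval_years, dtype=float)
    area_ha = np.asarray(area_ha, dtype=float)
    if np.any(interval_years <= 0) or np.any(area_ha <= 0):
        raise ValueError("interval_years and area_ha must be positive")
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("prob must lie in [0, 1]")
    na = (interval_years / 10.0) * (area_ha / 0.2)
    with np.errstate(divide="ignore"):
        out = -np.expm1(na * np.log1p(-prob))
    out = np.where(prob >= 1.0, 1.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class ColextParams:
    """Parameters of the colonization-extinction model (link scale).

    ``delta2``/``eps2`` are uncut colonization/extinction intercepts on
    the cloglog scale, ``eps1`` the cut-plot extinction intercept;
    ``beta`` maps covariate names to colonization slopes (uncut plots
    only). ``delta1`` is the cut-plot colonization intercept and is
    ``None`` by default, meaning colonization probability 0 on cut
    plots. ``psi1`` is the first-survey occupancy probability (cut
    plots use ``psi1_cut`` when given). ``p`` is the fixed detection
    probability.
    """

    delta2: float
    eps2: float
    eps1: float
    psi1: float
    beta: dict[str, float] = field(default_factory=dict)
    delta1: float | None = None
    psi1_cut: float | None = None
    p: float = 0.9

    def __post_init__(self) -> None:
        for name, val in (("psi1", self.psi1), ("p", self.p)):
            if not (0 <= val <= 1):
                raise ValueError(f"{name} must be a probability, got {val}")
        if self.p <= 0:
            raise ValueError("detection probability p must be in (0, 1]")
        if self.psi1_cut is not None and not (0 <= self.psi1_cut <= 1):
            raise ValueError("psi1_cut must be a probability")

    @property
    def psi1_for_cut(self) -> float:
        return self.psi1 if self.psi1_cut is None else self.psi1_cut


@dataclass
class ColextPlotData:
    """Two-survey plot records.

    ``table`` columns: plot_id, y1, y2 (observed occupancy per survey),
    interval_years, area_ha, cut (bool), plus one column per
    colonization covariate named in ``covariate_names``. ``truth``
    optionally carries the latent (z1, z2) states from a simulation.
    """

    table: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.table):
            if (self.table["interval_years"] <= 0).any():
                raise ValueError("interval_years must be positive")
            if (self.table["area_ha"] <= 0).any():
                raise ValueError("area_ha must be positive")


def _rates(params: ColextParams, X: pd.DataFrame, cut: np.ndarray):
    """Per-plot (c, e) on the probability scale before offsets."""
    lin = np.full(len(X), params.delta2, dtype=float)
    for name, b in params.beta.items():
        if name not in X.columns:
            raise KeyError(f"colonization covariate {name!r} missing from data")
        lin = lin + b * np.asarray(X[name], dtype=float)
    c = inv_cloglog(lin)
    if params.delta1 is None:
        c_cut = 0.0
    else:
        c_cut = inv_cloglog(params.delta1)
    c = np.where(cut, c_cut, c)
    e = np.where(cut, inv_cloglog(params.eps1), inv_cloglog(params.eps2))
    return c, e


def transition_probability(z_prev, params: ColextParams, covariates, interval_years, area_ha, cut=False):
    """P(Z_t = 1 | Z_{t-1}) with offset-corrected colonization/extinction.

    ``covariates`` is a mapping or single-row table holding the
    colonization covariates; ``z_prev`` may be scalar or array.
    """
    z_prev = np.asarray(z_prev, dtype=float)
    if np.any((z_prev != 0) & (z_prev != 1)):
        raise ValueError("z_prev must be 0 or 1")
    X = pd.DataFrame(covariates) if not isinstance(covariates, pd.DataFrame) else covariates
    if len(X) == 0:
        X = pd.DataFrame(index=range(z_prev.size if z_prev.ndim else 1))
    cut_arr = np.broadcast_to(np.asarray(cut, dtype=bool), (len(X),))
    c, e = _rates(params, X, cut_arr)
    c_star = offset_probability(c, interval_years, area_ha)
    e_star = offset_probability(e, interval_years, area_ha)
    psi = (1 - z_prev) * c_star + z_prev * (1 - e_star)
    return float(psi) if psi.ndim == 0 else psi


def colext_loglik(params: ColextParams, data: ColextPlotData) -> float:
    """Marginal log-likelihood, latent (Z1, Z2) summed out exactly.

    Per plot, P(Y1, Y2) = sum over the four latent states of
    Bern(Y1|Z1 p) Bern(Y2|Z2 p) P(Z2|Z1) P(Z1). Y=1 with Z=0 has
    probability zero (no false positives).
    """
    t = data.table
    if len(t) == 0:
        return 0.0
    p = params.p
    y1 = np.asarray(t["y1"], dtype=float)
    y2 = np.asarray(t["y2"], dtype=float)
    if p == 0 and (np.any(y1 == 1) or np.any(y2 == 1)):
        raise ValueError("p = 0 is incompatible with observed detections")
    cut = np.asarray(t["cut"], dtype=bool)
    X = t[data.covariate_names] if data.covariate_names else pd.DataFrame(index=t.index)
    c, e = _rates(params, X, cut)
    c_star = offset_probability(c, t["interval_years"].to_numpy(float), t["area_ha"].to_numpy(float))
    e_star = offset_probability(e, t["interval_years"].to_numpy(float), t["area_ha"].to_numpy(float))
    psi1 = np.where(cut, params.psi1_for_cut, params.psi1)

    def obs(y, z):
        # P(Y=y | Z=z) with Y ~ Bern(z*p)
        pz = z * p
        return np.where(y == 1, pz, 1 - pz)

    lik = np.zeros(len(t))
    for z1 in (0, 1):
        pz1 = psi1 if z1 == 1 else 1 - psi1
        psi2 = (1 - z1) * c_star + z1 * (1 - e_star)
        for z2 in (0, 1):
            pz2 = psi2 if z2 == 1 else 1 - psi2
            lik += pz1 * pz2 * obs(y1, z1) * obs(y2, z2)
    if np.any(lik <= 0):
        return -np.inf
    return float(np.sum(np.log(lik)))


# ---------------------------------------------------------------------------
# fitting


def _unpack(theta: np.ndarray, cov_names: list[str], has_cut: bool, p: float) -> ColextParams:
    i = 0
    delta2 = theta[i]; i += 1
    beta = {}
    for name in cov_names:
        beta[name] = theta[i]; i += 1
    eps2 = theta[i]; i += 1
    psi1 = expit(theta[i]); i += 1
    if has_cut:
        eps1 = theta[i]; i += 1
        psi1_cut = expit(theta[i]); i += 1
    else:
        eps1, psi1_cut = 0.0, None
    return ColextParams(delta2=delta2, eps2=eps2, eps1=eps1, psi1=psi1,
                        beta=beta, psi1_cut=psi1_cut, p=p)


def _param_names(cov_names: list[str], has_cut: bool) -> list[str]:
    names = ["delta2", *[f"beta_{c}" for c in cov_names], "eps2", "logit_psi1"]
    if has_cut:
        names += ["eps1", "logit_psi1_cut"]
    return names


def _neg_loglik_builder(data: ColextPlotData, cov_names: list[str], has_cut: bool, p: float):
    d = replace(data, covariate_names=cov_names)

    def nll(theta):
        try:
            params = _unpack(theta, cov_names, has_cut, p)
        except ValueError:
            return np.inf
        ll = colext_loglik(params, d)
        return np.inf if not np.isfinite(ll) else -ll

    return nll


def _fit_once(data: ColextPlotData, cov_names: list[str], p: float,
              method: str, seed: int, mcmc_steps: int, mcmc_burn: int):
    """Fit with a fixed covariate set; returns (est, lo, hi, names, loglik)."""
    has_cut = bool(np.asarray(data.table["cut"], dtype=bool).any())
    names = _param_names(cov_names, has_cut)
    ndim = len(names)
    nll = _neg_loglik_builder(data, cov_names, has_cut, p)
    x0 = np.zeros(ndim)
    x0[names.index("delta2")] = -1.0
    x0[names.index("eps2")] = -1.0
    if has_cut:
        x0[names.index("eps1")] = -1.0
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    res = minimize(nll, res.x, method="BFGS", options={"maxiter": 500})
    mle = res.x
    if method == "ml":
        # Wald intervals from the numerical Hessian
        cov = _hessian_cov(nll, mle)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        lo, hi = mle - 1.959964 * se, mle + 1.959964 * se
        return mle, lo, hi, names, -nll(mle), None
    # MCMC with Normal(0, 10) priors on all unconstrained parameters
    import emcee

    def logpost(theta):
        lp = -0.5 * np.sum((theta / 10.0) ** 2)
        ll = -nll(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    nwalkers = max(2 * ndim, 12)
    rng = np.random.default_rng(seed)
    p0 = mle + 0.05 * rng.standard_normal((nwalkers, ndim))
    np.random.seed(seed % (2**31))  # emcee snapshots the global state
    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
    sampler.run_mcmc(p0, mcmc_steps, progress=False)
    chain = sampler.get_chain(discard=mcmc_burn, flat=True)
    est = chain.mean(axis=0)
    lo = np.quantile(chain, 0.025, axis=0)
    hi = np.quantile(chain, 0.975, axis=0)
    return est, lo, hi, names, -nll(est), chain


def _hessian_cov(nll, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = nll(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = nll(x + ei + ej)
            fpm = nll(x + ei - ej)
            fmp = nll(x - ei + ej)
            fmm = nll(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_colext(data: ColextPlotData, p_fixed: float = 0.9, method: str = "mcmc",
               candidate_covariates: list[str] | None = None, seed: int = 0,
               mcmc_steps: int = 700, mcmc_burn: int = 250) -> FitResult:
    """Fit the colonization-extinction model with detection fixed at ``p_fixed``.

    Cut and uncut plots share the latent machinery but have separate
    intercepts; cut-plot colonization is fixed at zero. ``method`` is
    ``"mcmc"`` (ensemble sampler, Normal(0,10) priors, quantile
    intervals) or ``"ml"`` (maximum marginal likelihood with Wald
    intervals). Candidate colonization covariates enter by forward
    stepwise selection: a covariate is retained iff its 95% interval
    excludes zero.
    """
    t = data.table
    noncut = t[~t["cut"].astype(bool)]
    if len(noncut) == 0:
        raise ValueError("no uncut plots: uncut parameters are inestimable")
    if noncut["y1"].nunique() < 2 and noncut["y2"].nunique() < 2:
        warnings.warn("uncut plots show no variation in observed occupancy")
    candidates = list(candidate_covariates or [])

    kept: list[str] = []
    trace: list[dict] = []
    while True:
        best = None
        for cand in candidates:
            if cand in kept:
                continue
            est, lo, hi, names, ll, _ = _fit_once(
                data, kept + [cand], p_fixed, method, seed, mcmc_steps, mcmc_burn)
            k = names.index(f"beta_{cand}")
            significant = lo[k] > 0 or hi[k] < 0
            trace.append({"term": cand, "interval": [float(lo[k]), float(hi[k])],
                          "kept": bool(significant)})
            if significant and best is None:
                best = cand
        if best is None:
            break
        kept.append(best)

    est, lo, hi, names, ll, chain = _fit_once(
        data, kept, p_fixed, method, seed, mcmc_steps, mcmc_burn)
    params = pd.Series(est, index=names)
    ci = pd.DataFrame({"lo": lo, "hi": hi}, index=names)
    extra = {"loglik": float(ll), "p_fixed": float(p_fixed), "kept_covariates": kept,
             "method": method}
    fit = FitResult(model_kind="colext", params=params, conf_int=ci, link="cloglog",
                    selection_trace=trace, extra=extra)
    if chain is not None:
        fit.extra["n_mcmc_draws"] = int(chain.shape[0])
        fit._chain = chain  # full draws kept in memory, not serialized
    return fit


def params_from_fit(fit: FitResult, p: float | None = None) -> ColextParams:
    """Turn a ``fit_colext`` result back into :class:`ColextParams`."""
    s = fit.params
    beta = {n[len("beta_"):]: float(v) for n, v in s.items() if n.startswith("beta_")}
    has_cut = "eps1" in s.index
    return ColextParams(
        delta2=float(s["delta2"]), eps2=float(s["eps2"]),
        eps1=float(s["eps1"]) if has_cut else 0.0,
        psi1=float(expit(s["logit_psi1"])), beta=beta,
        psi1_cut=float(expit(s["logit_psi1_cut"])) if has_cut else None,
        p=float(fit.extra.get("p_fixed", 0.9)) if p is None else p,
    )


# ---------------------------------------------------------------------------
# forward simulation


def simulate_forward(initial_probs, plot_projections, params: ColextParams,
                     n_reps: int = 1000, seed: int = 0,
                     interval_years: float = 5.0) -> pd.DataFrame:
    """Monte-Carlo occupancy trajectories over projected plot covariates.

    ``plot_projections`` is a :class:`~sporecast.synthetic.PlotProjection`
    (or its long table) with one row per plot and step carrying the
    colonization covariates, an ``area_ha`` column (reference 0.2 ha if
    absent) and optionally a boolean ``cut`` column marking steps in
    which the plot was clear-cut. Z at the first step is Bernoulli with
    ``initial_probs``; each subsequent step applies the transition
    probability with the step interval (5 years -> n = 0.5) and the
    plot's area. Returns a plot x step table of mean occupancy over
    ``n_reps`` replicates.
    """
    long = getattr(plot_projections, "long", plot_projections)
    steps = np.sort(long["year"].unique())
    if len(steps) < 2:
        raise ValueError("projections must cover at least two steps")
    if np.any(np.diff(steps) != np.diff(steps)[0]):
        raise ValueError("projection steps must be evenly spaced (missing step?)")
    plots = np.sort(long["plot_id"].unique())
    n_plots = len(plots)
    initial_probs = np.broadcast_to(np.asarray(initial_probs, dtype=float), (n_plots,))
    if np.any((initial_probs < 0) | (initial_probs > 1)):
        raise ValueError("initial probabilities must lie in [0, 1]")

    wide = long.set_index(["plot_id", "year"]).sort_index()
    rng = np.random.default_rng(seed)
    z = rng.random((n_reps, n_plots)) < initial_probs
    traj = np.empty((n_plots, len(steps)))
    traj[:, 0] = z.mean(axis=0)
    for k, year in enumerate(steps[1:], start=1):
        rows = wide.xs(year, level="year").loc[plots]
        area = rows["area_ha"].to_numpy(float) if "area_ha" in rows else np.full(n_plots, 0.2)
        cut = rows["cut"].to_numpy(bool) if "cut" in rows else np.zeros(n_plots, bool)
        X = rows[[c for c in params.beta if c in rows.columns]]
        for name in params.beta:
            if name not in rows.columns:
                raise KeyError(f"projection lacks colonization covariate {name!r}")
        c, e = _rates(params, X, cut)
        c_star = offset_probability(c, interval_years, area)
        e_star = offset_probability(e, interval_years, area)
        psi = np.where(z, 1 - e_star, c_star)
        z = rng.random((n_reps, n_plots)) < psi
        traj[:, k] = z.mean(axis=0)
    return pd.DataFrame(traj, index=pd.Index(plots, name="plot_id"),
                        columns=pd.Index(steps, name="year"))
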