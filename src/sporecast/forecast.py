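"""Space-time-substitution forecasting under forest-management scenarios.

Each fitted occurrence model predicts the probability (or, for MaxEnt,
the relative suitability) of occurrence at every projected plot and
time step. Mechanistic filters then impose what the correlative models
cannot learn: the species is a deadwood decomposer, so it cannot occur
where no deadwood is present, nor in stands aged 25-64 years where the
post-harvest deadwood pulse has decayed and old-stand mortality has
not yet begun. Plot predictions are averaged with area weights over
all land and within the production / set-aside classes, converted to
relative change from the first to the last step, and ensembled across
models. Because relative change is scale-free, MaxEnt suitabilities
pool with probabilities only at that stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .results import FitResult, design_matrix

__all__ = [
    "ForecastTrajectory",
    "predict_timesteps",
    "apply_mechanistic_filters",
    "summarize_by_class",
    "relative_change",
    "ensemble_average",
    "sensitivity_analysis",
]

VARIANTS = ("none", "age", "deadwood", "both")
CLASSES = ("total", "production", "set_aside")


@dataclass
class ForecastTrajectory:
    """Weighted mean occurrence per step for total/production/set-aside."""

    values: pd.DataFrame  # index: year; columns: total, production, set_aside
    model: str = ""
    variant: str = "none"
    relative_change_2020_2110: dict[str, float] = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()


def predict_timesteps(fit, plot_projections, scale_factors: pd.Series | None = None,
                      cell_area: float = 1.0) -> pd.DataFrame:
    """Per-plot, per-step occurrence probability (or MaxEnt suitability).

    ``fit`` may be a :class:`FitResult` (glm, maxent, papo) or an
    occupancy posterior. Projection covariates are divided by the
    training scale factors before prediction; a missing model term
    raises a ``KeyError`` naming it.
    """
    long = getattr(plot_projections, "long", plot_projections)
    years = np.sort(long["year"].unique())
    plots = np.sort(long["plot_id"].unique())
    out = pd.DataFrame(index=pd.Index(plots, name="plot_id"),
                       columns=pd.Index(years, name="year"), dtype=float)
    sf = scale_factors
    if sf is None and isinstance(fit, FitResult):
        sf = fit.scale_factors
    for year in years:
        rows = long.loc[long["year"] == year].set_index("plot_id").loc[plots]
        table = rows.copy()
        if sf is not None:
            for col, s in sf.items():
                if col in table.columns:
                    table[col] = table[col] / s
        out[year] = _predict_one(fit, table, cell_area)
    return out


def _predict_one(fit, table: pd.DataFrame, cell_area: float) -> np.ndarray:
    from scipy.special import expit

    if hasattr(fit, "samples"):  # occupancy posterior
        from .occupancy import predict_occupancy
        mean, _, _ = predict_occupancy(fit, table)
        return mean
    if fit.model_kind == "glm":
        terms = fit.extra["terms"]
        X = design_matrix(table, terms)
        return expit(X.to_numpy() @ fit.params.loc[X.columns].to_numpy())
    if fit.model_kind in ("maxent", "maxent-tgb"):
        from .static_models import maxent_suitability
        return np.clip(maxent_suitability(fit, table, normalized=True), 0.0, 1.0)
    if fit.model_kind == "papo":
        from .static_models import papo_predict_occurrence
        return papo_predict_occurrence(fit, table, cell_area=cell_area)
    raise ValueError(f"cannot predict for model kind {fit.model_kind!r}")


def apply_mechanistic_filters(probs: pd.DataFrame, plot_projections,
                              variant: str = "both",
                              age_window: tuple[float, float] = (25.0, 64.0)) -> pd.DataFrame:
    """Zero out predictions where the species mechanistically cannot occur.

    ``deadwood``: probability 0 where deadwood volume is 0; ``age``:
    probability 0 where forest age is within the (inclusive) 25-64
    window; ``both`` composes the two; ``none`` is the identity.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "none":
        return probs.copy()
    long = getattr(plot_projections, "long", plot_projections)
    out = probs.copy()
    wide_age = long.pivot(index="plot_id", columns="year", values="forest_age")
    wide_dw = long.pivot(index="plot_id", columns="year", values="deadwood_volume")
    wide_age = wide_age.loc[probs.index, probs.columns]
    wide_dw = wide_dw.loc[probs.index, probs.columns]
    if variant in ("age", "both"):
        in_window = (wide_age >= age_window[0]) & (wide_age <= age_window[1])
        out = out.where(~in_window, 0.0)
    if variant in ("deadwood", "both"):
        out = out.where(wide_dw > 0, 0.0)
    return out


def summarize_by_class(probs: pd.DataFrame, plot_projections, model: str = "",
                       variant: str = "none") -> ForecastTrajectory:
    """Area-weighted mean trajectories for all land and per management class."""
    plots = getattr(plot_projections, "plots", plot_projections)
    meta = plots.set_index("plot_id").loc[probs.index]
    w = meta["area_weight"].to_numpy(float)
    w = w / w.sum()
    vals = {}
    P = probs.to_numpy(float)
    vals["total"] = w @ P
    for cls in ("production", "set_aside"):
        mask = (meta["management"] == cls).to_numpy()
        if mask.sum() == 0:
            vals[cls] = np.full(P.shape[1], np.nan)
        else:
            wc = w[mask] / w[mask].sum()
            vals[cls] = wc @ P[mask]
    values = pd.DataFrame(vals, index=probs.columns)
    traj = ForecastTrajectory(values=values, model=model, variant=variant)
    t0, t1 = int(values.index.min()), int(values.index.max())
    for cls in CLASSES:
        v0 = values.loc[t0, cls]
        if np.isfinite(v0) and v0 > 0:
            traj.relative_change_2020_2110[cls] = relative_change(traj, t0, t1, cls)
    return traj


def relative_change(trajectory: ForecastTrajectory, t0: int = 2020, t1: int = 2110,
                    cls: str = "total") -> float:
    """Percent change 100 * (v(t1) - v(t0)) / v(t0) of a class trajectory."""
    vals = trajectory.values
    for t in (t0, t1):
        if t not in vals.index:
            raise KeyError(f"step {t} not in trajectory")
    v0, v1 = float(vals.loc[t0, cls]), float(vals.loc[t1, cls])
    if v0 == 0:
        raise ValueError(f"relative change undefined: value at {t0} is zero ({cls})")
    return 100.0 * (v1 - v0) / v0


def ensemble_average(trajectories: list[ForecastTrajectory],
                     t0: int = 2020, t1: int = 2110) -> dict:
    """Mean and sample SD across models of the relative-change series.

    Requires at least two trajectories on identical steps. Returns per
    class the endpoint mean and SD plus per-step mean/SD series of the
    relative change from ``t0``.
    """
    if len(trajectories) < 2:
        raise ValueError("ensemble needs at least two trajectories")
    years = trajectories[0].years
    for tr in trajectories[1:]:
        if not np.array_equal(tr.years, years):
            raise ValueError("trajectories are on mismatched steps")
    out: dict = {"models": [tr.model for tr in trajectories], "per_class": {}}
    for cls in CLASSES:
        series = []
        for tr in trajectories:
            v0 = float(tr.values.loc[t0, cls])
            if not np.isfinite(v0) or v0 == 0:
                continue
            series.append(100.0 * (tr.values[cls] - v0) / v0)
        if len(series) < 2:
            continue
        M = pd.concat(series, axis=1)
        out["per_class"][cls] = {
            "mean_relative_change": float(M.loc[t1].mean()),
            "sd_relative_change": float(M.loc[t1].std(ddof=1)),
            "mean_series": M.mean(axis=1).to_dict(),
            "sd_series": M.std(axis=1, ddof=1).to_dict(),
        }
    return out


def sensitivity_analysis(fits: dict[str, object], plot_projections,
                         scale_factors: pd.Series | None = None) -> pd.DataFrame:
    """Full factorial of the four mechanistic-assumption variants.

    One row per (model, variant) with the weighted mean probability at
    the first and last steps and the relative change, per class.
    """
    rows = []
    for model, fit in fits.items():
        base = predict_timesteps(fit, plot_projections, scale_factors)
        for variant in VARIANTS:
            probs = apply_mechanistic_filters(base, plot_projections, variant)
            traj = summarize_by_class(probs, plot_projections, model=model, variant=variant)
            t0, t1 = int(traj.values.index.min()), int(traj.values.index.max())
            row = {"model": model, "variant": variant}
            for cls in CLASSES:
                row[f"{cls}_start"] = float(traj.values.loc[t0, cls])
                row[f"{cls}_end"] = float(traj.values.loc[t1, cls])
                row[f"{cls}_relative_change"] = traj.relative_change_2020_2110.get(cls, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
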