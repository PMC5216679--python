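"""Synthetic landscapes, observation processes, surveys, and projections.

Emulates the statistical structure of the data the downstream analyses
assume: a 100 m gridded boreal landscape with spatially autocorrelated
forest, climate and terrain covariates plus recording-bias fields;
presence-only citizen-science records produced by a biased visit
process with recorder-specific detectability; a presence-absence
subset contributed by "thorough" recorders; two-survey plot data with
colonization and extinction events; and per-plot forest projections
every 5 years from 2020 to 2110 split into production and set-aside
land.

Spatial fields are white noise smoothed with a Gaussian kernel of
scale ``spatial_range`` (cells) and then transformed marginally to
each covariate's support — a cheap, fully reproducible stand-in for
real geodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .colext import ColextParams, ColextPlotData, inv_cloglog, offset_probability
from .covariates import ConnectivityConfig, connectivity

__all__ = [
    "Landscape",
    "RecorderProfile",
    "ObservationSet",
    "PlotProjection",
    "generate_landscape",
    "simulate_true_occurrence",
    "make_recorders",
    "simulate_citizen_science",
    "simulate_forest_projection",
    "simulate_colext_surveys",
]

BIAS_COLUMNS = ["population_density", "log_population_density", "dist_small_roads",
                "dist_main_roads", "dist_cities", "dist_towns"]
ENV_COLUMNS = ["spruce_volume", "forest_age", "deadwood_volume", "temperature",
               "precipitation", "elevation"]


@dataclass
class Landscape:
    """A rectangular grid of cells with one row per cell in ``cells``."""

    cells: pd.DataFrame
    n_rows: int
    n_cols: int
    cell_size_m: float = 100.0

    def grid(self, column: str) -> np.ndarray:
        """Reshape a per-cell column to the (n_rows, n_cols) grid."""
        return np.asarray(self.cells[column], dtype=float).reshape(self.n_rows, self.n_cols)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class RecorderProfile:
    recorder_id: int
    is_thorough: bool
    recording_days: int
    skill_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.recording_days < 1:
            raise ValueError("recording_days must be >= 1")


@dataclass
class ObservationSet:
    """Citizen-science records derived from the simulated visit process.

    ``presence_only``: (cell_id, species_id, date, year) detections of
    any target-group species; ``presence_absence``: per-visit focal
    detections by thorough recorders only; ``visits``: every visit with
    its focal detection outcome.
    """

    presence_only: pd.DataFrame
    presence_absence: pd.DataFrame
    visits: pd.DataFrame
    recorders: list[RecorderProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.presence_only)


# ---------------------------------------------------------------------------
# landscape


def _gp_field(shape, spatial_range, rng) -> np.ndarray:
    """Unit-variance Gaussian field: smoothed white noise, wrap-free."""
    z = rng.standard_normal(shape)
    if spatial_range > 0:
        z = gaussian_filter(z, sigma=spatial_range, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def generate_landscape(n_rows: int, n_cols: int, spatial_range: float = 5.0,
                       seed: int = 0, cell_size_m: float = 100.0) -> Landscape:
    """Generate a landscape of autocorrelated covariate fields.

    Each covariate is a Gaussian-process-like field (white noise
    smoothed at scale ``spatial_range`` cells) pushed through a
    marginal transform onto its valid support: volumes and ages via
    gamma quantiles, densities and distances via log-normal shapes,
    climate via affine maps with a north-south gradient. Deterministic
    given the seed.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spatial_range < 0:
        raise ValueError("spatial_range must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)

    def f():
        return _gp_field(shape, spatial_range, rng).ravel()

    def to_uniform(z):
        return np.clip(norm.cdf(z), 1e-9, 1 - 1e-9)

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    lat = rows / max(n_rows - 1, 1)  # 0 at north edge, 1 at south

    z_age = f()
    forest_age = gamma_dist.ppf(to_uniform(z_age), a=1.8, scale=45.0)
    # spruce volume grows with stand age plus its own field
    z_spruce = 0.6 * z_age + 0.8 * f()
    spruce_volume = gamma_dist.ppf(to_uniform(z_spruce / np.std(z_spruce)), a=2.0, scale=90.0)
    # deadwood: harvest residue in young stands, accumulation in old ones,
    # absent in mid-aged stands (deadwood turnover after cutting)
    z_dw = 0.5 * z_age + 0.9 * f()
    dw_base = np.where(forest_age < 25, 8.0 * (1 - forest_age / 25.0),
                       np.where(forest_age > 64, 0.15 * (forest_age - 64), 0.0))
    deadwood_volume = dw_base * np.exp(0.5 * z_dw / np.std(z_dw))

    temperature = 6.0 - 4.0 * (1 - lat) + 1.2 * f()  # colder northwards
    precipitation = 450.0 + 120.0 * f() + 60.0 * (1 - lat)
    elevation = 250.0 + 180.0 * f() + 120.0 * (1 - lat)

    population_density = np.exp(2.0 + 1.5 * f())
    dist_small_roads = np.exp(5.5 + 0.8 * f())
    dist_main_roads = np.exp(7.0 + 0.9 * f())
    dist_cities = np.exp(10.0 + 0.6 * f())
    dist_towns = np.exp(8.5 + 0.7 * f())

    cells = pd.DataFrame({
        "cell_id": np.arange(n_rows * n_cols),
        "row": rows,
        "col": cols,
        "spruce_volume": spruce_volume,
        "forest_age": forest_age,
        "deadwood_volume": deadwood_volume,
        "temperature": temperature,
        "precipitation": precipitation,
        "elevation": elevation,
        "population_density": population_density,
        "log_population_density": np.log(population_density),
        "dist_small_roads": dist_small_roads,
        "dist_main_roads": dist_main_roads,
        "dist_cities": dist_cities,
        "dist_towns": dist_towns,
    })
    return Landscape(cells=cells, n_rows=n_rows, n_cols=n_cols, cell_size_m=cell_size_m)


def simulate_true_occurrence(landscape: Landscape, coefficients: dict[str, float],
                             seed: int = 0, standardize: bool = True):
    """Draw the true occupancy state every model tries to recover.

    ``coefficients`` maps covariate names (plus ``"intercept"``) to
    logit-scale slopes; covariates are divided by their SD first when
    ``standardize`` (matching how models are fitted). Returns
    ``(occupancy, probability)`` arrays over cells.
    """
    rng = np.random.default_rng(seed)
    cells = landscape.cells
    lin = np.full(len(cells), float(coefficients.get("intercept", 0.0)))
    for name, b in coefficients.items():
        if name == "intercept":
            continue
        if name not in cells.columns:
            raise KeyError(f"unknown covariate {name!r} in occurrence coefficients")
        x = np.asarray(cells[name], dtype=float)
        if standardize:
            sd = x.std()
            x = x / sd if sd > 0 else x
        lin = lin + b * x
    prob = expit(lin)
    occ = (rng.random(len(cells)) < prob).astype(int)
    return occ, prob


# ---------------------------------------------------------------------------
# citizen-science observation process


def make_recorders(n: int, n_thorough: int = 2, seed: int = 0,
                   skill_intercept: float = 0.0) -> list[RecorderProfile]:
    """Recorder pool with log-normal activity (recording days >= 1)."""
    rng = np.random.default_rng(seed)
    days = np.maximum(1, np.round(np.exp(rng.normal(3.0, 1.0, size=n)))).astype(int)
    return [RecorderProfile(recorder_id=i, is_thorough=i < n_thorough,
                            recording_days=int(days[i]), skill_intercept=skill_intercept)
            for i in range(n)]


def simulate_citizen_science(landscape: Landscape, occupancy, bias_coefficients: dict[str, float],
                             recorders: list[RecorderProfile], effort: float, seed: int = 0,
                             detect_slope: float = 0.35,
                             target_species_occupancy: dict[int, np.ndarray] | None = None,
                             years: tuple[int, int] = (2000, 2013),
                             perfect_detection: bool = False) -> ObservationSet:
    """Simulate the biased visit process and resulting record sets.

    Visit intensity per cell is proportional to exp(bias linear
    predictor) over the standardized bias covariates; visit counts are
    Poisson with mean ``effort`` times the (mean-1 normalized)
    intensity. Each visit is made by a random recorder in a random
    year/day; an occupying species is detected with probability
    inverse-logit(skill + ``detect_slope`` * log recording_days), or
    always under ``perfect_detection``. Presence-only records keep
    detections of the focal species (id 0) and of every target-group
    species in ``target_species_occupancy``; presence-absence records
    come from thorough recorders only.
    """
    if effort < 0:
        raise ValueError("effort must be >= 0")
    if not recorders:
        raise ValueError("need at least one recorder")
    rng = np.random.default_rng(seed)
    cells = landscape.cells
    occupancy = np.asarray(occupancy)

    lin = np.zeros(len(cells))
    for name, b in bias_coefficients.items():
        if name not in cells.columns:
            raise KeyError(f"unknown bias covariate {name!r}")
        x = np.asarray(cells[name], dtype=float)
        sd = x.std()
        lin = lin + b * (x / sd if sd > 0 else x)
    intensity = np.exp(lin - lin.max())
    total = intensity.sum()
    empty = ObservationSet(
        presence_only=pd.DataFrame(columns=["cell_id", "species_id", "date", "year",
                                            "recorder_id"]),
        presence_absence=pd.DataFrame(columns=["cell_id", "recorder_id", "detected", "year"]),
        visits=pd.DataFrame(columns=["cell_id", "date", "recorder_id", "detected", "year"]),
        recorders=recorders)
    if effort == 0 or total == 0:
        return empty
    n_visits = rng.poisson(effort * intensity / intensity.mean())
    visited = np.repeat(np.arange(len(cells)), n_visits)
    if len(visited) == 0:
        return empty

    rec_ids = np.array([r.recorder_id for r in recorders])
    rec_days = np.array([r.recording_days for r in recorders], dtype=float)
    rec_skill = np.array([r.skill_intercept for r in recorders], dtype=float)
    rec_thorough = np.array([r.is_thorough for r in recorders])
    which = rng.integers(0, len(recorders), size=len(visited))
    year = rng.integers(years[0], years[1] + 1, size=len(visited))
    day = rng.integers(1, 366, size=len(visited))
    date = year * 1000 + day  # ordinal yyyyddd keeps days distinct and sortable
    p_det = np.ones(len(visited)) if perfect_detection else expit(
        rec_skill[which] + detect_slope * np.log(rec_days[which]))

    focal_present = occupancy[visited] == 1
    focal_detected = focal_present & (rng.random(len(visited)) < p_det)

    visits = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy()[visited],
        "date": date, "year": year,
        "recorder_id": rec_ids[which],
        "detected": focal_detected.astype(int),
    })

    keep_cols = ["cell_id", "date", "year", "recorder_id"]
    po_parts = [visits.loc[focal_detected, keep_cols].assign(species_id=0)]
    for sp_id, occ_sp in (target_species_occupancy or {}).items():
        occ_sp = np.asarray(occ_sp)
        det = (occ_sp[visited] == 1) & (rng.random(len(visited)) < p_det)
        po_parts.append(visits.loc[det, keep_cols].assign(species_id=sp_id))
    presence_only = pd.concat(po_parts, ignore_index=True)[
        ["cell_id", "species_id", "date", "year", "recorder_id"]]

    thorough_mask = rec_thorough[which]
    presence_absence = visits.loc[thorough_mask, ["cell_id", "recorder_id", "detected", "year"]]
    presence_absence = presence_absence.reset_index(drop=True)
    return ObservationSet(presence_only=presence_only, presence_absence=presence_absence,
                          visits=visits, recorders=recorders)


def simulate_detection_histories(covariate_table: pd.DataFrame, beta: dict[str, float],
                                 recorders: list[RecorderProfile], a0: float, a1: float,
                                 repeat_fraction: float = 0.25, seed: int = 0,
                                 year: int = 2010, max_repeat_visits: int = 3):
    """Generative twin of the occupancy model: histories drawn from it exactly.

    Every cell of ``covariate_table`` becomes a surveyed site;
    z ~ Bernoulli(inverse-logit(beta'x)); a ``repeat_fraction`` of sites
    get 2..``max_repeat_visits`` visits, the rest one; each visit's
    recorder is drawn uniformly and detects with probability
    inverse-logit(a0 + a1 * log recording_days) when the site is
    occupied. Returns (histories, z).
    """
    rng = np.random.default_rng(seed)
    n = len(covariate_table)
    lin = np.full(n, float(beta.get("intercept", 0.0)))
    for name, b in beta.items():
        if name == "intercept":
            continue
        lin = lin + b * np.asarray(covariate_table[name], dtype=float)
    z = (rng.random(n) < expit(lin)).astype(int)
    n_visits = np.where(rng.random(n) < repeat_fraction,
                        rng.integers(2, max_repeat_visits + 1, size=n), 1)
    site = np.repeat(np.arange(n), n_visits)
    days = np.array([r.recording_days for r in recorders], dtype=float)
    rec_ids = np.array([r.recorder_id for r in recorders])
    which = rng.integers(0, len(recorders), size=len(site))
    p = expit(a0 + a1 * np.log(days[which]))
    y = (z[site] == 1) & (rng.random(len(site)) < p)
    hist = pd.DataFrame({
        "cell_id": covariate_table["cell_id"].to_numpy()[site],
        "year": year,
        "date": year * 1000 + np.concatenate([np.arange(k) for k in n_visits]) + 1,
        "recorder_id": rec_ids[which],
        "detected": y.astype(int),
    })
    hist["n_visits"] = hist.groupby(["cell_id", "year"])["date"].transform("size")
    return hist, z


# ---------------------------------------------------------------------------
# forest projections


@dataclass
class PlotProjection:
    """Per-plot covariate trajectories on 5-year steps, with area weights.

    ``plots``: plot_id, management ("production"/"set_aside"),
    area_weight (normalized to sum 1), x, y, area_ha. ``long``: one row
    per plot and year with spruce_volume, forest_age, deadwood_volume,
    connectivity, temperature, precipitation, area_ha and a ``cut``
    flag marking a clear-cut in the preceding step.
    """

    plots: pd.DataFrame
    long: pd.DataFrame

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.long["year"].unique())


def simulate_forest_projection(landscape: Landscape | int, set_aside_fraction: float = 0.16,
                               horizon: tuple[int, int] = (2020, 2110), step: int = 5,
                               harvest_rule: dict | None = None, seed: int = 0,
                               n_plots: int | None = None,
                               connectivity_config: ConnectivityConfig | None = None) -> PlotProjection:
    """Project plot-level forest state under a production/set-aside split.

    Plots are sampled from the landscape (or placed at random when an
    integer plot count is given). Set-aside plots age by ``step`` years
    per step and accumulate deadwood; production plots are clear-cut
    under ``harvest_rule`` (default: probability 0.25 per step once age
    >= 80), which resets age, drops spruce volume and leaves a decaying
    deadwood pulse. Deadwood is absent at ages 25-64 (turnover of the
    post-harvest pulse before old-stand mortality sets in), so the
    age-window mechanistic filter has a coherent generative twin.
    Area weights represent each plot's share of total land and are
    constant over time.
    """
    if not (0 <= set_aside_fraction <= 1):
        raise ValueError("set_aside_fraction must be in [0, 1]")
    if step <= 0:
        raise ValueError("step must be positive")
    rule = {"min_age": 80.0, "prob": 0.25, "spruce_after": 5.0, "deadwood_pulse": 8.0}
    rule.update(harvest_rule or {})
    rng = np.random.default_rng(seed)

    if isinstance(landscape, Landscape):
        cells = landscape.cells
        n = n_plots or min(len(cells), 600)
        idx = rng.choice(len(cells), size=n, replace=False)
        sub = cells.iloc[idx]
        x = sub["col"].to_numpy(float) * landscape.cell_size_m
        y = sub["row"].to_numpy(float) * landscape.cell_size_m
        age0 = sub["forest_age"].to_numpy(float)
        spruce0 = sub["spruce_volume"].to_numpy(float)
        temp = sub["temperature"].to_numpy(float)
        precip = sub["precipitation"].to_numpy(float)
    else:
        n = int(landscape)
        extent = 30_000.0
        x = rng.uniform(0, extent, n)
        y = rng.uniform(0, extent, n)
        age0 = rng.gamma(1.8, 45.0, n)
        spruce0 = rng.gamma(2.0, 90.0, n)
        temp = rng.normal(3.0, 1.5, n)
        precip = rng.normal(480.0, 110.0, n)

    # greedy assignment of set-aside status until the weight share is met
    raw_w = rng.uniform(0.5, 1.5, n)
    weights = raw_w / raw_w.sum()
    order = rng.permutation(n)
    management = np.full(n, "production", dtype=object)
    cum = 0.0
    for i in order:
        if cum >= set_aside_fraction:
            break
        management[i] = "set_aside"
        cum += weights[i]

    years = np.arange(horizon[0], horizon[1] + 1, step)
    dw_factor = np.exp(0.4 * rng.standard_normal(n))
    area_ha = np.full(n, 0.2)

    age = age0.copy()
    spruce = spruce0.copy()
    records = []
    cut_now = np.zeros(n, dtype=bool)
    for k, year in enumerate(years):
        if k > 0:
            age = age + step
            eligible = (management == "production") & (age >= rule["min_age"])
            cut_now = eligible & (rng.random(n) < rule["prob"])
            age[cut_now] = 0.0
            spruce[cut_now] = rule["spruce_after"]
        grow = (age > 0) & ~cut_now
        spruce[grow] = np.minimum(spruce[grow] * (1 + 0.18 * step / 5) + 2.0, 450.0)
        deadwood = _deadwood_from_age(age, rule["deadwood_pulse"]) * dw_factor
        records.append(pd.DataFrame({
            "plot_id": np.arange(n), "year": year,
            "spruce_volume": spruce.copy(), "forest_age": age.copy(),
            "deadwood_volume": deadwood, "temperature": temp,
            "precipitation": precip, "area_ha": area_ha,
            "cut": cut_now.copy(),
        }))

    plots = pd.DataFrame({"plot_id": np.arange(n), "management": management,
                          "area_weight": weights, "x": x, "y": y, "area_ha": area_ha})
    long = pd.concat(records, ignore_index=True)

    # per-step connectivity over plot coordinates, weighted by area share
    cfg = connectivity_config or ConnectivityConfig(mean_dispersal_km=1.0,
                                                    old_forest_age_threshold=100.0,
                                                    source_weight="spruce_volume")
    conn = np.empty(len(long))
    for year in years:
        mask = long["year"] == year
        snap = long.loc[mask, ["plot_id", "spruce_volume", "forest_age"]].merge(
            plots[["plot_id", "x", "y"]], on="plot_id")
        conn[mask.to_numpy()] = connectivity(snap, cfg)
    long["connectivity"] = conn
    return PlotProjection(plots=plots, long=long)


def _deadwood_from_age(age: np.ndarray, pulse: float) -> np.ndarray:
    """Deadwood volume as a function of stand age: post-cut pulse, gap, accumulation."""
    return np.where(age < 25, pulse * (1 - age / 25.0),
                    np.where(age > 64, 0.15 * (age - 64), 0.0))


# ---------------------------------------------------------------------------
# colonization-extinction surveys


def simulate_colext_surveys(n_plots: int, params: ColextParams, p_detect: float | None = None,
                            interval_years: float = 10.0, area_ha: float = 0.2,
                            cut_fraction: float = 0.2, seed: int = 0,
                            covariate_names: tuple[str, ...] = ("forest_age",)) -> ColextPlotData:
    """Generative twin of the colonization-extinction model.

    Z1 ~ Bernoulli(psi1); Z2 follows the offset-corrected transition
    (colonization probability 0 on cut plots); Y_t ~ Bernoulli(Z_t p).
    Covariates are standard-normal plot attributes. Survey interval and
    plot area may be scalars or per-plot arrays.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    p = params.p if p_detect is None else p_detect
    if not (0 < p <= 1):
        raise ValueError("p_detect must be in (0, 1]")
    rng = np.random.default_rng(seed)
    interval = np.broadcast_to(np.asarray(interval_years, float), (n_plots,))
    area = np.broadcast_to(np.asarray(area_ha, float), (n_plots,))
    cut = rng.random(n_plots) < cut_fraction
    X = {name: rng.standard_normal(n_plots) for name in covariate_names}

    lin = np.full(n_plots, params.delta2)
    for name, b in params.beta.items():
        lin = lin + b * X[name]
    c = np.where(cut, 0.0 if params.delta1 is None else inv_cloglog(params.delta1),
                 inv_cloglog(lin))
    e = np.where(cut, inv_cloglog(params.eps1), inv_cloglog(params.eps2))
    c_star = offset_probability(c, interval, area)
    e_star = offset_probability(e, interval, area)

    psi1 = np.where(cut, params.psi1_for_cut, params.psi1)
    z1 = (rng.random(n_plots) < psi1).astype(int)
    psi2 = (1 - z1) * c_star + z1 * (1 - e_star)
    z2 = (rng.random(n_plots) < psi2).astype(int)
    y1 = (z1 * (rng.random(n_plots) < p)).astype(int)
    y2 = (z2 * (rng.random(n_plots) < p)).astype(int)

    table = pd.DataFrame({"plot_id": np.arange(n_plots), "y1": y1, "y2": y2,
                          "interval_years": interval, "area_ha": area, "cut": cut, **X})
    truth = pd.DataFrame({"z1": z1, "z2": z2, "c_star": c_star, "e_star": e_star})
    return ColextPlotData(table=table, covariate_names=list(covariate_names), truth=truth)
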