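"""GLM, background sampling, MaxEnt-linear/IPP, and the joint PA/PO model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

from sporecast import covariates as cov
from sporecast import static_models as sm
from sporecast import synthetic as syn


def full_background(cells):
    ids = cells["cell_id"].to_numpy()
    return sm.BackgroundSample(cell_ids=ids, method="random",
                               n_requested=len(ids), n_returned=len(ids))


# ---------------------------------------------------------------------------
# GLM


def make_pa(cells, beta, n, seed, link="logit"):
    rng = np.random.default_rng(seed)
    lin = beta.get("const", 0.0) + sum(
        b * cells[k].to_numpy() for k, b in beta.items() if k != "const")
    p = 1 / (1 + np.exp(-lin))
    idx = rng.integers(0, len(cells), size=n)
    return pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()[idx],
                         "detected": (rng.random(n) < p[idx]).astype(int)})


def test_glm_recovers_known_slope(scaled_cells):
    cells, _ = scaled_cells
    pa = make_pa(cells, {"const": -1.0, "spruce_volume": 1.0}, 20_000, seed=1)
    fit = sm.fit_glm(pa, cells, ["spruce_volume", "temperature"])
    se = (fit.conf_int.loc["spruce_volume", "hi"] -
          fit.params["spruce_volume"]) / 1.959964
    assert abs(fit.params["spruce_volume"] - 1.0) < 3 * se


def test_glm_rejects_pure_noise_term(scaled_cells):
    cells, _ = scaled_cells
    rejected = 0
    for rep in range(10):
        c = cells.copy()
        rng = np.random.default_rng(rep)
        c["noise"] = rng.standard_normal(len(c))
        pa = make_pa(c, {"const": -0.5, "spruce_volume": 1.0}, 2000, seed=50 + rep)
        fit = sm.fit_glm(pa, c, ["spruce_volume", "noise"])
        if "noise" not in fit.extra["terms"]:
            rejected += 1
    assert rejected >= 8


def test_glm_requires_both_classes(scaled_cells):
    cells, _ = scaled_cells
    pa = pd.DataFrame({"cell_id": cells["cell_id"].iloc[:50], "detected": 0})
    with pytest.raises(ValueError, match="presence"):
        sm.fit_glm(pa, cells, ["spruce_volume"])


def test_glm_skips_zero_variance_term(scaled_cells):
    cells, _ = scaled_cells
    c = cells.copy()
    c["flat"] = 1.0
    pa = make_pa(c, {"spruce_volume": 1.0}, 2000, seed=3)
    with pytest.warns(UserWarning, match="zero variance"):
        fit = sm.fit_glm(pa, c, ["spruce_volume", "flat"])
    assert "flat" not in fit.extra["terms"]


# ---------------------------------------------------------------------------
# background sampling


@pytest.fixture(scope="module")
def obs_for_background(landscape, recorders):
    occ, _ = syn.simulate_true_occurrence(landscape, {"intercept": -0.5,
                                                      "spruce_volume": 1.0}, seed=7)
    rng = np.random.default_rng(8)
    targets = {s: (rng.random(len(landscape.cells)) < 0.3).astype(int) for s in (1, 2)}
    return syn.simulate_citizen_science(landscape, occ, {}, recorders, effort=1.5,
                                        seed=9, target_species_occupancy=targets)


def test_random_background_excludes_focal_cells(landscape, obs_for_background):
    bg = sm.sample_background(landscape, obs_for_background, 300, "random", seed=1)
    po = obs_for_background.presence_only
    focal = set(po.loc[po["species_id"] == 0, "cell_id"])
    assert not focal & set(bg.cell_ids)
    assert bg.n_returned == 300


def test_tgb_background_cells_hold_target_records(landscape, obs_for_background):
    po = obs_for_background.presence_only
    bg = sm.sample_background(landscape, obs_for_background, 100, "TGB",
                              target_group_records=po, seed=2)
    tg_cells = set(po.loc[po["species_id"] != 0, "cell_id"])
    focal = set(po.loc[po["species_id"] == 0, "cell_id"])
    assert set(bg.cell_ids) <= tg_cells - focal


def test_background_deterministic_and_capped(landscape, obs_for_background):
    a = sm.sample_background(landscape, obs_for_background, 300, "random", seed=5)
    b = sm.sample_background(landscape, obs_for_background, 300, "random", seed=5)
    np.testing.assert_array_equal(a.cell_ids, b.cell_ids)
    with pytest.warns(UserWarning, match="eligible"):
        big = sm.sample_background(landscape, obs_for_background, 10 ** 6, "random")
    assert big.n_returned < 10 ** 6


# ---------------------------------------------------------------------------
# MaxEnt-linear / IPP


def draw_presences(cells, slope_col, slope, n, seed):
    rng = np.random.default_rng(seed)
    lam = np.exp(slope * cells[slope_col].to_numpy())
    idx = rng.choice(len(cells), size=n, p=lam / lam.sum())
    return idx, pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()[idx],
                              "species_id": 0})


def test_maxent_equals_poisson_oracle(landscape50):
    cells, _ = cov.standardize(landscape50.cells, ["spruce_volume", "temperature"])
    idx, po = draw_presences(cells, "spruce_volume", 2.0, 800, seed=4)
    fit = sm.fit_maxent_linear(po, full_background(cells), cells,
                               ["spruce_volume", "temperature"], select=False)
    counts = np.bincount(idx, minlength=len(cells)).astype(float)
    X = smapi.add_constant(cells[["spruce_volume", "temperature"]])
    oracle = smapi.GLM(counts, X, family=smapi.families.Poisson()).fit()
    for term in ["spruce_volume"]:
        rel = abs(fit.params[term] - oracle.params[term]) / abs(oracle.params[term])
        assert rel < 1e-4  # identical data, same maximum


def test_maxent_null_slopes_near_zero(landscape50):
    cells, _ = cov.standardize(landscape50.cells, ["spruce_volume", "temperature"])
    rng = np.random.default_rng(5)
    idx = rng.integers(0, len(cells), size=600)
    po = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()[idx], "species_id": 0})
    fit = sm.fit_maxent_linear(po, full_background(cells), cells,
                               ["spruce_volume", "temperature"], select=False)
    for term in ["spruce_volume", "temperature"]:
        se = (fit.conf_int.loc[term, "hi"] - fit.params[term]) / 1.959964
        assert abs(fit.params[term]) < 3 * se


def test_maxent_suitability_normalizes(landscape, scaled_cells):
    cells, _ = scaled_cells
    _, po = draw_presences(cells, "spruce_volume", 1.0, 200, seed=6)
    bg = full_background(cells)
    fit = sm.fit_maxent_linear(po, bg, cells, ["spruce_volume"], select=False)
    s = sm.maxent_suitability(fit, cells.set_index("cell_id").loc[bg.cell_ids])
    assert s.sum() == pytest.approx(1.0, abs=1e-8)


def test_maxent_requires_presences(scaled_cells):
    cells, _ = scaled_cells
    empty = pd.DataFrame(columns=["cell_id", "species_id"])
    with pytest.raises(ValueError, match="presence"):
        sm.fit_maxent_linear(empty, full_background(cells), cells, ["spruce_volume"])


def test_importance_separates_driver_from_noise(scaled_cells):
    cells, _ = scaled_cells
    c = cells.copy()
    c["noise"] = np.random.default_rng(7).standard_normal(len(c))
    _, po = draw_presences(c, "spruce_volume", 1.5, 600, seed=8)
    fit = sm.fit_maxent_linear(po, full_background(c), c,
                               ["spruce_volume", "noise"], select=False)
    imp = sm.variable_importance(fit, po, full_background(c), c, seed=1)
    assert imp["noise"] < imp["spruce_volume"]
    assert all(v >= 0 for v in imp.values())


def test_maxent_selection_drops_zero_importance_term(scaled_cells):
    cells, _ = scaled_cells
    c = cells.copy()
    c["noise"] = np.random.default_rng(9).standard_normal(len(c))
    _, po = draw_presences(c, "spruce_volume", 1.5, 600, seed=10)
    pa = make_pa(c, {"const": -0.5, "spruce_volume": 1.0}, 800, seed=11)
    fit = sm.fit_maxent_linear(po, full_background(c), c, ["spruce_volume", "noise"],
                               presence_absence=pa, select=True, seed=2)
    assert "spruce_volume" in fit.extra["terms"]


# ---------------------------------------------------------------------------
# PA/PO model


def simulate_papo_world(seed, n_po=400, bias=True):
    land = syn.generate_landscape(40, 40, 3.0, seed=seed)
    cells, _ = cov.standardize(land.cells, ["spruce_volume", "temperature",
                                            "dist_small_roads"])
    rng = np.random.default_rng(seed + 1000)
    beta_true = {"spruce_volume": 1.0, "temperature": -0.5}
    parts = []
    for s, mult in enumerate([1.0, 0.7, 1.3]):
        eta = sum(b * mult * cells[k].to_numpy() for k, b in beta_true.items())
        if bias:
            eta = eta - 0.8 * cells["dist_small_roads"].to_numpy()
        lam = np.exp(eta)
        idx = rng.choice(len(cells), size=n_po, p=lam / lam.sum())
        parts.append(pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()[idx],
                                   "species_id": s}))
    po = pd.concat(parts, ignore_index=True)
    u = -1.0 + sum(b * cells[k].to_numpy() for k, b in beta_true.items())
    p = -np.expm1(-np.exp(u))
    pa_idx = rng.choice(len(cells), size=300, replace=False)
    pa = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()[pa_idx],
                       "detected": (rng.random(300) < p[pa_idx]).astype(int)})
    return cells, po, pa, beta_true


def test_papo_recovers_truth_within_wald_bands():
    cells, po, pa, truth = simulate_papo_world(seed=31)
    fit = sm.fit_papo(po, pa, full_background(cells), list(truth), ["dist_small_roads"],
                      cells)
    for term, b in truth.items():
        name = f"{term}[0]"
        se = (fit.conf_int.loc[name, "hi"] - fit.params[name]) / 1.959964
        assert abs(fit.params[name] - b) < 3 * se, term


def test_papo_bias_term_reduces_error():
    maes = {"with": [], "without": []}
    for rep in range(4):
        cells, po, pa, truth = simulate_papo_world(seed=40 + rep)
        f1 = sm.fit_papo(po, pa, full_background(cells), list(truth),
                         ["dist_small_roads"], cells)
        f0 = sm.fit_papo(po, pa, full_background(cells), list(truth), [], cells)
        for f, key in [(f1, "with"), (f0, "without")]:
            fc = f.extra["focal_coefficients"]
            maes[key].append(np.mean([abs(fc[t] - b) for t, b in truth.items()]))
    assert np.mean(maes["with"]) < np.mean(maes["without"])


def test_papo_constant_bias_covariate_falls_back():
    cells, po, pa, truth = simulate_papo_world(seed=50, bias=False)
    c = cells.copy()
    c["flatbias"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        fit = sm.fit_papo(po, pa, full_background(c), list(truth), ["flatbias"], c)
    plain = sm.fit_papo(po, pa, full_background(c), list(truth), [], c)
    for t in truth:
        assert fit.extra["focal_coefficients"][t] == pytest.approx(
            plain.extra["focal_coefficients"][t], abs=1e-6)


def test_papo_pa_only_reduces_to_cloglog_glm(scaled_cells):
    cells, _ = scaled_cells
    rng = np.random.default_rng(60)
    u = -1.0 + 0.8 * cells["spruce_volume"].to_numpy()
    y = (rng.random(len(cells)) < -np.expm1(-np.exp(u))).astype(int)
    pa = pd.DataFrame({"cell_id": cells["cell_id"], "detected": y})
    po = pd.DataFrame(columns=["cell_id", "species_id"])
    fit = sm.fit_papo(po, pa, full_background(cells), ["spruce_volume"],
                      ["dist_small_roads"], cells)
    X = smapi.add_constant(cells[["spruce_volume"]])
    oracle = smapi.GLM(y, X, family=smapi.families.Binomial(
        smapi.families.links.CLogLog())).fit()
    assert fit.extra["focal_coefficients"]["const"] == pytest.approx(
        oracle.params["const"], abs=1e-6)
    assert fit.extra["focal_coefficients"]["spruce_volume"] == pytest.approx(
        oracle.params["spruce_volume"], abs=1e-6)


def test_scaling_invariance_of_glm(landscape):
    """beta_hat * SD is invariant to whether covariates were standardized."""
    cells_raw = landscape.cells
    cells_std, scales = cov.standardize(cells_raw, ["spruce_volume"])
    pa = make_pa(cells_std, {"const": -0.5, "spruce_volume": 1.0}, 4000, seed=70)
    f_std = sm.fit_glm(pa, cells_std, ["spruce_volume"])
    f_raw = sm.fit_glm(pa, cells_raw, ["spruce_volume"])
    assert f_raw.params["spruce_volume"] * scales["spruce_volume"] == pytest.approx(
        f_std.params["spruce_volume"], rel=1e-6)
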