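"""Colonization-extinction model: links, offsets, likelihood, fitting, forecasting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from sporecast import colext as cx
from sporecast import synthetic as syn
from tests.conftest import toy_colext_data


# ---------------------------------------------------------------------------
# link and offset algebra


def test_cloglog_known_value():
    # -log(1-p) = 1 at p = 1 - e^-1, so cloglog is exactly 0 there
    assert cx.cloglog(1 - np.exp(-1)) == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_cloglog_round_trip(p):
    assert cx.inv_cloglog(cx.cloglog(p)) == pytest.approx(p, abs=1e-12)


def test_cloglog_strictly_increasing():
    p = np.linspace(1e-6, 1 - 1e-6, 1000)
    assert np.all(np.diff(cx.cloglog(p)) > 0)


@pytest.mark.parametrize("bad", [-0.1, 0.0, 1.0, 1.5])
def test_cloglog_domain_error(bad):
    with pytest.raises(ValueError):
        cx.cloglog(bad)


def test_offset_identity_at_reference_scale():
    for p in np.arange(0, 1.0001, 0.1):
        assert cx.offset_probability(p, 10, 0.2) == pytest.approx(p, abs=1e-12)


def test_offset_direct_arithmetic():
    # n = 2, a = 1: 1 - 0.8^2
    assert cx.offset_probability(0.2, 20, 0.2) == pytest.approx(0.36, abs=1e-12)
    assert cx.offset_probability(0.0, 7, 0.3) == 0.0


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=0.01, max_value=0.9),
       st.floats(min_value=1, max_value=15), st.floats(min_value=0.05, max_value=0.5))
def test_offset_monotone_in_interval_and_area(p, t, a):
    base = cx.offset_probability(p, t, a)
    assert cx.offset_probability(p, t * 1.5, a) > base
    assert cx.offset_probability(p, t, a * 1.5) > base
    assert base == pytest.approx(1 - (1 - p) ** ((t / 10) * (a / 0.2)), abs=1e-12)


def test_offset_rejects_nonpositive_scales():
    with pytest.raises(ValueError):
        cx.offset_probability(0.5, 0, 0.2)
    with pytest.raises(ValueError):
        cx.offset_probability(0.5, 10, -1)


# ---------------------------------------------------------------------------
# transition probability


def _params(**kw):
    base = dict(delta2=cx.cloglog(0.3), eps2=cx.cloglog(0.3), eps1=cx.cloglog(0.5),
                psi1=0.4)
    base.update(kw)
    return cx.ColextParams(**base)


def test_transition_no_extinction_is_certain_persistence():
    p = _params(eps2=cx.cloglog(1e-12))
    psi = cx.transition_probability(1, p, {}, interval_years=10, area_ha=0.2)
    assert psi == pytest.approx(1.0, abs=1e-9)


def test_transition_cut_plot_cannot_be_colonized():
    psi = cx.transition_probability(0, _params(), {}, 10, 0.2, cut=True)
    assert psi == 0.0


def test_transition_plugin_value():
    p = _params(delta2=cx.cloglog(0.3))
    psi = cx.transition_probability(0, p, {}, interval_years=10, area_ha=0.2)
    assert psi == pytest.approx(0.3, abs=1e-12)


def test_transition_missing_covariate_errors():
    p = _params(beta={"forest_age": 0.5})
    with pytest.raises(KeyError):
        cx.transition_probability(0, p, pd.DataFrame({"other": [1.0]}), 10, 0.2)


# ---------------------------------------------------------------------------
# likelihood


def brute_force_loglik(params, data):
    """Enumerate every joint latent configuration across plots."""
    t = data.table
    total = 0.0
    for _, rowdf in t.iterrows():
        row = rowdf.to_dict()
        psi1 = params.psi1_for_cut if row["cut"] else params.psi1
        prob = 0.0
        for z1, z2 in itertools.product([0, 1], repeat=2):
            pz1 = psi1 if z1 else 1 - psi1
            psi2 = cx.transition_probability(
                z1, params, pd.DataFrame({k: [row[k]] for k in data.covariate_names}),
                row["interval_years"], row["area_ha"], cut=row["cut"])
            pz2 = psi2 if z2 else 1 - psi2
            py1 = z1 * params.p if row["y1"] else 1 - z1 * params.p
            py2 = z2 * params.p if row["y2"] else 1 - z2 * params.p
            prob += pz1 * pz2 * py1 * py2
        total += np.log(prob)
    return total


def test_loglik_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    params = _params(beta={"x": 0.7}, p=0.9)
    for _ in range(5):
        data = cx.ColextPlotData(table=toy_colext_data(rng), covariate_names=["x"])
        assert cx.colext_loglik(params, data) == pytest.approx(
            brute_force_loglik(params, data), abs=1e-12)


def test_loglik_perfect_detection_reduction():
    rng = np.random.default_rng(6)
    table = toy_colext_data(rng)
    table["y1"] = [1, 0, 1, 0]
    table["y2"] = [1, 1, 0, 0]
    params = _params(p=1.0)
    data = cx.ColextPlotData(table=table, covariate_names=[])
    # with p = 1, Z == Y: complete-data Bernoulli likelihood
    ll = 0.0
    for _, row in table.iterrows():
        psi1 = params.psi1_for_cut if row["cut"] else params.psi1
        ll += np.log(psi1 if row["y1"] else 1 - psi1)
        psi2 = cx.transition_probability(row["y1"], params, {}, row["interval_years"],
                                         row["area_ha"], cut=row["cut"])
        ll += np.log(psi2 if row["y2"] else 1 - psi2)
    assert cx.colext_loglik(params, data) == pytest.approx(ll, abs=1e-10)


def test_loglik_empty_dataset_is_zero():
    data = cx.ColextPlotData(table=pd.DataFrame(
        columns=["plot_id", "y1", "y2", "interval_years", "area_ha", "cut"]))
    assert cx.colext_loglik(_params(), data) == 0.0


def test_loglik_plot_order_invariance():
    rng = np.random.default_rng(7)
    table = toy_colext_data(rng, n_plots=5)
    params = _params(beta={"x": 0.4})
    d1 = cx.ColextPlotData(table=table, covariate_names=["x"])
    d2 = cx.ColextPlotData(table=table.iloc[::-1].reset_index(drop=True),
                           covariate_names=["x"])
    assert cx.colext_loglik(params, d1) == pytest.approx(cx.colext_loglik(params, d2),
                                                         abs=1e-12)


# ---------------------------------------------------------------------------
# survey simulation


def test_certain_extinction_empties_occupied_plots():
    params = _params(eps2=cx.cloglog(1 - 1e-12), eps1=cx.cloglog(1 - 1e-12), psi1=1.0)
    d = syn.simulate_colext_surveys(200, params, p_detect=1.0, seed=3)
    assert d.truth["z1"].sum() == 200
    assert d.truth["z2"].sum() == 0


def test_perfect_detection_observations_equal_state():
    d = syn.simulate_colext_surveys(300, _params(beta={"forest_age": 0.5}),
                                    p_detect=1.0, seed=4)
    assert (d.table["y1"] == d.truth["z1"]).all()
    assert (d.table["y2"] == d.truth["z2"]).all()


def test_colonization_fraction_matches_rate():
    params = _params(delta2=cx.cloglog(0.25))
    d = syn.simulate_colext_surveys(4000, params, p_detect=1.0, cut_fraction=0.0, seed=5)
    empty = d.truth["z1"] == 0
    frac = d.truth.loc[empty, "z2"].mean()
    c_star = d.truth.loc[empty, "c_star"]
    se = np.sqrt(c_star.mean() * (1 - c_star.mean()) / empty.sum())
    assert abs(frac - c_star.mean()) < 3 * se


# ---------------------------------------------------------------------------
# fitting


def test_fit_rejects_all_cut_data():
    d = syn.simulate_colext_surveys(50, _params(), cut_fraction=1.0, seed=8)
    with pytest.raises(ValueError, match="uncut"):
        cx.fit_colext(d, method="ml")


def test_noise_covariate_excluded_by_selection():
    params = _params(delta2=cx.cloglog(0.25), eps2=cx.cloglog(0.3), psi1=0.4)
    rejected = 0
    for rep in range(10):
        d = syn.simulate_colext_surveys(400, params, seed=100 + rep,
                                        covariate_names=("noise",))
        fit = cx.fit_colext(d, method="ml", candidate_covariates=["noise"],
                            seed=rep)
        if "noise" not in fit.extra["kept_covariates"]:
            rejected += 1
    assert rejected >= 8


def test_mcmc_and_ml_agree():
    params = _params(delta2=cx.cloglog(0.25), eps2=cx.cloglog(0.3),
                     beta={"forest_age": 0.8})
    d = syn.simulate_colext_surveys(500, params, seed=9)
    ml = cx.fit_colext(d, method="ml", candidate_covariates=["forest_age"], seed=1)
    mc = cx.fit_colext(d, method="mcmc", candidate_covariates=["forest_age"], seed=1,
                       mcmc_steps=600, mcmc_burn=200)
    for name in ["delta2", "beta_forest_age", "eps2", "logit_psi1"]:
        assert mc.params[name] == pytest.approx(ml.params[name], abs=0.25)


def test_detection_misspecification_inflates_psi1():
    params = _params(psi1=0.4, p=1.0)
    d = syn.simulate_colext_surveys(800, params, p_detect=1.0, seed=10)
    fit_right = cx.fit_colext(d, p_fixed=1.0, method="ml", seed=2)
    fit_wrong = cx.fit_colext(d, p_fixed=0.9, method="ml", seed=2)
    # assuming detections are missed 10% of the time inflates occupancy
    assert expit(fit_wrong.params["logit_psi1"]) > expit(fit_right.params["logit_psi1"])


# ---------------------------------------------------------------------------
# forward simulation


def _static_projection(n_plots, n_steps=19, start=2020, step=5, area=0.2):
    years = np.arange(start, start + step * n_steps, step)
    rows = [pd.DataFrame({"plot_id": np.arange(n_plots), "year": y,
                          "area_ha": area}) for y in years]
    return pd.concat(rows, ignore_index=True)


def test_forward_absorbing_extinction():
    params = _params(delta2=cx.cloglog(1e-14), eps2=cx.cloglog(1 - 1e-14), psi1=1.0)
    traj = cx.simulate_forward(1.0, _static_projection(50, 4), params, n_reps=200, seed=1)
    assert np.all(traj.iloc[:, 0] == 1.0)
    assert np.all(traj.iloc[:, 1:] == 0.0)


def test_forward_matches_deterministic_recursion():
    c, e = 0.3, 0.4
    params = _params(delta2=cx.cloglog(c), eps2=cx.cloglog(e), psi1=0.2)
    proj = _static_projection(100, n_steps=6)
    traj = cx.simulate_forward(0.2, proj, params, n_reps=10_000, seed=2)
    c_star = cx.offset_probability(c, 5, 0.2)
    e_star = cx.offset_probability(e, 5, 0.2)
    psi = 0.2
    for k in range(6):
        mean = traj.iloc[:, k].mean()
        se = np.sqrt(max(psi * (1 - psi), 1e-12) / (10_000 * 100))
        assert abs(mean - psi) < max(3 * se, 1e-4), f"step {k}"
        psi = (1 - psi) * c_star + psi * (1 - e_star)


def test_forward_probabilities_bounded():
    params = _params(beta={}, psi1=0.5)
    traj = cx.simulate_forward(0.5, _static_projection(30, 5), params, n_reps=300, seed=3)
    assert ((traj >= 0) & (traj <= 1)).all().all()


def test_forward_missing_step_errors():
    proj = _static_projection(10, 5)
    proj = proj[proj["year"] != 2030]
    with pytest.raises(ValueError, match="evenly spaced|missing"):
        cx.simulate_forward(0.5, proj, _params(), n_reps=10, seed=1)
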