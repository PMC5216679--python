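"""Independent oracles used by the acceptance script.

These deliberately avoid the package's own fast paths: the likelihood
oracle enumerates latent states one plot at a time, and the AUC oracle
compares every presence/absence pair directly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from sporecast import colext as cx


def toy_colext_data(rng, n_plots=4) -> pd.DataFrame:
    return pd.DataFrame({
        "plot_id": np.arange(n_plots),
        "y1": rng.integers(0, 2, n_plots),
        "y2": rng.integers(0, 2, n_plots),
        "interval_years": rng.uniform(5, 15, n_plots),
        "area_ha": rng.uniform(0.1, 0.4, n_plots),
        "cut": rng.random(n_plots) < 0.4,
        "x": rng.standard_normal(n_plots),
    })


def brute_force_loglik(params: cx.ColextParams, data: cx.ColextPlotData) -> float:
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


def brute_force_auc(scores, labels) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))
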