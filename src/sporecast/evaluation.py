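"""Spatial block cross-validation AUC and coarse-grid aggregation.

Ordinary random cross-validation overstates the skill of spatial
models because nearby train and test cells share autocorrelated
covariates. Blocking assigns whole square spatial blocks to folds so
test data are spatially separated from training data. AUC is the
Mann-Whitney probability that a random presence outscores a random
absence, with midrank half-credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["BlockCVConfig", "auc_mann_whitney", "block_cv_auc", "aggregate_map"]


@dataclass
class BlockCVConfig:
    block_size_cells: int = 50
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size_cells < 1:
            raise ValueError("block_size_cells must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (midrank ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def assign_blocks(rows, cols, config: BlockCVConfig) -> np.ndarray:
    """Fold id per cell: square blocks of cells assigned to folds at random."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    block = (rows // config.block_size_cells).astype(np.int64) * 1_000_003 + \
        (cols // config.block_size_cells)
    uniq = np.unique(block)
    rng = np.random.default_rng(config.seed)
    fold_of_block = dict(zip(uniq, rng.integers(0, config.n_folds, size=len(uniq))))
    if len(uniq) >= config.n_folds:
        # guarantee every fold non-empty: deal a shuffled prefix round-robin
        shuffled = rng.permutation(uniq)
        for i, b in enumerate(shuffled[:config.n_folds]):
            fold_of_block[b] = i
    return np.array([fold_of_block[b] for b in block])


def block_cv_auc(fit_fn, presence_absence: pd.DataFrame, covariate_table: pd.DataFrame,
                 config: BlockCVConfig | None = None) -> pd.DataFrame:
    """Per-fold train/test AUC for a model under spatial block CV.

    ``fit_fn(train_df)`` fits on the merged presence-absence +
    covariate rows of the training folds and returns
    ``score_fn(df) -> scores``. Folds whose test data hold a single
    class are skipped and recorded with NaN AUC. Returns one row per
    fold plus a ``mean`` row.
    """
    config = config or BlockCVConfig()
    df = presence_absence.merge(covariate_table, on="cell_id", how="left")
    folds = assign_blocks(df["row"], df["col"], config)
    records = []
    for k in range(config.n_folds):
        test = df[folds == k]
        train = df[folds != k]
        if len(test) == 0 or len(train) == 0:
            warnings.warn(f"fold {k} empty; skipped")
            records.append({"fold": k, "train_auc": np.nan, "test_auc": np.nan,
                            "n_test": len(test), "skipped": True})
            continue
        y_test = np.asarray(test["detected"], dtype=float)
        y_train = np.asarray(train["detected"], dtype=float)
        if y_test.min() == y_test.max() or y_train.min() == y_train.max():
            warnings.warn(f"fold {k} has a single class; skipped")
            records.append({"fold": k, "train_auc": np.nan, "test_auc": np.nan,
                            "n_test": len(test), "skipped": True})
            continue
        score_fn = fit_fn(train)
        records.append({
            "fold": k,
            "train_auc": auc_mann_whitney(score_fn(train), y_train),
            "test_auc": auc_mann_whitney(score_fn(test), y_test),
            "n_test": len(test), "skipped": False,
        })
    out = pd.DataFrame(records)
    mean_row = {"fold": "mean",
                "train_auc": out["train_auc"].mean(), "test_auc": out["test_auc"].mean(),
                "n_test": out["n_test"].sum(), "skipped": False}
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def aggregate_map(fine_probs, factor: int) -> np.ndarray:
    """Aggregate a fine grid to coarse resolution by block means.

    Each coarse cell is the mean of its non-missing (non-NaN) fine
    cells; a fully missing block is NaN. ``factor`` 100 turns a 100 m
    grid into a 10 km grid. Edges are padded with NaN when the factor
    does not divide the grid shape.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    z = np.asarray(fine_probs, dtype=float)
    if z.ndim != 2:
        raise ValueError("fine grid must be 2-D")
    nr = -(-z.shape[0] // factor) * factor
    nc = -(-z.shape[1] // factor) * factor
    padded = np.full((nr, nc), np.nan)
    padded[:z.shape[0], :z.shape[1]] = z
    blocks = padded.reshape(nr // factor, factor, nc // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(blocks, axis=(1, 3))
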