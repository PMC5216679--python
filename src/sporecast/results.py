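"""Shared result container for fitted occurrence models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class FitResult:
    """A fitted model: named coefficients, intervals, and provenance.

    Attributes
    ----------
    model_kind:
        One of ``"glm"``, ``"maxent"``, ``"maxent-tgb"``, ``"papo"``,
        ``"occupancy"``, ``"colext"``.
    params:
        Point estimates indexed by coefficient name (``"const"`` for the
        intercept; derived terms use names like ``"spruce_volume^2"`` or
        ``"temperature:precipitation"``).
    conf_int:
        95% uncertainty intervals, columns ``lo`` and ``hi``, same index
        as ``params``.
    link:
        ``"logit"``, ``"cloglog"`` or ``"log-intensity"``.
    scale_factors:
        Per-column standard deviations the training covariates were
        divided by; apply the same factors to any new data before
        prediction.
    selection_trace:
        One record per selection step (term tried, criterion value,
        kept or not); empty when no selection ran.
    background_spec:
        ``"none"``, ``"random"`` or ``"TGB"``.
    extra:
        Model-specific payload (e.g. the MaxEnt normalising constant or
        the per-species coefficients of the joint point-process fit).
    """

    model_kind: str
    params: pd.Series
    conf_int: pd.DataFrame
    link: str = "logit"
    scale_factors: pd.Series | None = None
    selection_trace: list[dict] = field(default_factory=list)
    background_spec: str = "none"
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.params.index) - set(self.conf_int.index)
        if missing:
            raise ValueError(f"coefficients without intervals: {sorted(missing)}")

    @property
    def term_names(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "link": self.link,
            "background_spec": self.background_spec,
            "params": self.params.to_dict(),
            "conf_int": {k: [float(v["lo"]), float(v["hi"])] for k, v in self.conf_int.iterrows()},
            "scale_factors": None if self.scale_factors is None else self.scale_factors.to_dict(),
            "selection_trace": self.selection_trace,
            "extra": {k: v for k, v in self.extra.items() if _jsonable(v)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        ci = pd.DataFrame(d["conf_int"], index=["lo", "hi"]).T
        sf = d.get("scale_factors")
        return cls(
            model_kind=d["model_kind"],
            params=pd.Series(d["params"]),
            conf_int=ci,
            link=d.get("link", "logit"),
            scale_factors=None if sf is None else pd.Series(sf),
            selection_trace=list(d.get("selection_trace", [])),
            background_spec=d.get("background_spec", "none"),
            extra=dict(d.get("extra", {})),
        )


def _jsonable(v: Any) -> bool:
    if isinstance(v, (str, int, float, bool, type(None))):
        return True
    if isinstance(v, (list, tuple)):
        return all(_jsonable(x) for x in v)
    if isinstance(v, dict):
        return all(isinstance(k, str) and _jsonable(x) for k, x in v.items())
    return False


def design_matrix(table: pd.DataFrame, terms: list[str], add_const: bool = True) -> pd.DataFrame:
    """Build a design matrix from plain column names and derived terms.

    ``"x"`` is the column itself, ``"x^2"`` its square, and ``"a:b"``
    the product of two columns. Raises ``KeyError`` naming the missing
    column for unknown names.
    """
    cols: dict[str, np.ndarray] = {}
    if add_const:
        cols["const"] = np.ones(len(table))
    for term in terms:
        cols[term] = eval_term(table, term)
    return pd.DataFrame(cols, index=table.index)


def eval_term(table: pd.DataFrame, term: str) -> np.ndarray:
    if term.endswith("^2"):
        base = term[:-2]
        _require(table, base, term)
        return np.asarray(table[base], dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":", 1)
        _require(table, a, term)
        _require(table, b, term)
        return np.asarray(table[a], dtype=float) * np.asarray(table[b], dtype=float)
    _require(table, term, term)
    return np.asarray(table[term], dtype=float)


def base_column(term: str) -> str:
    """The underlying covariate column(s) a term is built from."""
    if term.endswith("^2"):
        return term[:-2]
    return term


def _require(table: pd.DataFrame, col: str, term: str) -> None:
    if col not in table.columns:
        raise KeyError(f"term {term!r} needs missing covariate column {col!r}")
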