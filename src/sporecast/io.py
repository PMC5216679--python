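"""Readers and writers for the package's CSV/JSON interchange formats.

CSV is the canonical format: headered, UTF-8, '.' decimal. Every file
starts with a versioned comment header line so format drift fails
loudly instead of silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .results import FitResult
from .synthetic import Landscape, ObservationSet

LANDSCAPE_COLUMNS = [
    "cell_id", "row", "col", "spruce_volume", "forest_age", "deadwood_volume",
    "temperature", "precipitation", "elevation", "population_density",
    "log_population_density", "dist_small_roads", "dist_main_roads",
    "dist_cities", "dist_towns",
]

_HEADERS = {"landscape": "# sporecast landscape v1",
            "observations": "# sporecast observations v1",
            "trajectories": "# sporecast trajectories v1"}


def _write_csv(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADERS[kind] + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != _HEADERS[kind]:
            raise ValueError(f"{path}: expected header {_HEADERS[kind]!r}, got {first!r}")
        return pd.read_csv(fh)


def write_landscape(landscape: Landscape, path) -> None:
    df = landscape.cells[LANDSCAPE_COLUMNS + [c for c in landscape.cells.columns
                                              if c not in LANDSCAPE_COLUMNS]]
    _write_csv(df, path, "landscape")


def read_landscape(path, extra_columns: list[str] = ()) -> Landscape:
    df = _read_csv(path, "landscape")
    allowed = set(LANDSCAPE_COLUMNS) | set(extra_columns)
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ValueError(f"{path}: unknown landscape columns {unknown}")
    missing = [c for c in LANDSCAPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landscape columns {missing}")
    return Landscape(cells=df, n_rows=int(df["row"].max()) + 1,
                     n_cols=int(df["col"].max()) + 1)


def write_observations(obs: ObservationSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_csv(obs.presence_only, d / "presence_only.csv", "observations")
    _write_csv(obs.presence_absence, d / "presence_absence.csv", "observations")
    _write_csv(obs.visits, d / "visits.csv", "observations")
    recs = pd.DataFrame([{"recorder_id": r.recorder_id, "is_thorough": r.is_thorough,
                          "recording_days": r.recording_days,
                          "skill_intercept": r.skill_intercept} for r in obs.recorders])
    recs.to_csv(d / "recorders.csv", index=False)


def read_observations(directory) -> ObservationSet:
    from .synthetic import RecorderProfile
    d = Path(directory)
    po = _read_csv(d / "presence_only.csv", "observations")
    pa = _read_csv(d / "presence_absence.csv", "observations")
    visits = _read_csv(d / "visits.csv", "observations")
    recorders = []
    rec_path = d / "recorders.csv"
    if rec_path.exists():
        for _, r in pd.read_csv(rec_path).iterrows():
            recorders.append(RecorderProfile(int(r["recorder_id"]), bool(r["is_thorough"]),
                                             int(r["recording_days"]),
                                             float(r["skill_intercept"])))
    return ObservationSet(presence_only=po, presence_absence=pa, visits=visits,
                          recorders=recorders)


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2), encoding="utf-8")


def read_fit(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_trajectories(rows: pd.DataFrame, path) -> None:
    _write_csv(rows, path, "trajectories")


def read_trajectories(path) -> pd.DataFrame:
    return _read_csv(path, "trajectories")
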