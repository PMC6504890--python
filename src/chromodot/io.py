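"""CSV/JSON/YAML readers and writers for every table the pipeline exchanges.

All tables are plain CSV with a leading ``# chromodot ...`` provenance
comment recording the seed that produced them; readers skip comment lines.
Schemas:

* coordinates: cell_id, t_min_absolute, channel (tetO|lacO), dot_index,
  x_um, y_um, and either z_um (already corrected) or z_index (plane number,
  converted via the z-step x refractive-scale correction on read);
* cell metadata: cell_id, NEBD_min, end_of_S_min (optional);
* states: cell_id, t_rel_NEBD_min, state, separated_channel;
* observed proportions: time_min, per-state counts, n_classified, per-state
  proportions over classified cells;
* model proportions: time_min, p_nonresolved, p_resolved, p_compacted, m, seed;
* model parameters: flat {tau1, tau2, r1, r2} mapping as JSON or YAML.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (ALL_STATES, CLASSIFIED_STATES, CellStateSeries,
                       ClassifierConfig, DotState, DotTimecourse,
                       ObservedProportionSeries, StateCall, correct_z)
from .model import ModelParameters, PopulationProportions

__all__ = [
    "SchemaError",
    "read_coordinates",
    "write_coordinates",
    "write_cell_metadata",
    "read_states",
    "write_states",
    "read_proportions",
    "write_proportions",
    "read_model_proportions",
    "write_model_proportions",
    "read_params",
    "write_params",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

_COORD_COLUMNS = ("cell_id", "t_min_absolute", "channel", "dot_index", "x_um", "y_um")
_PROPORTION_TOL = 1e-9


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _provenance_line(seed) -> str:
    return f"# chromodot seed={seed}\n"


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        # round_trip parsing: write->read->write must be byte-stable
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty file", path)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_coordinates(cells: list[DotTimecourse], path: str | Path,
                      seed=None) -> None:
    rows = []
    for cell in cells:
        for t, tet, lac in zip(cell.times, cell.tetO, cell.lacO):
            for channel, pts in (("tetO", tet), ("lacO", lac)):
                for j, p in enumerate(np.asarray(pts).reshape(-1, 3)):
                    rows.append((cell.cell_id, t, channel, j, p[0], p[1], p[2]))
    df = pd.DataFrame(rows, columns=list(_COORD_COLUMNS) + ["z_um"])
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        df.to_csv(fh, index=False)


def write_cell_metadata(cells: list[DotTimecourse], path: str | Path,
                        seed=None) -> None:
    df = pd.DataFrame({
        "cell_id": [c.cell_id for c in cells],
        "NEBD_min": [c.nebd_min for c in cells],
        "end_of_S_min": [c.end_of_s_min for c in cells],
    })
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        df.to_csv(fh, index=False)


def read_coordinates(coord_path: str | Path, metadata_path: str | Path,
                     config: ClassifierConfig = ClassifierConfig()
                     ) -> list[DotTimecourse]:
    """Read dot centroids plus per-cell metadata into timecourses.

    Accepts either a ``z_um`` column (micrometres, used as-is) or a
    ``z_index`` column (plane number, converted through :func:`correct_z`).
    Time points inside a cell's observed span with a missing channel come
    back as empty channels (classified UNDETERMINED downstream).
    """
    df = _read_csv(coord_path, _COORD_COLUMNS)
    meta = _read_csv(metadata_path, ("cell_id", "NEBD_min"))
    if df.empty:
        return []
    if "z_um" in df.columns:
        z = df["z_um"]
    elif "z_index" in df.columns:
        z = pd.Series(correct_z(df["z_index"].to_numpy(), config))
    else:
        raise SchemaError(f"{coord_path}: needs a z_um or z_index column")
    df = df.assign(_z=np.asarray(z, dtype=float))

    for col in ("t_min_absolute", "x_um", "y_um", "_z"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise SchemaError(
                f"{coord_path}: non-numeric {col.lstrip('_')} at data row {bad[0]}")
    unknown = set(df["channel"]) - {"tetO", "lacO"}
    if unknown:
        raise SchemaError(f"{coord_path}: unknown channel labels {sorted(unknown)}")

    meta = meta.set_index("cell_id")
    cells = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        if cell_id not in meta.index:
            raise SchemaError(f"{metadata_path}: no metadata row for cell {cell_id}")
        counts = g.groupby(["t_min_absolute", "channel"]).size()
        if (counts > 2).any():
            t_bad, ch_bad = counts.index[counts.to_numpy() > 2][0]
            raise SchemaError(
                f"{coord_path}: cell {cell_id} has >2 {ch_bad} dots at t={t_bad}")
        tmin, tmax = g["t_min_absolute"].min(), g["t_min_absolute"].max()
        n_t = int(round(tmax - tmin)) + 1
        times = tmin + np.arange(n_t, dtype=float)
        tet: list[np.ndarray] = [np.empty((0, 3)) for _ in range(n_t)]
        lac: list[np.ndarray] = [np.empty((0, 3)) for _ in range(n_t)]
        for (t, channel), gg in g.groupby(["t_min_absolute", "channel"]):
            k = int(round(t - tmin))
            pts = gg.sort_values("dot_index")[["x_um", "y_um", "_z"]].to_numpy(float)
            (tet if channel == "tetO" else lac)[k] = pts
        end_s = meta.loc[cell_id].get("end_of_S_min", math.nan)
        cells.append(DotTimecourse(
            cell_id=str(cell_id), times=times, tetO=tet, lacO=lac,
            nebd_min=float(meta.loc[cell_id, "NEBD_min"]),
            end_of_s_min=None if pd.isna(end_s) else float(end_s)))
    return cells


def write_states(series: list[CellStateSeries], path: str | Path, seed=None) -> None:
    rows = []
    for s in series:
        for t, call in zip(s.t_rel, s.calls):
            rows.append((s.cell_id, t, call.state.value, call.separated_channel or ""))
    df = pd.DataFrame(rows, columns=["cell_id", "t_rel_NEBD_min", "state",
                                     "separated_channel"])
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        df.to_csv(fh, index=False)


def read_states(path: str | Path) -> list[CellStateSeries]:
    df = _read_csv(path, ("cell_id", "t_rel_NEBD_min", "state"))
    if df.empty:
        return []
    bad = set(df["state"]) - set(ALL_STATES)
    if bad:
        raise SchemaError(f"{path}: unknown state labels {sorted(bad)}")
    out = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("t_rel_NEBD_min")
        calls = []
        for _, row in g.iterrows():
            sep = row.get("separated_channel")
            sep = None if (pd.isna(sep) or sep == "") else str(sep)
            calls.append(StateCall(DotState(row["state"]), separated_channel=sep))
        out.append(CellStateSeries(cell_id=str(cell_id),
                                   t_rel=g["t_rel_NEBD_min"].to_numpy(float),
                                   calls=calls))
    return out


def write_proportions(obs: ObservedProportionSeries, path: str | Path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        obs.table.to_csv(fh, index=False)


def read_proportions(path: str | Path) -> ObservedProportionSeries:
    cols = (["time_min"] + [f"n_{s.lower()}" for s in ALL_STATES]
            + ["n_classified"] + [f"p_{s.lower()}" for s in CLASSIFIED_STATES])
    df = _read_csv(path, tuple(cols))
    p = df[[f"p_{s.lower()}" for s in CLASSIFIED_STATES]].sum(axis=1)
    nonzero = df["n_classified"] > 0
    if not np.allclose(p[nonzero], 1.0, atol=_PROPORTION_TOL, rtol=0.0):
        worst = df.loc[nonzero, "time_min"].iloc[int(np.argmax(np.abs(p[nonzero] - 1.0)))]
        raise SchemaError(f"{path}: proportions do not sum to 1 (e.g. at t={worst})")
    return ObservedProportionSeries(table=df)


def write_model_proportions(pop: PopulationProportions, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_min": pop.grid.times,
        "p_nonresolved": pop.p_nonresolved,
        "p_resolved": pop.p_resolved,
        "p_compacted": pop.p_compacted,
        "m": pop.m,
        "seed": pop.seed,
    })
    with open(path, "w") as fh:
        fh.write(_provenance_line(pop.seed))
        df.to_csv(fh, index=False)


def read_model_proportions(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("time_min", "p_nonresolved", "p_resolved",
                          "p_compacted", "m", "seed"))
    s = df[["p_nonresolved", "p_resolved", "p_compacted"]].sum(axis=1)
    if not np.allclose(s, 1.0, atol=_PROPORTION_TOL, rtol=0.0):
        raise SchemaError(f"{path}: state proportions do not sum to 1")
    return df


def write_truth(truths, path: str | Path, seed=None) -> None:
    from .model import ModelState
    rows = []
    for tr in truths:
        for t, ms, os_, ch in zip(tr.t_rel, tr.model_states, tr.observable_states,
                                  tr.separated_channel):
            rows.append((tr.cell_id, t, ModelState(int(ms)).name, os_, ch or ""))
    df = pd.DataFrame(rows, columns=["cell_id", "t_rel_NEBD_min", "model_state",
                                     "observable_state", "separated_channel"])
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed))
        df.to_csv(fh, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ("cell_id", "t_rel_NEBD_min", "model_state",
                            "observable_state"))


def read_params(path: str | Path) -> ModelParameters:
    """Read a flat {tau1, tau2, r1, r2} mapping from JSON or YAML (by suffix)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    try:
        return ModelParameters(tau1=float(data["tau1"]), tau2=float(data["tau2"]),
                               r1=float(data["r1"]), r2=float(data["r2"]))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: expected a flat tau1/tau2/r1/r2 mapping") from exc


def write_params(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(params.as_dict(), fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(params.as_dict(), fh)
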