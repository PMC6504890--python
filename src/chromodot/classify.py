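"""Rule-based classification of 3D fluorescent-dot configurations.

Two bacterial operator arrays (tetO, visualized red; lacO, green) are
integrated a few hundred kbp apart on one chromosome and appear as 1-2
fluorescent dots per channel per time point.  The 3D centroid geometry of the
dots encodes the configuration of the marked region:

* ``BLUE`` nonresolved - at least one channel shows a single object (or a
  doublet closer than the sister-separation threshold) and the other channel
  does not show a separated doublet;
* ``BROWN`` partially resolved - exactly one channel shows a doublet
  separated beyond the threshold (the call records which channel);
* ``PINK`` resolved - both channels show separated doublets and at least one
  matched tetO-lacO pair is not colocalized;
* ``RED`` compacted - both channels separated and both matched tetO-lacO
  pairs colocalized;
* ``BLACK`` nonresolved-and-compacted - all dots mutually colocalized for a
  sustained run after NEBD (seen under topo II inhibition);
* ``UNDETERMINED`` - a channel has no detectable object.

Default thresholds: sister separation 0.85 um; colocalization expressed as a
centroid-distance radius of 0.4 um (a proxy for volumetric ">50%" overlap,
which centroid data cannot measure); z spacing 0.75 um per plane scaled by
0.85 for the oil/water refractive-index mismatch (~0.64 um effective).
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "DotState",
    "ClassifierConfig",
    "DotTimecourse",
    "StateCall",
    "CellStateSeries",
    "ObservedProportionSeries",
    "correct_z",
    "classify_timepoint",
    "classify_series",
    "proportions_over_time",
    "rolling_mean_smooth",
    "assign_phase",
    "phase_compare",
    "separation_asymmetry",
]

CLASSIFIED_STATES = ("BLUE", "BROWN", "PINK", "RED", "BLACK")
ALL_STATES = CLASSIFIED_STATES + ("UNDETERMINED",)


class DotState(str, enum.Enum):
    BLUE = "BLUE"
    BROWN = "BROWN"
    PINK = "PINK"
    RED = "RED"
    BLACK = "BLACK"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Geometric thresholds for dot-configuration classification (all in um)."""

    separation_threshold: float = 0.85
    coloc_radius: float = 0.4
    z_step: float = 0.75
    z_scale: float = 0.85
    black_min_run: int = 5
    smoothing_window: int = 9  # minutes, odd

    def __post_init__(self) -> None:
        for name in ("separation_threshold", "coloc_radius", "z_step", "z_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.black_min_run < 1:
            raise ValueError("black_min_run must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


@dataclass(frozen=True)
class StateCall:
    """Classification of one time point; BROWN carries the separated channel."""

    state: DotState
    separated_channel: str | None = None  # "tetO" or "lacO", BROWN only

    def __post_init__(self) -> None:
        if self.state is DotState.BROWN and self.separated_channel not in ("tetO", "lacO"):
            raise ValueError("BROWN call requires separated_channel 'tetO' or 'lacO'")
        if self.state is not DotState.BROWN and self.separated_channel is not None:
            raise ValueError("separated_channel is only meaningful for BROWN")


@dataclass
class DotTimecourse:
    """One cell's per-minute dot centroids (um) and NEBD alignment time."""

    cell_id: str
    times: np.ndarray  # absolute minutes, 1-min steps
    tetO: list[np.ndarray]  # per time point, (k, 3) array with k in 0..2
    lacO: list[np.ndarray]
    nebd_min: float
    end_of_s_min: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.times) == len(self.tetO) == len(self.lacO)):
            raise ValueError("times, tetO and lacO must have equal length")
        for name, chan in (("tetO", self.tetO), ("lacO", self.lacO)):
            for i, pts in enumerate(chan):
                pts = np.asarray(pts, dtype=float).reshape(-1, 3)
                if len(pts) > 2:
                    raise ValueError(
                        f"cell {self.cell_id}: >2 {name} centroids at t={self.times[i]}"
                    )
                if not np.all(np.isfinite(pts)):
                    raise ValueError(
                        f"cell {self.cell_id}: non-finite {name} coordinate at t={self.times[i]}"
                    )
                chan[i] = pts


@dataclass
class CellStateSeries:
    """Per-cell state calls re-indexed to minutes relative to NEBD."""

    cell_id: str
    t_rel: np.ndarray  # minutes relative to NEBD
    calls: list[StateCall]
    end_of_s_rel: float | None = None

    def states(self) -> list[str]:
        return [c.state.value for c in self.calls]


@dataclass
class ObservedProportionSeries:
    """Per-time-point state counts and proportions over classified cells.

    ``table`` columns: time_min, n_<state> for the five classified states and
    UNDETERMINED, n_classified, p_<state> over classified states.  The <10
    cells display mask used in figures is derivable from n_classified and is
    deliberately kept as data, never dropped.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        cls_counts = t[[f"n_{s.lower()}" for s in CLASSIFIED_STATES]].sum(axis=1)
        if not np.array_equal(cls_counts.to_numpy(), t["n_classified"].to_numpy()):
            raise ValueError("n_classified must equal the sum of classified-state counts")

    @property
    def times(self) -> np.ndarray:
        return self.table["time_min"].to_numpy()


def correct_z(z_index, config: ClassifierConfig = ClassifierConfig()):
    """Convert z plane index to um: ``z_index * z_step * z_scale``.

    The scale factor compensates the refractive-index mismatch between the
    oil immersion objective and the aqueous sample (0.75 um nominal spacing
    becomes ~0.64 um effective).
    """
    return np.asarray(z_index, dtype=float) * config.z_step * config.z_scale


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def _channel_summary(pts: np.ndarray, threshold: float) -> tuple[str, float | None]:
    """Reduce a channel to 'empty', 'single' or 'separated'.

    A doublet whose centers are <= threshold apart is treated as a single
    object (the two sisters are not resolved at this locus); equality at the
    threshold counts as nonresolved.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return "empty", None
    if len(pts) == 1:
        return "single", None
    d = _pairwise_dist(pts[0], pts[1])
    return ("separated", d) if d > threshold else ("single", d)


def _best_pairing(tet: np.ndarray, lac: np.ndarray) -> list[float]:
    """tetO-lacO pair distances under the minimal-total-distance assignment (2x2)."""
    d = np.linalg.norm(tet[:, None, :] - lac[None, :, :], axis=2)
    straight = d[0, 0] + d[1, 1]
    crossed = d[0, 1] + d[1, 0]
    if straight <= crossed:
        return [float(d[0, 0]), float(d[1, 1])]
    return [float(d[0, 1]), float(d[1, 0])]


def classify_timepoint(tetO, lacO, config: ClassifierConfig = ClassifierConfig()) -> StateCall:
    """Classify one time point from the two channels' centroids (um, z-corrected)."""
    tet = np.asarray(tetO, dtype=float).reshape(-1, 3)
    lac = np.asarray(lacO, dtype=float).reshape(-1, 3)
    if len(tet) > 2 or len(lac) > 2:
        raise ValueError("at most 2 centroids per channel per time point")

    tet_kind, _ = _channel_summary(tet, config.separation_threshold)
    lac_kind, _ = _channel_summary(lac, config.separation_threshold)
    if tet_kind == "empty" or lac_kind == "empty":
        return StateCall(DotState.UNDETERMINED)

    if tet_kind == "single" and lac_kind == "single":
        return StateCall(DotState.BLUE)
    if tet_kind == "single":  # lacO separated
        return StateCall(DotState.BROWN, separated_channel="lacO")
    if lac_kind == "single":
        return StateCall(DotState.BROWN, separated_channel="tetO")

    # both channels separated doublets: resolved vs compacted by colocalization
    pair_d = _best_pairing(tet, lac)
    if all(d <= config.coloc_radius for d in pair_d):
        return StateCall(DotState.RED)
    return StateCall(DotState.PINK)


def _all_colocalized(tet: np.ndarray, lac: np.ndarray, radius: float) -> bool:
    """True when both channels are detected and every pairwise centroid distance <= radius."""
    tet = np.asarray(tet, dtype=float).reshape(-1, 3)
    lac = np.asarray(lac, dtype=float).reshape(-1, 3)
    if len(tet) == 0 or len(lac) == 0:
        return False
    pts = np.vstack([tet, lac])
    for a, b in itertools.combinations(range(len(pts)), 2):
        if _pairwise_dist(pts[a], pts[b]) > radius:
            return False
    return True


def classify_series(cell: DotTimecourse,
                    config: ClassifierConfig = ClassifierConfig()) -> CellStateSeries:
    """Classify every time point of a cell and align to NEBD.

    After the per-timepoint calls, runs of >= ``black_min_run`` consecutive
    post-NEBD (t >= 0) time points in which all detected dots are mutually
    colocalized are relabelled BLACK ("nonresolved and compacted"); shorter
    runs keep their base call.
    """
    if cell.nebd_min is None or not math.isfinite(cell.nebd_min):
        raise ValueError(f"cell {cell.cell_id}: NEBD time is required for alignment")
    # snap to sub-microsecond so equal nominal times from different cells
    # collate exactly despite float round-trip error in absolute times
    t_rel = np.round(cell.times - cell.nebd_min, 6)
    calls = [classify_timepoint(tet, lac, config)
             for tet, lac in zip(cell.tetO, cell.lacO)]

    coloc = np.array([
        _all_colocalized(tet, lac, config.coloc_radius) and t >= 0
        for tet, lac, t in zip(cell.tetO, cell.lacO, t_rel)
    ])
    # relabel maximal runs of length >= black_min_run
    i = 0
    n = len(coloc)
    while i < n:
        if coloc[i]:
            j = i
            while j < n and coloc[j]:
                j += 1
            if j - i >= config.black_min_run:
                for k in range(i, j):
                    calls[k] = StateCall(DotState.BLACK)
            i = j
        else:
            i += 1

    end_s = None if cell.end_of_s_min is None else cell.end_of_s_min - cell.nebd_min
    return CellStateSeries(cell_id=cell.cell_id, t_rel=t_rel, calls=calls,
                           end_of_s_rel=end_s)


def proportions_over_time(cells: list[CellStateSeries]) -> ObservedProportionSeries:
    """Tally state calls per time point (relative to NEBD) over a cohort.

    UNDETERMINED calls are counted but never enter the classified denominator;
    proportions are over classified cells only.
    """
    if not cells:
        raise ValueError("at least one cell required")
    records: dict[float, dict[str, int]] = {}
    for cell in cells:
        for t, call in zip(cell.t_rel, cell.calls):
            rec = records.setdefault(round(float(t), 6), {s: 0 for s in ALL_STATES})
            rec[call.state.value] += 1
    rows = []
    for t in sorted(records):
        rec = records[t]
        n_cls = sum(rec[s] for s in CLASSIFIED_STATES)
        row = {"time_min": t}
        for s in ALL_STATES:
            row[f"n_{s.lower()}"] = rec[s]
        row["n_classified"] = n_cls
        for s in CLASSIFIED_STATES:
            row[f"p_{s.lower()}"] = rec[s] / n_cls if n_cls > 0 else np.nan
        rows.append(row)
    return ObservedProportionSeries(table=pd.DataFrame(rows))


def rolling_mean_smooth(series: pd.DataFrame | pd.Series, window: int):
    """Centered rolling mean over ``window`` minutes; edges use the points available.

    ``window`` must be odd so the window centers on a grid point; window 1 is
    the identity.  Operates column-wise on DataFrames.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    return series.rolling(window=window, center=True, min_periods=1).mean()


def smooth_proportions(obs: ObservedProportionSeries, window: int) -> pd.DataFrame:
    """Smoothed copy of the proportion columns, raw table untouched."""
    cols = [f"p_{s.lower()}" for s in CLASSIFIED_STATES]
    out = obs.table[["time_min"]].copy()
    out[cols] = rolling_mean_smooth(obs.table[cols], window)
    return out


def assign_phase(t: float, nebd: float, end_of_s: float) -> str:
    """Cell-cycle phase of absolute time t given NEBD and end-of-S times.

    prophase = the 20 min before NEBD; late G2 = the 120 min before prophase;
    early G2 = the first 90 min after the end of S; late S = the last 30 min
    of S; everything else is "other".
    """
    if not end_of_s < nebd:
        raise ValueError("end of S phase must precede NEBD")
    if nebd - 20 <= t < nebd:
        return "prophase"
    if nebd - 140 <= t < nebd - 20:
        return "late G2"
    if end_of_s <= t < end_of_s + 90:
        return "early G2"
    if end_of_s - 30 <= t < end_of_s:
        return "late S"
    return "other"


def phase_compare(table) -> tuple[float, float, int]:
    """Pearson chi-square test (no continuity correction) on a condition x state count table.

    Returns (statistic, p_value, dof).  Rows or columns summing to zero are
    rejected: the test is undefined on degenerate margins.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, dof, _ = _scipy_stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def separation_asymmetry(cells: list[CellStateSeries], phase: str,
                         nebd_rel: float = 0.0) -> dict[str, float | int]:
    """Fraction of BROWN time points in a phase whose separated channel is tetO vs lacO.

    Phases are evaluated on NEBD-relative time with each cell's own end-of-S
    time; cells lacking one fall back to phases defined by NEBD alone
    (prophase / late G2).  Returns {"tetO": f, "lacO": 1-f, "n": count}; with
    no BROWN calls in the phase, both fractions are NaN and n is 0.
    """
    n_tet = 0
    n_lac = 0
    for cell in cells:
        for t, call in zip(cell.t_rel, cell.calls):
            if call.state is not DotState.BROWN:
                continue
            if cell.end_of_s_rel is not None:
                ph = assign_phase(t, nebd_rel, cell.end_of_s_rel)
            else:
                if nebd_rel - 20 <= t < nebd_rel:
                    ph = "prophase"
                elif nebd_rel - 140 <= t < nebd_rel - 20:
                    ph = "late G2"
                else:
                    ph = "other"
            if ph != phase:
                continue
            if call.separated_channel == "tetO":
                n_tet += 1
            else:
                n_lac += 1
    n = n_tet + n_lac
    if n == 0:
        return {"tetO": math.nan, "lacO": math.nan, "n": 0}
    return {"tetO": n_tet / n, "lacO": n_lac / n, "n": n}
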