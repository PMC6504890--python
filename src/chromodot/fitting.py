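"""Least-squares fitting of the licensing model to observed state proportions.

The objective is the sum over in-window time points and over the three model
states of the squared difference between simulated and observed proportions.
The simulated proportions come from a Monte-Carlo population run with a fixed
common-random-numbers (CRN) seed reused across every objective evaluation of
a fit, which makes the objective a deterministic function of the parameters.
Parameters are optimized on the log scale (positivity without constraints)
with a quasi-Newton method; because the CRN surface is piecewise constant at
very fine scales, the finite-difference step for the numerical gradient is
deliberately wide (default 0.05 on the log scale, about 5% relative).

Uncertainty follows the study design: resample in-window time points with
replacement, refit, repeat B times (default 300), and summarize each
parameter's distribution by its median and a 1.5*IQR box plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .classify import ObservedProportionSeries
from .model import ModelParameters, PopulationProportions, TimeGrid, simulate_population

__all__ = [
    "FitWindow",
    "FitConfig",
    "FitResult",
    "BoxStats",
    "BootstrapResult",
    "observed_model_proportions",
    "objective_ss",
    "fit",
    "bootstrap_fit",
    "box_stats",
]

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("tau1", "tau2", "r1", "r2")
_PENALTY = 1e6  # objective value substituted for non-finite simulation output


@dataclass(frozen=True)
class FitWindow:
    """Time window (min, relative to NEBD) over which the objective is evaluated."""

    t_min: float = -50.0
    t_max: float = 30.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("window requires t_min < t_max")

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_min) & (t <= self.t_max)


@dataclass(frozen=True)
class FitConfig:
    window: FitWindow = field(default_factory=FitWindow)
    grid: TimeGrid = field(default_factory=TimeGrid)
    m_sim: int = 10_000
    optimizer: str = "L-BFGS-B"
    initial: ModelParameters = field(
        default_factory=lambda: ModelParameters(tau1=20.0, tau2=10.0, r1=0.1, r2=0.1)
    )
    crn_seed: int = 1234
    max_iter: int = 200
    tol: float = 1e-8
    fd_eps: float = 0.05  # finite-difference step on the log-parameter scale
    black_as_nonresolved: bool = False
    weight_by_count: bool = False
    effect: str = "next"

    def __post_init__(self) -> None:
        if self.m_sim < 1:
            raise ValueError("m_sim must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: ModelParameters
    objective: float
    converged: bool
    n_evaluations: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("sum of squares cannot be negative")


@dataclass(frozen=True)
class BoxStats:
    """Five-number box-plot summary with 1.5*IQR whiskers (type-7 quartiles)."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class BootstrapResult:
    samples: pd.DataFrame  # one row per repetition, columns tau1, tau2, r1, r2
    medians: ModelParameters
    boxes: dict[str, BoxStats]
    B_requested: int
    B_effective: int
    seed: int | None


def observed_model_proportions(observed: ObservedProportionSeries | pd.DataFrame,
                               black_as_nonresolved: bool = False) -> pd.DataFrame:
    """Project observed 5-state counts onto the model's 3 states.

    Brown "partially resolved" counts merge into nonresolved (the fitted model
    folds partial resolution into the nonresolved state).  Black counts are
    excluded from the denominator by default, since the model has no
    nonresolved-and-compacted state; ``black_as_nonresolved=True`` maps them
    to nonresolved instead.  Undetermined calls never enter the denominator.

    Returns columns time_min, p_nonresolved, p_resolved, p_compacted, n;
    time points with an empty denominator are dropped.
    """
    t = observed.table if isinstance(observed, ObservedProportionSeries) else observed
    n_non = t["n_blue"] + t["n_brown"]
    if black_as_nonresolved:
        n_non = n_non + t["n_black"]
    n = n_non + t["n_pink"] + t["n_red"]
    out = pd.DataFrame({
        "time_min": t["time_min"],
        "p_nonresolved": n_non / n,
        "p_resolved": t["n_pink"] / n,
        "p_compacted": t["n_red"] / n,
        "n": n.astype(int),
    })
    return out[out["n"] > 0].reset_index(drop=True)


def _window_table(observed, config: FitConfig) -> pd.DataFrame:
    tbl = observed_model_proportions(observed, config.black_as_nonresolved)
    tbl = tbl[config.window.contains(tbl["time_min"])].reset_index(drop=True)
    if tbl.empty:
        raise ValueError("no classified observed time points inside the fit window")
    times = tbl["time_min"].to_numpy()
    grid_idx = np.round((times - config.grid.t_start) / config.grid.dt).astype(int)
    on_grid = np.isclose(config.grid.t_start + grid_idx * config.grid.dt, times)
    if not (np.all(on_grid) and np.all((grid_idx >= 0) & (grid_idx < config.grid.n))):
        bad = times[~on_grid] if not np.all(on_grid) else times
        raise ValueError(f"observed time points must lie on the model grid; offending: {bad}")
    tbl["grid_index"] = grid_idx
    return tbl


def _objective_from_table(params: ModelParameters, tbl: pd.DataFrame,
                          config: FitConfig,
                          multiplicity: np.ndarray | None = None) -> float:
    sim = simulate_population(params, config.grid, m=config.m_sim,
                              seed=config.crn_seed, effect=config.effect)
    model = sim.stacked()[tbl["grid_index"].to_numpy()]
    obs = tbl[["p_nonresolved", "p_resolved", "p_compacted"]].to_numpy()
    sq = np.sum((model - obs) ** 2, axis=1)
    w = np.ones(len(tbl)) if multiplicity is None else np.asarray(multiplicity, float)
    if config.weight_by_count:
        w = w * tbl["n"].to_numpy()
    val = float(np.sum(w * sq))
    if not math.isfinite(val):
        logger.warning("non-finite objective at %s; substituting penalty %g",
                       params.as_dict(), _PENALTY)
        return _PENALTY
    return val


def objective_ss(params: ModelParameters, observed, config: FitConfig = FitConfig()) -> float:
    """Sum of squared proportion differences over in-window time points and 3 states."""
    return _objective_from_table(params, _window_table(observed, config), config)


def _fit_table(tbl: pd.DataFrame, config: FitConfig,
               multiplicity: np.ndarray | None = None,
               initial: ModelParameters | None = None) -> FitResult:
    x0 = np.log([getattr(initial or config.initial, p) for p in _PARAM_NAMES])
    n_eval = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        with np.errstate(over="ignore"):
            values = np.exp(x)
        if not np.all(np.isfinite(values)):
            return _PENALTY
        try:
            params = ModelParameters(*values)
        except (ValueError, OverflowError):
            return _PENALTY
        return _objective_from_table(params, tbl, config, multiplicity)

    options: dict = {"maxiter": config.max_iter}
    if config.optimizer in ("L-BFGS-B", "BFGS"):
        options["eps"] = config.fd_eps
    res = optimize.minimize(f, x0, method=config.optimizer, tol=config.tol,
                            options=options)
    best = ModelParameters(*np.exp(res.x))
    return FitResult(params=best, objective=float(res.fun), converged=bool(res.success),
                     n_evaluations=n_eval, message=str(res.message))


def fit(observed, config: FitConfig = FitConfig(),
        initial: ModelParameters | None = None) -> FitResult:
    """Minimize the CRN sum-of-squares objective over log-transformed parameters.

    Deterministic given the config (fixed CRN seed).  On non-convergence the
    best parameters found so far are still returned, with ``converged=False``.
    """
    return _fit_table(_window_table(observed, config), config, initial=initial)


def bootstrap_fit(observed, config: FitConfig = FitConfig(), B: int = 300,
                  seed: int | None = None) -> BootstrapResult:
    """Bootstrap the fit by resampling in-window time points with replacement.

    Each repetition draws as many time points as the original window contains;
    duplicated points contribute with their multiplicity, omitted points not
    at all.  Each refit starts from the configured initial parameters (not
    the full-data optimum: on the piecewise-constant CRN surface a refit
    started at an optimum stalls immediately and the bootstrap spread
    collapses).  Degenerate
    resamples collapsing onto a single time point are skipped and logged, so
    ``B_effective`` can be below ``B``.  The per-parameter median is the
    central estimate; dispersion is summarized by 1.5*IQR box statistics.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tbl = _window_table(observed, config)
    rng = np.random.default_rng(seed)
    n_pts = len(tbl)
    rows = []
    for b in range(B):
        idx = rng.integers(0, n_pts, size=n_pts)
        if n_pts > 1 and len(np.unique(idx)) == 1:
            logger.warning("bootstrap repetition %d degenerate (single time point); skipped", b)
            continue
        mult = np.bincount(idx, minlength=n_pts).astype(float)
        res = _fit_table(tbl, config, multiplicity=mult)
        rows.append(res.params.as_dict())
    samples = pd.DataFrame(rows, columns=list(_PARAM_NAMES))
    med = ModelParameters(**{p: float(samples[p].median()) for p in _PARAM_NAMES})
    boxes = {p: box_stats(samples[p].to_numpy()) for p in _PARAM_NAMES}
    return BootstrapResult(samples=samples, medians=med, boxes=boxes,
                           B_requested=B, B_effective=len(samples), seed=seed)


def box_stats(values) -> BoxStats:
    """Box-plot summary: type-7 quartiles, whiskers at the most extreme data
    values within 1.5*IQR of the box, points beyond listed as outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxStats(q1=float(q1), median=float(med), q3=float(q3),
                    whisker_low=float(inside.min()), whisker_high=float(inside.max()),
                    outliers=outliers)
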