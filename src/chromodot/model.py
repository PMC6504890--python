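"""Stochastic licensing/transition model of sister-chromatid resolution and compaction.

A marked chromosome region passes through three configurations during late G2
and early mitosis: nonresolved sisters, resolved sisters, and compacted
chromatids.  Each of the two transitions becomes *licensed* at a random time
drawn from an exponential distribution, and after licensing occurs
stochastically at a constant per-minute rate.  Time is measured in minutes
relative to nuclear envelope breakdown (NEBD, t = 0):

* licensing 1 at ``t1 = -Exp(tau1)`` (at or before NEBD); once ``t >= t1``
  the nonresolved -> resolved transition fires with per-step probability
  ``p1 = 1 - exp(-r1 * dt)``;
* licensing 2 at ``t2 = t1 + Exp(tau2)``; once the cell is resolved and
  ``t >= t2`` the resolved -> compacted transition fires with per-step
  probability ``p2 = 1 - exp(-r2 * dt)``.  Compaction can never precede
  resolution, even when licensing 2 fires first.

Simulating many cells on a fixed minute grid and tallying states per time
point yields population proportion curves that can be fitted to live-imaging
data (see :mod:`chromodot.fitting`).

Reported summaries: ``ST = tau1*ln2`` (median licensing-1 time before NEBD),
``TD = tau2*ln2`` (median delay of licensing 2 after licensing 1), rate
half-lives ``ln2/r`` and per-step probabilities ``1 - exp(-r*dt)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelState",
    "TimeGrid",
    "ModelParameters",
    "LicensingTimes",
    "ModelStateSequence",
    "PopulationProportions",
    "DerivedQuantities",
    "draw_licensing_times",
    "simulate_cell",
    "simulate_population",
    "derived_quantities",
]

_UNIFORMS_PER_CELL = 4  # lic1, lic2, resolution success, compaction success


class ModelState(enum.IntEnum):
    """The three configurations of the fitted model."""

    NONRESOLVED = 0
    RESOLVED = 1
    COMPACTED = 2


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid in minutes relative to NEBD (t = 0 at NEBD)."""

    t_start: float = -140.0
    t_end: float = 90.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (self.t_start < 0.0 < self.t_end):
            raise ValueError(
                f"grid must straddle NEBD (t=0): got [{self.t_start}, {self.t_end}]"
            )

    @property
    def n(self) -> int:
        """Number of grid points, endpoints inclusive (231 with defaults)."""
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n)

    def index_at_or_after(self, t: float) -> int:
        """First grid index k with ``times[k] >= t`` (clamped to [0, n])."""
        k = math.ceil((t - self.t_start) / self.dt - 1e-12)
        return min(max(k, 0), self.n)


@dataclass(frozen=True)
class ModelParameters:
    """Licensing time scales (min) and transition rates (min^-1)."""

    tau1: float
    tau2: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError(
                f"tau1 and tau2 must be strictly positive, got {self.tau1}, {self.tau2}"
            )
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError(f"rates must be non-negative, got {self.r1}, {self.r2}")

    def as_dict(self) -> dict[str, float]:
        return {"tau1": self.tau1, "tau2": self.tau2, "r1": self.r1, "r2": self.r2}


@dataclass(frozen=True)
class LicensingTimes:
    """Licensing times in minutes relative to NEBD; t_lic1 <= 0 <= ... t_lic2 >= t_lic1."""

    t_lic1: float
    t_lic2: float

    def __post_init__(self) -> None:
        if self.t_lic1 > 0:
            raise ValueError("licensing 1 must occur at or before NEBD")
        if self.t_lic2 < self.t_lic1:
            raise ValueError("licensing 2 cannot precede licensing 1")


@dataclass(frozen=True)
class ModelStateSequence:
    grid: TimeGrid
    states: np.ndarray  # int array of ModelState values, length grid.n
    licensing: LicensingTimes | None = None

    def __post_init__(self) -> None:
        if len(self.states) != self.grid.n:
            raise ValueError("state sequence length must equal grid size")


@dataclass(frozen=True)
class PopulationProportions:
    """Per-time-point state proportions over a simulated population of m cells."""

    grid: TimeGrid
    p_nonresolved: np.ndarray
    p_resolved: np.ndarray
    p_compacted: np.ndarray
    m: int
    seed: int | None = None

    def stacked(self) -> np.ndarray:
        """(n, 3) array ordered nonresolved, resolved, compacted."""
        return np.column_stack([self.p_nonresolved, self.p_resolved, self.p_compacted])


@dataclass(frozen=True)
class DerivedQuantities:
    """Reporting-scale summaries of the four model parameters."""

    ST: float  # tau1 * ln2, min before NEBD by which half the cells are licensed
    TD: float  # tau2 * ln2, median delay of licensing 2 after licensing 1
    r1_half_life: float  # ln2 / r1 (inf when r1 == 0)
    r2_half_life: float
    p1_step: float  # 1 - exp(-r1 * dt)
    p2_step: float
    dt: float = 1.0


def _exponential_icdf(u: float | np.ndarray, tau: float):
    """Inverse CDF of Exponential(scale tau) evaluated at u in [0, 1)."""
    return -tau * np.log1p(-u)


def _geometric_icdf(u, p):
    """Number of Bernoulli(p) trials until first success, inverse-CDF on u.

    Returns +inf where p == 0 (the transition can never fire) and 1 where
    p >= 1.  Vectorized over u and p.
    """
    u = np.asarray(u, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.empty(np.broadcast(u, p).shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        trials = np.floor(np.log1p(-u) / np.log1p(-p)) + 1.0
    out[...] = trials
    out = np.where(p <= 0.0, np.inf, out)
    out = np.where(p >= 1.0, 1.0, out)
    return np.maximum(out, 1.0)


def step_probability(r: float, dt: float) -> float:
    """Per-step transition probability ``1 - exp(-r * dt)``."""
    if r < 0:
        raise ValueError("rate must be non-negative")
    return -math.expm1(-r * dt)


def draw_licensing_times(params: ModelParameters, rng: np.random.Generator) -> LicensingTimes:
    """Draw the two licensing times for one cell.

    ``t_lic1 = -X1`` with ``X1 ~ Exp(tau1)`` and ``t_lic2 = t_lic1 + X2`` with
    ``X2 ~ Exp(tau2)``.  Consumes exactly two uniforms from ``rng`` via the
    inverse CDF, so a stubbed uniform stream gives deterministic times.
    """
    u = rng.random(2)
    x1 = float(_exponential_icdf(u[0], params.tau1))
    x2 = float(_exponential_icdf(u[1], params.tau2))
    return LicensingTimes(t_lic1=-x1, t_lic2=-x1 + x2)


def _transition_indices(us: np.ndarray, params: ModelParameters, grid: TimeGrid,
                        effect: str) -> tuple[np.ndarray, np.ndarray]:
    """Resolution/compaction effective grid indices for cells from uniforms.

    ``us`` has shape (m, 4): columns are the licensing-1 and licensing-2
    exponential uniforms and the resolution and compaction first-success
    uniforms.  An index >= grid.n means the transition never takes effect
    within the grid.

    The per-step Bernoulli chain is collapsed exactly to its geometric
    first-success law: trials for resolution start at the first grid point at
    or after t_lic1; with ``effect="next"`` a success at trial g makes the new
    state hold from the following grid point, with ``effect="current"`` from
    the trial's own grid point.  Compaction trials start once the cell is
    resolved and t >= t_lic2.
    """
    if effect not in ("next", "current"):
        raise ValueError(f"effect must be 'next' or 'current', got {effect!r}")
    t_lic1 = -_exponential_icdf(us[:, 0], params.tau1)
    t_lic2 = t_lic1 + _exponential_icdf(us[:, 1], params.tau2)

    p1 = step_probability(params.r1, grid.dt)
    p2 = step_probability(params.r2, grid.dt)

    # first trial index for resolution (t_lic1 <= 0 so always within grid)
    k1 = np.ceil((t_lic1 - grid.t_start) / grid.dt - 1e-12)
    k1 = np.clip(k1, 0, grid.n)
    g1 = _geometric_icdf(us[:, 2], p1)
    lag = 0.0 if effect == "current" else 1.0
    res_idx = k1 + g1 - 1.0 + lag

    # compaction trials start once resolved AND licensed-2
    k2 = np.ceil((t_lic2 - grid.t_start) / grid.dt - 1e-12)
    k2 = np.clip(k2, 0, grid.n)
    first_cmp_trial = np.maximum(res_idx + (1.0 - lag), k2)
    g2 = _geometric_icdf(us[:, 3], p2)
    cmp_idx = first_cmp_trial + g2 - 1.0 + lag

    n = float(grid.n)
    res_idx = np.minimum(res_idx, n)
    cmp_idx = np.minimum(np.maximum(cmp_idx, res_idx), n)
    return res_idx, cmp_idx


def simulate_cell(params: ModelParameters, grid: TimeGrid,
                  rng: np.random.Generator, *, effect: str = "next") -> ModelStateSequence:
    """Simulate one cell's state sequence over the grid.

    Consumes exactly four uniforms (two licensing draws, two first-success
    draws), making single-cell behaviour fully deterministic under a stubbed
    uniform stream.  ``effect`` pins when a successful transition draw takes
    effect: ``"next"`` (default; new state from the following grid point) or
    ``"current"``.
    """
    us = np.asarray(rng.random(_UNIFORMS_PER_CELL), dtype=float).reshape(1, 4)
    res_idx, cmp_idx = _transition_indices(us, params, grid, effect)
    k = np.arange(grid.n)
    states = np.full(grid.n, int(ModelState.NONRESOLVED), dtype=np.int8)
    states[k >= res_idx[0]] = int(ModelState.RESOLVED)
    states[k >= cmp_idx[0]] = int(ModelState.COMPACTED)
    t1 = float(-_exponential_icdf(us[0, 0], params.tau1))
    t2 = t1 + float(_exponential_icdf(us[0, 1], params.tau2))
    return ModelStateSequence(grid=grid, states=states,
                              licensing=LicensingTimes(t_lic1=t1, t_lic2=t2))


def simulate_population(params: ModelParameters, grid: TimeGrid, m: int = 10_000,
                        seed: int | None = None, *,
                        effect: str = "next") -> PopulationProportions:
    """Simulate ``m`` cells and return per-time-point state proportions.

    Cell i consumes row i of an (m, 4) uniform block drawn from one seeded
    generator, so results are bit-identical across runs with the same seed and
    identical to ``m`` calls of :func:`simulate_cell` on the corresponding
    stubbed rows.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    us = rng.random((m, _UNIFORMS_PER_CELL))
    res_idx, cmp_idx = _transition_indices(us, params, grid, effect)

    n = grid.n
    # count cells resolved/compacted at or before each grid index
    res_clipped = np.minimum(res_idx, n).astype(np.int64)
    cmp_clipped = np.minimum(cmp_idx, n).astype(np.int64)
    res_counts = np.cumsum(np.bincount(res_clipped, minlength=n + 1))[:n]
    cmp_counts = np.cumsum(np.bincount(cmp_clipped, minlength=n + 1))[:n]

    p_cmp = cmp_counts / m
    p_res = (res_counts - cmp_counts) / m
    p_non = (m - res_counts) / m
    return PopulationProportions(grid=grid, p_nonresolved=p_non, p_resolved=p_res,
                                 p_compacted=p_cmp, m=m, seed=seed)


def derived_quantities(params: ModelParameters, dt: float = 1.0) -> DerivedQuantities:
    """Convert model parameters to the reported summaries (ST, TD, half-lives, step probabilities)."""
    ln2 = math.log(2.0)
    return DerivedQuantities(
        ST=params.tau1 * ln2,
        TD=params.tau2 * ln2,
        r1_half_life=(ln2 / params.r1) if params.r1 > 0 else math.inf,
        r2_half_life=(ln2 / params.r2) if params.r2 > 0 else math.inf,
        p1_step=step_probability(params.r1, dt),
        p2_step=step_probability(params.r2, dt),
        dt=dt,
    )
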