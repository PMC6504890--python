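"""Synthetic live-imaging cohorts with known ground truth.

The generator produces per-cell dot-coordinate time courses with the
statistical structure the analysis pipeline assumes, so classification,
proportion estimation, fitting and bootstrap can all be exercised without
microscopy data:

* each cell's three-state trajectory comes from the licensing model
  (:mod:`chromodot.model`);
* a two-state telegraph overlay produces transient "partially resolved"
  (brown) episodes on top of the nonresolved state within a configurable
  pre-NEBD window - episodes start as a Poisson process, last an
  exponential few minutes, and separate the tetO channel with a configurable
  bias;
* each observable state is rendered as 3D centroids whose distances are
  drawn from truncated log-normal bands kept a safety margin away from the
  classifier thresholds, so the noiseless rendering classifies back to the
  truth exactly;
* isotropic Gaussian centroid noise and random undetermined time points
  emulate measurement imperfections.

Defaults reflect the study conditions: wild-type parameters tau1 = 18.0 min,
tau2 = 9.3 min, r1 = 0.065/min (r2 = 0.12/min, an assumption - see the
methods note), ~40-cell cohorts, brown episodes of mean 2 min occupying ~20%
of eligible late-G2 time, active up to 120 min before NEBD, 80% tetO bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import DotTimecourse
from .model import (LicensingTimes, ModelParameters, ModelState, TimeGrid,
                    simulate_cell)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "telegraph_occupancy",
    "generate_truth",
    "render_coordinates",
    "generate_dataset",
]

WT_PARAMS = ModelParameters(tau1=18.0, tau2=9.3, r1=0.065, r2=0.12)


@dataclass(frozen=True)
class SyntheticConfig:
    params: ModelParameters = WT_PARAMS
    grid: TimeGrid = field(default_factory=TimeGrid)
    n_cells: int = 50
    nebd_jitter_min: float = 15.0  # spread of absolute NEBD times across cells
    g2_length_min: float = 360.0   # end of S precedes NEBD by this much
    # observation spans: a fraction of cells covers the whole grid at each
    # end; the rest enter after the grid start / leave before the grid end,
    # giving per-time-point counts that rise toward NEBD (~15 at the edges,
    # ~50 at NEBD, mean ~33, emulating the study's 15-55 range)
    frac_full_start: float = 0.3
    frac_full_end: float = 0.3
    # telegraph overlay (brown episodes)
    episode_rate: float = 0.125        # starts per minute while nonresolved
    episode_mean_duration: float = 2.0  # minutes
    cycling_window: float = 120.0       # episodes active this long before NEBD
    tetO_bias: float = 0.8              # P(episode separates tetO)
    # geometry bands (um); margins keep noiseless classification unambiguous
    nonres_sister_band: tuple[float, float] = (0.20, 0.60)
    separated_band: tuple[float, float] = (1.10, 1.60)
    coloc_pair_band: tuple[float, float] = (0.02, 0.12)
    noncoloc_pair_band: tuple[float, float] = (0.65, 1.00)
    p_subthreshold_doublet: float = 0.3
    separation_threshold: float = 0.85
    coloc_radius: float = 0.40
    # measurement imperfections
    noise_sigma: float = 0.05
    undetermined_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tetO_bias", "undetermined_rate", "p_subthreshold_doublet"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.episode_rate < 0 or self.episode_mean_duration <= 0:
            raise ValueError("episode rate must be >= 0 and mean duration > 0")
        if self.nonres_sister_band[1] > self.separation_threshold:
            raise ValueError("nonresolved sister band must stay below the separation threshold")
        if self.separated_band[0] < self.separation_threshold:
            raise ValueError("separated band must stay above the separation threshold")
        if self.coloc_pair_band[1] > self.coloc_radius:
            raise ValueError("colocalized pair band must stay within the coloc radius")
        if self.noncoloc_pair_band[0] < self.coloc_radius:
            raise ValueError("non-colocalized pair band must stay outside the coloc radius")


@dataclass
class GroundTruth:
    """One cell's generating state: model states plus the brown overlay."""

    cell_id: str
    nebd_abs_min: float
    end_of_s_abs_min: float
    t_rel: np.ndarray                 # minutes relative to NEBD (grid times)
    model_states: np.ndarray          # ModelState ints
    observable_states: list[str]      # BLUE/BROWN/PINK/RED
    separated_channel: list[str | None]  # set on BROWN points
    licensing: LicensingTimes
    episodes: list[tuple[float, float, str]]  # (start, end, channel), rel. NEBD


_MODEL_TO_OBS = {
    int(ModelState.NONRESOLVED): "BLUE",
    int(ModelState.RESOLVED): "PINK",
    int(ModelState.COMPACTED): "RED",
}


def telegraph_occupancy(rate: float, mean_duration: float) -> float:
    """Stationary brown occupancy of the alternating renewal overlay, rate*dur/(1+rate*dur)."""
    x = rate * mean_duration
    return x / (1.0 + x)


def _episodes_for_cell(cfg: SyntheticConfig, rng: np.random.Generator
                       ) -> list[tuple[float, float, str]]:
    """Alternating renewal (off ~ Exp(1/rate), on ~ Exp(mean_duration)) over
    the cycling window [-cycling_window, 0), started at stationarity."""
    if cfg.episode_rate == 0.0:
        return []
    t = -cfg.cycling_window
    episodes: list[tuple[float, float, str]] = []
    pi = telegraph_occupancy(cfg.episode_rate, cfg.episode_mean_duration)
    in_episode = rng.random() < pi
    while t < 0.0:
        if in_episode:
            end = min(t + rng.exponential(cfg.episode_mean_duration), 0.0)
            channel = "tetO" if rng.random() < cfg.tetO_bias else "lacO"
            episodes.append((t, end, channel))
            t = end
            in_episode = False
        else:
            t = t + rng.exponential(1.0 / cfg.episode_rate)
            in_episode = True
    return episodes


def generate_truth(config: SyntheticConfig) -> list[GroundTruth]:
    """Simulate the cohort's ground-truth state sequences.

    The brown overlay is only visible while the model state is NONRESOLVED
    and the time point falls inside the cycling window; elsewhere the
    observable state equals the model state (blue/pink/red).
    """
    rng = np.random.default_rng(config.seed)
    truths = []
    times = config.grid.times
    for i in range(config.n_cells):
        seq = simulate_cell(config.params, config.grid, rng)
        episodes = _episodes_for_cell(config, rng)
        nebd_abs = 500.0 + float(rng.uniform(0.0, config.nebd_jitter_min))
        if rng.random() < config.frac_full_start:
            t_first = config.grid.t_start
        else:
            t_first = float(rng.uniform(config.grid.t_start, 0.0))
        if rng.random() < config.frac_full_end:
            t_last = config.grid.t_end
        else:
            t_last = float(rng.uniform(0.0, config.grid.t_end))
        span = (times >= t_first) & (times <= t_last)
        obs = []
        sep = []
        for t, s in zip(times, seq.states):
            state = _MODEL_TO_OBS[int(s)]
            channel = None
            if (s == int(ModelState.NONRESOLVED) and -config.cycling_window <= t < 0.0):
                for a, b, ch in episodes:
                    if a <= t < b:
                        state, channel = "BROWN", ch
                        break
            obs.append(state)
            sep.append(channel)
        obs = [o for o, keep in zip(obs, span) if keep]
        sep = [c for c, keep in zip(sep, span) if keep]
        truths.append(GroundTruth(
            cell_id=f"cell{i:03d}", nebd_abs_min=nebd_abs,
            end_of_s_abs_min=nebd_abs - config.g2_length_min,
            t_rel=times[span].copy(), model_states=seq.states[span].copy(),
            observable_states=obs, separated_channel=sep,
            licensing=seq.licensing, episodes=episodes))
    return truths


def _band_sample(rng: np.random.Generator, band: tuple[float, float]) -> float:
    """Truncated log-normal on [lo, hi] (rejection, clipped as a last resort)."""
    lo, hi = band
    mu = math.log(math.sqrt(lo * hi))
    for _ in range(64):
        x = float(rng.lognormal(mu, 0.25))
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perp_unit(rng: np.random.Generator, axis: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= v.dot(axis) * axis
    n = np.linalg.norm(v)
    if n < 1e-12:  # pragma: no cover - measure-zero redraw
        return _perp_unit(rng, axis)
    return v / n


def _channel_points(rng, center, cfg, doublet_allowed: bool) -> np.ndarray:
    """Single object, or a sub-threshold sister doublet with configured probability."""
    if doublet_allowed and rng.random() < cfg.p_subthreshold_doublet:
        d = _band_sample(rng, cfg.nonres_sister_band)
        u = _unit(rng)
        return np.vstack([center - 0.5 * d * u, center + 0.5 * d * u])
    return center.reshape(1, 3)


def _render_timepoint(state: str, channel: str | None, cfg: SyntheticConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free centroids for one observable state; inverse of the classifier rules."""
    anchor = rng.uniform(0.0, 10.0, size=3)
    if state == "BLUE":
        offset = _band_sample(rng, cfg.noncoloc_pair_band) * _unit(rng)
        tet = _channel_points(rng, anchor, cfg, doublet_allowed=True)
        lac = _channel_points(rng, anchor + offset, cfg, doublet_allowed=True)
        return tet, lac
    if state == "BROWN":
        d = _band_sample(rng, cfg.separated_band)
        u = _unit(rng)
        doublet = np.vstack([anchor - 0.5 * d * u, anchor + 0.5 * d * u])
        other_center = anchor + _band_sample(rng, cfg.noncoloc_pair_band) * _perp_unit(rng, u)
        other = _channel_points(rng, other_center, cfg, doublet_allowed=True)
        return (doublet, other) if channel == "tetO" else (other, doublet)
    # resolved (PINK) and compacted (RED): two sister units along a random
    # axis; lacO offset perpendicular so sister-sister distances stay >= the
    # unit separation regardless of the offsets.
    d = _band_sample(rng, cfg.separated_band)
    axis = _unit(rng)
    centers = [anchor - 0.5 * d * axis, anchor + 0.5 * d * axis]
    band = cfg.coloc_pair_band if state == "RED" else cfg.noncoloc_pair_band
    tet = np.vstack(centers)
    lac = np.vstack([c + _band_sample(rng, band) * _perp_unit(rng, axis) for c in centers])
    return tet, lac


def render_coordinates(truths: list[GroundTruth],
                       config: SyntheticConfig) -> list[DotTimecourse]:
    """Render noisy centroid time courses from ground truth.

    Gaussian noise of ``noise_sigma`` is added per coordinate; at the
    configured undetermined rate one randomly chosen channel loses its dots
    for that time point, producing an UNDETERMINED call downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cells = []
    for truth in truths:
        tets, lacs = [], []
        for state, channel in zip(truth.observable_states, truth.separated_channel):
            tet, lac = _render_timepoint(state, channel, config, rng)
            tet = tet + rng.normal(0.0, config.noise_sigma, size=tet.shape)
            lac = lac + rng.normal(0.0, config.noise_sigma, size=lac.shape)
            if rng.random() < config.undetermined_rate:
                if rng.random() < 0.5:
                    tet = np.empty((0, 3))
                else:
                    lac = np.empty((0, 3))
            tets.append(tet)
            lacs.append(lac)
        cells.append(DotTimecourse(
            cell_id=truth.cell_id, times=truth.t_rel + truth.nebd_abs_min,
            tetO=tets, lacO=lacs, nebd_min=truth.nebd_abs_min,
            end_of_s_min=truth.end_of_s_abs_min))
    return cells


def generate_dataset(config: SyntheticConfig, outdir: str | Path
                     ) -> dict[str, Path]:
    """Generate a cohort and write coordinates/metadata/truth CSVs.

    Returns the three file paths.  The seed is embedded in each file so any
    artifact can be regenerated bit-identically.
    """
    from . import io as cio  # deferred: io imports classify, not synth

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = generate_truth(config)
    cells = render_coordinates(truths, config)
    paths = {
        "coordinates": outdir / "coordinates.csv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.csv",
    }
    cio.write_coordinates(cells, paths["coordinates"], seed=config.seed)
    cio.write_cell_metadata(cells, paths["metadata"], seed=config.seed)
    cio.write_truth(truths, paths["truth"], seed=config.seed)
    return paths
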