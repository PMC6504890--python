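import numpy as np
import pytest

from chromodot.classify import classify_series, proportions_over_time
from chromodot.model import ModelParameters, TimeGrid
from chromodot.synth import SyntheticConfig, generate_truth, render_coordinates


class StubRNG:
    """Minimal uniform-stream stub: hands out preset values in order."""

    def __init__(self, values):
        self._values = list(values)

    def random(self, n=None):
        if n is None:
            return self._values.pop(0)
        out = np.array([self._values.pop(0) for _ in range(n)], dtype=float)
        return out


@pytest.fixture(scope="session")
def wt_params() -> ModelParameters:
    return ModelParameters(tau1=18.0, tau2=9.3, r1=0.065, r2=0.12)


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def wt_cohort():
    """One default synthetic cohort, classified: (config, truths, cells, series, obs)."""
    cfg = SyntheticConfig(seed=11)
    truths = generate_truth(cfg)
    cells = render_coordinates(truths, cfg)
    series = [classify_series(c) for c in cells]
    obs = proportions_over_time(series)
    return cfg, truths, cells, series, obs


def analytic_nonresolved(tau1: float, r1: float, grid: TimeGrid) -> np.ndarray:
    """Semi-analytic P(nonresolved; t_k) for the r2-free stage.

    Integrates over the exponential licensing-1 density: licensing in the
    grid interval ending at t_j has probability e^{t_j/tau1} - e^{t_j-1/tau1}
    (t <= 0), after which each elapsed step fails to resolve with probability
    (1-p1).  Independent of the simulator's code path.
    """
    times = grid.times
    p1 = 1.0 - np.exp(-r1 * grid.dt)
    k0 = int(np.searchsorted(times, 0.0))
    w = np.zeros(k0 + 1)
    w[0] = np.exp(times[0] / tau1)
    for j in range(1, k0 + 1):
        w[j] = np.exp(min(times[j], 0.0) / tau1) - np.exp(times[j - 1] / tau1)
    p = np.zeros(grid.n)
    for k in range(grid.n):
        js = np.arange(k0 + 1)
        p[k] = np.sum(w * (1.0 - p1) ** np.maximum(0, k - js))
    return p
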