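import numpy as np
import pytest

from ceusflow.cine import TimeIntensityCurve
from ceusflow.synthetic import CineConfig, TissueMap, simulate_cine


def make_tic(
    O: float,
    A: float,
    beta: float,
    t_f: float = 3.0,
    fps: float = 15.0,
    post_duration: float = 15.0,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeIntensityCurve:
    """Replenishment-model TIC sampled on a regular grid, with optional
    multiplicative log-normal noise of unit mean."""
    n = int(round((t_f + post_duration) * fps))
    t = np.arange(n) / fps
    y = np.where(t >= t_f, O + A * (1.0 - np.exp(-beta * np.maximum(t - t_f, 0.0))), O)
    if sigma > 0:
        y = y * np.exp(rng.standard_normal(y.size) * sigma - sigma**2 / 2.0)
    return TimeIntensityCurve(times_s=t, intensities_au=y)


@pytest.fixture
def small_cine_config():
    return CineConfig(height_px=8, width_px=8, baseline_duration_s=1.0, noise_sigma=0.0, seed=0)


@pytest.fixture
def uniform_clip(small_cine_config):
    tissue = TissueMap.uniform(small_cine_config.shape, amplitude=2.0, rate=0.5, offset=0.0)
    return simulate_cine(small_cine_config, tissue)
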