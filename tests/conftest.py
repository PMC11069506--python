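import numpy as np
import pytest

from ptoct import PhantomLayout, SimulationConfig, simulate_phantom_mscan


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    """All noise off and an effectively instantaneous thermal transient, so
    every pixel's trace is a pure steady-state sinusoid plus DC plateau."""
    return SimulationConfig(
        phase_noise_floor_rad=0.0,
        pink_noise_scale_rad=0.0,
        intensity_speckle_db=0.0,
        transient_tau_s=1e-7,
    )


@pytest.fixture(scope="session")
def small_layout() -> PhantomLayout:
    return PhantomLayout.bands(n_depth=40, n_lateral=24, surface_row=4)


@pytest.fixture(scope="session")
def noiseless_cube(noiseless_config, small_layout):
    return simulate_phantom_mscan(small_layout, noiseless_config, seed=11)


@pytest.fixture(scope="session")
def noisy_cube(small_layout):
    cfg = SimulationConfig()
    return simulate_phantom_mscan(small_layout, cfg, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
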