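import numpy as np
import pytest

from gevikit import (
    DecaySimSpec,
    TrajSimSpec,
    simulate_decay_trace,
    simulate_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flim_decay():
    """Four-component FLIM-like decay with Poisson noise and its IRF."""
    spec = DecaySimSpec(
        lifetimes=(90.0, 300.0, 790.0, 2850.0),
        amplitudes=(0.895 / 90, 0.04 / 300, 0.01 / 790, 0.055 / 2850),
        irf_fwhm=60.0,
        peak_counts=1e5,
        seed=21,
    )
    return simulate_decay_trace(spec)


@pytest.fixture
def scripted_traj():
    """Deterministic toy trajectory: 30% H-bond occupancy, 50% inward flips,
    a ramping water schedule."""
    spec = TrajSimSpec(
        n_frames=200,
        frame_dt=1.0,
        hbond_occupancy=0.30,
        inward_fraction=0.5,
        waters_in_pocket=tuple(i % 4 for i in range(200)),
        geometry_noise=0.0,
        seed=7,
    )
    return simulate_trajectory(spec)
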