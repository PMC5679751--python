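import numpy as np
import pytest

from gastrotrack import DirectionConvention, EmbryoGeometry, SimulationParams


@pytest.fixture
def geom():
    """Canonical upright frame: vegetal at origin, animal up, dorsal +x."""
    return EmbryoGeometry(
        animal_pole=np.array([0.0, 600.0]),
        vegetal_pole=np.array([0.0, 0.0]),
        dorsal_ref=np.array([300.0, 300.0]),
        height=600.0,
        width=600.0,
    )


@pytest.fixture
def conv():
    return DirectionConvention()


@pytest.fixture
def small_params():
    """Quick simulation: short movie, no lineage events."""
    return SimulationParams(
        n_cells=20,
        duration=60.0,
        frame_interval=2.0,
        division_prob_per_window=0.0,
        death_prob_per_window=0.0,
        seed=7,
    )


def rigid_transform(rng):
    """Random rotation + translation as (R, t)."""
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = rng.uniform(-500, 500, 2)
    return R, t
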