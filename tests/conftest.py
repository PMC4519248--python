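import numpy as np
import pytest

from fintrace.trajectory import Trajectory


def make_trajectory(
    x,
    y,
    fps=25.0,
    body_length_cm=4.0,
    tank_width_cm=18.0,
    tank_height_cm=24.0,
    fish_id="fish",
    genotype="WT",
    age_group="9mpf",
    frame_index=None,
):
    x = np.asarray(x, dtype=float)
    if frame_index is None:
        frame_index = np.arange(len(x))
    return Trajectory(
        fish_id=fish_id,
        genotype=genotype,
        age_group=age_group,
        fps=fps,
        body_length_cm=body_length_cm,
        tank_width_cm=tank_width_cm,
        tank_height_cm=tank_height_cm,
        frame_index=frame_index,
        x_cm=x,
        y_cm=np.asarray(y, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_trajectory(rng):
    """A 1000-frame random walk strictly inside the tank."""
    n = 1000
    x = np.clip(9 + np.cumsum(rng.normal(0, 0.1, n)), 0, 18)
    y = np.clip(12 + np.cumsum(rng.normal(0, 0.1, n)), 0, 24)
    return make_trajectory(x, y)
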