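import warnings

import numpy as np
import pytest

from circumkin.simulate import PlantSimConfig, simulate_plant


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Boundary variance fits legitimately warn; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def noiseless_plant():
    return simulate_plant(PlantSimConfig(noise_sd_mm=0.0, seed=0))


@pytest.fixture(scope="session")
def noiseless_flip_plant():
    cfg = PlantSimConfig(
        noise_sd_mm=0.0,
        directions=(
            (1, 1, 1, 1, 1, 1),
            (1, 1, 1, 1, 1, 1),
            (1, 1, -1, -1, 1),
            (1, -1, 1, -1, 1),
            (1, 1, -1, -1),
        ),
        seed=0,
    )
    return simulate_plant(cfg)


def circle_path(n: int, radius: float = 10.0, clockwise: bool = False, closed: bool = True):
    """Sampled circle; with ``closed`` the last point repeats the first."""
    from circumkin.kinematics import PlanarPath

    theta = 2.0 * np.pi * np.arange(n + 1) / n
    if clockwise:
        theta = -theta
    pts = radius * np.c_[np.cos(theta), np.sin(theta)]
    pts[-1] = pts[0]
    if not closed:
        pts = pts[:-1]
    return PlanarPath(np.arange(len(pts)) * 3.0, pts)
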