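import numpy as np
import pytest

from auglam import GridSpec, Volume3D
from auglam.pipeline import DemoConfig, run_al_experiment

_RUN_CACHE: dict = {}


@pytest.fixture(scope="session")
def al_run():
    """Cached access to full simulated CL/CT/AL experiments by seed.

    The default experiment (128×128×32 flat phantom, θ=29.8°, 5×
    magnification ratio, 360 projections) takes a couple of minutes per
    seed, so runs are shared across the whole session.
    """

    def get(seed: int = 1) -> dict:
        if seed not in _RUN_CACHE:
            _RUN_CACHE[seed] = run_al_experiment(DemoConfig(), seed=seed)
        return _RUN_CACHE[seed]

    return get


@pytest.fixture
def gaussian_volume():
    """Factory for smooth, compactly supported test volumes."""

    def make(shape=(32, 32, 32), voxel_size=1.0, amplitude=0.05, sigma=None,
             center=(0.0, 0.0, 0.0)) -> Volume3D:
        grid = GridSpec(shape, voxel_size)
        X, Y, Z = grid.coords()
        if sigma is None:
            sigma = min(shape) * voxel_size / 6
        cx, cy, cz = center
        data = amplitude * np.exp(
            -(((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * sigma**2))
        )
        return Volume3D(data, voxel_size)

    return make


@pytest.fixture
def sphere_volume():
    """Factory for uniform-sphere phantoms (known chord lengths)."""

    def make(n=48, radius=16.0, mu=0.05, voxel_size=1.0) -> Volume3D:
        grid = GridSpec((n, n, n), voxel_size)
        X, Y, Z = grid.coords()
        data = np.where(X**2 + Y**2 + Z**2 <= radius**2, mu, 0.0)
        return Volume3D(data, voxel_size)

    return make
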