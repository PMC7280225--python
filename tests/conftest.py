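import numpy as np
import pytest

from memfes.core import CVSpace, GridSpec, ThermoContext


@pytest.fixture(scope="session")
def thermo300():
    return ThermoContext(temperature=300.0, bias_factor=10.0)


@pytest.fixture
def cv_space():
    return CVSpace(ranges=((-np.pi, np.pi), (0.0, 4.0)))


@pytest.fixture
def small_grid(cv_space):
    return GridSpec(cv_space=cv_space, bins=(48, 32))


def make_flat_square_grid(n: int = 12, extent: float = 1.2) -> GridSpec:
    """Non-periodic n x n grid on [0, extent]^2 for toy landscape tests."""
    space = CVSpace(
        names=("s1", "s2"),
        periodic=(False, False),
        ranges=((0.0, extent), (0.0, extent)),
    )
    return GridSpec(cv_space=space, bins=(n, n))


def random_gaussian_landscape(rng: np.random.Generator, n: int = 15, n_bumps: int = 6):
    """Smooth random landscape: sum of isotropic Gaussian bumps/wells."""
    from memfes.landscape import FESGrid

    grid = make_flat_square_grid(n, extent=1.0)
    X, Y = grid.mesh()
    F = np.zeros((n, n))
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0, 1, 2)
        s = rng.uniform(0.08, 0.3)
        h = rng.uniform(-12, 12)
        F += h * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s * s))
    return FESGrid(grid=grid, values=F, thermo=ThermoContext())


@pytest.fixture(scope="session")
def fixture_fes():
    """The four-basin membrane fixture on the default analysis grid,
    zero-referenced at bulk water."""
    from memfes.core import default_grid
    from memfes.landscape import set_zero_reference
    from memfes.toysim import make_melatonin_like_fes

    fes = make_melatonin_like_fes(default_grid())
    return set_zero_reference(fes, (0.0, 4.0))
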