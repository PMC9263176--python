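import numpy as np
import pytest

from sotdr.actigraphy_io import MINUTES_PER_DAY, ActigraphyPanel, StudyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_panel():
    """Two days, every minute equal to 7.5."""
    return ActigraphyPanel("const", np.full((2, MINUTES_PER_DAY), 7.5))


def make_panel(values, subject_id="s1"):
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[None, :]
    return ActigraphyPanel(subject_id, values)


@pytest.fixture
def ramp_panel():
    """One day; minute m has value m (1..1440)."""
    return make_panel(np.arange(1, MINUTES_PER_DAY + 1, dtype=float))


def make_study(y, Z=None, family="gaussian"):
    y = np.asarray(y, float)
    n = y.size
    Z = np.empty((n, 0)) if Z is None else np.atleast_2d(np.asarray(Z, float))
    return StudyTable([f"s{i:04d}" for i in range(n)], y, Z, family)


@pytest.fixture
def gp_curves():
    """Full-rank smooth random curves on a 144-point diurnal grid."""
    grid = np.linspace(0.0, 24.0, 144)
    D = np.abs(grid[:, None] - grid[None, :])
    K = np.exp(-((D / 2.0) ** 2) / 2)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(grid.size))

    def gen(n, seed=0, mean=2.0):
        r = np.random.default_rng(seed)
        return grid, mean + r.normal(size=(n, grid.size)) @ L.T

    return gen
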