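import numpy as np
import pandas as pd
import pytest

from fjordconn import ScenarioConfig, SeedingSchedule, VelocityField


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Small but fully featured scenario configuration."""
    return ScenarioConfig(n_fjords=6, grid_nx=48, grid_ny=16,
                          n_asv_pro=80, n_asv_euk=80, seq_depth=5000, seed=11)


@pytest.fixture
def tiny_schedule():
    return SeedingSchedule(cohort_interval=10, floats_per_cohort=20,
                           lifetime=60, n_cohorts=2)


def make_uniform_field(c=5.0, nx=20, ny=20, n_days=40, cell=1.0, v=0.0):
    """All-ocean field with constant velocity (c, v)."""
    x = (np.arange(nx) + 0.5) * cell
    y = (np.arange(ny) + 0.5) * cell
    time = np.arange(n_days, dtype=float)
    u = np.full((n_days, ny, nx), float(c))
    vv = np.full((n_days, ny, nx), float(v))
    mask = np.ones((ny, nx), dtype=bool)
    return VelocityField(x=x, y=y, time=time, u=u, v=vv, mask=mask)


def make_rotation_field(omega, nx=41, ny=41, n_days=200, cell=1.0):
    """Solid-body rotation around the grid centre: u = -w*(y-yc), v = w*(x-xc)."""
    x = (np.arange(nx) + 0.5) * cell
    y = (np.arange(ny) + 0.5) * cell
    xc, yc = x.mean(), y.mean()
    X, Y = np.meshgrid(x, y)
    u1 = -omega * (Y - yc)
    v1 = omega * (X - xc)
    time = np.arange(n_days, dtype=float)
    u = np.broadcast_to(u1, (n_days, ny, nx)).copy()
    v = np.broadcast_to(v1, (n_days, ny, nx)).copy()
    mask = np.ones((ny, nx), dtype=bool)
    return VelocityField(x=x, y=y, time=time, u=u, v=v, mask=mask), (xc, yc)


@pytest.fixture
def random_counts(rng):
    """Random small ASV count table with guaranteed >= 2 nonzero per sample."""
    def make(n_samples=6, n_asvs=12, depth=500, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        p = r.dirichlet(np.ones(n_asvs) * 0.6, size=n_samples)
        counts = np.vstack([r.multinomial(depth, p[i])
                            for i in range(n_samples)])
        # ensure >= 2 nonzero parts per sample
        for i in range(n_samples):
            if (counts[i] > 0).sum() < 2:
                counts[i, :2] += 1
        return pd.DataFrame(counts,
                            index=[f"s{i}" for i in range(n_samples)],
                            columns=[f"asv{j}" for j in range(n_asvs)])
    return make
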