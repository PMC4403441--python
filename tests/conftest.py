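import pytest

from synclattice import (
    IsingRunConfig, ModelParams, SimulationConfig, SyncSeries,
    build_landscape, simulate, simulate_ising, derive_seed,
)


@pytest.fixture(scope="session")
def ricker_params():
    return ModelParams("ricker", r=2.3, epsilon=0.1, lam=0.12)


@pytest.fixture(scope="session")
def small_ricker_trajectory(ricker_params):
    """Short ordered-phase run used by several statistics tests."""
    land = build_landscape(16, 2, "nearest")
    cfg = SimulationConfig(land, ricker_params, T_burnin=2000, T_steps=4000,
                           M=4000, seed=101)
    return simulate(cfg, record_snapshots=True)


@pytest.fixture(scope="session")
def ising_critical_series():
    """Wolff magnetization series at the exact critical temperature, L=16."""
    from synclattice import exact_critical_temperature

    cfg = IsingRunConfig(L=16, T=exact_critical_temperature(), n_burnin=1000,
                         n_samples=20000, sample_interval=2, seed=derive_seed(7, 1))
    traj = simulate_ising(cfg)
    return SyncSeries(values=traj.m_t, n_sites=256)
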