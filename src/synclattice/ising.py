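"""Reference 2D Ising model simulator (universality-class anchor).

Ferromagnetic Ising model on a periodic square lattice with energy
E = -J * sum_<ij> s_i s_j, J = 1, Boltzmann constant 1.  Two samplers are
provided: single-site Metropolis and the Wolff cluster algorithm (bond
probability 1 - exp(-2J/T)), the latter being the default near criticality
where single-site dynamics suffer severe critical slowing down.

The magnetization-per-site series m_t produced here feeds the very same
synchrony statistics (order parameter, susceptibility, Binder cumulant,
correlation length) applied to the ecological coupled-map lattices, which is
what anchors the universality comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .models import ParameterError

__all__ = [
    "IsingRunConfig",
    "IsingTrajectory",
    "simulate_ising",
    "exact_critical_temperature",
    "ising_energy",
    "zero_temperature_quench",
]


def exact_critical_temperature() -> float:
    """Onsager's exact critical temperature of the 2D Ising model, 2/ln(1+sqrt(2))."""
    return 2.0 / np.log(1.0 + np.sqrt(2.0))


@dataclass(frozen=True)
class IsingRunConfig:
    L: int
    T: float
    n_burnin: int
    n_samples: int
    sample_interval: int = 1
    algorithm: str = "wolff"
    seed: int = 0
    snapshot_interval: int = 0  # in samples; 0 disables snapshot recording

    def __post_init__(self):
        if self.T <= 0:
            raise ParameterError(f"temperature must be > 0, got {self.T}")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.algorithm not in ("metropolis", "wolff"):
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        if self.L < 2:
            raise ParameterError("L must be >= 2")


@dataclass
class IsingTrajectory:
    m_t: np.ndarray
    snapshots: Optional[np.ndarray]
    config: IsingRunConfig

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": np.arange(len(self.m_t)), "m_t": self.m_t}).to_csv(path, index=False)


@njit(cache=True)
def _wolff_run(L, T, n_burn, n_samples, interval, seed, snaps):
    np.random.seed(seed)
    N = L * L
    spins = np.ones((L, L), dtype=np.int8)
    p_add = 1.0 - np.exp(-2.0 / T)
    stack = np.empty(N, dtype=np.int64)
    m_out = np.empty(n_samples)
    n_snap = snaps.shape[0]
    snap_every = 0 if n_snap == 0 else max(1, n_samples // n_snap)
    isnap = 0
    msum = N  # aligned start

    total_steps = n_burn + n_samples * interval
    k = 0
    for step in range(total_steps):
        i0 = np.random.randint(N)
        x0, y0 = i0 // L, i0 % L
        cs = spins[x0, y0]
        spins[x0, y0] = -cs
        msum -= 2 * cs
        stack[0] = i0
        top = 1
        while top > 0:
            top -= 1
            idx = stack[top]
            x, y = idx // L, idx % L
            for n in range(4):
                if n == 0:
                    xn, yn = (x + 1) % L, y
                elif n == 1:
                    xn, yn = (x - 1) % L, y
                elif n == 2:
                    xn, yn = x, (y + 1) % L
                else:
                    xn, yn = x, (y - 1) % L
                if spins[xn, yn] == cs and np.random.random() < p_add:
                    spins[xn, yn] = -cs
                    msum -= 2 * cs
                    stack[top] = xn * L + yn
                    top += 1
        if step >= n_burn:
            s = step - n_burn
            if (s + 1) % interval == 0:
                m_out[k] = msum / N
                if n_snap > 0 and (k + 1) % snap_every == 0 and isnap < n_snap:
                    snaps[isnap] = spins
                    isnap += 1
                k += 1
    return m_out


@njit(cache=True)
def _metropolis_run(L, T, n_burn, n_samples, interval, seed, snaps, zero_T):
    np.random.seed(seed)
    N = L * L
    spins = np.ones((L, L), dtype=np.int8)
    m_out = np.empty(n_samples)
    n_snap = snaps.shape[0]
    snap_every = 0 if n_snap == 0 else max(1, n_samples // n_snap)
    isnap = 0
    msum = N

    total_sweeps = n_burn + n_samples * interval
    k = 0
    for sweep in range(total_sweeps):
        for _ in range(N):
            i0 = np.random.randint(N)
            x, y = i0 // L, i0 % L
            s = spins[x, y]
            nb = (spins[(x + 1) % L, y] + spins[(x - 1) % L, y]
                  + spins[x, (y + 1) % L] + spins[x, (y - 1) % L])
            dE = 2.0 * s * nb
            if dE <= 0.0 or (not zero_T and np.random.random() < np.exp(-dE / T)):
                spins[x, y] = -s
                msum -= 2 * s
        if sweep >= n_burn:
            sw = sweep - n_burn
            if (sw + 1) % interval == 0:
                m_out[k] = msum / N
                if n_snap > 0 and (k + 1) % snap_every == 0 and isnap < n_snap:
                    snaps[isnap] = spins
                    isnap += 1
                k += 1
    return m_out


def _derive_seed(seed: int) -> int:
    return int(np.random.SeedSequence([int(seed)]).generate_state(1)[0])


def simulate_ising(config: IsingRunConfig) -> IsingTrajectory:
    """Sample the magnetization per site m_t = (1/N) sum_i s_i.

    Initial spin configurations are fully aligned.  ``wolff`` counts one
    cluster update per step; ``metropolis`` counts one lattice sweep (N
    single-site attempts) per step.  Seeded and bit-reproducible.
    """
    n_snap = 0
    if config.snapshot_interval > 0:
        n_snap = config.n_samples // config.snapshot_interval
    snaps = np.zeros((n_snap, config.L, config.L), dtype=np.int8)
    args = (config.L, float(config.T), int(config.n_burnin), int(config.n_samples),
            int(config.sample_interval), _derive_seed(config.seed), snaps)
    if config.algorithm == "wolff":
        m = _wolff_run(*args)
    else:
        m = _metropolis_run(*args, False)
    return IsingTrajectory(m_t=m, snapshots=snaps if n_snap else None, config=config)


def ising_energy(spins: np.ndarray) -> float:
    """Total energy -sum_<ij> s_i s_j over the bonds of the periodic lattice."""
    s = np.asarray(spins, dtype=float)
    e = 0.0
    for axis in range(s.ndim):
        e -= float(np.sum(s * np.roll(s, 1, axis=axis)))
    return e


def zero_temperature_quench(L: int, n_sweeps: int, seed: int = 0) -> np.ndarray:
    """Energy series under T=0 single-site dynamics from a random start.

    Flips are accepted only when they do not raise the energy, so the
    returned series is non-increasing; used as a detailed-balance/dynamics
    sanity check.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
    energies = np.empty(n_sweeps + 1)
    energies[0] = ising_energy(spins)
    for i in range(n_sweeps):
        spins = _quench_sweep(spins, _derive_seed(seed + 7919 * (i + 1)))
        energies[i + 1] = ising_energy(spins)
    return energies


@njit(cache=True)
def _quench_sweep(spins, seed):
    np.random.seed(seed)
    L = spins.shape[0]
    N = L * L
    for _ in range(N):
        i0 = np.random.randint(N)
        x, y = i0 // L, i0 % L
        s = spins[x, y]
        nb = (spins[(x + 1) % L, y] + spins[(x - 1) % L, y]
              + spins[x, (y + 1) % L] + spins[x, (y - 1) % L])
        if 2.0 * s * nb <= 0.0:
            spins[x, y] = -s
    return spins
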