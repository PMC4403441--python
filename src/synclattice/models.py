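"""Stochastic coupled-map-lattice models of oscillating spatial populations.

Four discrete-time metapopulation models are implemented on periodic 1D/2D
lattices.  Each generation consists of local growth under multiplicative
lognormal environmental noise followed by even dispersal of a fraction
``epsilon`` of every local population among its ``z`` neighbouring patches:

* ``ricker``            -- X' = X * exp(r*(1 - X) + lambda*xi), nearest neighbours
* ``ricker_moore``      -- same growth, Moore (nearest + next-nearest) dispersal
* ``logistic``          -- X' = r * X * (1 - X) * exp(lambda*xi)
* ``host_parasitoid``   -- noisy Nicholson-Bailey:
                           H' = r * H * exp(-a*P + lambda*xi),
                           P' = H * (1 - exp(-a*P)) * exp(lambda*xi')
* ``deterministic_ricker`` -- the lambda = 0 limit of ``ricker``

The environmental deviates ``xi`` are standard normal, independent across
patches, generations and (for the two-species model) species.  The local
two-cycle amplitude m_{j,t} = (-1)^t (X_{j,t} - X_{j,t-1}) / 2 plays the role
of a local spin; its spatial average m_t is the instantaneous synchronization
recorded along every trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "GeometryError",
    "ParameterError",
    "ExtinctionError",
    "DivergenceError",
    "Landscape",
    "ModelParams",
    "PopulationState",
    "SimulationConfig",
    "Trajectory",
    "build_landscape",
    "local_growth",
    "dispersal",
    "simulate",
    "deterministic_orbit",
    "replicate_rng",
    "VARIANTS",
]

VARIANTS = ("ricker", "logistic", "ricker_moore", "host_parasitoid", "deterministic_ricker")

_KERNEL_OFFSETS = {
    # kernel -> {d -> list of per-axis shifts}
    ("nearest", 1): [(1,), (-1,)],
    ("nearest", 2): [(1, 0), (-1, 0), (0, 1), (0, -1)],
    ("moore", 1): [(1,), (-1,), (2,), (-2,)],
    ("moore", 2): [
        (1, 0), (-1, 0), (0, 1), (0, -1),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ],
}


class GeometryError(ValueError):
    """Invalid lattice geometry."""


class ParameterError(ValueError):
    """Model or run parameter outside its admissible range."""


class ExtinctionError(RuntimeError):
    """The metapopulation hit the absorbing all-zero state.

    The long-lived metastable state from which statistics are gathered no
    longer exists; the generation at which extinction occurred is recorded.
    """

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population went extinct at generation {generation}")


class DivergenceError(ArithmeticError):
    """Map iteration produced non-finite values."""


@dataclass(frozen=True)
class Landscape:
    """Periodic lattice of habitat patches.

    Attributes
    ----------
    L : side length (patches per dimension)
    d : number of spatial dimensions (1 or 2)
    kernel : dispersal kernel, ``nearest`` (z = 2d) or ``moore``
        (z = 4 in 1D, z = 8 in 2D)
    """

    L: int
    d: int
    kernel: str

    @property
    def z(self) -> int:
        return len(_KERNEL_OFFSETS[(self.kernel, self.d)])

    @property
    def N(self) -> int:
        return self.L ** self.d

    @property
    def shape(self) -> tuple:
        return (self.L,) * self.d

    @property
    def offsets(self) -> list:
        return _KERNEL_OFFSETS[(self.kernel, self.d)]

    def neighbor_sum(self, field: np.ndarray) -> np.ndarray:
        """Sum of ``field`` over the z neighbours of every site (periodic)."""
        out = np.zeros_like(field, dtype=float)
        for off in self.offsets:
            shifted = field
            for axis, s in enumerate(off):
                if s:
                    shifted = np.roll(shifted, s, axis=axis)
            out += shifted
        return out

    def neighbor_table(self) -> np.ndarray:
        """(N, z) integer table of neighbour flat indices (for inspection/tests)."""
        idx = np.arange(self.N).reshape(self.shape)
        cols = []
        for off in self.offsets:
            shifted = idx
            for axis, s in enumerate(off):
                if s:
                    shifted = np.roll(shifted, s, axis=axis)
            cols.append(shifted.ravel())
        return np.stack(cols, axis=1)


def build_landscape(L: int, d: int, kernel: str = "nearest") -> Landscape:
    """Validate and build a periodic lattice of habitat patches."""
    if d not in (1, 2):
        raise GeometryError(f"d must be 1 or 2, got {d}")
    if kernel not in ("nearest", "moore"):
        raise GeometryError(f"unknown kernel {kernel!r}")
    if L < 2:
        raise GeometryError(f"L must be >= 2, got {L}")
    if kernel == "moore" and d == 2 and L < 4:
        raise GeometryError("moore kernel in 2D needs L >= 4 for distinct neighbours")
    return Landscape(L=int(L), d=int(d), kernel=kernel)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the local map: growth rate r, dispersal fraction
    epsilon, environmental noise s.d. lambda, and (host-parasitoid only)
    parasitoid searching efficiency a."""

    variant: str
    r: float
    epsilon: float
    lam: float
    a: float = float("nan")

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown model variant {self.variant!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ParameterError(f"dispersal fraction must lie in [0, 1], got {self.epsilon}")
        if self.lam < 0.0:
            raise ParameterError(f"noise level must be >= 0, got {self.lam}")
        if self.variant == "host_parasitoid" and not (self.a > 0):
            raise ParameterError("searching efficiency a must be > 0 for host_parasitoid")
        if self.variant == "deterministic_ricker" and self.lam != 0.0:
            raise ParameterError("deterministic_ricker requires lambda = 0")

    @property
    def two_species(self) -> bool:
        return self.variant == "host_parasitoid"


@dataclass
class PopulationState:
    """Per-patch densities at one generation (X single-species, H/P two-species)."""

    t: int
    X: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None

    @property
    def primary(self) -> np.ndarray:
        """The field that carries the two-cycle amplitude (host for two species)."""
        return self.X if self.X is not None else self.H


@dataclass(frozen=True)
class SimulationConfig:
    landscape: Landscape
    params: ModelParams
    T_burnin: int
    T_steps: int
    M: int
    mu0: float = 0.5
    sigma0: float = 0.1
    seed: int = 0
    snapshot_interval: int = 1  # amplitude snapshots every this many samples

    def __post_init__(self):
        if self.T_burnin < 0 or self.T_steps < 1:
            raise ParameterError("T_burnin must be >= 0 and T_steps >= 1")
        if not 1 <= self.M <= self.T_steps:
            raise ParameterError("sample count M must satisfy 1 <= M <= T_steps")
        if not (self.mu0 > 0 and self.sigma0 > 0):
            raise ParameterError("initial condition mean and s.d. must be positive")
        if self.snapshot_interval < 1:
            raise ParameterError("snapshot_interval must be >= 1")

    @property
    def sample_interval(self) -> int:
        return self.T_steps // self.M


@dataclass
class Trajectory:
    """Sampled output of one coupled-map-lattice run."""

    generations: np.ndarray          # absolute generation index of each sample
    m_t: np.ndarray                  # instantaneous synchronization at each sample
    mean_density: np.ndarray         # spatial mean of the primary field
    snapshots: Optional[np.ndarray]  # (M, *shape) amplitude fields, or None
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.m_t) != len(self.generations):
            raise ValueError("m_t and generations must have equal length")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"t": self.generations, "m_t": self.m_t, "mean_density": self.mean_density}
        ).to_csv(path, index=False)

    def save(self, path) -> None:
        """Persist as a self-describing .npz container (meta, series, snapshots)."""
        meta = dict(self.meta)
        c = self.config
        meta.update(
            model=c.params.variant, L=c.landscape.L, d=c.landscape.d,
            kernel=c.landscape.kernel, r=c.params.r, epsilon=c.params.epsilon,
            **{"lambda": c.params.lam}, a=c.params.a, T_burnin=c.T_burnin,
            T_steps=c.T_steps, M=c.M, mu0=c.mu0, sigma0=c.sigma0, seed=c.seed,
        )
        arrays = {
            "generations": self.generations,
            "m_t": self.m_t,
            "mean_density": self.mean_density,
            "meta_json": np.array(json.dumps(meta)),
        }
        if self.snapshots is not None:
            arrays["snapshots"] = self.snapshots
        np.savez_compressed(path, **arrays)


def replicate_rng(master_seed: int, *indices: int) -> np.random.Generator:
    """Independent stream for (cell, replicate, ...) derived from one master seed.

    Streams are keyed by the index tuple, not by draw order, so replicate
    ensembles are reproducible regardless of execution order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, indices)]))


# ---------------------------------------------------------------------------
# local growth and dispersal
# ---------------------------------------------------------------------------

def local_growth(state, params: ModelParams, noise):
    """Apply one generation of local (within-patch) growth.

    ``state`` is a density array for single-species variants or an ``(H, P)``
    pair for ``host_parasitoid``; ``noise`` is a matching array of standard
    normal deviates (a pair of arrays for two species).  Returns the
    post-growth field(s).  The deterministic variants are the lambda = 0 limit.
    """
    lam = params.lam
    if params.two_species:
        H, P = state
        if np.any(H < 0) or np.any(P < 0):
            raise ParameterError("densities must be nonnegative")
        xi_h, xi_p = noise
        esc = np.exp(-params.a * P)
        H_new = params.r * H * esc * np.exp(lam * xi_h)
        P_new = H * (1.0 - esc) * np.exp(lam * xi_p)
        return H_new, P_new

    X = state
    if np.any(X < 0):
        raise ParameterError("densities must be nonnegative")
    if params.variant in ("ricker", "ricker_moore", "deterministic_ricker"):
        return X * np.exp(params.r * (1.0 - X) + lam * noise)
    if params.variant == "logistic":
        out = params.r * X * (1.0 - X) * np.exp(lam * noise)
        # X > 1 maps below zero; densities are defined nonnegative, so clip.
        neg = out < 0
        if np.any(neg):
            out = np.where(neg, 0.0, out)
        return out
    raise ParameterError(f"unknown variant {params.variant!r}")


def dispersal(field_arr: np.ndarray, landscape: Landscape, epsilon: float) -> np.ndarray:
    """Even redistribution of a fraction ``epsilon`` among the z neighbours.

    out_j = (1 - eps) * f_j + (eps / z) * sum_{k in nbrs(j)} f_k.
    Conserves the lattice total exactly (up to float summation order).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ParameterError(f"dispersal fraction must lie in [0, 1], got {epsilon}")
    if epsilon == 0.0:
        return np.asarray(field_arr, dtype=float).copy()
    return (1.0 - epsilon) * field_arr + (epsilon / landscape.z) * landscape.neighbor_sum(field_arr)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _draw_initial(rng, shape, mu0, sigma0):
    """Normal(mu0, sigma0) per patch; negative draws are redrawn."""
    x = rng.normal(mu0, sigma0, size=shape)
    while True:
        neg = x < 0
        if not np.any(neg):
            return x
        x[neg] = rng.normal(mu0, sigma0, size=int(neg.sum()))


@njit(cache=True)
def _advance_chunk(X, nbr, z, is_logistic, r, eps, lam, xi, t0, n_steps,
                   T_burnin, interval, M, k0, m_out, dens, gens, snaps, snap_every):
    """Advance the single-species lattice by ``n_steps`` generations.

    ``nbr`` is the (N, z) periodic neighbour table; growth is applied first,
    then even dispersal of fraction ``eps`` among the z neighbours.  ``xi``
    holds the pre-drawn standard normal deviates for the chunk (one row per
    generation; zero rows when the noise level is zero).  Samples of the
    instantaneous synchronization are appended to the output arrays starting
    at slot ``k0``; returns (next slot, extinction generation or -1).
    """
    N = X.size
    Xprev = np.empty(N)
    grown = np.empty(N)
    record_snaps = snaps.shape[0] > 0
    use_noise = xi.shape[0] > 0
    k = k0
    for s in range(n_steps):
        step = t0 + s + 1  # absolute generation after this update
        for j in range(N):
            Xprev[j] = X[j]
        if is_logistic:
            if use_noise:
                for j in range(N):
                    g = r * X[j] * (1.0 - X[j]) * np.exp(lam * xi[s, j])
                    grown[j] = g if g > 0.0 else 0.0
            else:
                for j in range(N):
                    g = r * X[j] * (1.0 - X[j])
                    grown[j] = g if g > 0.0 else 0.0
        else:
            if use_noise:
                for j in range(N):
                    grown[j] = X[j] * np.exp(r * (1.0 - X[j]) + lam * xi[s, j])
            else:
                for j in range(N):
                    grown[j] = X[j] * np.exp(r * (1.0 - X[j]))
        alive = False
        for j in range(N):
            acc = 0.0
            for q in range(z):
                acc += grown[nbr[j, q]]
            X[j] = (1.0 - eps) * grown[j] + (eps / z) * acc
            if X[j] > 0.0:
                alive = True
        if not alive:
            return k, step
        if step > T_burnin and (step - T_burnin) % interval == 0 and k < M:
            parity = 1.0 if step % 2 == 0 else -1.0
            s_amp = 0.0
            s_den = 0.0
            for j in range(N):
                s_amp += X[j] - Xprev[j]
                s_den += X[j]
            m_out[k] = parity * s_amp / (2.0 * N)
            dens[k] = s_den / N
            gens[k] = step
            if record_snaps and k % snap_every == 0 and k // snap_every < snaps.shape[0]:
                for j in range(N):
                    snaps[k // snap_every, j] = parity * (X[j] - Xprev[j]) / 2.0
            k += 1
    return k, -1


def simulate(config: SimulationConfig, record_snapshots: bool = False) -> Trajectory:
    """Run one seeded coupled-map-lattice trajectory.

    Initial densities are drawn from Normal(mu0, sigma0) with negative draws
    rejected; ``T_burnin`` generations are discarded; ``M`` samples of the
    instantaneous synchronization m_t (and optionally the full amplitude
    field) are recorded every ``T_steps // M`` generations.  Runs are
    bit-reproducible for a fixed config.
    """
    land = config.landscape
    p = config.params
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed)]))
    shape = land.shape
    interval = config.sample_interval

    two = p.two_species
    if not two:
        X = _draw_initial(rng, shape, config.mu0, config.sigma0).ravel()
        nbr = land.neighbor_table()
        snap_every = config.snapshot_interval
        n_snap = -(-config.M // snap_every) if record_snapshots else 0
        snaps_flat = np.empty((n_snap, land.N))
        m_series = np.empty(config.M)
        dens = np.empty(config.M)
        gens = np.empty(config.M, dtype=np.int64)
        total = config.T_burnin + config.T_steps
        # noise pre-drawn per chunk with the fast bit generator; chunking does
        # not change the stream, so runs are bit-identical for a fixed seed
        chunk = max(1, min(total, (1 << 22) // land.N))
        k, t = 0, 0
        empty_xi = np.empty((0, land.N))
        while t < total:
            n = min(chunk, total - t)
            xi = rng.standard_normal((n, land.N)) if p.lam > 0 else empty_xi
            k, ext = _advance_chunk(
                X, nbr, land.z, p.variant == "logistic",
                float(p.r), float(p.epsilon), float(p.lam), xi, t, n,
                int(config.T_burnin), int(interval), int(config.M), k,
                m_series, dens, gens, snaps_flat, snap_every)
            if ext >= 0:
                raise ExtinctionError(ext)
            t += n
        if record_snapshots:
            n_rec = -(-k // snap_every)
            snaps = snaps_flat[:n_rec].reshape((n_rec,) + shape)
        else:
            snaps = None
        return Trajectory(
            generations=gens[:k], m_t=m_series[:k], mean_density=dens[:k],
            snapshots=snaps, config=config,
            meta={"n_sites": land.N, "sample_interval": interval},
        )

    H = _draw_initial(rng, shape, config.mu0, config.sigma0)
    P = _draw_initial(rng, shape, config.mu0, config.sigma0)

    def step(state):
        Hc, Pc = state
        noise = (rng.standard_normal(shape), rng.standard_normal(shape)) if p.lam > 0 else (0.0, 0.0)
        Hn, Pn = local_growth((Hc, Pc), p, noise)
        return dispersal(Hn, land, p.epsilon), dispersal(Pn, land, p.epsilon)

    state = (H, P)
    t = 0
    for _ in range(config.T_burnin):
        state = step(state)
        t += 1
        if not np.any(state[0] > 0):
            raise ExtinctionError(t)

    gens = np.empty(config.M, dtype=np.int64)
    m_series = np.empty(config.M)
    dens = np.empty(config.M)
    snap_every = config.snapshot_interval
    snaps = [] if record_snapshots else None

    prev_primary = state[0].copy()
    k = 0
    for s in range(1, config.T_steps + 1):
        state = step(state)
        t += 1
        prim = state[0]
        if not np.any(prim > 0):
            raise ExtinctionError(t)
        if s % interval == 0 and k < config.M:
            amp = (1 if t % 2 == 0 else -1) * (prim - prev_primary) / 2.0
            gens[k] = t
            m_series[k] = amp.mean()
            dens[k] = prim.mean()
            if record_snapshots and k % snap_every == 0:
                snaps.append(amp)
            k += 1
        prev_primary = prim

    return Trajectory(
        generations=gens[:k], m_t=m_series[:k], mean_density=dens[:k],
        snapshots=None if snaps is None else np.stack(snaps), config=config,
        meta={"n_sites": land.N, "sample_interval": interval},
    )


def deterministic_orbit(variant: str, r: float, x0: float,
                        n_transient: int, n_record: int) -> np.ndarray:
    """Iterate the noise-free local map from x0 and record the asymptotic orbit.

    Utility for locating steady-state, two-cycle and chaotic regimes of the
    underlying single-patch dynamics.
    """
    if n_transient < 0 or n_record < 2:
        raise ParameterError("need n_transient >= 0 and n_record >= 2")
    if variant in ("ricker", "ricker_moore", "deterministic_ricker"):
        f = lambda x: x * np.exp(r * (1.0 - x))
    elif variant == "logistic":
        f = lambda x: r * x * (1.0 - x)
    else:
        raise ParameterError(f"deterministic orbit undefined for variant {variant!r}")
    x = float(x0)
    out = np.empty(n_record)
    with np.errstate(over="ignore", invalid="ignore"):  # overflow IS the signal
        for _ in range(n_transient):
            x = f(x)
            if not np.isfinite(x):
                raise DivergenceError("orbit diverged during transient")
        for i in range(n_record):
            x = f(x)
            if not np.isfinite(x):
                raise DivergenceError(f"orbit diverged at record step {i}")
            out[i] = x
    return out
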