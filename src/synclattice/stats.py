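"""Asymptotic spatial-synchrony statistics with principled error bars.

All statistics operate on local two-cycle amplitudes
m_{j,t} = (-1)^t (X_{j,t} - X_{j,t-1}) / 2 and their spatial average, the
instantaneous synchronization m_t.  They apply verbatim to Ising spin fields
(s_i in place of m_{j,t}), which is how the universality comparison between
the ecological models and the Ising reference is carried out.

Error bars follow standard Monte Carlo practice: the time-averaged order
parameter carries an error based on the integrated autocorrelation time
(Madras-Sokal self-consistent truncation window); variance-type statistics
use a block bootstrap with 100 contiguous blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .models import ParameterError

__all__ = [
    "AmplitudeField",
    "SyncSeries",
    "StatEstimate",
    "CorrelationFunction",
    "UndefinedStatisticError",
    "amplitude_field",
    "instantaneous_sync",
    "order_parameter",
    "susceptibility",
    "binder_cumulant",
    "connected_correlation",
    "correlation_length",
    "integrated_autocorr_time",
    "block_bootstrap_error",
]


class UndefinedStatisticError(ArithmeticError):
    """The requested statistic is not defined for the given input."""


@dataclass(frozen=True)
class AmplitudeField:
    """Per-patch two-cycle amplitudes on the lattice at one generation (t >= 1)."""

    values: np.ndarray
    t: int

    def __post_init__(self):
        if self.t < 1:
            raise ParameterError("amplitude fields are defined only for t >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("amplitude field contains non-finite values")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.ndim


@dataclass(frozen=True)
class SyncSeries:
    """Ordered samples of the instantaneous synchronization m_t."""

    values: np.ndarray
    n_sites: int
    sample_interval: int = 1

    def __post_init__(self):
        if len(self.values) < 2:
            raise ParameterError("a synchronization series needs at least 2 samples")

    @classmethod
    def from_trajectory(cls, traj) -> "SyncSeries":
        n = traj.meta.get("n_sites") if getattr(traj, "meta", None) else None
        if n is None:  # Ising trajectory
            n = traj.config.L ** 2
        interval = getattr(traj.config, "sample_interval", 1)
        return cls(values=np.asarray(traj.m_t, dtype=float), n_sites=int(n),
                   sample_interval=int(interval))


@dataclass(frozen=True)
class StatEstimate:
    value: float
    stderr: float
    method: str
    n_samples_used: int

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class CorrelationFunction:
    r: np.ndarray        # axis-direction displacement magnitudes, 0..L/2
    G: np.ndarray        # connected correlation at each displacement
    counts: np.ndarray   # products averaged per bin


def amplitude_field(X_prev: np.ndarray, X_curr: np.ndarray, t: int) -> AmplitudeField:
    """Two-cycle amplitude m_{j,t} = (-1)^t (X_{j,t} - X_{j,t-1}) / 2.

    The alternating parity factor keeps the sign of a phase-locked two-cycle
    constant in time, so clusters oscillating in opposite temporal phase
    carry amplitudes of opposite sign.  For the host-parasitoid model pass
    the host density field.
    """
    X_prev = np.asarray(X_prev, dtype=float)
    X_curr = np.asarray(X_curr, dtype=float)
    if X_prev.shape != X_curr.shape:
        raise ParameterError(f"field shapes differ: {X_prev.shape} vs {X_curr.shape}")
    sign = 1.0 if t % 2 == 0 else -1.0
    return AmplitudeField(values=sign * (X_curr - X_prev) / 2.0, t=t)


def instantaneous_sync(field: AmplitudeField) -> float:
    """Spatial average m_t = (1/N) sum_j m_{j,t}."""
    return float(np.mean(field.values))


def order_parameter(series: SyncSeries) -> StatEstimate:
    """Finite-size synchronization order parameter m_L = <|m_t|>.

    Time average of the absolute spatial mean amplitude; its standard error
    is sqrt(2 * tau_int * Var(|m_t|) / M) with tau_int the integrated
    autocorrelation time of the |m_t| series.
    """
    absm = np.abs(series.values)
    M = len(absm)
    value = float(absm.mean())
    var = float(absm.var())
    if var == 0.0:
        return StatEstimate(value, 0.0, "autocorr_time", M)
    tau = _tau_int(absm)[0]
    stderr = float(np.sqrt(2.0 * tau * var / M))
    return StatEstimate(value, stderr, "autocorr_time", M)


def susceptibility(series: SyncSeries, seed: int = 0) -> StatEstimate:
    """Finite-size susceptibility chi_L = N * (<m_t^2> - <|m_t|>^2).

    Measures the strength of fluctuations in the synchronization order
    parameter; peaks at the critical transition.  Error by block bootstrap.
    """
    if len(series.values) < 10:
        raise ParameterError("susceptibility needs at least 10 samples")
    N = series.n_sites

    def stat(v):
        return N * (np.mean(v ** 2) - np.mean(np.abs(v)) ** 2)

    value = float(stat(series.values))
    err = block_bootstrap_error(series.values, stat, seed=seed)
    return StatEstimate(value, err, "block_bootstrap", len(series.values))


def binder_cumulant(series: SyncSeries, seed: int = 0) -> StatEstimate:
    """Binder cumulant U = <m_t^4>/<m_t^2>^2 - 3 (excess-kurtosis convention).

    U -> 0 deep in the disordered (Gaussian) phase, U -> -2 deep in the
    ordered (two-delta) phase; at 2D Ising criticality the universal value
    lies between -1.830 and -1.835.  Error by block bootstrap.
    """
    if len(series.values) < 10:
        raise ParameterError("Binder cumulant needs at least 10 samples")
    if np.mean(series.values ** 2) == 0.0:
        raise UndefinedStatisticError("Binder cumulant undefined for identically zero series")

    def stat(v):
        m2 = np.mean(v ** 2)
        return np.mean(v ** 4) / m2 ** 2 - 3.0

    value = float(stat(series.values))
    err = block_bootstrap_error(series.values, stat, seed=seed)
    return StatEstimate(value, err, "block_bootstrap", len(series.values))


# ---------------------------------------------------------------------------
# spatial correlations
# ---------------------------------------------------------------------------

def _field_stack(fields: Sequence[AmplitudeField]) -> np.ndarray:
    arrs = [f.values if isinstance(f, AmplitudeField) else np.asarray(f, dtype=float)
            for f in fields]
    return np.stack(arrs)


def connected_correlation(fields: Sequence[AmplitudeField]) -> CorrelationFunction:
    """Spatially averaged connected correlation function G(r).

    G(r) = <m_j m_{j+r}> - <m>^2, where the product is averaged over all
    sites, both axis directions (with periodic wrap) and all supplied fields,
    and <m> is the grand mean over the whole ensemble.  Displacements run
    from 0 to L/2 along the lattice axes.
    """
    if len(fields) < 1:
        raise ParameterError("need at least one field")
    stack = _field_stack(fields)
    d = stack.ndim - 1
    L = stack.shape[1]
    rmax = L // 2
    mu = float(stack.mean())
    G = np.empty(rmax + 1)
    counts = np.empty(rmax + 1, dtype=np.int64)
    n_prod = stack.shape[0] * stack[0].size * d
    for r in range(rmax + 1):
        acc = 0.0
        for axis in range(1, d + 1):
            acc += float(np.mean(stack * np.roll(stack, r, axis=axis)))
        G[r] = acc / d - mu ** 2
        counts[r] = n_prod
    return CorrelationFunction(r=np.arange(rmax + 1), G=G, counts=counts)


def _fourier_scalars(stack: np.ndarray) -> tuple:
    """Per-field k=0 and k_min Fourier amplitudes of a stack of 2D fields."""
    _, L, _ = stack.shape
    M0 = stack.sum(axis=(1, 2))
    phase = np.exp(-2j * np.pi * np.arange(L) / L)
    a1 = (stack * phase[None, :, None]).sum(axis=(1, 2))
    a2 = (stack * phase[None, None, :]).sum(axis=(1, 2))
    return M0, a1, a2


def _structure_factor_from_scalars(M0, a1, a2, N) -> tuple:
    """Connected ensemble-averaged S(0) and S(k_min) from per-field amplitudes."""
    S0 = (np.mean(M0 ** 2) - np.mean(M0) ** 2) / N
    Sk = 0.0
    for a in (a1, a2):
        Sk += (np.mean(np.abs(a) ** 2) - np.abs(np.mean(a)) ** 2) / N
    return S0, Sk / 2.0


def _structure_factor_ratio(stack: np.ndarray) -> tuple:
    n, L, _ = stack.shape
    M0, a1, a2 = _fourier_scalars(stack)
    return _structure_factor_from_scalars(M0, a1, a2, L * L)


def correlation_length(fields: Sequence[AmplitudeField], seed: int = 0,
                       n_boot: int = 200, align_signs: bool = False) -> StatEstimate:
    """Second-moment fluctuation correlation length xi_L.

    xi_L = 1/(2 sin(pi/L)) * sqrt(S(0)/S(k_min) - 1), where S(k) is the
    connected structure factor of the amplitude field averaged over the
    supplied fields and both lattice axes, and k_min = 2*pi/L.  Error by
    bootstrap over fields.

    ``align_signs`` multiplies each field by the sign of its spatial mean
    before averaging: use it for ensembles whose samples hop between the two
    symmetry-broken sectors (e.g. cluster-update Ising runs in the ordered
    phase), so that the k = 0 fluctuations measure in-sector variability as
    they do in a single metastable ecological trajectory.
    """
    stack = _field_stack(fields)
    if align_signs:
        signs = np.sign(stack.reshape(stack.shape[0], -1).sum(axis=1))
        signs[signs == 0] = 1.0
        stack = stack * signs[(slice(None),) + (None,) * (stack.ndim - 1)]
    if stack.ndim != 3:
        raise ParameterError("correlation length requires 2D fields")
    L = stack.shape[1]
    if L < 8:
        raise ParameterError("correlation length requires L >= 8")
    N = L * L
    M0, A1, A2 = _fourier_scalars(stack)
    S0, Sk = _structure_factor_from_scalars(M0, A1, A2, N)
    if Sk <= 0 or S0 <= Sk:
        raise UndefinedStatisticError(
            f"structure factor does not support a length estimate (S0={S0:.3g}, Sk={Sk:.3g})")
    prefac = 1.0 / (2.0 * np.sin(np.pi / L))
    value = float(prefac * np.sqrt(S0 / Sk - 1.0))
    # bootstrap over fields, resampling the per-field Fourier amplitudes
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    n = stack.shape[0]
    vals = []
    if n >= 2:
        for _ in range(n_boot):
            sel = rng.integers(0, n, size=n)
            S0b, Skb = _structure_factor_from_scalars(M0[sel], A1[sel], A2[sel], N)
            if Skb > 0 and S0b > Skb:
                vals.append(prefac * np.sqrt(S0b / Skb - 1.0))
    stderr = float(np.std(vals)) if len(vals) >= 2 else 0.0
    return StatEstimate(value, stderr, "block_bootstrap", n)


# ---------------------------------------------------------------------------
# time-series errors
# ---------------------------------------------------------------------------

def _tau_int(x: np.ndarray, c: float = 6.0) -> tuple:
    """Integrated autocorrelation time with the Madras-Sokal self-consistent
    truncation window W = min{k : k >= c * tau_int(k)}.  Returns (tau, W)."""
    x = np.asarray(x, dtype=float)
    M = len(x)
    v = x - x.mean()
    var = float(np.mean(v ** 2))
    if var == 0.0:
        return 0.5, 0
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * M)))
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:M].real / M
    rho = acov / acov[0]
    tau = 0.5
    W = 0
    for k in range(1, M):
        tau += rho[k]
        W = k
        if k >= c * tau:
            break
    return max(tau, 0.5), W


def integrated_autocorr_time(series) -> StatEstimate:
    """Integrated autocorrelation time of an ordered series.

    tau_int = 1/2 + sum_{k=1}^{W} rho(k), truncated at the self-consistent
    window W (smallest k with k >= 6 tau_int(k)); the Madras-Sokal formula
    gives the standard error sqrt(2(2W+1)/M) * tau.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float)
    if len(x) < 100:
        raise ParameterError("need at least 100 samples for an autocorrelation time")
    tau, W = _tau_int(x)
    M = len(x)
    stderr = float(tau * np.sqrt(2.0 * (2.0 * W + 1.0) / M))
    return StatEstimate(float(tau), stderr, "autocorr_time", M)


def block_bootstrap_error(series, statistic: Callable[[np.ndarray], float],
                          n_blocks: int = 100, n_resample: int = 1000,
                          seed: int = 0) -> float:
    """Block-bootstrap standard error of ``statistic`` over an ordered series.

    The series is split into ``n_blocks`` contiguous blocks; blocks are
    resampled with replacement ``n_resample`` times and the standard
    deviation of the statistic across resamples is returned.  Seeded.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float)
    M = len(x)
    if M < n_blocks:
        warnings.warn(f"series length {M} < {n_blocks} blocks; reducing block count to {M}")
        n_blocks = M
    block_len = M // n_blocks
    blocks = x[: n_blocks * block_len].reshape(n_blocks, block_len)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    out = np.empty(n_resample)
    for b in range(n_resample):
        sel = rng.integers(0, n_blocks, size=n_blocks)
        out[b] = statistic(blocks[sel].ravel())
    return float(np.std(out))
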