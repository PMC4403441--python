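"""Critical-point estimation and finite-size scaling analysis.

Workflow: Binder-cumulant curves U_L(control) for two or more lattice sizes
are interpolated and their crossings located, giving the critical control
value (critical noise level lambda_c for the ecological models, critical
temperature T_c for the Ising reference) and the cumulant value U* at the
crossing.  Measurements of the order parameter m_L, susceptibility chi_L
and correlation length xi_L are then rescaled with the 2D Ising exponents
(nu = 1, beta = 1/8, gamma = 7/4),

    x = a * tau * L^(1/nu),   tau = (control - critical) / control,
    y_m = b * m_L * L^(beta/nu),
    y_chi = b^2 * chi_L * L^(-gamma/nu),
    y_xi = xi_L / L,

so that data from different sizes -- and, multiplied by the model-dependent
scale factors (a_model, b_model), from different models -- fall on common
master curves.  Collapse quality is scored with a Houdayer-Hartmann style local
linear master-curve fit (about 1 for a perfect collapse with honest error
bars), which also serves as the objective when fitting (a_model, b_model)
against the Ising reference curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import ParameterError

__all__ = [
    "IsingExponents",
    "ScalingDataset",
    "CriticalPointEstimate",
    "RescaledSet",
    "CollapseResult",
    "CoarseningFit",
    "PhaseBoundary",
    "NoCrossingError",
    "UndefinedQualityError",
    "estimate_critical_point",
    "reduced_control",
    "fss_rescale",
    "collapse_quality",
    "fit_scale_factors",
    "coarsening_exponent",
    "phase_boundary",
]

STATS = ("m", "chi", "xi", "U")


class NoCrossingError(ArithmeticError):
    """Binder curves do not cross on the supplied control grid."""


class UndefinedQualityError(ArithmeticError):
    """Rescaled sets share no overlapping x-range."""


@dataclass(frozen=True)
class IsingExponents:
    """2D Ising critical exponents (fixed by the universality class)."""

    nu: float = 1.0
    beta: float = 0.125
    gamma: float = 1.75


@dataclass
class ScalingDataset:
    """(L, control, statistic, value, stderr) records for one model."""

    model: str
    table: pd.DataFrame  # columns: L, control, stat, value, stderr

    COLUMNS = ("L", "control", "stat", "value", "stderr")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ParameterError(f"scaling table missing columns {sorted(missing)}")

    @classmethod
    def from_records(cls, model: str, records: Sequence[tuple]) -> "ScalingDataset":
        return cls(model, pd.DataFrame(records, columns=list(cls.COLUMNS)))

    def select(self, stat: str) -> pd.DataFrame:
        if stat not in STATS:
            raise ParameterError(f"unknown statistic {stat!r}")
        return self.table[self.table["stat"] == stat].sort_values(["L", "control"])

    def sizes(self, stat: str) -> List[int]:
        return sorted(self.select(stat)["L"].unique())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "model", self.model)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScalingDataset":
        df = pd.read_csv(path)
        model = str(df["model"].iloc[0])
        return cls(model, df[list(cls.COLUMNS)].copy())


@dataclass(frozen=True)
class CriticalPointEstimate:
    value: float             # lambda_c or T_c
    stderr: float
    U_star: float            # cumulant value at the crossing
    U_star_stderr: float
    crossings: tuple         # ((L_small, L_large, crossing), ...)


@dataclass(frozen=True)
class RescaledSet:
    label: str
    x: np.ndarray
    y: np.ndarray
    yerr: np.ndarray


@dataclass(frozen=True)
class CollapseResult:
    a: float
    b: float
    quality: float
    exponents: IsingExponents

    def to_json(self, **extra) -> str:
        d = {"a_model": self.a, "b_model": self.b, "quality": self.quality,
             "nu": self.exponents.nu, "beta": self.exponents.beta,
             "gamma": self.exponents.gamma}
        d.update(extra)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class CoarseningFit:
    exponent: float
    stderr: float
    t_min: int
    t_max: int


@dataclass(frozen=True)
class PhaseBoundary:
    rows: np.ndarray          # the scanned row values (r or epsilon)
    lambda_star: np.ndarray   # interpolated boundary, NaN where absent
    present: np.ndarray       # boolean mask


# ---------------------------------------------------------------------------
# critical point from Binder crossings
# ---------------------------------------------------------------------------

def _crossing_of_pair(g1, u1, g2, u2) -> tuple:
    """First crossing of two piecewise-linear curves on their overlapping range."""
    lo, hi = max(g1.min(), g2.min()), min(g1.max(), g2.max())
    if not lo < hi:
        raise NoCrossingError("control grids do not overlap")
    xs = np.unique(np.concatenate([g1, g2]))
    xs = xs[(xs >= lo) & (xs <= hi)]
    f = np.interp(xs, g1, u1) - np.interp(xs, g2, u2)
    sign = np.sign(f)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise NoCrossingError("Binder curves do not change order on the grid")
    i = idx[0]
    if f[i + 1] == f[i]:
        xc = 0.5 * (xs[i] + xs[i + 1])
    else:
        xc = xs[i] - f[i] * (xs[i + 1] - xs[i]) / (f[i + 1] - f[i])
    uc = float(np.interp(xc, g1, u1))
    return float(xc), uc


def estimate_critical_point(dataset: ScalingDataset, n_boot: int = 200,
                            seed: int = 0) -> CriticalPointEstimate:
    """Critical control value from Binder-cumulant crossings of size pairs (L, 2L).

    Piecewise-linear interpolants of U_L and U_2L are intersected for every
    available doubling pair; the estimate is the mean crossing, with a
    standard error from resampling the U values within their stated errors.
    Also reports the cumulant value at the crossing (the U* estimate).
    """
    tab = dataset.select("U")
    sizes = sorted(tab["L"].unique())
    pairs = [(L, 2 * L) for L in sizes if 2 * L in sizes]
    if not pairs:
        raise ParameterError("need U data for at least one size pair (L, 2L)")

    curves = {}
    for L in {s for p in pairs for s in p}:
        sub = tab[tab["L"] == L].sort_values("control")
        curves[L] = (sub["control"].to_numpy(float), sub["value"].to_numpy(float),
                     sub["stderr"].to_numpy(float))

    crossings, ustars = [], []
    for L1, L2 in pairs:
        g1, u1, _ = curves[L1]
        g2, u2, _ = curves[L2]
        xc, uc = _crossing_of_pair(g1, u1, g2, u2)
        crossings.append((L1, L2, xc))
        ustars.append(uc)
    value = float(np.mean([c[2] for c in crossings]))
    u_star = float(np.mean(ustars))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    boot, boot_u = [], []
    for _ in range(n_boot):
        vals, uvals = [], []
        for L1, L2 in pairs:
            g1, u1, e1 = curves[L1]
            g2, u2, e2 = curves[L2]
            try:
                xc, uc = _crossing_of_pair(g1, u1 + rng.standard_normal(len(u1)) * e1,
                                           g2, u2 + rng.standard_normal(len(u2)) * e2)
                vals.append(xc)
                uvals.append(uc)
            except NoCrossingError:
                continue
        if vals:
            boot.append(np.mean(vals))
            boot_u.append(np.mean(uvals))
    stderr = float(np.std(boot)) if len(boot) >= 2 else 0.0
    u_stderr = float(np.std(boot_u)) if len(boot_u) >= 2 else 0.0
    return CriticalPointEstimate(value=value, stderr=stderr, U_star=u_star,
                                 U_star_stderr=u_stderr, crossings=tuple(crossings))


def reduced_control(value: float, critical: float):
    """Reduced control parameter tau = (value - critical) / value.

    The denominator is the running control value (noise level or
    temperature), not the critical one.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value == 0):
        raise ZeroDivisionError("reduced control parameter undefined at value = 0")
    out = (value - critical) / value
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# finite-size scaling rescale and collapse
# ---------------------------------------------------------------------------

def fss_rescale(dataset: ScalingDataset, critical: float, a: float = 1.0,
                b: float = 1.0, exponents: IsingExponents = IsingExponents(),
                stats: Sequence[str] = ("m", "chi", "xi")) -> Dict[str, List[RescaledSet]]:
    """Rescale (L, control, value) measurements onto master-curve coordinates.

    Returns, per statistic, one ``RescaledSet`` per lattice size with
    x = a * tau * L^(1/nu) and the statistic-specific y transform: model
    measurements are multiplied by the model-dependent pre-factor (b for
    amplitudes, b^2 for the susceptibility) and the size factor, so that
    y_m = b * m_L * L^(beta/nu), y_chi = b^2 * chi_L * L^(-gamma/nu) and
    y_xi = xi_L / L fall on master curves shared with the Ising reference
    (a = b = 1).  Errors are propagated through the same factors.
    """
    ex = exponents
    out: Dict[str, List[RescaledSet]] = {}
    for stat in stats:
        tab = dataset.select(stat)
        sets = []
        for L in sorted(tab["L"].unique()):
            sub = tab[tab["L"] == L].sort_values("control")
            ctrl = sub["control"].to_numpy(float)
            val = sub["value"].to_numpy(float)
            err = sub["stderr"].to_numpy(float)
            tau = reduced_control(ctrl, critical)
            x = a * tau * L ** (1.0 / ex.nu)
            if stat == "m":
                f = b * L ** (ex.beta / ex.nu)
            elif stat == "chi":
                f = b ** 2 * L ** (-ex.gamma / ex.nu)
            elif stat == "xi":
                f = 1.0 / L
            else:  # U is already dimensionless
                f = 1.0
            sets.append(RescaledSet(label=f"{dataset.model} L={L}", x=np.asarray(x),
                                    y=f * val, yerr=np.abs(f) * err))
        if sets:
            out[stat] = sets
    return out


def _quality_contributions(sets: Sequence[RescaledSet]) -> List[float]:
    contribs = []
    floor = 1e-8 + 1e-6 * max(float(np.max(np.abs(s.y))) for s in sets)
    for j, s in enumerate(sets):
        others = [o for i, o in enumerate(sets) if i != j]
        for xi, yi, ei in zip(s.x, s.y, s.yerr):
            K = Kx = Kxx = Ky = Kxy = 0.0
            found = False
            for o in others:
                order = np.argsort(o.x)
                ox, oy, oe = o.x[order], o.y[order], o.yerr[order]
                pos = np.searchsorted(ox, xi)
                if pos == 0 or pos >= len(ox):
                    continue  # xi not bracketed by this set
                for idx in (pos - 1, pos):
                    w = 1.0 / max(oe[idx], floor) ** 2
                    K += w
                    Kx += w * ox[idx]
                    Kxx += w * ox[idx] ** 2
                    Ky += w * oy[idx]
                    Kxy += w * ox[idx] * oy[idx]
                    found = True
            if not found:
                continue
            delta = K * Kxx - Kx ** 2
            if delta <= 0:
                continue
            m_hat = (K * Kxy - Kx * Ky) / delta
            c_hat = (Kxx * Ky - Kx * Kxy) / delta
            y_hat = m_hat * xi + c_hat
            var_hat = (Kxx - 2.0 * xi * Kx + xi ** 2 * K) / delta
            contribs.append((yi - y_hat) ** 2 / (max(ei, floor) ** 2 + var_hat))
    return contribs


def collapse_quality(sets: Sequence[RescaledSet]) -> float:
    """Houdayer-Hartmann collapse quality of two or more rescaled point sets.

    Each point is compared with a local-linear master-curve estimate built
    from the bracketing points of the other sets, in units of the combined
    errors; the mean squared deviation is about 1 for a perfect collapse
    with honest error bars and grows as the collapse degrades.
    """
    if len(sets) < 2:
        raise ParameterError("collapse quality needs at least two point sets")
    contribs = _quality_contributions(sets)
    if not contribs:
        raise UndefinedQualityError("rescaled sets have no overlapping x-range")
    return float(np.mean(contribs))


def fit_scale_factors(model_ds: ScalingDataset, ising_ds: ScalingDataset,
                      model_critical: float, ising_critical: float,
                      exponents: IsingExponents = IsingExponents(),
                      stats: Sequence[str] = ("m", "chi", "xi"),
                      a0: float = 1.0, b0: float = 1.0) -> CollapseResult:
    """Fit the model-dependent scale factors (a_model, b_model).

    Minimizes the combined collapse quality of the model's {m/b, chi/b^2,
    xi} curves against the Ising reference curves (a_Ising = b_Ising = 1 by
    convention) as functions of a * tau * L^(1/nu).
    """
    ising_sets = fss_rescale(ising_ds, ising_critical, 1.0, 1.0, exponents, stats)
    used = [s for s in stats if s in ising_sets]
    if not used:
        raise ParameterError("ising reference dataset carries none of the requested statistics")

    def objective(p):
        a, b = np.exp(p)
        model_sets = fss_rescale(model_ds, model_critical, a, b, exponents, used)
        total, n = 0.0, 0
        for stat in used:
            if stat not in model_sets:
                continue
            try:
                total += collapse_quality(list(ising_sets[stat]) + list(model_sets[stat]))
                n += 1
            except UndefinedQualityError:
                total += 1e6
        return total / max(n, 1) if n else 1e9

    # coarse log-grid bracketing, then Nelder-Mead refinement
    best, best_q = (np.log(a0), np.log(b0)), np.inf
    for la in np.log(a0) + np.linspace(-1.5, 1.5, 7):
        for lb in np.log(b0) + np.linspace(-1.5, 1.5, 7):
            q = objective((la, lb))
            if q < best_q:
                best, best_q = (la, lb), q
    res = minimize(objective, np.asarray(best), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    if not np.isfinite(res.fun) or res.fun >= 1e6:
        raise ArithmeticError(
            f"scale-factor fit failed to bracket a minimum (quality={res.fun:.3g}, "
            f"a={np.exp(res.x[0]):.3g}, b={np.exp(res.x[1]):.3g})")
    a, b = np.exp(res.x)
    return CollapseResult(a=float(a), b=float(b), quality=float(res.fun),
                          exponents=exponents)


# ---------------------------------------------------------------------------
# coarsening exponent and phase boundary
# ---------------------------------------------------------------------------

def coarsening_exponent(trajectories: np.ndarray, t: np.ndarray,
                        t_min: int = 2, t_max: Optional[int] = None,
                        saturation: Optional[float] = None,
                        n_boot: int = 200, seed: int = 0) -> CoarseningFit:
    """Power-law growth exponent of the ensemble-mean correlation length index.

    ``trajectories`` is (n_replicates, n_times) of CL_t values (NaN where the
    index was undefined); the slope of ln(mean CL_t) vs ln t is fit over
    [t_min, t_max], with a replicate bootstrap for the error.  If
    ``saturation`` is given, times where the ensemble mean exceeds it are
    truncated with a warning (fits must stay in the pre-saturation regime).
    """
    traj = np.asarray(trajectories, dtype=float)
    t = np.asarray(t)
    if traj.ndim != 2 or traj.shape[1] != len(t):
        raise ParameterError("trajectories must be (n_replicates, n_times)")
    if traj.shape[0] < 2:
        raise ParameterError("need replicate trajectories")
    if t_min < 2:
        raise ParameterError("coarsening fits start at t >= 2")
    t_max = int(t[-1]) if t_max is None else t_max

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_cl = np.nanmean(traj, axis=0)
    mask = (t >= t_min) & (t <= t_max) & np.isfinite(mean_cl) & (mean_cl > 0)
    if saturation is not None:
        sat = mean_cl > saturation
        if np.any(sat & mask):
            warnings.warn("fit range truncated at the saturation level")
            mask &= ~sat
    if mask.sum() < 3:
        raise ParameterError("fewer than 3 usable time points in the fit range")
    slope = float(np.polyfit(np.log(t[mask]), np.log(mean_cl[mask]), 1)[0])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    n = traj.shape[0]
    boots = []
    for _ in range(n_boot):
        sel = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mc = np.nanmean(traj[sel], axis=0)
        ok = mask & np.isfinite(mc) & (mc > 0)
        if ok.sum() >= 3:
            boots.append(np.polyfit(np.log(t[ok]), np.log(mc[ok]), 1)[0])
    stderr = float(np.std(boots)) if len(boots) >= 2 else 0.0
    return CoarseningFit(exponent=slope, stderr=stderr, t_min=int(t_min), t_max=int(t_max))


def phase_boundary(rows: np.ndarray, lam_grid: np.ndarray,
                   xi_values: np.ndarray) -> PhaseBoundary:
    """Critical curve from the ridge of the fluctuation correlation length.

    ``xi_values`` is (n_rows, n_lambda); for each row with an interior
    maximum of xi_L, a quadratic through the maximal point and its two
    neighbours is interpolated and its vertex reported as lambda*(row).
    Rows whose maximum sits on the grid edge are marked boundary-absent.
    """
    rows = np.asarray(rows, dtype=float)
    lam = np.asarray(lam_grid, dtype=float)
    xi = np.asarray(xi_values, dtype=float)
    if xi.shape != (len(rows), len(lam)):
        raise ParameterError("xi grid shape must be (n_rows, n_lambda)")
    if len(lam) < 5:
        raise ParameterError("each row needs at least 5 lambda points")
    lam_star = np.full(len(rows), np.nan)
    for i in range(len(rows)):
        row = xi[i]
        if not np.all(np.isfinite(row)):
            continue
        j = int(np.argmax(row))
        if j == 0 or j == len(lam) - 1:
            continue  # boundary-absent: maximum at grid edge
        xs, ys = lam[j - 1:j + 2], row[j - 1:j + 2]
        c2, c1, _ = np.polyfit(xs, ys, 2)
        if c2 >= 0:
            continue
        lam_star[i] = -c1 / (2.0 * c2)
    return PhaseBoundary(rows=rows, lambda_star=lam_star, present=np.isfinite(lam_star))
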