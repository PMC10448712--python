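"""Energy terms of the 1BPS model and the distribution-fitting machinery.

Covers the harmonic backbone bonds, tabulated bending/dihedral potentials,
the near-collinearity penalty on XGG triplets, Debye-Hueckel screened
electrostatics, the WCA (shifted, truncated Lennard-Jones) steric term,
(iterative) Boltzmann inversion primitives, and the analytic PDF fits used
to smooth histograms between iterations: a log-normal/Gumbel mixture for
bending angles and periodic quadratic splines for dihedrals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize

from . import constants as c

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Tabulated potentials
# --------------------------------------------------------------------------

def _centered_slopes(grid: np.ndarray, energy: np.ndarray, periodic: bool) -> np.ndarray:
    """Nodal dV/dx by centered finite differences (periodic-aware).

    Defining the tabulated force as the centered difference of the energy
    column makes force/energy consistency exact at the nodes; interpolation
    between nodes is cubic Hermite on (energy, slope), so the interpolated
    force is the analytic derivative of the interpolated energy everywhere.
    """
    dx = grid[1] - grid[0]
    n = len(grid)
    s = np.empty(n)
    s[1:-1] = (energy[2:] - energy[:-2]) / (2 * dx)
    if periodic:
        # node 0 and node n-1 are the same physical point
        s[0] = s[-1] = (energy[1] - energy[-2]) / (2 * dx)
    else:
        s[0] = (energy[1] - energy[0]) / dx
        s[-1] = (energy[-1] - energy[-2]) / dx
    return s


@dataclass
class TabulatedPotential:
    """Energy/force table on a uniform coordinate grid (degrees for angles).

    ``force`` is -dV/dx per grid point.  Periodic tables include both
    endpoints of the period with equal energy values.  Evaluation uses C1
    cubic Hermite interpolation of (energy, -force), exact at grid points.
    """

    grid: np.ndarray  # coordinate values, uniform spacing
    energy: np.ndarray  # kJ/mol
    force: np.ndarray  # -dV/dx, kJ/mol per grid unit
    periodic: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.grid) == len(self.energy) == len(self.force)):
            raise ValueError("grid, energy, force must have equal length")
        dx = np.diff(self.grid)
        if len(dx) and not np.allclose(dx, dx[0], rtol=1e-8):
            raise ValueError("grid must be uniform")
        if self.periodic and not math.isclose(self.energy[0], self.energy[-1],
                                              abs_tol=1e-9 + 1e-9 * abs(self.energy[0])):
            raise ValueError("periodic table must have equal endpoint energies")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @classmethod
    def from_energy(cls, grid: np.ndarray, energy: np.ndarray,
                    periodic: bool = False) -> "TabulatedPotential":
        grid = np.asarray(grid, dtype=float)
        energy = np.asarray(energy, dtype=float)
        if periodic:
            energy = energy.copy()
            energy[-1] = energy[0]
        return cls(grid, energy, -_centered_slopes(grid, energy, periodic), periodic)

    @classmethod
    def from_function(cls, fn, x0: float, x1: float, dx: float,
                      periodic: bool = False) -> "TabulatedPotential":
        grid = np.arange(np.round((x1 - x0) / dx) + 1) * dx + x0
        return cls.from_energy(grid, fn(grid), periodic)

    def __call__(self, x):
        """Evaluate (energy, force) at x; linear extrapolation outside a
        non-periodic domain (flagged in logs)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x).copy()
        x0, x1 = self.domain
        period = x1 - x0
        if self.periodic:
            x = x0 + np.mod(x - x0, period)
        elif np.any((x < x0) | (x > x1)):
            log.warning("tabulated potential queried outside [%g, %g]; "
                        "linearly extrapolating", x0, x1)
        dx = self.dx
        slopes = -self.force
        u = (x - x0) / dx
        i = np.clip(np.floor(u).astype(int), 0, len(self.grid) - 2)
        t = u - i
        below, above = t < 0.0, t > 1.0  # out-of-domain (non-periodic only)
        t = np.clip(t, 0.0, 1.0)
        y0, y1 = self.energy[i], self.energy[i + 1]
        m0, m1 = slopes[i] * dx, slopes[i + 1] * dx
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        e = h00 * y0 + h10 * m0 + h01 * y1 + h11 * m1
        de = (6 * t * (t - 1) * (y0 - y1) / dx
              + (3 * t * t - 4 * t + 1) * slopes[i]
              + (3 * t * t - 2 * t) * slopes[i + 1])
        if np.any(below):
            e[below] = self.energy[0] + slopes[0] * (x[below] - x0)
            de[below] = slopes[0]
        if np.any(above):
            e[above] = self.energy[-1] + slopes[-1] * (x[above] - x1)
            de[above] = slopes[-1]
        f = -de
        if scalar:
            return float(e[0]), float(f[0])
        return e, f


def evaluate_tabulated(pot: TabulatedPotential, x):
    """Interpolated (energy, force) of a tabulated potential at x."""
    return pot(x)


def cap_potential(pot: TabulatedPotential, vmax: float) -> TabulatedPotential:
    """Clip tabulated energies at vmax and recompute the force column."""
    if vmax <= pot.energy.min():
        raise ValueError("vmax must exceed the potential minimum")
    return TabulatedPotential.from_energy(pot.grid, np.minimum(pot.energy, vmax),
                                          periodic=pot.periodic)


# --------------------------------------------------------------------------
# Analytic energy terms
# --------------------------------------------------------------------------

def harmonic_bond(r, r0: float, k: float):
    """V = 1/2 k (r - r0)^2; returns (energy kJ/mol, force = -dV/dr)."""
    r = np.asarray(r, dtype=float)
    v = 0.5 * k * (r - r0) ** 2
    f = -k * (r - r0)
    if r.ndim == 0:
        return float(v), float(f)
    return v, f


@dataclass(frozen=True)
class PenaltyParams:
    a: float = c.PENALTY_A  # kJ/mol
    b: float = c.PENALTY_B  # rad

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("penalty parameters a, b must be positive")


def penalty_energy(theta, p: PenaltyParams = PenaltyParams()):
    """XGG near-collinearity penalty.

    V(theta) = a b^2 / ((pi - theta)^2 - b^2) for theta < pi - b, diverging
    at theta = pi - b and +inf for theta >= pi - b.  Strictly increasing
    toward 180 deg, linear in a, negligible at the XGG distribution peak,
    and with no preferred angle; it only forbids the collinear region where
    the dihedral force would be singular.  theta in radians.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    s = np.pi - theta
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(s > p.b, p.a * p.b ** 2 / (s ** 2 - p.b ** 2), np.inf)
    if theta.ndim == 0:
        return float(v)
    return v


@dataclass(frozen=True)
class ElectrostaticsParams:
    eps_r: float = c.DEFAULT_EPS_R
    T: float = c.DEFAULT_TEMPERATURE  # K
    C_s: float = 0.150  # mol/L monovalent salt
    cutoff_factor: float = c.DEFAULT_CUTOFF_FACTOR  # in Debye lengths

    def __post_init__(self):
        if self.C_s <= 0:
            raise ValueError("salt concentration must be positive")
        if self.cutoff_factor <= 0:
            raise ValueError("cutoff_factor must be positive")


def debye_length(p: ElectrostaticsParams) -> float:
    """kappa^-1 = sqrt(eps0 eps_r kB T / (2 e^2 N_A C_s)) in nm."""
    cs_m3 = p.C_s * 1000.0  # mol/L -> mol/m^3
    lam = math.sqrt(c.EPS0 * p.eps_r * c.KB_SI * p.T
                    / (2 * c.ELEMENTARY_CHARGE ** 2 * c.N_AVOGADRO * cs_m3))
    return lam * 1e9  # m -> nm


def debye_huckel_energy(r, z_i: float, z_j: float, p: ElectrostaticsParams):
    """Screened Coulomb z_i z_j e^2 exp(-kappa r) / (4 pi eps0 eps_r r),
    truncated (unshifted) at cutoff_factor Debye lengths.  kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    lam = debye_length(p)
    v = c.F_COULOMB * z_i * z_j / (p.eps_r * r) * np.exp(-r / lam)
    v = np.where(r < p.cutoff_factor * lam, v, 0.0)
    if r.ndim == 0:
        return float(v)
    return v


def wca_energy(r, sigma_ij: float, eps_ij: float = c.EPS_LJ):
    """Shifted Lennard-Jones (WCA): 4 eps [(s/r)^12 - (s/r)^6] + eps,
    truncated to zero at r >= 2^(1/6) sigma_ij.  Continuous at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sr6 = (sigma_ij / r) ** 6
    v = 4.0 * eps_ij * (sr6 * sr6 - sr6) + eps_ij
    v = np.where(r < 2.0 ** (1.0 / 6.0) * sigma_ij, v, 0.0)
    if r.ndim == 0:
        return float(v)
    return v


# --------------------------------------------------------------------------
# Boltzmann inversion
# --------------------------------------------------------------------------

def boltzmann_invert(grid: np.ndarray, pdf: np.ndarray, T: float,
                     periodic: bool = False, v_wall_kt: float = 50.0,
                     p_floor: float = 1e-8) -> TabulatedPotential:
    """V = -kB T ln P, offset so min(V) = 0.

    Bins with P below ``p_floor`` (unsampled, high-energy regions) get a
    linear extrapolation of V from the last two sampled bins, capped at
    ``v_wall_kt`` kB T above the minimum.
    """
    grid = np.asarray(grid, dtype=float)
    pdf = np.asarray(pdf, dtype=float)
    if np.any(pdf < 0):
        raise ValueError("pdf must be nonnegative")
    if not np.any(pdf > 0):
        raise ValueError("pdf is identically zero")
    kt = c.KB * T
    sampled = pdf > p_floor
    v = np.full(len(grid), np.nan)
    v[sampled] = -kt * np.log(pdf[sampled])
    idx = np.flatnonzero(sampled)
    # linear extrapolation outward from the edges of the sampled region
    if idx[0] > 0:
        slope = (v[idx[0]] - v[idx[0] + 1]) if idx[0] + 1 in idx else 0.0
        for i in range(idx[0] - 1, -1, -1):
            v[i] = v[i + 1] + abs(slope)
    if idx[-1] < len(grid) - 1:
        slope = (v[idx[-1]] - v[idx[-1] - 1]) if idx[-1] - 1 in idx else 0.0
        for i in range(idx[-1] + 1, len(grid)):
            v[i] = v[i - 1] + abs(slope)
    # interior gaps: linear interpolation between sampled neighbours
    if np.any(np.isnan(v)):
        nan = np.isnan(v)
        v[nan] = np.interp(grid[nan], grid[~nan], v[~nan])
    v -= v.min()
    v = np.minimum(v, v_wall_kt * kt)
    return TabulatedPotential.from_energy(grid, v, periodic=periodic)


# --------------------------------------------------------------------------
# Angle PDF fit: convex log-normal / Gumbel mixture
# --------------------------------------------------------------------------

def f_lognormal(theta, s: float, mu: float):
    """Log-normal density in the angle variable (degrees)."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    pos = theta > 0
    out[pos] = (1.0 / (theta[pos] * s * math.sqrt(2 * math.pi))
                * np.exp(-((np.log(theta[pos]) - mu) ** 2) / (2 * s * s)))
    return out


def f_gumbel(theta, gamma: float, delta: float):
    """Gumbel density with location gamma and scale delta (degrees)."""
    z = (np.asarray(theta, dtype=float) - gamma) / delta
    return np.exp(-z - np.exp(-z)) / delta


@dataclass
class AngleFitParams:
    beta: float  # mixture weight of the log-normal component, in [0, 1]
    s: float  # log-normal shape
    mu: float  # log-normal location (of ln theta)
    gamma: float  # Gumbel location, deg
    delta: float  # Gumbel scale, deg
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_ANGLE_BOUNDS))
    residual: float = float("nan")  # rms fit residual, deg^-1

    def as_vector(self) -> np.ndarray:
        return np.array([self.beta, self.s, self.mu, self.gamma, self.delta])


# Default parameter ranges; the role of the original work's bound table.
DEFAULT_ANGLE_BOUNDS = {
    "beta": (0.0, 1.0),
    "s": (1e-3, 2.0),
    "mu": (math.log(5.0), math.log(180.0)),
    "gamma": (0.0, 180.0),
    "delta": (0.5, 60.0),
}

ANGLE_GRID = np.arange(0.5, 180.0, c.ANGLE_BIN_DEG)  # histogram bin centers


def angle_mixture_pdf(theta, params: AngleFitParams, normalize: bool = True):
    """beta f_LN + (1-beta) f_Gumbel, renormalized over (0, 180] degrees."""
    raw = (params.beta * f_lognormal(theta, params.s, params.mu)
           + (1 - params.beta) * f_gumbel(theta, params.gamma, params.delta))
    if not normalize:
        return raw
    dense = np.linspace(1e-6, 180.0, 2001)
    z = np.trapezoid(params.beta * f_lognormal(dense, params.s, params.mu)
                     + (1 - params.beta) * f_gumbel(dense, params.gamma, params.delta),
                     dense)
    return raw / z


class FitError(RuntimeError):
    """Raised when a bounded least-squares PDF fit fails to converge."""


def fit_angle_pdf(grid: np.ndarray, histogram: np.ndarray,
                  init: AngleFitParams | None = None,
                  bounds: dict | None = None) -> AngleFitParams:
    """Bounded least-squares fit of the angle-PDF mixture to a histogram.

    ``histogram`` is a normalized density (deg^-1) at the ``grid`` bin
    centers.  Returns fitted parameters (clamped inside bounds) with the rms
    residual; raises FitError with diagnostics on non-convergence.
    """
    grid = np.asarray(grid, dtype=float)
    hist = np.asarray(histogram, dtype=float)
    bounds = {**DEFAULT_ANGLE_BOUNDS, **(bounds or {})}
    names = ["beta", "s", "mu", "gamma", "delta"]
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    if init is None:
        mean = float(np.sum(grid * hist) / max(np.sum(hist), 1e-300))
        sd = math.sqrt(max(float(np.sum((grid - mean) ** 2 * hist) / max(np.sum(hist), 1e-300)), 1.0))
        init = AngleFitParams(beta=0.5, s=min(max(sd / mean, 2e-3), 1.9),
                              mu=math.log(max(mean, 6.0)), gamma=mean, delta=max(sd, 1.0))
    x0 = np.clip(init.as_vector(), lo + 1e-12, hi - 1e-12)

    def resid(x):
        p = AngleFitParams(*x)
        return angle_mixture_pdf(grid, p) - hist

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-12, ftol=1e-12, max_nfev=2000)
    if not sol.success:
        raise FitError(f"angle PDF fit failed: {sol.message} (status {sol.status}); "
                       f"x={sol.x}, cost={sol.cost:.3e}")
    rms = math.sqrt(2 * sol.cost / len(grid))
    return AngleFitParams(*np.clip(sol.x, lo, hi), bounds=bounds, residual=rms)


# --------------------------------------------------------------------------
# Dihedral PDF: periodic quadratic spline
# --------------------------------------------------------------------------

DIHEDRAL_GRID = np.arange(-180.0 + c.DIHEDRAL_BIN_DEG / 2, 180.0, c.DIHEDRAL_BIN_DEG)


class PeriodicSplineDensity:
    """Periodic quadratic-spline density over (-180, 180] degrees.

    Interpolates histogram bin heights with a spline that is periodic and
    differentiable at +/-180 deg, floored at a small positive value, and
    renormalized to unit integral.
    """

    def __init__(self, grid: np.ndarray, histogram: np.ndarray,
                 floor: float = 1e-10):
        grid = np.asarray(grid, dtype=float)
        hist = np.asarray(histogram, dtype=float)
        if np.any(hist < 0):
            raise ValueError("histogram must be nonnegative")
        self.grid = grid
        self.floor = floor
        # extend by one period point for the periodic spline
        x = np.concatenate([grid, [grid[0] + 360.0]])
        y = np.concatenate([hist, [hist[0]]])
        self._tck = interpolate.splrep(x, y, k=2, per=True, s=0)
        dense = np.linspace(grid[0], grid[0] + 360.0, 3601)
        vals = np.maximum(interpolate.splev(dense, self._tck), floor)
        self._norm = float(np.trapezoid(vals, dense))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xw = self.grid[0] + np.mod(x - self.grid[0], 360.0)
        vals = np.maximum(interpolate.splev(xw, self._tck), self.floor)
        return vals / self._norm

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        xw = self.grid[0] + np.mod(x - self.grid[0], 360.0)
        raw = interpolate.splev(xw, self._tck)
        d = interpolate.splev(xw, self._tck, der=1)
        return np.where(raw > self.floor, d, 0.0) / self._norm


def fit_dihedral_spline(grid: np.ndarray, histogram: np.ndarray) -> PeriodicSplineDensity:
    """Periodic quadratic-spline density through dihedral histogram bins."""
    return PeriodicSplineDensity(grid, histogram)
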