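"""Conformational observables: characteristic ratio, bond autocorrelation,
persistence length, radius of gyration, Ramachandran-type densities.

Conventions.  The characteristic ratio is C_N = <Ree^2> / (N l_b^2) with N
the number of monosaccharides (beads) and l_b = 0.525 nm the average bond
length; a bond-count convention (N-1) is available via ``denominator``.
Statistics discard the first 20% of frames by default.  When several
replica trajectories are supplied, reported errors are the standard
deviation over replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import constants as c
from . import geometry


def _frames(traj, discard_fraction: float = 0.2) -> np.ndarray:
    if hasattr(traj, "equilibrated"):
        return traj.equilibrated(discard_fraction)
    arr = np.asarray(traj, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    start = int(np.floor(len(arr) * discard_fraction))
    return arr[start:]


@dataclass
class ChainStatistics:
    mean_sq_ree: float  # nm^2
    c_n: float
    r_g: float  # nm
    c_of_n: np.ndarray  # bond autocorrelation vs separation
    l_p: float  # nm
    l_p_sd: float  # nm, replica sd (nan for a single replica)
    n_mono: int
    l_b: float = c.L_BOND


def mean_squared_end_to_end(traj, discard_fraction: float = 0.2) -> float:
    frames = _frames(traj, discard_fraction)
    ree = frames[:, -1] - frames[:, 0]
    return float(np.mean(np.sum(ree * ree, axis=-1)))


def characteristic_ratio(traj, n_mono: int | None = None, l_b: float = c.L_BOND,
                         denominator: str = "monosaccharides",
                         discard_fraction: float = 0.2) -> float:
    """C_N = <Ree^2> / (N l_b^2) over the equilibrated trajectory segment.

    ``denominator='bonds'`` uses N-1 instead of N.
    """
    frames = _frames(traj, discard_fraction)
    n = frames.shape[1] if n_mono is None else n_mono
    if n < 2:
        raise ValueError("need at least 2 beads")
    msre = float(np.mean(np.sum((frames[:, -1] - frames[:, 0]) ** 2, axis=-1)))
    denom = n if denominator == "monosaccharides" else n - 1
    return msre / (denom * l_b * l_b)


def characteristic_ratio_replicas(trajs, **kw) -> tuple[float, float]:
    vals = np.array([characteristic_ratio(t, **kw) for t in trajs])
    return float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else np.nan)


def bond_autocorrelation(traj, discard_fraction: float = 0.2) -> np.ndarray:
    """C(n) = < b_i . b_{i+n} / (|b_i| |b_{i+n}|) > over frames and bond
    pairs at separation n; C(0) = 1 exactly."""
    frames = _frames(traj, discard_fraction)
    if frames.shape[1] < 2:
        raise ValueError("need at least 2 beads")
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    b = frames[:, 1:] - frames[:, :-1]  # (frames, nbonds, 3)
    u = b / np.linalg.norm(b, axis=-1, keepdims=True)
    nb = u.shape[1]
    out = np.empty(nb)
    out[0] = 1.0
    for n in range(1, nb):
        out[n] = float(np.mean(np.einsum("fij,fij->fi", u[:, :-n], u[:, n:])))
    return out


def persistence_length(c_of_n: np.ndarray, l_b: float = c.L_BOND,
                       fit_range: tuple[int, int] = (1, 20)) -> tuple[float, float]:
    """Fit exp(-n l_b / l_p) to the bond autocorrelation over fit_range.

    Returns (l_p, standard error from the fit covariance), both nm.
    Nonpositive C(n) values inside the range shrink it with a warning.
    """
    c_of_n = np.asarray(c_of_n, dtype=float)
    lo, hi = fit_range
    hi = min(hi, len(c_of_n) - 1)
    n = np.arange(lo, hi + 1)
    y = c_of_n[lo:hi + 1]
    bad = np.flatnonzero(y <= 0)
    if len(bad):
        warnings.warn(f"nonpositive C(n) at n={n[bad[0]]}; shrinking fit range")
        n, y = n[:bad[0]], y[:bad[0]]
    if len(n) < 2:
        raise ValueError("fit range too small after removing nonpositive values")
    popt, pcov = optimize.curve_fit(lambda nn, lp: np.exp(-nn * l_b / lp), n, y,
                                    p0=[5 * l_b], maxfev=10000)
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def persistence_length_replicas(trajs, l_b: float = c.L_BOND,
                                fit_range=(1, 20), discard_fraction=0.2):
    vals = np.array([persistence_length(bond_autocorrelation(t, discard_fraction),
                                        l_b, fit_range)[0] for t in trajs])
    return float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else np.nan)


def radius_of_gyration(traj, masses: np.ndarray | None = None,
                       weighting: str = "mass", discard_fraction: float = 0.2) -> float:
    """Root-mean-square distance from the (weighted) centroid, frame-averaged."""
    frames = _frames(traj, discard_fraction)
    nb = frames.shape[1]
    if weighting == "geometric" or masses is None:
        w = np.ones(nb)
    elif weighting == "mass":
        w = np.asarray(masses, dtype=float)
    else:
        raise ValueError("weighting must be 'mass' or 'geometric'")
    w = w / w.sum()
    com = np.einsum("j,fjd->fd", w, frames)
    d2 = np.sum((frames - com[:, None]) ** 2, axis=-1)
    return float(np.sqrt(np.mean(np.einsum("j,fj->f", w, d2))))


@dataclass
class RamachandranDensity:
    """Joint density of paired backbone dihedrals on (-180, 180]^2 (deg^-2)."""

    density: np.ndarray  # (nbins, nbins)
    bin_width: float
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return np.arange(-180.0 + self.bin_width / 2, 180.0, self.bin_width)


def ramachandran_density(gxgx_series, xgxg_series,
                         bin_width: float = c.DIHEDRAL_BIN_DEG) -> RamachandranDensity:
    """Normalized 2D histogram of paired (GXGX, XGXG) dihedral samples.

    Pairing convention: a GXGX dihedral at window k is paired with the
    XGXG dihedral of the adjacent window (the one sharing its three last
    beads); callers build the paired series, e.g. via
    :func:`paired_dihedral_series`.
    """
    x = np.asarray(gxgx_series, dtype=float)
    y = np.asarray(xgxg_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired dihedral series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    h, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    dens = h / (h.sum() * bin_width * bin_width)
    return RamachandranDensity(dens, bin_width, len(x))


def paired_dihedral_series(traj_or_frames, topology,
                           discard_fraction: float = 0.2):
    """(GXGX, XGXG) sample pairs from adjacent dihedral windows of a chain."""
    frames = _frames(traj_or_frames, discard_fraction)
    gx = topology.dihedral_index("GXGX")
    xg = topology.dihedral_index("XGXG")
    # window starting at bead 2k pairs with the window starting at 2k+1
    pairs = []
    xg_start = {int(r[0]): i for i, r in enumerate(xg)}
    for i, r in enumerate(gx):
        j = xg_start.get(int(r[0]) + 1)
        if j is not None:
            pairs.append((i, j))
    psi = geometry.dihedrals_deg(frames, gx)
    phi = geometry.dihedrals_deg(frames, xg)
    a = np.concatenate([psi[:, i] for i, _ in pairs])
    b = np.concatenate([phi[:, j] for _, j in pairs])
    return a, b


def max_abs_deviation(d1: RamachandranDensity | np.ndarray,
                      d2: RamachandranDensity | np.ndarray) -> float:
    """Sup-norm of the density difference (deg^-2)."""
    a = d1.density if isinstance(d1, RamachandranDensity) else np.asarray(d1)
    b = d2.density if isinstance(d2, RamachandranDensity) else np.asarray(d2)
    if a.shape != b.shape:
        raise ValueError("density grids do not match")
    return float(np.max(np.abs(a - b)))


def power_law_fit(r_g_values, molar_masses) -> tuple[float, tuple[float, float]]:
    """Exponent nu of R_g ~ M^nu by log-log regression, with a 95% CI.

    With replicas, pass replica-mean R_g values; the CI comes from the
    regression residuals (t-distribution, n-2 dof).
    """
    rg = np.asarray(r_g_values, dtype=float)
    m = np.asarray(molar_masses, dtype=float)
    if len(rg) < 3:
        raise ValueError("need at least 3 points for a confidence interval")
    if np.any(rg <= 0) or np.any(m <= 0):
        raise ValueError("R_g and M must be positive")
    res = stats.linregress(np.log(m), np.log(rg))
    tcrit = stats.t.ppf(0.975, len(rg) - 2)
    return float(res.slope), (float(res.slope - tcrit * res.stderr),
                              float(res.slope + tcrit * res.stderr))


def chain_statistics(trajs, topology, l_b: float = c.L_BOND,
                     fit_range=(1, 20), discard_fraction: float = 0.2) -> ChainStatistics:
    """Replica-aware summary statistics for one chain length."""
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    msre = float(np.mean([mean_squared_end_to_end(t, discard_fraction) for t in trajs]))
    cn, _ = characteristic_ratio_replicas(trajs, l_b=l_b, discard_fraction=discard_fraction)
    rg = float(np.mean([radius_of_gyration(t, topology.masses, "mass", discard_fraction)
                        for t in trajs]))
    c_curves = [bond_autocorrelation(t, discard_fraction) for t in trajs]
    cn_curve = np.mean(c_curves, axis=0)
    lp, lp_sd = persistence_length_replicas(trajs, l_b, fit_range, discard_fraction)
    return ChainStatistics(msre, cn, rg, cn_curve, lp, lp_sd, topology.n_beads, l_b)
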