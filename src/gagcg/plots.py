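"""Diagnostic figures: IBI convergence panels and dihedral heatmaps."""

from __future__ import annotations

import numpy as np

from . import constants as c
from .potentials import ANGLE_GRID, DIHEDRAL_GRID


def plot_ibi_panels(result, path) -> None:
    """Multipanel figure: per-DOF final potential (left axis), fitted and
    target densities (right axis), plus the convergence history."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    state = result.state
    names = [n for n in state.potentials if n not in state.immutable]
    ncols = 3
    nrows = int(np.ceil((len(names) + 1) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
    axes = np.atleast_1d(axes).ravel()
    kt = c.KB * state.T
    for ax, name in zip(axes, names):
        pot = state.potentials[name]
        ax.plot(pot.grid, pot.energy / kt, color="tab:red", label="V / kT")
        ax.set_xlabel(f"{name} (deg)")
        ax.set_ylabel("V / kT")
        tw = ax.twinx()
        grid = DIHEDRAL_GRID if pot.periodic else ANGLE_GRID
        for fit, style, color in ((state.target_fits.get(name), "--", "k"),
                                  (result.final_fits.get(name), "-", "tab:blue")):
            if fit is None:
                continue
            if callable(fit):
                tw.plot(grid, fit(grid), style, color=color, lw=1)
            else:
                dens = np.asarray(fit)
                x = grid if len(dens) == len(grid) else pot.grid
                tw.plot(x[:len(dens)], dens, style, color=color, lw=1)
        tw.set_ylabel("P (deg$^{-1}$)")
        ax.set_title(name)
    hx = axes[len(names)]
    for name in names:
        hx.semilogy([row[name] for row in result.history], label=name)
    hx.set_xlabel("iteration")
    hx.set_ylabel("sup-norm (deg$^{-1}$)")
    hx.legend(fontsize=7)
    hx.set_title("convergence")
    for ax in axes[len(names) + 1:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ramachandran(density, path, title: str = "") -> None:
    """Heatmap of a 2D dihedral density on (-180, 180]^2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = density.density if hasattr(density, "density") else np.asarray(density)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(arr.T, origin="lower", extent=(-180, 180, -180, 180),
                   cmap="viridis", aspect="equal")
    fig.colorbar(im, ax=ax, label="P (deg$^{-2}$)")
    ax.set_xlabel("GXGX (deg)")
    ax.set_ylabel("XGXG (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
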