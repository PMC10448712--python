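"""Vectorized internal-coordinate geometry on (frame, bead, xyz) arrays."""

from __future__ import annotations

import numpy as np


def _as_frames(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.ndim != 3 or pos.shape[-1] != 3:
        raise ValueError(f"positions must be (n, 3) or (frames, n, 3), got {pos.shape}")
    return pos


def distances(positions: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Pair distances for index rows (i, j); shape (frames, npairs)."""
    pos = _as_frames(positions)
    idx = np.asarray(index, dtype=int).reshape(-1, 2)
    d = pos[:, idx[:, 1]] - pos[:, idx[:, 0]]
    return np.linalg.norm(d, axis=-1)


def angles_deg(positions: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Bead angles i-j-k in degrees, in (0, 180]; shape (frames, nangles)."""
    pos = _as_frames(positions)
    idx = np.asarray(index, dtype=int).reshape(-1, 3)
    u = pos[:, idx[:, 0]] - pos[:, idx[:, 1]]
    v = pos[:, idx[:, 2]] - pos[:, idx[:, 1]]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("fij,fij->fi", u, v) / np.clip(nu * nv, 1e-300, None)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedrals_deg(positions: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Dihedral angles i-j-k-l in degrees, in (-180, 180].

    Sign convention: the IUPAC torsion measured by atan2 of the axis-projected
    normals (positive for a right-handed twist about j->k).  Collinear inner
    triplets yield NaN; callers drop those samples rather than propagate them.
    """
    pos = _as_frames(positions)
    idx = np.asarray(index, dtype=int).reshape(-1, 4)
    b1 = pos[:, idx[:, 1]] - pos[:, idx[:, 0]]
    b2 = pos[:, idx[:, 2]] - pos[:, idx[:, 1]]
    b3 = pos[:, idx[:, 3]] - pos[:, idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.clip(np.linalg.norm(b2, axis=-1)[..., None], 1e-300, None))
    x = np.einsum("fij,fij->fi", n1, n2)
    y = np.einsum("fij,fij->fi", m1, n2)
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    phi = np.degrees(np.arctan2(y, x))
    phi = np.where(degenerate, np.nan, phi)
    # map -180 exactly onto +180 so the domain is (-180, 180]
    return np.where(phi <= -180.0, phi + 360.0, phi)


def wrap_deg(x: np.ndarray) -> np.ndarray:
    """Wrap values into (-180, 180]."""
    w = np.mod(np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(w <= -180.0, w + 360.0, w)
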