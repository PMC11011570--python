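"""Mass-weighted rigid-body superposition (Kabsch algorithm).

The minimized quantity is the mass-weighted RMSD

    RMSD = sqrt( (1/M) * sum_i m_i |r_i(ref) - (R r_i(mob) + t)|^2 ),

with M the total weight; reflections are excluded so the returned matrix
is always a proper rotation (det = +1).
"""

from __future__ import annotations

import numpy as np


class DegenerateGeometryError(ValueError):
    """The point set does not determine a unique rotation (collinear)."""


def _as_points(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    return x


def kabsch_superpose(mobile, reference, weights=None):
    """Optimal proper rotation and translation mapping mobile onto reference.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays, n >= 3
    weights : per-atom weights (e.g. masses); uniform when omitted.
        Zero-weight atoms are carried along but do not influence the fit.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix
    translation : (3,) vector; ``mobile @ rotation.T + translation``
        superposes mobile onto reference
    rmsd : weighted minimum RMSD in the input length unit
    """
    mob = _as_points(mobile, "mobile")
    ref = _as_points(reference, "reference")
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have equal point counts")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must be one per point")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")

    cm = (w[:, None] * mob).sum(axis=0) / wsum
    cr = (w[:, None] * ref).sum(axis=0) / wsum
    a = mob - cm
    b = ref - cr

    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    scale = max(s[0], 1e-30)
    if np.sum(s / scale > 1e-8) < 2:
        raise DegenerateGeometryError(
            "points are collinear; rotation is not uniquely determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm

    moved = a @ rotation.T
    rmsd = float(np.sqrt((w * ((moved - b) ** 2).sum(axis=1)).sum() / wsum))
    return rotation, translation, rmsd


def apply_transform(coords, rotation, translation) -> np.ndarray:
    """Apply ``x -> R x + t`` row-wise."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T \
        + np.asarray(translation)


def quaternion_superpose_rmsd(mobile, reference, weights=None) -> float:
    """Minimum weighted RMSD via the quaternion (Kearsley) eigenvalue method.

    Independent of :func:`kabsch_superpose`; used as a cross-check oracle.
    """
    mob = _as_points(mobile, "mobile")
    ref = _as_points(reference, "reference")
    n = mob.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    a = mob - (w[:, None] * mob).sum(axis=0) / wsum
    b = ref - (w[:, None] * ref).sum(axis=0) / wsum
    xm, ym, zm = (a - b).T
    xp, yp, zp = (a + b).T

    def sw(u, v):
        return float((w * u * v).sum())

    k = np.array([
        [sw(xm, xm) + sw(ym, ym) + sw(zm, zm),
         sw(yp, zm) - sw(ym, zp), sw(xm, zp) - sw(xp, zm),
         sw(xp, ym) - sw(xm, yp)],
        [0, sw(yp, yp) + sw(zp, zp) + sw(xm, xm),
         sw(xm, ym) - sw(xp, yp), sw(xm, zm) - sw(xp, zp)],
        [0, 0, sw(xp, xp) + sw(zp, zp) + sw(ym, ym),
         sw(ym, zm) - sw(yp, zp)],
        [0, 0, 0, sw(xp, xp) + sw(yp, yp) + sw(zm, zm)],
    ])
    k = k + np.triu(k, 1).T
    lam_min = np.linalg.eigvalsh(k)[0]
    return float(np.sqrt(max(lam_min, 0.0) / wsum))
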