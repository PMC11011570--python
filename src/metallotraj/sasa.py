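"""Solvent-accessible surface area by the Shrake-Rupley method.

Each atom is inflated by the probe radius (1.4 A, a water-sized probe)
and covered with a deterministic golden-spiral point set; the accessible
fraction of points, times the inflated sphere area, is the atom's SASA.
Iron is given zero radius by default: in FeS clusters the metal is buried
by its ligand atoms and should not contribute surface of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel, SelectionSpec, resolve_selection

#: Bondi-type van der Waals radii (Angstrom).  The table is configuration
#: data: swap in another convention via SASAParams.radii_table.
DEFAULT_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "NA": 2.27, "MG": 1.73, "K": 2.75,
    "CA": 2.31, "ZN": 1.39, "FE": 1.56,  # Fe overridden to 0 by default
}


@dataclass
class SASAParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    fe_radius_override: float = 0.0

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_sphere_points < 32:
            raise ValueError("need at least 32 sphere points")

    def radius_of(self, element: str) -> float:
        el = element.upper()
        if el == "FE":
            return self.fe_radius_override
        if el not in self.radii_table:
            raise KeyError(el)
        return self.radii_table[el]


def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit-sphere points on a golden spiral (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom accessible areas (A^2) for given coordinates and vdW radii."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    unit = sphere_points(n_points)
    # a zero-radius atom (e.g. a ligand-buried metal) has no surface of
    # its own and occludes nothing, even after probe inflation
    inflated = np.where(radii > 0, radii + probe_radius, 0.0)
    areas = np.zeros(n)
    if n == 0:
        return areas
    tree = cKDTree(coords)
    r_max = inflated.max()
    for i in range(n):
        ri = inflated[i]
        if ri <= 0:
            continue
        # Any atom whose inflated sphere can reach atom i's surface points
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + r_max)
                      if j != i and inflated[j] > 0]
        pts = coords[i] + ri * unit
        if neighbours:
            nb = np.array(neighbours, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * ri * ri * accessible / n_points
    return areas


def sasa(model: StructureModel, params: SASAParams | None = None,
         subset: SelectionSpec | None = None) -> tuple[np.ndarray, float]:
    """Per-atom areas and their total for a model (or an isolated subset).

    When ``subset`` is given the computation sees ONLY the subset atoms --
    this is the "bare" convention used by the compactness ratio, where
    each domain's area is evaluated ignoring all other atoms.
    """
    params = params or SASAParams()
    work = model if subset is None else model.subset(resolve_selection(model, subset))
    missing = sorted({a.element.upper() for a in work.atoms
                      if a.element.upper() != "FE"
                      and a.element.upper() not in params.radii_table})
    if missing:
        raise KeyError(f"no SASA radius for elements: {missing}")
    radii = np.array([params.radius_of(a.element) for a in work.atoms])
    areas = shrake_rupley(work.coords, radii, params.probe_radius,
                          params.n_sphere_points)
    return areas, float(areas.sum())
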