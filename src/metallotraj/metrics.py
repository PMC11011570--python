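"""Time-resolved structural metrics for metalloprotein trajectories.

The suite covers the quantities used to characterize [FeFe]-hydrogenase
models in solution: mass-weighted RMSD and gyration radius, the radial
distribution function g(r) of Fe-water pairs, salt-bridge counts,
solvent accessibility (via :mod:`.sasa`), the compactness ratio R, RMSF
from a truncated principal-component decomposition, the probability that
a first-shell water points a hydrogen at the distal iron, FeS
cluster-cluster centre-of-mass distances, and statistics of collective-
variable samples in distance windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (StructureModel, Trajectory, DomainMap, SelectionSpec,
                    resolve_selection)
from .sasa import SASAParams, sasa
from .superpose import kabsch_superpose, apply_transform


# ----------------------------------------------------------------------
# RMSD / Rg
# ----------------------------------------------------------------------

def rmsd(frame_a, frame_b, masses=None, fit: bool = False) -> float:
    """Mass-weighted RMSD between two coordinate sets (Angstrom).

    With ``fit`` the mobile frame is first rigidly superposed onto the
    reference (the standard convention for comparing structures); without
    it the raw positional deviation is returned.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("frames must be equal-shape (n, 3) arrays")
    w = np.ones(len(a)) if masses is None else np.asarray(masses, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total mass must be positive")
    if fit:
        _, _, value = kabsch_superpose(b, a, w)
        return value
    return float(np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum() / w.sum()))


def gyration_radius(frame, masses=None) -> float:
    """Mass-weighted radius of gyration about the centre of mass."""
    r = np.asarray(frame, dtype=float)
    if r.size == 0:
        raise ValueError("empty selection")
    if r.ndim != 2:
        r = r.reshape(-1, 3)
    w = np.ones(len(r)) if masses is None else np.asarray(masses, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total mass must be positive")
    com = (w[:, None] * r).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((r - com) ** 2).sum(axis=1)).sum() / w.sum()))


# ----------------------------------------------------------------------
# Radial distribution function
# ----------------------------------------------------------------------

@dataclass
class RadialDistribution:
    bin_edges: np.ndarray          # Angstrom
    g_values: np.ndarray           # dimensionless, one per bin
    n_a: int
    n_b: int
    local_density: float           # atoms / A^3 used for normalization

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _minimum_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def rdf(traj: Trajectory, group_a, group_b, bin_width: float = 0.1,
        r_max: float = 10.0, density_mode: str = "box") -> RadialDistribution:
    """Radial distribution function of b-atoms around a-atoms.

    Pair distances use the minimum-image convention when the trajectory
    carries an orthorhombic box; each bin is normalized by its shell
    volume 4*pi*r^2*dr and by the mean b density so that an ideal gas
    gives g -> 1.  Self-pairs (shared atom indices) are excluded.

    ``density_mode``: ``"box"`` uses the whole-cell density N_b/V;
    ``"local"`` renormalizes by the density actually observed inside the
    r_max sphere (useful for inhomogeneous, non-periodic systems).
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("rdf groups must be non-empty")
    if density_mode not in ("box", "local"):
        raise ValueError(f"unknown density_mode {density_mode!r}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    shared = np.isin(ga, gb)
    volumes = []
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        diff = coords[gb][None, :, :] - coords[ga][:, None, :]
        if traj.box is not None:
            box = traj.box[f]
            if r_max > box.min() / 2 + 1e-9:
                raise ValueError(
                    f"r_max {r_max} exceeds half the smallest box edge "
                    f"({box.min() / 2:.3f} A) at frame {f}")
            diff = _minimum_image(diff, box)
            volumes.append(float(np.prod(box)))
        d = np.sqrt((diff ** 2).sum(axis=2))
        if shared.any():
            for i in np.nonzero(shared)[0]:
                j = np.nonzero(gb == ga[i])[0]
                d[i, j] = np.inf
        counts += np.histogram(d, bins=edges)[0]
    if traj.box is not None:
        density = gb.size / float(np.mean(volumes))
    else:
        warnings.warn(
            "rdf without a box: normalizing by the density inside the "
            "r_max sphere", stacklevel=2)
        density_mode = "local"
        density = np.nan
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if density_mode == "local":
        total_in_sphere = counts.sum() / (traj.n_frames * ga.size)
        density = total_in_sphere / (4.0 / 3.0 * np.pi * r_max ** 3)
    if density > 0:
        g = counts / (traj.n_frames * ga.size * shell * density)
    else:
        g = np.zeros_like(counts)
    return RadialDistribution(edges, g, int(ga.size), int(gb.size),
                              float(density))


# ----------------------------------------------------------------------
# Salt bridges
# ----------------------------------------------------------------------

@dataclass
class ChargeGroups:
    """Acidic / basic atom index groups for salt-bridge counting."""

    acidic: np.ndarray
    basic: np.ndarray
    cutoff: float = 4.0

    def __post_init__(self):
        self.acidic = np.asarray(self.acidic, dtype=int)
        self.basic = np.asarray(self.basic, dtype=int)
        if np.intersect1d(self.acidic, self.basic).size:
            raise ValueError("acidic and basic groups must be disjoint")

    @classmethod
    def from_model(cls, model: StructureModel, cutoff: float = 4.0) -> "ChargeGroups":
        """Charged-group atoms by convention: Cdelta(Glu), Cgamma(Asp) and
        the C-terminal carboxyl carbon versus Nzeta(Lys), Neta(Arg) and
        the N-terminal nitrogen."""
        acidic, basic = [], []
        for (_, _, resname), idx in model.residues():
            for i in idx:
                a = model.atoms[i]
                if resname == "GLU" and a.name == "CD":
                    acidic.append(i)
                elif resname == "ASP" and a.name == "CG":
                    acidic.append(i)
                elif resname == "LYS" and a.name == "NZ":
                    basic.append(i)
                elif resname == "ARG" and a.name in ("NH1", "NH2"):
                    basic.append(i)
        by_chain: dict[str, list[int]] = {}
        for i, a in enumerate(model.atoms):
            by_chain.setdefault(a.chain_id, []).append(i)
        for idx in by_chain.values():
            first_res = model.atoms[idx[0]].residue_number
            last_res = model.atoms[idx[-1]].residue_number
            for i in idx:
                a = model.atoms[i]
                if a.residue_number == first_res and a.name == "N":
                    basic.append(i)
                if a.residue_number == last_res and a.name == "C":
                    acidic.append(i)
        return cls(np.array(sorted(set(acidic))), np.array(sorted(set(basic))),
                   cutoff)


def salt_bridges(frame, groups: ChargeGroups) -> int:
    """Number of acidic-basic atom pairs in contact (distance <= cutoff)."""
    coords = np.asarray(frame, dtype=float)
    if groups.acidic.size == 0 or groups.basic.size == 0:
        return 0
    diff = coords[groups.basic][None, :, :] - coords[groups.acidic][:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return int(np.count_nonzero(d <= groups.cutoff))


# ----------------------------------------------------------------------
# Compactness
# ----------------------------------------------------------------------

@dataclass
class CompactnessResult:
    R: float
    sasa_whole: float
    sasa_bare: dict[str, float]
    compact: bool
    threshold: float = 0.95


def is_compact(R: float, threshold: float = 0.95) -> bool:
    """Compact iff R <= threshold (the boundary itself counts as compact)."""
    return R <= threshold


def compactness_ratio(model: StructureModel, domains: DomainMap,
                      params: SASAParams | None = None,
                      threshold: float = 0.95,
                      f_label: str = "F", h_label: str = "H",
                      ) -> CompactnessResult:
    """Compactness ratio R = SASA(whole) / (SASA(bare F) + SASA(bare H)).

    "Bare" areas are computed with each domain isolated from every other
    atom, so R -> 1 for non-overlapping domains, R < 1 when one domain
    occludes the other, and R can slightly exceed 1 when residues outside
    F and H (a short C-terminus) contribute to the whole-molecule area.
    """
    params = params or SASAParams()
    for label in (f_label, h_label):
        if label not in domains:
            raise ValueError(f"domain map lacks the {label!r} domain")
    _, whole = sasa(model, params)
    bare = {}
    for label in (f_label, h_label):
        _, area = sasa(model, params, subset=domains.selection(label))
        bare[label] = area
    denom = sum(bare.values())
    if denom <= 0:
        raise ValueError("bare domain SASA sum is zero")
    ratio = whole / denom
    return CompactnessResult(ratio, whole, bare, is_compact(ratio, threshold),
                             threshold)


# ----------------------------------------------------------------------
# RMSF by principal component analysis
# ----------------------------------------------------------------------

@dataclass
class RMSFResult:
    atom_indices: np.ndarray       # indices into the topology
    per_atom: np.ndarray           # Angstrom
    per_residue: dict[int, float]  # residue number -> Angstrom
    eigenvalues: np.ndarray        # full spectrum, descending


def rmsf_pca(traj: Trajectory, selection: SelectionSpec | None = None,
             n_eigenvectors: int = 4, fit: bool = True) -> RMSFResult:
    """Per-atom / per-residue RMSF from the top principal components.

    Frames are superposed (mass-weighted) onto their mean structure, the
    3N x 3N positional covariance is diagonalized, and the fluctuation of
    each atom is rebuilt from the ``n_eigenvectors`` largest modes.  With
    the full spectrum this equals the direct per-atom variance; truncation
    can only lower it.  Per-residue values are root-mean-square over the
    residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sel = selection if selection is not None else SelectionSpec()
    idx = resolve_selection(traj.topology, sel)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    n3 = 3 * idx.size
    if n_eigenvectors > n3:
        raise ValueError(f"requested {n_eigenvectors} eigenvectors for a "
                         f"{n3}-dimensional covariance")
    masses = traj.topology.masses[idx]
    if masses.sum() <= 0:
        masses = np.ones(idx.size)
    x = traj.frames[:, idx, :].copy()
    if fit:
        # two-pass: align to the first frame, then to the resulting mean
        for pass_no in range(2):
            target = x[0].copy() if pass_no == 0 else x.mean(axis=0)
            for f in range(x.shape[0]):
                rot, tr, _ = kabsch_superpose(x[f], target, masses)
                x[f] = apply_transform(x[f], rot, tr)
    mean = x.mean(axis=0)
    fluct = (x - mean).reshape(traj.n_frames, n3)
    cov = fluct.T @ fluct / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = n_eigenvectors
    msf_coords = (evecs[:, :k] ** 2 * evals[:k][None, :]).sum(axis=1)
    per_atom = np.sqrt(msf_coords.reshape(idx.size, 3).sum(axis=1))
    per_residue_sq: dict[int, list[float]] = {}
    for local, i in enumerate(idx):
        resnum = traj.topology.atoms[i].residue_number
        per_residue_sq.setdefault(resnum, []).append(per_atom[local] ** 2)
    per_res = {r: float(np.sqrt(np.mean(v))) for r, v in per_residue_sq.items()}
    return RMSFResult(idx, per_atom, per_res, evals)


# ----------------------------------------------------------------------
# Fe-water orientation
# ----------------------------------------------------------------------

@dataclass
class OrientationResult:
    probability: float | None      # None when no shell event occurred
    n_events: int
    n_inward: int

    @property
    def defined(self) -> bool:
        return self.n_events > 0


def fe_water_orientation(traj: Trajectory, fe_atom: int,
                         waters: Sequence[tuple[int, int, int]],
                         shell_cutoff: float = 4.0) -> OrientationResult:
    """Fraction of first-shell waters oriented H-first towards an iron.

    A shell event is a frame/water pair whose oxygen lies within
    ``shell_cutoff`` of the iron; the event counts as H-inward when the
    nearer hydrogen is closer to the iron than the oxygen is.  With no
    events at all the probability is undefined (None), not zero.
    """
    waters = [tuple(w) for w in waters]
    if not waters:
        raise ValueError("no waters supplied")
    o_idx = np.array([w[0] for w in waters])
    h1_idx = np.array([w[1] for w in waters])
    h2_idx = np.array([w[2] for w in waters])
    fe = traj.frames[:, fe_atom, :]
    d_o = np.linalg.norm(traj.frames[:, o_idx, :] - fe[:, None, :], axis=2)
    d_h1 = np.linalg.norm(traj.frames[:, h1_idx, :] - fe[:, None, :], axis=2)
    d_h2 = np.linalg.norm(traj.frames[:, h2_idx, :] - fe[:, None, :], axis=2)
    in_shell = d_o <= shell_cutoff
    n_events = int(in_shell.sum())
    if n_events == 0:
        return OrientationResult(None, 0, 0)
    inward = (np.minimum(d_h1, d_h2) < d_o) & in_shell
    n_inward = int(inward.sum())
    return OrientationResult(n_inward / n_events, n_events, n_inward)


# ----------------------------------------------------------------------
# Cluster distances and the functional window
# ----------------------------------------------------------------------

def center_of_mass(coords, masses) -> np.ndarray:
    w = np.asarray(masses, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total mass must be positive")
    return (w[:, None] * np.asarray(coords, dtype=float)).sum(axis=0) / w.sum()


def cluster_com_distance(frame, cluster_a_indices, cluster_b_indices,
                         masses) -> float:
    """Distance between two mass-weighted cluster centres, in nm."""
    ia = np.asarray(cluster_a_indices, dtype=int)
    ib = np.asarray(cluster_b_indices, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("cluster selections must be non-empty")
    coords = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    ca = center_of_mass(coords[ia], masses[ia])
    cb = center_of_mass(coords[ib], masses[ib])
    return float(np.linalg.norm(ca - cb)) / 10.0  # Angstrom -> nm


#: Inter-cluster centre-of-mass distances compatible with electron
#: transfer in active [FeFe] hydrogenases, in nm (11-14 Angstrom).
FUNCTIONAL_RANGE_NM: tuple[float, float] = (1.1, 1.4)


def classify_functional(d: float,
                        window: tuple[float, float] = FUNCTIONAL_RANGE_NM) -> bool:
    """True iff the cluster-cluster distance (nm) is in the functional range.

    Bounds are inclusive.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    return window[0] <= d <= window[1]


# ----------------------------------------------------------------------
# CV samples and distance-window statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CVSample:
    """One sampled configuration in collective-variable space."""

    d: float                       # cluster-cluster COM distance, nm
    sasa_h_cluster: float          # raw Angstrom^2
    R: float                       # compactness ratio
    walker: int = 0
    frame: int = 0

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be non-negative")


@dataclass(frozen=True)
class WindowSpec:
    label: str
    d_min: float                   # nm, inclusive
    d_max: float                   # nm, inclusive

    def __post_init__(self):
        if self.d_min > self.d_max:
            raise ValueError(f"window {self.label!r}: d_min > d_max")

    def contains(self, d: float) -> bool:
        return self.d_min <= d <= self.d_max


#: The three distance windows used to stratify metadynamics samples.
DEFAULT_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec("w1", 0.75, 1.25),
    WindowSpec("w2", 1.75, 2.25),
    WindowSpec("w3", 2.75, 3.25),
)


def window_stats(samples: Sequence[CVSample],
                 windows: Sequence[WindowSpec] = DEFAULT_WINDOWS,
                 r_threshold: float = 0.95,
                 per_window_denominator: bool = False) -> pd.DataFrame:
    """Membership count, H-cluster SASA mean +- sd, and percent-compact
    per distance window.

    By default the percent-compact denominator is the TOTAL number of
    collected samples (the tabulation convention for metadynamics
    ensembles); ``per_window_denominator`` switches to the window's own
    count.  Empty windows report count 0 and NaN statistics.
    """
    if not samples:
        raise ValueError("no samples supplied")
    total = len(samples)
    rows = []
    for w in windows:
        members = [s for s in samples if w.contains(s.d)]
        n = len(members)
        if n:
            areas = np.array([s.sasa_h_cluster for s in members])
            n_compact = sum(1 for s in members if is_compact(s.R, r_threshold))
            denom = n if per_window_denominator else total
            rows.append({"window": w.label, "count": n,
                         "sasa_mean": float(areas.mean()),
                         "sasa_sd": float(areas.std(ddof=0)),
                         "compact_percent": 100.0 * n_compact / denom})
        else:
            rows.append({"window": w.label, "count": 0,
                         "sasa_mean": np.nan, "sasa_sd": np.nan,
                         "compact_percent": np.nan})
    return pd.DataFrame(rows).set_index("window")
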