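"""Ground-truth generators: every pipeline stage gets a testable input.

Each generator returns its artifact together with a :class:`SyntheticTruth`
recording the planted parameters, so downstream metrics can be checked
against known answers.  All generators are deterministic under
``(seed, params)``.

What these toys emulate -- and what they do not: the structures are
idealized helical sticks (real domains pack side chains and clusters),
the trajectories are uncorrelated Gaussian jitter (real MD is correlated
in time), and the hydration shells fix rigid water geometry with only the
orientation statistics controlled.  They validate the metrics, not the
biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .annotation import MotifDef
from .metadyn import ToySystem
from .model import AtomRecord, StructureModel, Trajectory, DomainMap, ClusterSpec


@dataclass
class SyntheticTruth:
    """Provenance plus planted parameters and expected downstream values."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=_jsonable, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ----------------------------------------------------------------------
# Toy structures
# ----------------------------------------------------------------------

# Ideal alpha-helix: ~1.5 A rise and 100 degrees twist per residue on a
# 2.3 A radius; backbone atoms offset around the C-alpha trace.
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3


def _helix_residue(i: int, origin: np.ndarray) -> dict[str, np.ndarray]:
    ang = i * _HELIX_TWIST
    ca = origin + np.array([_HELIX_RADIUS * np.cos(ang),
                            _HELIX_RADIUS * np.sin(ang),
                            i * _HELIX_RISE])
    # fixed local offsets; adequate for occupancy/SASA work
    radial = np.array([np.cos(ang), np.sin(ang), 0.0])
    tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
    return {
        "N": ca + 0.9 * tangent - 0.8 * np.array([0, 0, 1.0]),
        "CA": ca,
        "C": ca - 0.9 * tangent + 0.8 * np.array([0, 0, 1.0]),
        "O": ca - 1.2 * tangent + 1.7 * np.array([0, 0, 1.0]),
        "CB": ca + 1.2 * radial,
    }


def gen_toy_protein(n_domains: int = 2, residues_per_domain: int = 30,
                    separation: float = 100.0, with_c_terminus: bool = False,
                    seed: int = 0,
                    ) -> tuple[StructureModel, DomainMap, SyntheticTruth]:
    """Idealized multi-domain helical protein with an F/H/C architecture.

    Domains are straight alpha-helices laid along z and displaced along x
    by ``separation`` (A) between consecutive domain origins; an optional
    short C-terminal tail is placed well away from both domains.
    """
    if n_domains < 1 or residues_per_domain < 1:
        raise ValueError("sizes must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    labels = ["F", "H"][:n_domains] + [f"D{k}" for k in range(2, n_domains)]
    atoms: list[AtomRecord] = []
    ranges: dict[str, tuple[int, int]] = {}
    serial, resnum = 1, 0
    for d, label in enumerate(labels):
        origin = np.array([d * separation, 0.0, 0.0])
        start = resnum + 1
        for i in range(residues_per_domain):
            resnum += 1
            for name, pos in _helix_residue(i, origin).items():
                atoms.append(AtomRecord.create(serial, name, resnum, "ALA",
                                               "A", pos,
                                               element=name[0]))
                serial += 1
        ranges[label] = (start, resnum)
    if with_c_terminus:
        tail_origin = np.array([-max(separation, 50.0), 80.0, 0.0])
        start = resnum + 1
        for i in range(5):
            resnum += 1
            for name, pos in _helix_residue(i, tail_origin).items():
                atoms.append(AtomRecord.create(serial, name, resnum, "ALA",
                                               "A", pos, element=name[0]))
                serial += 1
        ranges["C"] = (start, resnum)
    model = StructureModel(atoms, title="toy multi-domain helical protein")
    domains = DomainMap(ranges)
    truth = SyntheticTruth(
        "gen_toy_protein", seed,
        params={"n_domains": n_domains,
                "residues_per_domain": residues_per_domain,
                "separation": separation,
                "with_c_terminus": with_c_terminus},
        expected={"n_atoms": model.n_atoms, "domain_ranges": dict(ranges)})
    return model, domains, truth


_CUBANE_EDGE = 2.7  # Fe-Fe edge of an idealized [4Fe4S] cubane, Angstrom


def gen_cubane(center, label: str = "4Fe4S",
               first_serial: int = 1) -> tuple[StructureModel, ClusterSpec]:
    """An idealized [4Fe4S] cubane: Fe and S on alternating cube corners."""
    center = np.asarray(center, dtype=float)
    h = _CUBANE_EDGE / 2.0
    corners = np.array([[sx, sy, sz] for sx in (-h, h) for sy in (-h, h)
                        for sz in (-h, h)])
    atoms = []
    serial = first_serial
    fe_serials = []
    n_fe = n_s = 0
    for c in corners:
        is_fe = (c > 0).sum() % 2 == 0   # alternate corners
        if is_fe:
            n_fe += 1
            element, name = "Fe", f"FE{n_fe}"
            fe_serials.append(serial)
        else:
            n_s += 1
            element, name = "S", f"S{n_s}"
        atoms.append(AtomRecord.create(serial, name, 1,
                                       "SF4", "X", center + c, element=element))
        serial += 1
    model = StructureModel(atoms, title=label)
    spec = ClusterSpec(label, tuple(a.atom_id for a in atoms))
    return model, spec


# ----------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------

def gen_harmonic_trajectory(model: StructureModel, per_atom_std,
                            n_frames: int, seed: int = 0,
                            axis: str | None = None,
                            ) -> tuple[Trajectory, SyntheticTruth]:
    """Frames = reference + independent Gaussian displacements.

    ``per_atom_std`` gives each atom's displacement standard deviation
    (A); isotropic over x, y, z unless ``axis`` restricts the motion to
    one Cartesian direction.  The truth records the exact per-atom
    fluctuation, i.e. the expected full-spectrum RMSF: std * sqrt(3)
    isotropically, std along a single axis.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    stds = np.broadcast_to(np.asarray(per_atom_std, dtype=float),
                           (model.n_atoms,)).copy()
    if np.any(stds < 0):
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    ref = model.coords
    noise = rng.standard_normal((n_frames, model.n_atoms, 3)) * stds[None, :, None]
    if axis is not None:
        keep = {"x": 0, "y": 1, "z": 2}[axis]
        mask = np.zeros(3)
        mask[keep] = 1.0
        noise = noise * mask[None, None, :]
        expected_rmsf = stds.copy()
    else:
        expected_rmsf = stds * np.sqrt(3.0)
    traj = Trajectory(model, ref[None, :, :] + noise)
    truth = SyntheticTruth(
        "gen_harmonic_trajectory", seed,
        params={"n_frames": n_frames, "axis": axis, "per_atom_std": stds},
        expected={"per_atom_rmsf": expected_rmsf})
    return traj, truth


_OH = 0.957                      # rigid O-H bond length, A
_HOH = np.deg2rad(104.5)         # rigid water angle


def _water_coords(o_pos: np.ndarray, bisector: np.ndarray,
                  perp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """H positions for an O at ``o_pos`` with the H-O-H bisector along
    ``bisector`` (unit) and the molecular plane spanned with ``perp``."""
    half = _HOH / 2.0
    h1 = o_pos + _OH * (np.cos(half) * bisector + np.sin(half) * perp)
    h2 = o_pos + _OH * (np.cos(half) * bisector - np.sin(half) * perp)
    return h1, h2


def gen_hydration_shell(fe_position=(0.0, 0.0, 0.0), n_events: int = 1000,
                        orientation_fraction: float = 0.1,
                        r_O: float = 3.5, r_H_in: float = 2.5, seed: int = 0,
                        ) -> tuple[Trajectory, SyntheticTruth]:
    """Shell waters around an iron with a planted H-inward fraction.

    Each frame holds one water whose oxygen sits at ``r_O`` from the iron
    in a random direction; with probability ``orientation_fraction`` one
    hydrogen points at the iron, placed exactly at ``r_H_in`` (the O-H1
    bond absorbs the small difference from the rigid 0.957 A length; H2
    keeps the rigid geometry), otherwise both hydrogens lie beyond the
    oxygen (H-outward).
    """
    if not 0.0 <= orientation_fraction <= 1.0:
        raise ValueError("orientation fraction must be in [0, 1]")
    if r_H_in > r_O + _OH:
        raise ValueError("impossible geometry: r_H_in exceeds r_O + O-H length")
    if n_events < 1:
        raise ValueError("need at least one event")
    fe = np.asarray(fe_position, dtype=float)
    rng = np.random.default_rng(seed)
    inward = rng.random(n_events) < orientation_fraction
    frames = np.empty((n_events, 4, 3))
    for k in range(n_events):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        perp = np.cross(u, rng.standard_normal(3))
        perp /= np.linalg.norm(perp)
        o_pos = fe + r_O * u
        if inward[k]:
            h1 = fe + r_H_in * u                      # planted inward H
            h2 = o_pos + _OH * (np.cos(_HOH) * (-u) + np.sin(_HOH) * perp)
        else:
            h1, h2 = _water_coords(o_pos, u, perp)    # bisector away from Fe
        frames[k] = [fe, o_pos, h1, h2]
    atoms = [
        AtomRecord.create(1, "FE", 1, "FES", "X", fe, element="Fe"),
        AtomRecord.create(2, "OW", 2, "HOH", "W", frames[0, 1], element="O"),
        AtomRecord.create(3, "HW1", 2, "HOH", "W", frames[0, 2], element="H"),
        AtomRecord.create(4, "HW2", 2, "HOH", "W", frames[0, 3], element="H"),
    ]
    traj = Trajectory(StructureModel(atoms, title="hydration shell"), frames)
    truth = SyntheticTruth(
        "gen_hydration_shell", seed,
        params={"n_events": n_events, "p": orientation_fraction,
                "r_O": r_O, "r_H_in": r_H_in},
        expected={"planted_fraction": float(inward.mean()),
                  "fe_atom": 0, "waters": [(1, 2, 3)]})
    return traj, truth


# ----------------------------------------------------------------------
# Sequences
# ----------------------------------------------------------------------

_BACKGROUND_ALPHABET = "ADEFGHIKLMNPQRSTVWY"   # 19 letters, no Cys


def gen_sequence(length: int,
                 planted_motifs: list[tuple[MotifDef, int]] = (),
                 planted_cys_positions: list[int] = (),
                 seed: int = 0) -> tuple[str, SyntheticTruth]:
    """Random sequence with planted motifs and exact Cys positions.

    The background alphabet excludes cysteine, so the Cys positions of
    the output are exactly the planted ones (plus any C inside a planted
    motif).  Positions are 1-based; overlapping planted features raise.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_BACKGROUND_ALPHABET), size=length))
    occupied: set[int] = set()
    for motif, pos in planted_motifs:
        span = range(pos, pos + len(motif.consensus))
        if pos < 1 or span[-1] > length:
            raise ValueError(f"motif {motif.motif_id} does not fit at {pos}")
        if occupied & set(span):
            raise ValueError(f"motif {motif.motif_id} collides at {pos}")
        occupied.update(span)
        for off, letter in enumerate(motif.consensus):
            seq[pos - 1 + off] = letter
    for pos in planted_cys_positions:
        if pos < 1 or pos > length:
            raise ValueError(f"Cys position {pos} outside the sequence")
        if pos in occupied:
            raise ValueError(f"Cys position {pos} collides with a motif")
        occupied.add(pos)
        seq[pos - 1] = "C"
    sequence = "".join(seq)
    truth = SyntheticTruth(
        "gen_sequence", seed,
        params={"length": length,
                "planted_motifs": [(m.motif_id, m.consensus, p)
                                   for m, p in planted_motifs],
                "planted_cys_positions": list(planted_cys_positions)},
        expected={"cys_positions": sorted(
            set(planted_cys_positions)
            | {p + off
               for m, p in planted_motifs
               for off, letter in enumerate(m.consensus) if letter == "C"})})
    return sequence, truth


# ----------------------------------------------------------------------
# Toy potentials
# ----------------------------------------------------------------------

def gen_double_well(barrier: float, asymmetry: float = 0.0,
                    ) -> tuple[ToySystem, SyntheticTruth]:
    """Quartic 1D double well U(s) = barrier*(s^2-1)^2 + asymmetry*(s+1)/2.

    Wells near s = -1 (lower) and s = +1 (higher by ~``asymmetry``); both
    energies in kBT units.  The truth stores the basin free-energy
    difference Delta F = -ln(Z+/Z-) from numerical quadrature of
    exp(-U(s)) over the two basins split at the barrier top.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    b, a = float(barrier), float(asymmetry)

    def potential(q: np.ndarray) -> np.ndarray:
        s = q[:, 0]
        return b * (s * s - 1.0) ** 2 + a * (s + 1.0) / 2.0

    def force(q: np.ndarray) -> np.ndarray:
        s = q[:, 0]
        return -(4.0 * b * s * (s * s - 1.0) + a / 2.0)[:, None]

    system = ToySystem(dimension=1, potential=potential, force=force)

    from scipy.integrate import quad
    u = lambda s: b * (s * s - 1.0) ** 2 + a * (s + 1.0) / 2.0
    from scipy.optimize import minimize_scalar
    top = minimize_scalar(lambda s: -u(s), bounds=(-0.8, 0.8),
                          method="bounded").x
    z_left = quad(lambda s: np.exp(-u(s)), -4.0, top, limit=200)[0]
    z_right = quad(lambda s: np.exp(-u(s)), top, 4.0, limit=200)[0]
    delta_f = -np.log(z_right / z_left)
    truth = SyntheticTruth(
        "gen_double_well", 0,
        params={"barrier": b, "asymmetry": a},
        expected={"delta_f_kbt": float(delta_f), "barrier_top": float(top)})
    return system, truth
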