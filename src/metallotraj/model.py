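"""Core domain types shared by every analysis stage.

The unit conventions are fixed package-wide: lengths are stored in
Angstrom, masses in amu, times in ps.  Nanometres appear only at the
presentation layer (e.g. cluster--cluster distances are *reported* in nm
because that is how distance windows are conventionally quoted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import seq1

# Standard atomic weights (amu) for the elements that occur in protein /
# FeS-cluster models.  Unknown elements are kept with mass 0 and excluded
# from mass-weighted operations (a warning is emitted at creation time).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
}

#: Heavy backbone atom names used for scaffold superpositions.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


def element_mass(element: str) -> float:
    """Mass in amu for ``element``; 0.0 for unrecognised symbols."""
    return ATOMIC_MASSES.get(element.upper(), 0.0)


def guess_element(atom_name: str) -> str:
    """Guess the element symbol from a PDB atom name.

    Two-letter candidates (e.g. ``FE``) are preferred when they are known
    elements, otherwise the first alphabetic character is used.
    """
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return "X"
    if stripped[:2].upper() in ATOMIC_MASSES and len(stripped) >= 2:
        # Avoid eating "CA" (alpha carbon) / "CD" etc.: a two-letter element
        # is only accepted when the name does not look like a carbon/nitro/
        # oxygen/sulfur position label (C..., N..., O..., S..., H...).
        if stripped[0].upper() not in ("C", "N", "O", "S", "H", "P"):
            return stripped[:2].upper().capitalize()
    return stripped[0].upper()


@dataclass
class AtomRecord:
    """A single atom with the attributes every metric consumes.

    ``mass`` and ``position`` are the m_i and r_i entering the
    mass-weighted structural formulas (RMSD, gyration radius, centres of
    mass).
    """

    atom_id: int
    name: str
    element: str
    mass: float
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite coordinates")
        if self.mass < 0:
            raise ValueError(f"atom {self.atom_id}: negative mass")

    @classmethod
    def create(cls, atom_id: int, name: str, residue_number: int,
               residue_name: str, chain_id: str, position,
               element: str | None = None) -> "AtomRecord":
        """Build an atom, assigning mass (and element, if omitted) from the name."""
        if element is None or not element.strip():
            element = guess_element(name)
        element = element.strip()
        mass = element_mass(element)
        if mass == 0.0:
            warnings.warn(
                f"atom {atom_id} ({name}): unknown element {element!r}; "
                "mass set to 0, atom excluded from mass-weighted operations",
                stacklevel=2,
            )
            element = "X"
        return cls(atom_id, name, element, mass, residue_number,
                   residue_name, chain_id, np.asarray(position, dtype=float))


class StructureModel:
    """An ordered collection of atoms: the unit of all structural work."""

    def __init__(self, atoms: Sequence[AtomRecord], title: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.title = title

    # -- array views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    # -- residue helpers -----------------------------------------------
    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
        """Iterate ``((chain, resnum, resname), atom_indices)`` in atom order."""
        key = None
        indices: list[int] = []
        for i, atom in enumerate(self.atoms):
            k = (atom.chain_id, atom.residue_number, atom.residue_name)
            if k != key:
                if key is not None:
                    yield key, indices
                key, indices = k, []
            indices.append(i)
        if key is not None:
            yield key, indices

    @property
    def sequence(self) -> str:
        """One-letter amino-acid sequence derived from the residue records.

        Non-amino-acid residues (waters, FeS clusters) are skipped.
        """
        letters = []
        for (_, _, resname), _idx in self.residues():
            one = seq1(resname.capitalize(), undef_code="?")
            if one != "?":
                letters.append(one)
        return "".join(letters)

    def subset(self, indices: Iterable[int], title: str | None = None) -> "StructureModel":
        idx = list(indices)
        return StructureModel([self.atoms[i] for i in idx],
                              title=title if title is not None else self.title)

    def copy(self) -> "StructureModel":
        return StructureModel(
            [AtomRecord(a.atom_id, a.name, a.element, a.mass, a.residue_number,
                        a.residue_name, a.chain_id, a.position.copy())
             for a in self.atoms],
            title=self.title,
        )

    def validate(self) -> None:
        """Check the structural invariants (ordering, positive total mass)."""
        if self.total_mass <= 0:
            raise ValueError("structure has no mass-carrying atoms")
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_number < prev:
                raise ValueError(
                    f"residue numbering decreases within chain {a.chain_id!r} "
                    f"at residue {a.residue_number}")
            last[a.chain_id] = a.residue_number

    def __repr__(self) -> str:
        return f"StructureModel(n_atoms={self.n_atoms}, title={self.title!r})"


class Trajectory:
    """Ordered frames of coordinates for a fixed atom set."""

    def __init__(self, topology: StructureModel, frames: np.ndarray,
                 times: np.ndarray | None = None,
                 box: np.ndarray | None = None):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frames carry {frames.shape[1]} atoms but topology has "
                f"{topology.n_atoms}")
        self.topology = topology
        self.frames = frames
        self.times = None if times is None else np.asarray(times, dtype=float)
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.ndim == 1:
                box = np.tile(box, (len(frames), 1))
            if box.shape != (len(frames), 3):
                raise ValueError("box must be (3,) or (n_frames, 3)")
            if np.any(box <= 0):
                raise ValueError("box edge lengths must be positive")
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


@dataclass(frozen=True)
class SelectionSpec:
    """A structured atom filter; resolution is deterministic in atom order."""

    chain: str | None = None
    residue_range: tuple[int, int] | None = None  # 1-based inclusive
    atom_names: tuple[str, ...] | None = None
    elements: tuple[str, ...] | None = None
    residue_names: tuple[str, ...] | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.elements is not None and \
                atom.element.upper() not in tuple(e.upper() for e in self.elements):
            return False
        if self.residue_names is not None and \
                atom.residue_name not in self.residue_names:
            return False
        return True


#: Selection matching the heavy backbone atoms (N, C-alpha, C, O).
BACKBONE_SELECTION = SelectionSpec(atom_names=BACKBONE_ATOMS)


def resolve_selection(model: StructureModel, sel: SelectionSpec) -> np.ndarray:
    """Atom indices (file order) matching ``sel``; empty result is legal."""
    return np.array([i for i, a in enumerate(model.atoms) if sel.matches(a)],
                    dtype=int)


class DomainMap:
    """Named 1-based inclusive residue intervals (F-domain, H-domain, ...)."""

    def __init__(self, ranges: Mapping[str, tuple[int, int]],
                 scaffold: Mapping[str, tuple[int, int]] | None = None):
        intervals = []
        for label, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"domain {label!r}: empty interval {lo}-{hi}")
            intervals.append((lo, hi, label))
        intervals.sort()
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(intervals, intervals[1:]):
            if lo2 <= hi1:
                raise ValueError(f"domains {l1!r} and {l2!r} overlap")
        self.ranges: dict[str, tuple[int, int]] = dict(ranges)
        self.scaffold = dict(scaffold) if scaffold else {}

    def __getitem__(self, label: str) -> tuple[int, int]:
        return self.ranges[label]

    def __contains__(self, label: str) -> bool:
        return label in self.ranges

    def selection(self, label: str, chain: str | None = None) -> SelectionSpec:
        return SelectionSpec(chain=chain, residue_range=self.ranges[label])

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={lo}-{hi}" for k, (lo, hi) in self.ranges.items())
        return f"DomainMap({body})"


@dataclass
class ClusterSpec:
    """An FeS cluster: member atom serials plus optional Fe role tags.

    ``fe_roles`` maps atom serials to ``"Fe_d"`` / ``"Fe_p"`` (the distal /
    proximal irons of the diiron subsite); at most one of each.
    """

    label: str
    member_atom_ids: tuple[int, ...]
    fe_roles: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = list(self.fe_roles.values())
        for tag in ("Fe_d", "Fe_p"):
            if roles.count(tag) > 1:
                raise ValueError(f"cluster {self.label!r}: duplicate {tag} tag")

    def resolve(self, model: StructureModel) -> np.ndarray:
        by_serial = {a.atom_id: i for i, a in enumerate(model.atoms)}
        missing = [s for s in self.member_atom_ids if s not in by_serial]
        if missing:
            raise ValueError(
                f"cluster {self.label!r}: atom serials {missing} not in model")
        return np.array([by_serial[s] for s in self.member_atom_ids], dtype=int)
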