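"""Chimeric model construction: graft a donor domain onto a host.

The host's residue range (e.g. the unfolded N-terminal F-domain of a
predicted structure) receives the coordinates of a positionally aligned
donor range (e.g. the folded F-domain of a crystal structure).  The rigid
placement of the donor is fixed by superposing the shared heavy atoms of
a single junction residue, so the graft joins the host backbone with the
smallest possible seam RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import StructureModel, ClusterSpec
from .superpose import kabsch_superpose, apply_transform


@dataclass(frozen=True)
class GraftPlan:
    """Which residues to replace, where they come from, and the seam."""

    host_range: tuple[int, int]    # 1-based inclusive residue interval
    donor_range: tuple[int, int]
    junction_residue: int          # host numbering
    atom_matching: str = "by-name-within-aligned-residue"

    def __post_init__(self):
        for label, (lo, hi) in (("host", self.host_range),
                                ("donor", self.donor_range)):
            if lo > hi:
                raise ValueError(f"{label}_range is empty")
        n_host = self.host_range[1] - self.host_range[0] + 1
        n_donor = self.donor_range[1] - self.donor_range[0] + 1
        if n_host != n_donor:
            raise ValueError(
                f"host range covers {n_host} residues but donor covers "
                f"{n_donor}; the positional mapping requires equal counts")
        lo, hi = self.host_range
        if not (lo - 1 <= self.junction_residue <= hi + 1):
            raise ValueError("junction residue must lie in or adjacent to "
                             "the host range")
        if self.atom_matching != "by-name-within-aligned-residue":
            raise ValueError(f"unknown atom matching {self.atom_matching!r}")


@dataclass
class GraftReport:
    """Bookkeeping of a graft: seam quality and unmatched atoms."""

    junction_rmsd: float
    n_replaced: int
    retained_unmatched: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_retained_unmatched(self) -> int:
        return len(self.retained_unmatched)


def _residue_atoms(model: StructureModel, resnum: int) -> dict[str, int]:
    """Atom name -> index for one residue (first chain carrying it)."""
    out: dict[str, int] = {}
    chain = None
    for i, a in enumerate(model.atoms):
        if a.residue_number == resnum and (chain is None or a.chain_id == chain):
            chain = a.chain_id
            out.setdefault(a.name, i)
    return out


def graft_domain(host: StructureModel, donor: StructureModel,
                 plan: GraftPlan, junction_atoms: str = "heavy",
                 ) -> tuple[StructureModel, GraftReport]:
    """Overwrite the host range with rigidly placed donor coordinates.

    The transform is the mass-weighted Kabsch superposition of the shared
    atoms of the junction residue (donor residue mapped positionally onto
    the host junction).  Host atoms with no name-matched donor partner are
    retained untouched and listed in the report.

    ``junction_atoms`` selects which shared junction atoms drive the fit:
    ``"heavy"`` (all non-hydrogen, the default) or ``"backbone"``.
    """
    host_lo, host_hi = plan.host_range
    donor_lo, _ = plan.donor_range
    offset = donor_lo - host_lo
    donor_junction = plan.junction_residue + offset

    host_j = _residue_atoms(host, plan.junction_residue)
    donor_j = _residue_atoms(donor, donor_junction)
    shared = [n for n in host_j if n in donor_j]
    if junction_atoms == "backbone":
        shared = [n for n in shared if n in ("N", "CA", "C", "O")]
    elif junction_atoms == "heavy":
        shared = [n for n in shared
                  if host.atoms[host_j[n]].element.upper() != "H"]
    else:
        raise ValueError(f"unknown junction_atoms {junction_atoms!r}")
    if len(shared) < 3:
        raise ValueError(
            f"junction residue {plan.junction_residue}: only {len(shared)} "
            "shared atoms, need >= 3 for a rigid fit")

    mob = np.array([donor.atoms[donor_j[n]].position for n in shared])
    ref = np.array([host.atoms[host_j[n]].position for n in shared])
    w = np.array([host.atoms[host_j[n]].mass for n in shared])
    rotation, translation, rmsd = kabsch_superpose(mob, ref, w)

    # Donor atoms of the graft range, rigidly placed, indexed by residue
    donor_by_res: dict[int, dict[str, np.ndarray]] = {}
    for a in donor.atoms:
        if plan.donor_range[0] <= a.residue_number <= plan.donor_range[1]:
            placed = apply_transform(a.position[None, :], rotation, translation)[0]
            donor_by_res.setdefault(a.residue_number, {})[a.name] = placed

    result = host.copy()
    report = GraftReport(junction_rmsd=rmsd, n_replaced=0)
    for atom in result.atoms:
        if not (host_lo <= atom.residue_number <= host_hi):
            continue
        mapped = donor_by_res.get(atom.residue_number + offset, {})
        if atom.name in mapped:
            atom.position = mapped[atom.name].copy()
            report.n_replaced += 1
        else:
            report.retained_unmatched.append((atom.residue_number, atom.name))
    return result, report


@dataclass
class LigationEntry:
    residue_number: int
    distance: float | None        # minimum Sgamma-Fe distance, Angstrom
    bound: bool | None
    error: str | None = None


@dataclass
class LigationReport:
    cluster_label: str
    threshold: float
    entries: list[LigationEntry]

    @property
    def all_bound(self) -> bool:
        return all(e.bound for e in self.entries if e.error is None) and \
            any(e.error is None for e in self.entries)


def check_cluster_ligation(model: StructureModel, cluster: ClusterSpec,
                           cys_residues: list[int],
                           threshold: float = 2.6) -> LigationReport:
    """Per-cysteine minimum Sgamma-Fe distance against a bonding threshold.

    The default 2.6 A is an upper bound for a covalent Fe-S(thiolate)
    bond.  A cysteine lacking its SG atom yields an error entry; the other
    residues are still reported.
    """
    idx = cluster.resolve(model)
    fe_pos = np.array([model.atoms[i].position for i in idx
                       if model.atoms[i].element.upper() == "FE"])
    if fe_pos.size == 0:
        raise ValueError(f"cluster {cluster.label!r} has no Fe atoms")
    entries = []
    for resnum in cys_residues:
        atoms = _residue_atoms(model, resnum)
        if "SG" not in atoms:
            entries.append(LigationEntry(resnum, None, None,
                                         error="missing SG atom"))
            continue
        sg = model.atoms[atoms["SG"]].position
        d = float(np.min(np.linalg.norm(fe_pos - sg, axis=1)))
        entries.append(LigationEntry(resnum, d, d <= threshold))
    return LigationReport(cluster.label, threshold, entries)
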