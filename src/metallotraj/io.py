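"""Readers and writers: fixed-column PDB, XYZ with box comment, FASTA.

The PDB codec covers the v3.3 coordinate records (ATOM/HETATM, MODEL/
ENDMDL) with the policies the rest of the package relies on: altloc
resolved to the highest-occupancy copy (first-in-file on ties), only the
first MODEL read as a structure (all models as a trajectory), HETATM
retained so FeS clusters and waters survive.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .model import AtomRecord, StructureModel, Trajectory, element_mass


class FormatError(ValueError):
    """A file does not parse as the named format."""


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "resname": line[17:20].strip() or line[17:21].strip(),
            "chain": line[21:22].strip() or "A",
            "resnum": int(line[22:26]),
            "xyz": (float(line[30:38]), float(line[38:46]), float(line[46:54])),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: unparseable PDB record: {exc}") from exc


def _resolve_altlocs(raw_atoms: list[dict]) -> list[dict]:
    """Keep one copy per (chain, resnum, name): highest occupancy, first on tie."""
    chosen: dict[tuple, dict] = {}
    order: list[tuple] = []
    for a in raw_atoms:
        key = (a["chain"], a["resnum"], a["resname"], a["name"])
        if key not in chosen:
            chosen[key] = a
            order.append(key)
        elif a["occupancy"] > chosen[key]["occupancy"]:
            chosen[key] = a
    return [chosen[k] for k in order]


def _read_pdb_models(path: str | Path) -> list[list[dict]]:
    """All MODELs of a PDB file as lists of raw atom dicts."""
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current, in_model = [], True
            elif rec == "ENDMDL":
                models.append(current)
                current, in_model = [], False
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            # TER / REMARK / CRYST1 / END etc. are ignored
    if current:
        models.append(current)
    return [m for m in models if m]


def _model_from_raw(raw: list[dict]) -> StructureModel:
    atoms = []
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        for a in _resolve_altlocs(raw):
            atoms.append(AtomRecord.create(
                atom_id=a["serial"], name=a["name"],
                residue_number=a["resnum"], residue_name=a["resname"],
                chain_id=a["chain"], position=a["xyz"],
                element=a["element"] or None))
    return StructureModel(atoms)


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a structure; for multi-model files only the first MODEL is kept."""
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    models = _read_pdb_models(path)
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    if len(models) > 1:
        warnings.warn(
            f"{path}: {len(models)} MODELs present; reading the first only "
            "(use read_trajectory for all frames)", stacklevel=2)
    model = _model_from_raw(models[0])
    model.title = str(Path(path).stem)
    return model


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "pdb") -> None:
    """Write fixed-column PDB coordinate records (3-decimal coordinates)."""
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    with open(path, "w") as fh:
        _write_model_records(model, fh)
        fh.write("END\n")


def _write_model_records(model: StructureModel, fh) -> None:
    for atom in model.atoms:
        if atom.residue_number > 9999 or atom.residue_number < -999:
            raise ValueError(
                f"residue number {atom.residue_number} does not fit PDB columns")
        if np.any(np.abs(atom.position) >= 10000):
            raise ValueError(
                f"atom {atom.atom_id}: coordinate overflows the 8.3f PDB column")
        record = "ATOM  " if _is_amino(atom) else "HETATM"
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.position
        fh.write(
            f"{record}{atom.atom_id % 100000:5d} {name:<4.4s} "
            f"{atom.residue_name:>3.3s} {atom.chain_id[:1]}{atom.residue_number:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element[:2].upper():>2s}\n")


_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _is_amino(atom: AtomRecord) -> bool:
    return atom.residue_name.upper() in _AMINO3


# ----------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------

def read_trajectory(paths, format: str = "pdb",
                    topology: StructureModel | None = None) -> Trajectory:
    """Read a multi-frame trajectory.

    ``format="pdb"``: every MODEL of every file becomes a frame; the
    topology is taken from the first model unless given explicitly.
    ``format="xyz"``: plain XYZ frames; a comment line of three floats is
    interpreted as orthorhombic box edges ``Lx Ly Lz`` (Angstrom).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if format == "pdb":
        return _read_pdb_trajectory(paths, topology)
    if format == "xyz":
        return _read_xyz_trajectory(paths, topology)
    raise ValueError(f"unsupported trajectory format {format!r}")


def _read_pdb_trajectory(paths, topology):
    frames = []
    for path in paths:
        for raw in _read_pdb_models(path):
            if topology is None:
                topology = _model_from_raw(raw)
            if len(raw) != topology.n_atoms:
                raise FormatError(
                    f"{path}: frame {len(frames)} has {len(raw)} atoms, "
                    f"topology has {topology.n_atoms}")
            frames.append([a["xyz"] for a in raw])
    if not frames:
        raise FormatError("no frames found")
    return Trajectory(topology, np.array(frames, dtype=float))


def _read_xyz_trajectory(paths, topology):
    frames, boxes = [], []
    have_box = False
    for path in paths:
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {i + 1}: expected atom count") from exc
            comment = lines[i + 1] if i + 1 < len(lines) else ""
            box = _parse_box_comment(comment)
            symbols, coords = [], []
            for j in range(n):
                parts = lines[i + 2 + j].split()
                symbols.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
            if topology is None:
                topology = _xyz_topology(symbols)
            if n != topology.n_atoms:
                raise FormatError(
                    f"{path}: frame {len(frames)} has {n} atoms, topology "
                    f"has {topology.n_atoms}")
            frames.append(coords)
            boxes.append(box)
            have_box = have_box or box is not None
            i += 2 + n
    if not frames:
        raise FormatError("no frames found")
    box_arr = None
    if have_box:
        if any(b is None for b in boxes):
            raise FormatError("box comment present in some frames but not all")
        box_arr = np.array(boxes, dtype=float)
    return Trajectory(topology, np.array(frames, dtype=float), box=box_arr)


def _parse_box_comment(comment: str):
    parts = comment.split()
    if len(parts) == 3:
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            return None
        if all(v > 0 for v in vals):
            return vals
    return None


def _xyz_topology(symbols) -> StructureModel:
    atoms = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, sym in enumerate(symbols, start=1):
            # one residue per atom: keeps (residue, name) keys unique when
            # the topology is re-exported to PDB
            atoms.append(AtomRecord(
                atom_id=i, name=sym, element=sym.capitalize(),
                mass=element_mass(sym), residue_number=i, residue_name="UNK",
                chain_id="A", position=np.zeros(3)))
    return StructureModel(atoms, title="xyz")


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "xyz") -> None:
    """Write a trajectory as multi-model PDB or XYZ (box on the comment line)."""
    if format == "xyz":
        with open(path, "w") as fh:
            for i in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                if traj.box is not None:
                    fh.write("{:.6f} {:.6f} {:.6f}\n".format(*traj.box[i]))
                else:
                    fh.write(f"frame {i}\n")
                for atom, xyz in zip(traj.topology.atoms, traj.frames[i]):
                    fh.write(f"{atom.element:<2s} {xyz[0]:14.6f} "
                             f"{xyz[1]:14.6f} {xyz[2]:14.6f}\n")
    elif format == "pdb":
        work = traj.topology.copy()
        with open(path, "w") as fh:
            for i in range(traj.n_frames):
                fh.write(f"MODEL {i + 1:8d}\n")
                work.set_coords(traj.frames[i])
                _write_model_records(work, fh)
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


# ----------------------------------------------------------------------
# Sequences
# ----------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA file as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
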