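"""Structure and trajectory I/O with continuous multi-chain residue renumbering.

Parses static structures (PDB, or single-frame XYZ with a JSON sidecar chain
map) and coordinate trajectories (multi-model PDB, multi-frame XYZ) into the
internal model used by every downstream analysis.  The central convention is
a *global* residue numbering: residues are numbered 1..n continuously across
chains in a caller-declared order (for an IgG, the alternating
light-heavy-light'-heavy' pattern), so that a single index addresses any
residue of a multi-chain assembly.  Ligand and glycan chains are appended
after all protein chains so protein-only matrices stay dense and contiguous.

Also provides the text matrix writer/reader used for DCCM/RCM output
(full-precision round-trip) and PDB/XYZ writers used by the synthetic
trajectory generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AllopathError",
    "ValidationError",
    "FormatError",
    "Atom",
    "Structure",
    "Trajectory",
    "renumber_chains",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_matrix",
    "read_matrix",
    "write_renumber_map",
    "STANDARD_MASSES",
    "PROTEIN_RESIDUES",
    "DEFAULT_TIMESTEP_PS",
]

# Saved-frame spacing used when a trajectory format carries no time axis.
DEFAULT_TIMESTEP_PS = 10.0

PROTEIN_ROLES = ("light", "heavy")
NONPROTEIN_ROLES = ("ligand", "glycan")
ROLES = PROTEIN_ROLES + NONPROTEIN_ROLES

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common variants
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}

# a.m.u.; covers the elements that occur in proteins, glycans and small ligands
STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971,
}


class AllopathError(Exception):
    """Base class for all package errors."""


class ValidationError(AllopathError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(AllopathError, ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom of a structure.

    ``residue_index`` is the *global* 1-based index assigned by the
    renumbering scheme, not the author-assigned residue number from the file
    (kept separately in ``author_resid``).
    """

    serial: int
    name: str
    element: str
    residue_index: int
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    mass: float
    resname: str = "UNK"
    author_resid: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.serial}: non-finite position")
        if not self.mass > 0:
            raise ValidationError(f"atom {self.serial}: mass must be > 0, got {self.mass}")


@dataclass
class Structure:
    """Atoms grouped into residues and chains, with the global renumber map.

    Invariants: global residue indices are contiguous from 1; atoms are
    ordered by global residue index; every atom's residue exists in
    ``renumber_map``.
    """

    atoms: list[Atom]
    chains: list[tuple[str, str]]  # (chain_id, role)
    renumber_map: dict[tuple[str, int], int]

    _inverse: dict[int, tuple[str, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        indices = sorted(set(self.renumber_map.values()))
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError("global residue indices must be contiguous from 1")
        image = set(indices)
        for atom in self.atoms:
            if atom.residue_index not in image:
                raise ValidationError(
                    f"atom {atom.serial}: residue index {atom.residue_index} "
                    "not present in renumber map"
                )
        self._inverse = {g: key for key, g in self.renumber_map.items()}

    # -- residue-level views ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.renumber_map)

    def author_residue(self, global_index: int) -> tuple[str, int]:
        """Inverse renumbering: (chain_id, author residue number)."""
        try:
            return self._inverse[global_index]
        except KeyError:
            raise ValidationError(f"no residue with global index {global_index}") from None

    def chain_role(self, chain_id: str) -> str:
        for cid, role in self.chains:
            if cid == chain_id:
                return role
        raise ValidationError(f"unknown chain {chain_id!r}")

    def residue_name(self, global_index: int) -> str:
        for atom in self.atoms:
            if atom.residue_index == global_index:
                return atom.resname
        raise ValidationError(f"no atoms in residue {global_index}")

    def residue_indices(self, protein_only: bool = False) -> list[int]:
        if not protein_only:
            return sorted(set(self.renumber_map.values()))
        keep = {cid for cid, role in self.chains if role in PROTEIN_ROLES}
        return sorted(g for (cid, _), g in self.renumber_map.items() if cid in keep)

    def atom_indices(self, residue_index: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index]

    def ca_indices(self, protein_only: bool = True) -> list[int]:
        """Index of one Cα per residue, in global residue order."""
        wanted = set(self.residue_indices(protein_only=protein_only))
        by_res: dict[int, int] = {}
        for i, a in enumerate(self.atoms):
            if a.name == "CA" and a.element == "C" and a.residue_index in wanted:
                by_res.setdefault(a.residue_index, i)
        return [by_res[r] for r in sorted(by_res)]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class Trajectory:
    """F frames x N atoms x 3 Cartesian coordinates (Angstrom)."""

    coords: np.ndarray
    structure: Structure
    timestep: float = DEFAULT_TIMESTEP_PS  # ps between saved frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("trajectory coordinates must have shape (F, N, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ValidationError(
                f"trajectory has {self.coords.shape[1]} atoms per frame but the "
                f"structure has {self.structure.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time of each saved frame in ps (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.timestep


# ---------------------------------------------------------------------------
# renumbering
# ---------------------------------------------------------------------------

def renumber_chains(
    chains: Sequence[tuple[str, int] | tuple[str, Sequence[int]]],
) -> dict[tuple[str, int], int]:
    """Build the continuous global residue numbering across chains.

    ``chains`` is an ordered list of ``(chain_id, residue_count)`` or
    ``(chain_id, [author residue numbers])``; the order given is the order
    the chains occupy in the global numbering (the alternating
    light-heavy-light'-heavy' pattern for a whole antibody).  Global indices
    are 1-based and strictly increasing, continuous across chain boundaries.
    """
    mapping: dict[tuple[str, int], int] = {}
    offset = 0
    for chain_id, spec in chains:
        if isinstance(spec, (int, np.integer)):
            resnums: Sequence[int] = range(1, int(spec) + 1)
        else:
            resnums = list(spec)
        resnums = list(resnums)
        if len(resnums) == 0:
            raise ValidationError(f"chain {chain_id!r} has no residues")
        for k, resnum in enumerate(resnums, start=1):
            key = (chain_id, int(resnum))
            if key in mapping:
                raise ValidationError(f"duplicate residue {resnum} in chain {chain_id!r}")
            mapping[key] = offset + k
        offset += len(resnums)
    return mapping


def _order_chains(
    file_order: Sequence[str],
    chain_is_protein: Mapping[str, bool],
    chain_roles: Mapping[str, str] | None,
) -> list[tuple[str, str]]:
    """Resolve chain order and roles.

    Order: the key order of ``chain_roles`` when given (the caller-declared
    pattern), otherwise file order -- with ligand/glycan chains always moved
    after all protein chains.
    """
    roles: dict[str, str] = {}
    for cid in file_order:
        if chain_roles and cid in chain_roles:
            role = chain_roles[cid]
            if role not in ROLES:
                raise ValidationError(
                    f"chain {cid!r}: unknown role {role!r} (expected one of {ROLES})"
                )
            roles[cid] = role
        else:
            roles[cid] = "heavy" if chain_is_protein.get(cid, False) else "ligand"
    if chain_roles:
        declared = [c for c in chain_roles if c in roles]
        rest = [c for c in file_order if c not in chain_roles]
        order = declared + rest
    else:
        order = list(file_order)
    protein = [c for c in order if roles[c] in PROTEIN_ROLES]
    other = [c for c in order if roles[c] not in PROTEIN_ROLES]
    return [(c, roles[c]) for c in protein + other]


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _infer_element(name: str, field: str) -> str:
    """Element from PDB columns 77-78, else from the atom name convention."""
    field = field.strip()
    if field and field.upper() in STANDARD_MASSES:
        return field.upper()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValidationError(f"cannot infer element for atom name {name!r}")
    two = stripped[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE") and len(name.strip()) <= 2:
        return two
    return stripped[0].upper()


def _mass_for(element: str) -> float:
    try:
        return STANDARD_MASSES[element.upper()]
    except KeyError:
        raise ValidationError(f"no standard mass for element {element!r}") from None


@dataclass
class _RawAtom:
    serial: int
    name: str
    altloc: str
    resname: str
    chain_id: str
    resid: int
    position: np.ndarray
    occupancy: float
    element: str
    is_het: bool


def _parse_pdb_atom_line(line: str, lineno: int) -> _RawAtom:
    if len(line) < 54:
        raise FormatError(f"line {lineno}: truncated ATOM/HETATM record")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # serial may overflow/asterisk in long files; tolerate
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip() or line[17:21].strip()
    chain_id = line[21].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError:
        raise FormatError(f"line {lineno}: unparseable residue number {line[22:26]!r}") from None
    try:
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError:
        raise FormatError(f"line {lineno}: unparseable coordinate field") from None
    try:
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        occupancy = 1.0
    element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
    return _RawAtom(
        serial=serial, name=name, altloc=altloc, resname=resname,
        chain_id=chain_id, resid=resid, position=xyz, occupancy=occupancy,
        element=element, is_het=line.startswith("HETATM"),
    )


def _read_pdb_model(path: Path) -> list[_RawAtom]:
    """Raw atoms of the first model, highest-occupancy altloc only."""
    raw: list[_RawAtom] = []
    seen: dict[tuple[str, int, str], int] = {}  # (chain, resid, atom name) -> raw index
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model:
                    break
                in_model = True
            elif rec == "ENDMDL":
                break
            elif rec in ("ATOM", "HETATM"):
                atom = _parse_pdb_atom_line(line, lineno)
                key = (atom.chain_id, atom.resid, atom.name)
                if key in seen:
                    prev = raw[seen[key]]
                    if atom.altloc and prev.altloc and atom.altloc != prev.altloc:
                        # altloc policy: keep the highest-occupancy conformer
                        if atom.occupancy > prev.occupancy:
                            raw[seen[key]] = atom
                        continue
                    raise ValidationError(
                        f"line {lineno}: duplicate atom {atom.name!r} in "
                        f"{atom.chain_id}/{atom.resid}"
                    )
                seen[key] = len(raw)
                raw.append(atom)
    if not raw:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return raw


def _structure_from_raw(
    raw: list[_RawAtom], chain_roles: Mapping[str, str] | None
) -> Structure:
    file_order: list[str] = []
    chain_is_protein: dict[str, bool] = {}
    residues_by_chain: dict[str, list[int]] = {}
    for a in raw:
        if a.chain_id not in file_order:
            file_order.append(a.chain_id)
            residues_by_chain[a.chain_id] = []
            chain_is_protein[a.chain_id] = False
        if a.resid not in residues_by_chain[a.chain_id]:
            residues_by_chain[a.chain_id].append(a.resid)
        if a.resname in PROTEIN_RESIDUES and not a.is_het:
            chain_is_protein[a.chain_id] = True
    chains = _order_chains(file_order, chain_is_protein, chain_roles)
    renumber_map = renumber_chains(
        [(cid, residues_by_chain[cid]) for cid, _ in chains]
    )
    # serials are renumbered sequentially in file order so they double as the
    # frame-coordinate index when reading trajectories of this structure
    atoms = [
        Atom(
            serial=pos + 1, name=a.name, element=a.element,
            residue_index=renumber_map[(a.chain_id, a.resid)],
            chain_id=a.chain_id, position=a.position,
            mass=_mass_for(a.element), resname=a.resname, author_resid=a.resid,
        )
        for pos, a in enumerate(raw)
    ]
    atoms.sort(key=lambda at: at.residue_index)
    return Structure(atoms=atoms, chains=chains, renumber_map=renumber_map)


# ---------------------------------------------------------------------------
# XYZ parsing (one Calpha per residue; chain layout from a JSON sidecar)
# ---------------------------------------------------------------------------

def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"line {i + 1}: expected atom count") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"line {i + 1}: frame truncated ({len(block)} of {n} atoms)")
        coords = np.empty((n, 3))
        for j, row in enumerate(block):
            parts = row.split()
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (IndexError, ValueError):
                raise FormatError(f"line {i + 3 + j}: unparseable XYZ atom line") from None
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    return frames


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".chains.json")


def _structure_from_xyz(
    path: Path, chain_roles: Mapping[str, str] | None
) -> Structure:
    coords = _read_xyz_frames(path)[0]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(
            f"{path}: XYZ structures need a sidecar chain map at {sidecar.name}"
        )
    layout = json.loads(sidecar.read_text())["chains"]
    total = sum(int(c["n_res"]) for c in layout)
    if total != len(coords):
        raise ValidationError(
            f"{path}: sidecar declares {total} residues but frame has {len(coords)} atoms"
        )
    roles = dict(chain_roles or {})
    for c in layout:
        roles.setdefault(c["id"], c.get("role", "heavy"))
    chains = _order_chains([c["id"] for c in layout], {c["id"]: True for c in layout}, roles)
    renumber_map = renumber_chains([(c["id"], int(c["n_res"])) for c in layout])
    atoms = []
    k = 0
    for c in layout:
        for resnum in range(1, int(c["n_res"]) + 1):
            atoms.append(
                Atom(
                    serial=k + 1, name="CA", element="C",
                    residue_index=renumber_map[(c["id"], resnum)],
                    chain_id=c["id"], position=coords[k],
                    mass=STANDARD_MASSES["C"], resname="ALA", author_resid=resnum,
                )
            )
            k += 1
    atoms.sort(key=lambda at: at.residue_index)
    return Structure(atoms=atoms, chains=chains, renumber_map=renumber_map)


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path, chain_roles: Mapping[str, str] | None = None
) -> Structure:
    """Parse a structure file and apply the continuous renumbering.

    ``chain_roles`` maps chain id to one of ``light | heavy | ligand |
    glycan``; its key order declares the chain order of the global
    numbering (default: file order, ligand/glycan chains last).  Unknown
    chains default to ``heavy`` when they contain standard amino acids and
    ``ligand`` otherwise.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _structure_from_xyz(path, chain_roles)
    return _structure_from_raw(_read_pdb_model(path), chain_roles)


def _read_pdb_frames(path: Path, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[np.ndarray] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current:
                    frames.append(np.array(current))
                    current = []
            elif rec == "ENDMDL":
                if current:
                    frames.append(np.array(current))
                current = []
            elif rec in ("ATOM", "HETATM"):
                atom = _parse_pdb_atom_line(line, lineno)
                current.append(atom.position)
    if current:
        frames.append(np.array(current))
    if not frames:
        raise FormatError(f"{path}: no coordinate frames found")
    del saw_model
    for fi, frame in enumerate(frames, start=1):
        if len(frame) != n_atoms:
            raise ValidationError(
                f"frame {fi}: has {len(frame)} atoms, expected {n_atoms}"
            )
    return np.stack(frames)


def read_trajectory(
    path: str | Path,
    structure: Structure,
    timestep: float = DEFAULT_TIMESTEP_PS,
) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ trajectory.

    Every frame must carry exactly the structure's atom count; a mismatch
    raises :class:`ValidationError` naming the 1-based frame index.  Atom
    order within frames must match the file the structure was read from
    (writers in this module and the synthetic generator guarantee this).
    """
    path = Path(path)
    n = structure.n_atoms
    if path.suffix.lower() == ".xyz":
        frames = _read_xyz_frames(path)
        for fi, frame in enumerate(frames, start=1):
            if len(frame) != n:
                raise ValidationError(f"frame {fi}: has {len(frame)} atoms, expected {n}")
        coords = np.stack(frames)
    else:
        coords = _read_pdb_frames(path, n)
    # file order == serial order; our Structure is sorted by global residue,
    # which for files we read equals file order after chain reordering.
    order = _file_to_structure_order(structure)
    return Trajectory(coords=coords[:, order, :], structure=structure, timestep=timestep)


def _file_to_structure_order(structure: Structure) -> np.ndarray:
    """Permutation taking file atom order to the structure's atom order.

    Serials are assigned sequentially in file order by the readers, so
    ``atom.serial - 1`` is the atom's position within each coordinate frame.
    """
    return np.array([atom.serial - 1 for atom in structure.atoms])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _pdb_atom_line(atom: Atom, position: np.ndarray, serial: int) -> str:
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    record = "ATOM  " if atom.resname in PROTEIN_RESIDUES else "HETATM"
    return (
        f"{record}{serial:>5d} {name:4s}{'':1s}{atom.resname:>3s} "
        f"{atom.chain_id:1s}{atom.author_resid:>4d}    "
        f"{position[0]:8.3f}{position[1]:8.3f}{position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (atoms in global residue order)."""
    path = Path(path)
    with open(path, "w") as fh:
        for serial, atom in enumerate(structure.atoms, start=1):
            fh.write(_pdb_atom_line(atom, atom.position, serial))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or multi-frame XYZ (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        with open(path, "w") as fh:
            for fi in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"frame {fi}\n")
                for atom, pos in zip(traj.structure.atoms, traj.coords[fi]):
                    fh.write(
                        f"{atom.element:<2s} {pos[0]:15.8f} {pos[1]:15.8f} {pos[2]:15.8f}\n"
                    )
        return
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"MODEL {fi + 1:>8d}\n")
            for serial, atom in enumerate(traj.structure.atoms, start=1):
                fh.write(_pdb_atom_line(atom, traj.coords[fi, serial - 1], serial))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_matrix(
    matrix: np.ndarray, labels: Sequence[int], path: str | Path
) -> None:
    """Write a square residue matrix as TSV with a header row of labels.

    Values are written with 17 significant digits so that
    ``read_matrix(write_matrix(M)) == M`` exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {matrix.shape}")
    labels = list(labels)
    if len(labels) != matrix.shape[0]:
        raise ValidationError(
            f"{len(labels)} labels for a {matrix.shape[0]}x{matrix.shape[1]} matrix"
        )
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(str(l) for l in labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(str(lab) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Read a matrix written by :func:`write_matrix`; returns (matrix, labels)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = [int(x) for x in header[1:]]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels) + 1:
                raise FormatError(f"line {lineno}: expected {len(labels) + 1} columns")
            rows.append([float(x) for x in parts[1:]])
    matrix = np.array(rows)
    if matrix.shape != (len(labels), len(labels)):
        raise FormatError(f"{path}: matrix is not square")
    return matrix, labels


def write_renumber_map(structure: Structure, path: str | Path) -> None:
    """JSON sidecar mapping 'chain:author_resnum' to global residue index."""
    payload = {
        "chains": [{"id": cid, "role": role} for cid, role in structure.chains],
        "map": {f"{cid}:{num}": g for (cid, num), g in sorted(
            structure.renumber_map.items(), key=lambda kv: kv[1])},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
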