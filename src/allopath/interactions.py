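"""Geometric detection of non-covalent interactions and their occupancy.

Per-frame detectors for four interaction classes, each defined by a purely
geometric criterion:

* hydrogen bond — donor-acceptor distance < 3.0 A and D-H...A angle
  (vertex at the hydrogen) > 150 degrees;
* hydrophobic contact — Cα-Cα distance < 4.0 A between hydrophobic-class
  residues that are not sequence neighbours (a side-chain-carbon minimum
  distance mode is available behind the same threshold);
* cation-π — any aromatic ring atom within 6.0 A of a cationic nitrogen
  (Lys NZ, Arg NE/NH1/NH2, or any ligand nitrogen);
* π-π stacking — aromatic ring centroids closer than 5.0 A.

Occupancy is the percentage of frames in which at least one event of a
type is present at a site, with min/max/mean per-frame pair counts.
Periodic boundary conditions are not applied; inputs are assumed whole.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Structure, Trajectory, ValidationError

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_cation_pi",
    "detect_pi_pi",
    "detect_all",
    "occupancy",
    "occupancy_table",
    "events_to_tsv",
    "HYDROPHOBIC_RESIDUES",
    "AROMATIC_RINGS",
    "CATION_ATOMS",
]

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("hbond", "hydrophobic", "cation_pi", "pi_pi")

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}

# His is treated as aromatic for π detection but not as a cation
# (protonation state unknown without explicit hydrogens/charges).
AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "HID": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "HIE": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "HIP": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

CATION_ATOMS: dict[str, list[str]] = {
    "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"],
}

MAX_DH_BOND = 1.25  # A; a hydrogen this close to N/O/S is treated as bonded


@dataclass
class InteractionCriteria:
    """Geometric thresholds for the four interaction classes."""

    hbond_max_dist: float = 3.0  # A, donor-acceptor
    hbond_min_angle: float = 150.0  # degrees, D-H...A
    hydrophobic_max_dist: float = 4.0  # A
    cation_pi_max_dist: float = 6.0  # A, ring atom to cationic N
    pi_pi_max_centroid_dist: float = 5.0  # A
    hydrophobic_mode: str = "ca"  # "ca" | "sidechain"
    # extra ring definitions for ligand residues: resname -> list of rings
    extra_rings: dict[str, list[list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_dist", "hydrophobic_max_dist",
            "cation_pi_max_dist", "pi_pi_max_centroid_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.hbond_min_angle <= 180:
            raise ValidationError("hbond_min_angle must lie in (0, 180]")
        if self.hydrophobic_mode not in ("ca", "sidechain"):
            raise ValidationError("hydrophobic_mode must be 'ca' or 'sidechain'")


@dataclass
class InteractionEvent:
    """One detected interaction in one frame."""

    frame: int
    type: str
    residue_a: int
    atom_a: str
    residue_b: int
    atom_b: str
    distance: float  # A
    angle: float | None = None  # degrees, hydrogen bonds only

    def involves(self, residues: set[int]) -> bool:
        return self.residue_a in residues or self.residue_b in residues


# ---------------------------------------------------------------------------
# atom classification helpers
# ---------------------------------------------------------------------------

def _ligand_residues(structure: Structure) -> set[int]:
    out = set()
    for cid, role in structure.chains:
        if role in ("ligand", "glycan"):
            out.update(
                g for (c, _), g in structure.renumber_map.items() if c == cid
            )
    return out


def _find_donors_and_hydrogens(
    structure: Structure, coords: np.ndarray
) -> list[tuple[int, list[int]]]:
    """(heavy donor atom index, [hydrogen indices]) for N/O/S with bonded H."""
    heavy = [i for i, a in enumerate(structure.atoms) if a.element in ("N", "O", "S")]
    hydro = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    donors: list[tuple[int, list[int]]] = []
    if not heavy:
        return donors
    if hydro:
        tree = cKDTree(coords[hydro])
        for i in heavy:
            near = tree.query_ball_point(coords[i], MAX_DH_BOND)
            hs = [
                hydro[k] for k in near
                if structure.atoms[hydro[k]].residue_index
                == structure.atoms[i].residue_index
            ]
            donors.append((i, hs))
    else:
        donors = [(i, []) for i in heavy]
    return donors


def _acceptors(structure: Structure) -> list[int]:
    return [i for i, a in enumerate(structure.atoms) if a.element in ("N", "O", "S")]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_hbonds(
    structure: Structure,
    coords: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Hydrogen bonds in one frame.

    An event requires donor-acceptor distance below the cutoff *and* a
    bonded hydrogen whose D-H...A angle (vertex at H) exceeds the minimum.
    Donors without a resolvable hydrogen are skipped (counted in the log).
    Intra-residue pairs are excluded.
    """
    crit = criteria or InteractionCriteria()
    donors = _find_donors_and_hydrogens(structure, coords)
    acceptors = _acceptors(structure)
    if not donors or not acceptors:
        return []
    acc_tree = cKDTree(coords[acceptors])
    events: list[InteractionEvent] = []
    skipped_no_h = 0
    for d_idx, hydrogens in donors:
        d_atom = structure.atoms[d_idx]
        near = acc_tree.query_ball_point(coords[d_idx], crit.hbond_max_dist)
        candidates = [
            acceptors[k] for k in near
            if structure.atoms[acceptors[k]].residue_index != d_atom.residue_index
        ]
        if not candidates:
            continue
        if not hydrogens:
            skipped_no_h += 1
            continue
        for a_idx in candidates:
            dist = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
            if dist >= crit.hbond_max_dist:
                continue  # KD-tree query is <=; criterion is strict <
            best = None
            for h_idx in hydrogens:
                ang = _angle_deg(coords[d_idx], coords[h_idx], coords[a_idx])
                if ang > crit.hbond_min_angle and (best is None or ang > best):
                    best = ang
            if best is not None:
                a_atom = structure.atoms[a_idx]
                events.append(InteractionEvent(
                    frame=frame, type="hbond",
                    residue_a=d_atom.residue_index, atom_a=d_atom.name,
                    residue_b=a_atom.residue_index, atom_b=a_atom.name,
                    distance=dist, angle=best,
                ))
    if skipped_no_h:
        logger.warning(
            "frame %d: %d donor(s) without bonded hydrogen skipped", frame, skipped_no_h
        )
    return events


def detect_hydrophobic(
    structure: Structure,
    coords: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Hydrophobic contacts between hydrophobic-class residues.

    Default mode measures Cα-Cα distance (the criterion as stated);
    ``sidechain`` mode measures the minimum side-chain-carbon distance.
    Sequence neighbours (|i-j| <= 1 in the global numbering) are excluded.
    """
    crit = criteria or InteractionCriteria()
    groups: dict[int, list[int]] = defaultdict(list)
    for i, a in enumerate(structure.atoms):
        if a.resname not in HYDROPHOBIC_RESIDUES:
            continue
        if crit.hydrophobic_mode == "ca":
            if a.name == "CA":
                groups[a.residue_index].append(i)
        else:
            if a.element == "C" and a.name not in ("CA", "C"):
                groups[a.residue_index].append(i)
    residues = sorted(groups)
    events: list[InteractionEvent] = []
    for ii, ri in enumerate(residues):
        for rj in residues[ii + 1:]:
            if abs(ri - rj) <= 1:
                continue
            best = None
            for i in groups[ri]:
                for j in groups[rj]:
                    d = float(np.linalg.norm(coords[i] - coords[j]))
                    if d < crit.hydrophobic_max_dist and (best is None or d < best[0]):
                        best = (d, i, j)
            if best is not None:
                d, i, j = best
                events.append(InteractionEvent(
                    frame=frame, type="hydrophobic",
                    residue_a=ri, atom_a=structure.atoms[i].name,
                    residue_b=rj, atom_b=structure.atoms[j].name,
                    distance=d,
                ))
    return events


def _rings(structure: Structure, crit: InteractionCriteria) -> list[tuple[int, list[int]]]:
    """(residue_index, [ring atom indices]) for each complete aromatic ring."""
    defs = dict(AROMATIC_RINGS)
    defs.update(crit.extra_rings)
    by_res: dict[int, dict[str, int]] = defaultdict(dict)
    for i, a in enumerate(structure.atoms):
        by_res[a.residue_index][a.name] = i
    out: list[tuple[int, list[int]]] = []
    for res in sorted(by_res):
        resname = structure.residue_name(res)
        for ring_names in defs.get(resname, []):
            idx = [by_res[res][n] for n in ring_names if n in by_res[res]]
            if len(idx) == len(ring_names):  # only complete rings
                out.append((res, idx))
    return out


def _cations(structure: Structure) -> list[int]:
    ligand = _ligand_residues(structure)
    out = []
    for i, a in enumerate(structure.atoms):
        if a.resname in CATION_ATOMS and a.name in CATION_ATOMS[a.resname]:
            out.append(i)
        elif a.residue_index in ligand and a.element == "N":
            out.append(i)  # ligand nitrogens treated as potential cations
    return out


def detect_cation_pi(
    structure: Structure,
    coords: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Cation-π contacts: a cationic nitrogen within the cutoff of any
    aromatic ring atom (minimum over ring atoms), different residues."""
    crit = criteria or InteractionCriteria()
    rings = _rings(structure, crit)
    cations = _cations(structure)
    events: list[InteractionEvent] = []
    for res, ring_idx in rings:
        ring_xyz = coords[ring_idx]
        for c_idx in cations:
            c_atom = structure.atoms[c_idx]
            if c_atom.residue_index == res:
                continue
            d = float(np.min(np.linalg.norm(ring_xyz - coords[c_idx], axis=1)))
            if d < crit.cation_pi_max_dist:
                events.append(InteractionEvent(
                    frame=frame, type="cation_pi",
                    residue_a=res, atom_a="ring",
                    residue_b=c_atom.residue_index, atom_b=c_atom.name,
                    distance=d,
                ))
    return events


def detect_pi_pi(
    structure: Structure,
    coords: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionEvent]:
    """π-π stacking: aromatic ring centroids closer than the cutoff.

    Rings of the same residue (e.g. the two Trp rings) are excluded."""
    crit = criteria or InteractionCriteria()
    rings = _rings(structure, crit)
    events: list[InteractionEvent] = []
    for a in range(len(rings)):
        res_a, idx_a = rings[a]
        cen_a = coords[idx_a].mean(axis=0)
        for b in range(a + 1, len(rings)):
            res_b, idx_b = rings[b]
            if res_a == res_b:
                continue
            cen_b = coords[idx_b].mean(axis=0)
            d = float(np.linalg.norm(cen_a - cen_b))
            if d < crit.pi_pi_max_centroid_dist:
                events.append(InteractionEvent(
                    frame=frame, type="pi_pi",
                    residue_a=res_a, atom_a="ring",
                    residue_b=res_b, atom_b="ring",
                    distance=d,
                ))
    return events


_DETECTORS = {
    "hbond": detect_hbonds,
    "hydrophobic": detect_hydrophobic,
    "cation_pi": detect_cation_pi,
    "pi_pi": detect_pi_pi,
}


def detect_all(
    traj: Trajectory,
    criteria: InteractionCriteria | None = None,
    types: Sequence[str] = INTERACTION_TYPES,
) -> list[InteractionEvent]:
    """Run the selected detectors over every trajectory frame."""
    crit = criteria or InteractionCriteria()
    for t in types:
        if t not in _DETECTORS:
            raise ValidationError(f"unknown interaction type {t!r}")
    events: list[InteractionEvent] = []
    for f in range(traj.n_frames):
        for t in types:
            events.extend(_DETECTORS[t](traj.structure, traj.coords[f], crit, frame=f))
    return events


# ---------------------------------------------------------------------------
# occupancy accounting
# ---------------------------------------------------------------------------

def occupancy(
    events: Iterable[InteractionEvent],
    site: Iterable[int] | None,
    type: str,
    n_frames: int,
) -> dict:
    """Occupancy of one interaction type at a site.

    Occupancy % = 100 x (frames with >=1 event of the type touching the
    site) / n_frames.  ``site`` is a set of global residue indices (None =
    whole structure).  Pair-count statistics (min/max/mean per frame) are
    taken over *all* frames, zero-event frames included.
    """
    if type not in INTERACTION_TYPES:
        raise ValidationError(f"unknown interaction type {type!r}")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    site_set = None if site is None else set(int(r) for r in site)
    if site_set is not None and not site_set:
        raise ValidationError("empty site selection")
    per_frame = np.zeros(n_frames, dtype=int)
    for ev in events:
        if ev.type != type:
            continue
        if site_set is not None and not ev.involves(site_set):
            continue
        if not 0 <= ev.frame < n_frames:
            raise ValidationError(f"event frame {ev.frame} outside 0..{n_frames - 1}")
        per_frame[ev.frame] += 1
    occupied = int(np.count_nonzero(per_frame))
    return {
        "type": type,
        "occupancy_pct": 100.0 * occupied / n_frames,
        "min_pairs": int(per_frame.min()),
        "max_pairs": int(per_frame.max()),
        "mean_pairs": float(per_frame.mean()),
    }


def occupancy_table(
    events: Iterable[InteractionEvent],
    sites: dict[str, Iterable[int] | None],
    n_frames: int,
    types: Sequence[str] = INTERACTION_TYPES,
) -> pd.DataFrame:
    """Occupancy summary over named sites x interaction types."""
    events = list(events)
    rows = []
    for site_name, site in sites.items():
        for t in types:
            row = occupancy(events, site, t, n_frames)
            rows.append({"site": site_name, **row})
    return pd.DataFrame(rows)


def events_to_tsv(events: Iterable[InteractionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\ttype\tres_a\tatom_a\tres_b\tatom_b\tdistance_A\tangle_deg\n")
        for ev in events:
            ang = "" if ev.angle is None else f"{ev.angle:.6g}"
            fh.write(
                f"{ev.frame}\t{ev.type}\t{ev.residue_a}\t{ev.atom_a}\t"
                f"{ev.residue_b}\t{ev.atom_b}\t{ev.distance:.6g}\t{ang}\n"
            )
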