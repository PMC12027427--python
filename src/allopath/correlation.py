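"""Residue-residue covariance, dynamic cross-correlation (DCCM) and contact
matrices from a Cα trajectory.

The covariance of residue displacement vectors is

    c(i,j) = < dr_i(t) . dr_j(t) >_t ,   dr_i(t) = r_i(t) - <r_i>

(a full 3-vector dot product, frames superposed onto the mean structure),
and the DCCM is its Pearson-style normalisation

    C(i,j) = c(i,j) / sqrt( c(i,i) c(j,j) )

so C is symmetric with unit diagonal and |C| <= 1.  The contact matrix
records the fraction of frames in which a residue pair is closer than a
cutoff, either between Cα atoms or as the minimum heavy-atom distance
(the smallest-distance convention of gmx mdmat); the mean smallest
distance is kept alongside for the distance-encoding variant.

The denominator is F (not F-1); correlation is scale-free so the choice
cancels in the DCCM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backbone_metrics import superpose_trajectory
from .structure_io import Trajectory, ValidationError

__all__ = [
    "CovarianceMatrix",
    "DCCM",
    "ContactMatrix",
    "covariance_matrix",
    "dccm",
    "contact_matrix",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 10.0  # Angstrom, smallest heavy-atom distance
DISTANCE_MODES = ("min_heavy", "ca")


@dataclass
class CovarianceMatrix:
    """n_res x n_res displacement covariance (Angstrom^2) plus the mean
    structure it was measured about."""

    c: np.ndarray
    mean_structure: np.ndarray  # (n_res, 3) Angstrom
    residues: np.ndarray  # global residue indices

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if not np.allclose(self.c, self.c.T, atol=1e-10):
            raise ValidationError("covariance matrix must be symmetric")
        if np.any(np.diag(self.c) < 0):
            raise ValidationError("covariance diagonal must be non-negative")


@dataclass
class DCCM:
    """Normalised cross-correlation matrix, dimensionless, unit diagonal."""

    C: np.ndarray
    residues: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if np.max(np.abs(self.C)) > 1 + 1e-12:
            raise ValidationError("|C(i,j)| must not exceed 1")


@dataclass
class ContactMatrix:
    """Per-pair contact frequency in [0,1] under a distance cutoff."""

    freq: np.ndarray
    cutoff: float
    distance_mode: str
    residues: np.ndarray
    mean_distance: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any(self.freq < 0) or np.any(self.freq > 1):
            raise ValidationError("contact frequencies must lie in [0, 1]")


def _ca_selection(traj: Trajectory, selection: Sequence[int] | None) -> np.ndarray:
    if selection is None:
        sel = np.asarray(traj.structure.ca_indices(), dtype=int)
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValidationError("empty residue selection")
    residues = [traj.structure.atoms[i].residue_index for i in sel]
    if len(set(residues)) != len(residues):
        raise ValidationError("selection must contain one atom per residue")
    return sel


def covariance_matrix(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose: bool = True,
) -> CovarianceMatrix:
    """Displacement covariance of one atom per residue (default protein Cα).

    Frames are superposed onto the iterated mean structure first (align to
    frame 0, re-mean, align to the mean) unless ``superpose`` is disabled,
    e.g. for pre-aligned input.
    """
    if traj.n_frames < 2:
        raise ValidationError("covariance needs at least 2 frames")
    sel = _ca_selection(traj, selection)
    coords = superpose_trajectory(traj, sel) if superpose else traj.coords
    x = coords[:, sel, :]  # (F, n, 3)
    mean = x.mean(axis=0)
    d = x - mean
    c = np.einsum("fia,fja->ij", d, d) / traj.n_frames
    c = 0.5 * (c + c.T)  # remove float asymmetry
    residues = np.array([traj.structure.atoms[i].residue_index for i in sel])
    return CovarianceMatrix(c=c, mean_structure=mean, residues=residues)


def dccm(cov: CovarianceMatrix) -> DCCM:
    """Normalise a covariance matrix to the dynamic cross-correlation matrix.

    C(i,j) = c(i,j)/sqrt(c(i,i)c(j,j)); the diagonal is set to exactly 1.
    A residue with zero positional variance cannot be normalised and raises
    :class:`ValidationError` naming it.
    """
    var = np.diag(cov.c).copy()
    immobile = np.nonzero(var <= 0)[0]
    if immobile.size:
        names = ", ".join(str(cov.residues[i]) for i in immobile[:5])
        raise ValidationError(f"zero-variance residue(s) cannot be normalised: {names}")
    norm = np.sqrt(var)
    C = cov.c / np.outer(norm, norm)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return DCCM(C=C, residues=cov.residues.copy())


def _heavy_atoms_by_residue(traj: Trajectory, residues: np.ndarray) -> list[np.ndarray]:
    groups: dict[int, list[int]] = {int(r): [] for r in residues}
    for i, atom in enumerate(traj.structure.atoms):
        if atom.element != "H" and atom.residue_index in groups:
            groups[atom.residue_index].append(i)
    out = []
    for r in residues:
        idx = groups[int(r)]
        if not idx:
            raise ValidationError(f"residue {r} has no heavy atoms")
        out.append(np.asarray(idx, dtype=int))
    return out


def contact_matrix(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    distance_mode: str = "min_heavy",
    selection: Sequence[int] | None = None,
) -> ContactMatrix:
    """Residue contact matrix: fraction of frames with pair distance < cutoff.

    ``distance_mode`` is ``min_heavy`` (smallest distance between any heavy
    atoms of the two residues, the mdmat convention) or ``ca`` (Cα-Cα).
    The mean per-pair distance over frames is stored alongside the
    frequency for the distance-encoding variant of the matrix.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if distance_mode not in DISTANCE_MODES:
        raise ValidationError(f"distance_mode must be one of {DISTANCE_MODES}")
    sel = _ca_selection(traj, selection)
    residues = np.array([traj.structure.atoms[i].residue_index for i in sel])
    n = residues.size
    counts = np.zeros((n, n))
    dist_sum = np.zeros((n, n))
    if distance_mode == "ca":
        for f in range(traj.n_frames):
            p = traj.coords[f, sel, :]
            d = np.sqrt(np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=2))
            counts += d < cutoff
            dist_sum += d
    else:
        groups = _heavy_atoms_by_residue(traj, residues)
        flat = np.concatenate(groups)
        starts = np.cumsum([0] + [g.size for g in groups[:-1]])
        for f in range(traj.n_frames):
            p = traj.coords[f, flat, :]
            d = np.sqrt(np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=2))
            # blockwise min over residue groups along both axes
            d = np.minimum.reduceat(d, starts, axis=0)
            d = np.minimum.reduceat(d, starts, axis=1)
            counts += d < cutoff
            dist_sum += d
    freq = counts / traj.n_frames
    np.fill_diagonal(freq, 1.0)
    mean_dist = dist_sum / traj.n_frames
    return ContactMatrix(
        freq=freq, cutoff=float(cutoff), distance_mode=distance_mode,
        residues=residues, mean_distance=mean_dist,
    )
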