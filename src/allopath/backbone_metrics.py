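"""Backbone fluctuation metrics: RMSD, radius of gyration, per-residue RMSF.

All computations are in Angstrom.  RMSD uses optimal least-squares
superposition (Kabsch-equivalent rotation via scipy); RMSF is measured
against the time-average structure after one superposition pass, the
convention of the standard MD analysis tools this module mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Structure, Trajectory, ValidationError

__all__ = [
    "MetricSeries",
    "ResidueProfile",
    "superpose",
    "rmsd_series",
    "rg_series",
    "radius_of_gyration",
    "rmsf_profile",
    "superpose_trajectory",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class MetricSeries:
    """A per-frame scalar metric (RMSD or Rg) over a trajectory."""

    metric: str  # "RMSD" | "Rg"
    times: np.ndarray  # ps
    values: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.metric} values must be non-negative")

    def to_tsv(self, path: str | Path, nm: bool = False) -> None:
        """Two-column (time_ps, value) TSV; ``nm`` emits nanometres."""
        scale = 1.0 / ANGSTROM_PER_NM if nm else 1.0
        unit = "nm" if nm else "A"
        with open(path, "w") as fh:
            fh.write(f"time_ps\t{self.metric.lower()}_{unit}\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.17g}\t{v * scale:.17g}\n")


@dataclass
class ResidueProfile:
    """Per-residue RMSF values, indexed by global residue index."""

    residues: np.ndarray
    values: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residues.shape != self.values.shape:
            raise ValidationError("one RMSF value per residue required")
        if np.any(self.values < 0):
            raise ValidationError("RMSF values must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\trmsf_A\n")
            for r, v in zip(self.residues, self.values):
                fh.write(f"{r}\t{v:.17g}\n")


def _check_selection(selection: Sequence[int] | None, n_atoms: int) -> np.ndarray:
    if selection is None:
        sel = np.arange(n_atoms)
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValidationError("empty atom selection")
    if sel.min() < 0 or sel.max() >= n_atoms:
        raise ValidationError("selection index out of range")
    return sel


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Finds the rigid transform (rotation + translation) minimising the
    (optionally weighted) RMSD over the selected atoms and applies it to
    *all* atoms of ``mobile``.

    Returns
    -------
    (transformed, rmsd)
        Transformed copy of ``mobile`` and the minimised selection RMSD in
        Angstrom.

    Raises
    ------
    ValidationError
        If the selection has fewer than 3 atoms or is collinear (the
        optimal rotation is then not unique).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = _check_selection(selection, mobile.shape[0])
    if sel.size < 3:
        raise ValidationError("superposition needs at least 3 selected atoms")
    mob_sel = mobile[sel]
    ref_sel = reference[sel]
    if weights is None:
        w = np.ones(sel.size)
    else:
        w = np.asarray(weights, dtype=float)
    mob_c = np.average(mob_sel, axis=0, weights=w)
    ref_c = np.average(ref_sel, axis=0, weights=w)
    a = ref_sel - ref_c
    b = mob_sel - mob_c
    # collinear selections leave a free rotation about the common axis
    svals = np.linalg.svd(b * np.sqrt(w)[:, None], compute_uv=False)
    if svals[1] < 1e-8 * max(1.0, svals[0]):
        raise ValidationError("degenerate superposition: selection atoms are collinear")
    rot, _ = Rotation.align_vectors(a, b, weights=w)
    transformed = rot.apply(mobile - mob_c) + ref_c
    diff = transformed[sel] - ref_sel
    rmsd = float(np.sqrt(np.average(np.sum(diff * diff, axis=1), weights=w)))
    return transformed, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: int | Structure = 0,
    selection: Sequence[int] | None = None,
) -> MetricSeries:
    """RMSD of each frame to a reference after optimal superposition.

    ``reference`` is a frame index or a :class:`Structure`; ``selection``
    defaults to all protein Cα atoms.
    """
    if selection is None:
        selection = traj.structure.ca_indices()
    sel = _check_selection(selection, traj.n_atoms)
    if isinstance(reference, Structure):
        ref_coords = reference.coordinates()
        if ref_coords.shape[0] != traj.n_atoms:
            raise ValidationError("reference structure atom count mismatch")
    else:
        ref_coords = traj.coords[int(reference)]
    values = np.array(
        [superpose(traj.coords[f], ref_coords, sel)[1] for f in range(traj.n_frames)]
    )
    return MetricSeries(metric="RMSD", times=traj.times, values=values)


def radius_of_gyration(
    frame: np.ndarray,
    selection: Sequence[int] | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration of one frame, in Angstrom.

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ).
    """
    frame = np.asarray(frame, dtype=float)
    sel = _check_selection(selection, frame.shape[0])
    pos = frame[sel]
    if masses is None:
        m = np.ones(sel.size)
    else:
        m = np.asarray(masses, dtype=float)
        if m.size == frame.shape[0] and m.size != sel.size:
            m = m[sel]
        elif m.size != sel.size:
            raise ValidationError("masses must match the selection or the frame")
    total = m.sum()
    if not total > 0:
        raise ValidationError("total mass must be positive")
    com = (m[:, None] * pos).sum(axis=0) / total
    d2 = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt((m * d2).sum() / total))


def rg_series(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Radius-of-gyration time series (no superposition needed: Rg is
    rigid-motion invariant)."""
    sel = _check_selection(selection, traj.n_atoms)
    masses = traj.structure.masses()[sel] if mass_weighted else None
    values = np.array(
        [radius_of_gyration(traj.coords[f], sel, masses) for f in range(traj.n_frames)]
    )
    return MetricSeries(metric="Rg", times=traj.times, values=values)


def superpose_trajectory(
    traj: Trajectory, selection: Sequence[int] | None = None
) -> np.ndarray:
    """Superpose every frame onto the time-average structure.

    One iteration of the mean-structure fit: frames are first aligned to
    frame 0, the mean is taken, then every frame is re-aligned to that mean.
    Returns the aligned coordinate array (F, N, 3); the trajectory is not
    modified.
    """
    if traj.n_frames < 2:
        raise ValidationError("need at least 2 frames")
    sel = _check_selection(selection, traj.n_atoms)
    aligned = np.array(
        [superpose(traj.coords[f], traj.coords[0], sel)[0] for f in range(traj.n_frames)]
    )
    mean = aligned.mean(axis=0)
    aligned = np.array(
        [superpose(aligned[f], mean, sel)[0] for f in range(traj.n_frames)]
    )
    return aligned


def rmsf_profile(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose_first: bool = True,
) -> ResidueProfile:
    """Per-residue root-mean-square fluctuation about the time average.

    RMSF_i = sqrt( <|r_i(t) - <r_i>|^2>_t ) for each selected atom
    (default: one Cα per protein residue), after superposing every frame
    onto the time-average structure when ``superpose_first`` is set.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    if selection is None:
        selection = traj.structure.ca_indices()
    sel = _check_selection(selection, traj.n_atoms)
    coords = superpose_trajectory(traj, sel) if superpose_first else traj.coords
    x = coords[:, sel, :]
    mean = x.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    residues = np.array([traj.structure.atoms[i].residue_index for i in sel])
    return ResidueProfile(residues=residues, values=rmsf)
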