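"""Essential dynamics: PCA of Cα coordinates and the free-energy landscape.

PCA eigen-decomposes the 3n x 3n Cartesian covariance of the selected Cα
atoms after removing overall translation and rotation (superposition onto
the mean structure).  Frames projected onto the first two principal
components define a 2-D probability density P, converted to a relative
free energy by Boltzmann inversion

    G_b = -kT ln( P_b / P_max )

so the most populated bin sits at exactly G = 0 and empty bins are
unvisited (G = +inf).  Only probability *ratios* enter, so G is invariant
under rescaling all counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .backbone_metrics import superpose_trajectory
from .structure_io import Trajectory, ValidationError

__all__ = [
    "PCAResult",
    "FELGrid",
    "pca",
    "free_energy_landscape",
    "KB_KJ_PER_MOL_K",
]

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/(mol K)
DEFAULT_FEL_BINS = 50
DEFAULT_TEMPERATURE_K = 300.0


@dataclass
class PCAResult:
    """Eigen-decomposition of the Cartesian Cα covariance.

    ``eigenvalues`` (Angstrom^2, descending), ``eigenvectors`` as columns of
    a (3n, k) orthonormal matrix, and per-frame ``projections`` (F, k) in
    Angstrom.  ``variance_fraction`` sums to 1 over all 3n components.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    variance_fraction: np.ndarray
    mean_coords: np.ndarray  # (n, 3) mean structure of the selection
    residues: np.ndarray

    def cumulative_variance(self, k: int = 2) -> float:
        """Fraction of total positional variance carried by the first k PCs
        (the percentage usually quoted for PC1+PC2)."""
        return float(self.variance_fraction[:k].sum())

    def to_tsv(self, path: str | Path, k: int = 10) -> None:
        k = min(k, self.eigenvalues.size)
        cum = np.cumsum(self.variance_fraction)
        with open(path, "w") as fh:
            fh.write("pc\teigenvalue_A2\tvariance_fraction\tcumulative_fraction\n")
            for i in range(k):
                fh.write(
                    f"{i + 1}\t{self.eigenvalues[i]:.17g}\t"
                    f"{self.variance_fraction[i]:.17g}\t{cum[i]:.17g}\n"
                )


@dataclass
class FELGrid:
    """Free-energy surface over a B x B grid of PC1/PC2 projections."""

    P: np.ndarray  # probability per bin, sums to 1
    G: np.ndarray  # free energy per bin; +inf marks unvisited bins
    edges1: np.ndarray
    edges2: np.ndarray
    temperature: float
    units: str  # "kJ/mol" | "kT"

    def __post_init__(self) -> None:
        if abs(self.P.sum() - 1.0) > 1e-12:
            raise ValidationError("bin probabilities must sum to 1")
        occupied = self.G[np.isfinite(self.G)]
        if occupied.size and abs(occupied.min()) > 1e-12:
            raise ValidationError("minimum free energy over occupied bins must be 0")

    def to_tsv(self, path: str | Path) -> None:
        """(PC1 center, PC2 center, P, G) rows; unvisited bins write 'inf'."""
        c1 = 0.5 * (self.edges1[:-1] + self.edges1[1:])
        c2 = 0.5 * (self.edges2[:-1] + self.edges2[1:])
        with open(path, "w") as fh:
            fh.write(f"pc1\tpc2\tP\tG_{'kT' if self.units == 'kT' else 'kJmol'}\n")
            for i, x in enumerate(c1):
                for j, y in enumerate(c2):
                    fh.write(
                        f"{x:.17g}\t{y:.17g}\t{self.P[i, j]:.17g}\t{self.G[i, j]:.17g}\n"
                    )


def pca(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    superpose: bool = True,
) -> PCAResult:
    """Principal component analysis of the selected Cα coordinates.

    Frames are superposed onto the mean structure (translation/rotation
    removed), flattened to 3n-vectors, and the covariance (denominator F)
    is eigen-decomposed.  Projections are the centred frames on each
    eigenvector.
    """
    if traj.n_frames <= 1:
        raise ValidationError("PCA needs more than one frame")
    if selection is None:
        selection = traj.structure.ca_indices()
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValidationError("empty atom selection")
    coords = superpose_trajectory(traj, sel) if superpose else traj.coords
    x = coords[:, sel, :].reshape(traj.n_frames, -1)  # (F, 3n)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    trace = float(np.trace(cov))
    if evals[-1] < -1e-8 * max(trace, 1e-300):
        raise ValidationError("covariance eigenvalues unexpectedly negative")
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    projections = xc @ evecs
    residues = np.array([traj.structure.atoms[i].residue_index for i in sel])
    return PCAResult(
        eigenvalues=evals, eigenvectors=evecs, projections=projections,
        variance_fraction=frac, mean_coords=mean.reshape(-1, 3), residues=residues,
    )


def free_energy_landscape(
    projections: np.ndarray,
    bins: int = DEFAULT_FEL_BINS,
    temperature: float = DEFAULT_TEMPERATURE_K,
    units: str = "kJ/mol",
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> FELGrid:
    """Boltzmann inversion of the 2-D PC1/PC2 projection density.

    ``projections`` is (F, >=2); the first two columns are binned on a
    ``bins`` x ``bins`` grid spanning the data extrema, or an explicit
    ``extent`` ((lo1, hi1), (lo2, hi2)) — e.g. robust quantiles — in which
    case samples outside it are dropped.  G is in kJ/mol by default, or in
    units of kT with ``units="kT"``.
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim == 1:
        raise ValidationError("projections must be 2-D (frames x components)")
    if proj.shape[0] < 1 or proj.shape[1] < 2:
        raise ValidationError("need at least one frame and two components")
    if bins < 2:
        raise ValidationError("need at least 2 bins per axis")
    if units not in ("kJ/mol", "kT"):
        raise ValidationError("units must be 'kJ/mol' or 'kT'")
    p1, p2 = proj[:, 0], proj[:, 1]

    def _range(v: np.ndarray) -> tuple[float, float]:
        lo, hi = float(v.min()), float(v.max())
        if hi - lo == 0.0:  # all frames in one bin: pad to a finite box
            lo, hi = lo - 0.5, hi + 0.5
        return lo, hi

    rng = list(extent) if extent is not None else [_range(p1), _range(p2)]
    counts, e1, e2 = np.histogram2d(p1, p2, bins=bins, range=rng)
    if counts.sum() == 0:
        raise ValidationError("no samples fall inside the requested extent")
    P = counts / counts.sum()
    kT = 1.0 if units == "kT" else KB_KJ_PER_MOL_K * temperature
    pmax = P.max()
    with np.errstate(divide="ignore"):
        G = np.where(P > 0, -kT * np.log(np.where(P > 0, P, 1.0) / pmax), np.inf)
    G[P > 0] -= G[P > 0].min()  # exact 0 at the global minimum despite rounding
    return FELGrid(P=P, G=G, edges1=e1, edges2=e2, temperature=float(temperature), units=units)
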