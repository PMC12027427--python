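"""Synthetic ensembles with known ground truth.

Stand-ins for long MD trajectories, built so every downstream statistic has
an analytic expectation:

* :func:`generate_ensemble` — multi-chain Cα ensembles whose per-frame
  displacements are drawn from a multivariate Gaussian with a prescribed
  residue-residue correlation matrix, applied *isotropically* per axis.
  Because the same correlation acts on x, y and z, the 3-vector dot-product
  correlation measured by the DCCM equals the generating correlation in
  expectation — the ground truth is exact, not approximate.
* :func:`generate_planted_path` — an ensemble containing a designated
  "communication chain": consecutive chain residues are in spatial contact
  and highly correlated (AR(1) structure along the chain, so the matrix
  stays positive semidefinite), while off-chain residue pairs receive only
  weak correlations.  The chain is the unique low-weight route between two
  distal sites, and the returned truth set lists its residues.
* :func:`generate_interaction_fixture` — minimal atom groups placed at a
  controlled distance/angle just inside or outside each non-covalent
  interaction criterion.

Base geometry is an ideal α-helical Cα trace (3.8 A between consecutive
residues), a compact self-avoiding curve with realistic short-range
contacts.  Each generator call consumes a single RNG stream; the seed is
mandatory, and identical specs produce byte-identical written files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .structure_io import (
    Atom,
    STANDARD_MASSES,
    Structure,
    Trajectory,
    ValidationError,
    renumber_chains,
)

__all__ = [
    "EnsembleSpec",
    "PlantedPathSpec",
    "generate_ensemble",
    "generate_planted_path",
    "generate_interaction_fixture",
    "helical_trace",
    "DEFAULT_SIGMA",
]

# Per-residue isotropic displacement scale (A per axis).  0.5 A gives Cα
# RMSF ~ 0.87 A, the magnitude typical of a folded protein core at 300 K.
DEFAULT_SIGMA = 0.5

# Ideal alpha-helix Calpha parameters: 100 deg twist and 1.5 A rise per
# residue at 2.3 A radius give |r_{i+1} - r_i| = 3.81 A.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0


def helical_trace(n_res: int) -> np.ndarray:
    """Ideal α-helical Cα trace of ``n_res`` residues (Angstrom)."""
    if n_res < 1:
        raise ValidationError("need at least one residue")
    t = np.arange(n_res) * np.radians(_HELIX_TWIST_DEG)
    return np.column_stack([
        _HELIX_RADIUS * np.cos(t),
        _HELIX_RADIUS * np.sin(t),
        _HELIX_RISE * np.arange(n_res),
    ])


def extended_trace(n_res: int) -> np.ndarray:
    """Extended (straight-line) Cα trace with 3.8 A spacing."""
    coords = np.zeros((n_res, 3))
    coords[:, 0] = np.arange(n_res) * 3.8
    return coords


@dataclass
class EnsembleSpec:
    """Specification of a Gaussian Cα ensemble.

    ``correlation`` is the target residue-residue correlation matrix
    (symmetric PSD, unit diagonal); ``sigma`` the per-residue per-axis
    displacement scale in Angstrom (scalar or per-residue).  ``chains``
    lists (chain_id, role, length) in the order they occupy the global
    numbering; lengths must sum to ``n_res``.
    """

    n_res: int
    n_frames: int
    seed: int
    chains: list[tuple[str, str, int]] = field(default_factory=list)
    geometry: str = "helix"  # "helix" | "extended"
    correlation: np.ndarray | None = None  # default: identity
    sigma: float | np.ndarray = DEFAULT_SIGMA
    base_coords: np.ndarray | None = None  # explicit Cα trace overriding geometry

    def __post_init__(self) -> None:
        if self.n_res < 1 or self.n_frames < 1:
            raise ValidationError("n_res and n_frames must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not self.chains:
            self.chains = [("A", "heavy", self.n_res)]
        if sum(length for _, _, length in self.chains) != self.n_res:
            raise ValidationError("chain lengths must sum to n_res")
        if self.geometry not in ("helix", "extended"):
            raise ValidationError("geometry must be 'helix' or 'extended'")
        if self.correlation is None:
            self.correlation = np.eye(self.n_res)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (self.n_res, self.n_res):
            raise ValidationError("correlation matrix must be n_res x n_res")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have unit diagonal")
        sig = np.asarray(self.sigma, dtype=float)
        if np.any(sig <= 0):
            raise ValidationError("sigma must be positive")
        if self.base_coords is not None:
            self.base_coords = np.asarray(self.base_coords, dtype=float)
            if self.base_coords.shape != (self.n_res, 3):
                raise ValidationError("base_coords must have shape (n_res, 3)")


@dataclass
class PlantedPathSpec:
    """A planted communication chain between two distal residues.

    ``chain`` lists the intermediate residues (global indices) between
    ``source`` and ``target``; consecutive members must lie within
    ``contact_radius`` of each other in the base geometry.  On-chain
    correlation follows an AR(1) profile ``on_chain_c**k`` with chain
    distance k (guaranteed PSD on the chain); off-chain pairs receive
    random correlations capped at ``off_chain_cap``.
    """

    source: int
    target: int
    chain: list[int]
    on_chain_c: float = 0.9
    off_chain_cap: float = 0.2
    contact_radius: float = 10.0
    n_off_chain_pairs: int | None = None  # default: n_res

    def members(self) -> list[int]:
        return [self.source, *self.chain, self.target]

    def __post_init__(self) -> None:
        members = self.members()
        if len(set(members)) != len(members):
            raise ValidationError("planted chain residues must be distinct")
        if not 0 < self.on_chain_c < 1:
            raise ValidationError("on_chain_c must lie in (0, 1)")
        if not 0 <= self.off_chain_cap < self.on_chain_c:
            raise ValidationError("off_chain_cap must be below on_chain_c")


def _clip_psd(corr: np.ndarray) -> np.ndarray:
    """Clip small negative eigenvalues (relative floor -1e-8) and
    re-normalise to unit diagonal; reject matrices that are far from PSD."""
    evals, evecs = np.linalg.eigh(corr)
    floor = -1e-8 * max(evals.max(), 1.0)
    if evals.min() < 100 * floor:
        raise ValidationError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {evals.min():.3g})"
        )
    evals = np.clip(evals, 0.0, None)
    fixed = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return 0.5 * (fixed + fixed.T)


def _structure_from_spec(spec: EnsembleSpec, base: np.ndarray) -> Structure:
    chains = [(cid, role) for cid, role, _ in spec.chains]
    renumber_map = renumber_chains([(cid, length) for cid, role, length in spec.chains])
    atoms = []
    k = 0
    for cid, _, length in spec.chains:
        for resnum in range(1, length + 1):
            atoms.append(Atom(
                serial=k + 1, name="CA", element="C",
                residue_index=renumber_map[(cid, resnum)], chain_id=cid,
                position=base[k], mass=STANDARD_MASSES["C"],
                resname="ALA", author_resid=resnum,
            ))
            k += 1
    return Structure(atoms=atoms, chains=chains, renumber_map=renumber_map)


def generate_ensemble(spec: EnsembleSpec) -> tuple[Structure, Trajectory]:
    """Sample a Gaussian Cα ensemble with the prescribed correlation.

    Per-frame displacements are drawn independently per Cartesian axis from
    N(0, S) with S = diag(sigma) @ correlation @ diag(sigma), then added to
    the static base geometry.  Deterministic given the spec's seed.
    """
    if spec.base_coords is not None:
        base = spec.base_coords
    else:
        base = (helical_trace if spec.geometry == "helix" else extended_trace)(spec.n_res)
    structure = _structure_from_spec(spec, base)
    corr = _clip_psd(spec.correlation)
    sig = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (spec.n_res,))
    cov = corr * np.outer(sig, sig)
    # cholesky of the clipped (possibly singular) covariance via eigh
    evals, evecs = np.linalg.eigh(cov)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, spec.n_res))
    disp = z @ root.T  # (F, 3, n_res)
    coords = base[None, :, :] + np.transpose(disp, (0, 2, 1))
    return structure, Trajectory(coords=coords, structure=structure)


# sequence-local backbone coupling: neighbours in sequence are always
# somewhat correlated in a connected polymer
LOCAL_RHO = 0.5
LOCAL_RANGE = 4  # |i-j| beyond which local coupling is dropped (0.5^4 ~ 0.06)


def _bridge_trace(n_before: int, n_chain: int, n_after: int) -> np.ndarray:
    """Dumbbell Cα trace: two helical lobes joined by an extended linker.

    The linker residues contact only their own sequence neighbours, so a
    chain planted on them is the sole physical route between the lobes —
    the geometry of an allosteric conduit between two distal sites.
    """
    lobe_a = helical_trace(max(n_before, 1))
    # 5.5 A spacing: consecutive linker residues are in contact at the
    # default 10 A cutoff, but second neighbours (11 A) are not, so the
    # linker's contact-edge set is exactly its consecutive pairs
    step = np.array([0.0, 0.0, 5.5])
    linker = lobe_a[-1] + step * np.arange(1, n_chain + 1)[:, None]
    lobe_b = helical_trace(max(n_after, 1))
    lobe_b = lobe_b + (linker[-1] + step - lobe_b[0])
    parts = []
    if n_before:
        parts.append(lobe_a[:n_before])
    parts.append(linker)
    if n_after:
        parts.append(lobe_b[:n_after])
    return np.vstack(parts)


def generate_planted_path(
    spec: PlantedPathSpec, base: EnsembleSpec
) -> tuple[Structure, Trajectory, list[int]]:
    """Ensemble whose RDCM graph contains the planted chain as the unique
    low-weight route between two distal lobes.

    When the chain residues are sequence-contiguous (the default use), the
    base geometry is a dumbbell: two helical lobes joined by the chain as
    an extended linker, so every cross-lobe shortest path must traverse
    every chain edge.  Non-contiguous chains fall back to the base spec's
    geometry, with consecutive members validated against the contact
    radius.  The correlation matrix combines the AR(1) chain profile
    (``on_chain_c**k``), weak sequence-local backbone coupling, and random
    off-chain couplings capped at ``off_chain_cap``; it is projected back
    to the PSD cone if the overlays push it slightly outside.

    Returns (structure, trajectory, truth) with ``truth`` the ordered
    chain residues (source, intermediates, target); the base spec's
    ``correlation`` field is ignored.
    """
    members = spec.members()
    n = base.n_res
    if any(not 1 <= r <= n for r in members):
        raise ValidationError("chain residues must be valid global indices")
    contiguous = members == list(range(members[0], members[-1] + 1))
    if contiguous:
        geometry = _bridge_trace(members[0] - 1, len(members), n - members[-1])
    else:
        geometry = (helical_trace if base.geometry == "helix" else extended_trace)(n)
    pos = {r: geometry[r - 1] for r in members}
    for a, b in zip(members[:-1], members[1:]):
        d = float(np.linalg.norm(pos[a] - pos[b]))
        if d > spec.contact_radius:
            raise ValidationError(
                f"chain break: residues {a} and {b} are {d:.1f} A apart, "
                f"beyond the contact radius {spec.contact_radius} A"
            )
    corr = np.eye(n)
    for i in range(1, n + 1):  # backbone coupling
        for j in range(i + 1, min(i + LOCAL_RANGE, n) + 1):
            corr[i - 1, j - 1] = corr[j - 1, i - 1] = LOCAL_RHO ** (j - i)
    for ki, a in enumerate(members):  # chain overlay dominates
        for kj in range(ki + 1, len(members)):
            b = members[kj]
            rho = spec.on_chain_c ** (kj - ki)
            if rho > corr[a - 1, b - 1]:
                corr[a - 1, b - 1] = corr[b - 1, a - 1] = rho
    rng = np.random.default_rng(base.seed)
    on_chain = set(members)
    n_off = n if spec.n_off_chain_pairs is None else spec.n_off_chain_pairs
    placed = 0
    attempts = 0
    while placed < n_off and attempts < 50 * max(n_off, 1) and spec.off_chain_cap > 0:
        attempts += 1
        i, j = rng.integers(1, n + 1, size=2)
        if i == j or (i in on_chain and j in on_chain):
            continue
        if corr[i - 1, j - 1] != 0.0:
            continue  # pair already assigned
        rho = rng.uniform(0.05, spec.off_chain_cap)
        corr[i - 1, j - 1] = corr[j - 1, i - 1] = rho
        placed += 1
    # overlays can push the matrix slightly outside the PSD cone
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < 0:
        evals2, evecs = np.linalg.eigh(corr)
        evals2 = np.clip(evals2, 1e-6, None)
        corr = (evecs * evals2) @ evecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        corr = 0.5 * (corr + corr.T)
    ens = EnsembleSpec(
        n_res=n, n_frames=base.n_frames, seed=base.seed + 1,
        chains=base.chains, geometry=base.geometry,
        correlation=corr, sigma=base.sigma,
        base_coords=geometry,
    )
    structure, traj = generate_ensemble(ens)
    return structure, traj, members


def write_truth(truth: Sequence[int], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"chain_residues": list(truth)}, indent=1) + "\n")


# ---------------------------------------------------------------------------
# interaction geometry fixtures
# ---------------------------------------------------------------------------

def _mk_structure(atom_specs: list[tuple[str, str, str, int, np.ndarray]]) -> Structure:
    """Build a toy single-chain structure from (name, element, resname,
    author resid, position) tuples."""
    resnums: list[int] = []
    for _, _, _, resid, _ in atom_specs:
        if resid not in resnums:
            resnums.append(resid)
    renumber_map = renumber_chains([("A", resnums)])
    atoms = [
        Atom(
            serial=k + 1, name=name, element=elem,
            residue_index=renumber_map[("A", resid)], chain_id="A",
            position=np.asarray(pos, dtype=float),
            mass=STANDARD_MASSES[elem], resname=resname, author_resid=resid,
        )
        for k, (name, elem, resname, resid, pos) in enumerate(atom_specs)
    ]
    atoms.sort(key=lambda a: a.residue_index)
    return Structure(atoms=atoms, chains=[("A", "heavy")], renumber_map=renumber_map)


def _ring_atoms(resname: str, resid: int, center: np.ndarray,
                normal_z: bool = True) -> list[tuple[str, str, str, int, np.ndarray]]:
    """Planar 6-ring of a Phe/Tyr at the given centroid (radius 1.39 A)."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    out = []
    for k, name in enumerate(names):
        ang = np.radians(60.0 * k)
        offset = np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
        out.append((name, "C", resname, resid, center + offset))
    return out


def generate_interaction_fixture(
    kind: str,
    distance: float,
    angle: float = 180.0,
) -> tuple[Structure, Trajectory]:
    """Minimal atom group realising one interaction geometry exactly.

    ``distance`` is the criterion's own distance (donor-acceptor for
    ``hbond``, Cα-Cα for ``hydrophobic``, nearest-ring-atom-to-N for
    ``cation_pi``, centroid-centroid for ``pi_pi``); ``angle`` is the
    D-H...A angle for hydrogen bonds.  Returns the structure and a
    one-frame trajectory over it.
    """
    if kind == "hbond":
        d_pos = np.array([0.0, 0.0, 0.0])
        h_pos = np.array([0.96, 0.0, 0.0])
        theta = np.radians(angle)
        u = np.array([-np.cos(theta), np.sin(theta), 0.0])  # unit, angle to H->D
        # solve |h + r*u - d| = distance for r > 0
        b = 2 * np.dot(h_pos - d_pos, u)
        c = np.dot(h_pos - d_pos, h_pos - d_pos) - distance**2
        disc = b * b - 4 * c
        if disc < 0:
            raise ValidationError("no acceptor placement satisfies this geometry")
        r = (-b + np.sqrt(disc)) / 2
        a_pos = h_pos + r * u
        specs = [
            ("OG", "O", "SER", 1, d_pos),
            ("HG", "H", "SER", 1, h_pos),
            ("O", "O", "GLY", 2, a_pos),
        ]
    elif kind == "hydrophobic":
        specs = [
            ("CA", "C", "LEU", 1, np.array([0.0, 0.0, 0.0])),
            ("CA", "C", "GLY", 2, np.array([50.0, 50.0, 50.0])),
            ("CA", "C", "VAL", 3, np.array([distance, 0.0, 0.0])),
        ]
    elif kind == "cation_pi":
        specs = _ring_atoms("PHE", 1, np.array([0.0, 0.0, 0.0]))
        # nearest ring atom is CG at (1.39, 0, 0); place NZ beyond it on +x
        specs.append(("NZ", "N", "LYS", 2, np.array([1.39 + distance, 0.0, 0.0])))
    elif kind == "pi_pi":
        specs = _ring_atoms("PHE", 1, np.array([0.0, 0.0, 0.0]))
        specs += _ring_atoms("TYR", 2, np.array([0.0, 0.0, distance]))
    else:
        raise ValidationError(f"unknown interaction fixture kind {kind!r}")
    structure = _mk_structure(specs)
    traj = Trajectory(coords=structure.coordinates()[None, :, :], structure=structure)
    return structure, traj
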