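import numpy as np
import pytest

import allopath as ap

TOY_PDB = """\
ATOM      1  N   ALA L   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA L   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA L   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY L   2       4.000   2.000   0.000  1.00  0.00           C
ATOM      5  CA  SER L   3       7.500   2.500   0.500  1.00  0.00           C
ATOM      6  CA  VAL H   1       1.000   5.000   3.000  1.00  0.00           C
ATOM      7  CA  LEU H   2       4.500   5.500   3.500  1.00  0.00           C
ATOM      8  CA  THR H   3       8.000   6.000   4.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_structure(toy_pdb):
    return ap.read_structure(toy_pdb, {"L": "light", "H": "heavy"})


def make_toy_trajectory(structure, n_frames=4, sigma=0.3, seed=0):
    """Small Gaussian-jitter trajectory around a structure's coordinates."""
    rng = np.random.default_rng(seed)
    base = structure.coordinates()
    coords = base[None] + sigma * rng.standard_normal((n_frames, *base.shape))
    return ap.Trajectory(coords=coords, structure=structure)


@pytest.fixture
def toy_trajectory(toy_structure):
    return make_toy_trajectory(toy_structure)


@pytest.fixture(scope="session")
def small_ensemble():
    """20-residue identity-correlation ensemble shared across tests."""
    spec = ap.EnsembleSpec(n_res=20, n_frames=500, seed=99)
    return ap.generate_ensemble(spec)


@pytest.fixture(scope="session")
def correlated_ensemble():
    """50-residue ensemble with planted correlations 0.8, -0.6 and 0."""
    n = 50
    corr = np.eye(n)
    corr[0, 1] = corr[1, 0] = 0.8
    corr[2, 3] = corr[3, 2] = -0.6
    spec = ap.EnsembleSpec(n_res=n, n_frames=5000, seed=11, correlation=corr)
    structure, traj = ap.generate_ensemble(spec)
    return structure, traj, corr


@pytest.fixture(scope="session")
def planted_path_system():
    """30-residue dumbbell with a 6-residue planted communication chain."""
    base = ap.EnsembleSpec(n_res=30, n_frames=5000, seed=7)
    spec = ap.PlantedPathSpec(source=13, target=18, chain=[14, 15, 16, 17])
    structure, traj, truth = ap.generate_planted_path(spec, base)
    return structure, traj, truth


def random_rigid_transform(rng):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
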