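"""Non-covalent interaction detectors vs criteria and a brute-force oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import allopath as ap
from allopath.interactions import (
    AROMATIC_RINGS,
    CATION_ATOMS,
    HYDROPHOBIC_RESIDUES,
    MAX_DH_BOND,
    InteractionCriteria,
)
from allopath.structure_io import Atom, Structure, ValidationError, renumber_chains
from allopath.synthetic_data import generate_interaction_fixture


class TestThresholds:
    """Boundary geometries for each criterion."""

    @pytest.mark.parametrize("kind,distance,angle,expected", [
        ("hbond", 2.8, 180.0, 1),   # collinear, inside 3 A
        ("hbond", 3.2, 180.0, 0),   # outside the distance cutoff
        ("hbond", 2.8, 120.0, 0),   # angle below 150 degrees
        ("hbond", 2.9, 170.0, 1),
        ("hbond", 3.1, 170.0, 0),
        ("hydrophobic", 3.8, None, 1),
        ("hydrophobic", 4.2, None, 0),
        ("cation_pi", 5.5, None, 1),
        ("cation_pi", 6.3, None, 0),
        ("pi_pi", 4.5, None, 1),
        ("pi_pi", 4.9, None, 1),
        ("pi_pi", 5.1, None, 0),
        ("pi_pi", 5.4, None, 0),
    ])
    def test_criterion_boundaries(self, kind, distance, angle, expected):
        kwargs = {} if angle is None else {"angle": angle}
        _, traj = generate_interaction_fixture(kind, distance, **kwargs)
        events = ap.detect_all(traj, types=[kind])
        assert len(events) == expected
        for ev in events:
            assert ev.distance == pytest.approx(distance, abs=1e-6)

    def test_sequence_neighbours_excluded_from_hydrophobic(self):
        # Leu/Val at 3.8 A but adjacent in sequence: excluded
        atoms = [
            ("CA", "C", "LEU", 1, [0.0, 0.0, 0.0]),
            ("CA", "C", "VAL", 2, [3.8, 0.0, 0.0]),
        ]
        s = _build(atoms)
        events = ap.detect_hydrophobic(s, s.coordinates())
        assert events == []

    def test_trp_own_rings_not_pi_pi_partners(self):
        from allopath.synthetic_data import _mk_structure
        specs = []
        names5 = ["CG", "CD1", "NE1", "CE2", "CD2"]
        names6 = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
        # rough indole geometry: two fused rings share CD2/CE2
        ring5 = {"CG": [0, 0, 0], "CD1": [1.1, 0.9, 0], "NE1": [2.3, 0.2, 0],
                 "CE2": [2.0, -1.1, 0], "CD2": [0.7, -1.2, 0]}
        ring6 = {"CZ2": [2.8, -2.2, 0], "CH2": [2.1, -3.4, 0],
                 "CZ3": [0.8, -3.5, 0], "CE3": [0.0, -2.4, 0]}
        for n in names5:
            specs.append((n, "N" if n.startswith("N") else "C", "TRP", 1, np.array(ring5[n])))
        for n in ("CZ2", "CH2", "CZ3", "CE3"):
            specs.append((n, "C", "TRP", 1, np.array(ring6[n])))
        s = _mk_structure(specs)
        events = ap.detect_pi_pi(s, s.coordinates())
        assert events == []

    def test_ligand_nitrogen_counts_as_cation(self):
        # guanidinium-like ligand N near a Tyr ring
        ring = _ring("TYR", 1, center=np.zeros(3))
        atoms = ring + [("N1", "N", "LIG", 2, [1.39 + 4.0, 0.0, 0.0])]
        s = _build(atoms, ligand_chain=True)
        events = ap.detect_cation_pi(s, s.coordinates())
        assert len(events) == 1
        assert events[0].residue_b == 2


def _ring(resname, resid, center):
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    out = []
    for k, name in enumerate(names):
        ang = np.radians(60.0 * k)
        out.append((name, "C", resname, resid,
                    [center[0] + 1.39 * np.cos(ang),
                     center[1] + 1.39 * np.sin(ang), center[2]]))
    return out


def _build(atom_specs, ligand_chain=False):
    resnums = []
    for _, _, _, resid, _ in atom_specs:
        if resid not in resnums:
            resnums.append(resid)
    if ligand_chain:
        protein = [r for r in resnums if r == 1]
        lig = [r for r in resnums if r != 1]
        chains = [("A", "heavy"), ("X", "ligand")]
        rmap = renumber_chains([("A", protein), ("X", lig)])
        chain_of = {r: ("A" if r in protein else "X") for r in resnums}
    else:
        chains = [("A", "heavy")]
        rmap = renumber_chains([("A", resnums)])
        chain_of = {r: "A" for r in resnums}
    atoms = [
        Atom(serial=k + 1, name=name, element=elem,
             residue_index=rmap[(chain_of[resid], resid)], chain_id=chain_of[resid],
             position=np.asarray(pos, dtype=float), mass=12.0,
             resname=resname, author_resid=resid)
        for k, (name, elem, resname, resid, pos) in enumerate(atom_specs)
    ]
    atoms.sort(key=lambda a: a.residue_index)
    return Structure(atoms=atoms, chains=chains, renumber_map=rmap)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_events(structure, coords, crit):
    """O(n^2)/O(n^4) literal re-reading of the four criteria, written
    independently of the detector implementations."""
    atoms = structure.atoms
    n = len(atoms)
    found = {"hbond": set(), "hydrophobic": set(), "cation_pi": set(), "pi_pi": set()}

    # hydrogen bonds
    for i in range(n):
        if atoms[i].element not in ("N", "O", "S"):
            continue
        hs = [k for k in range(n)
              if atoms[k].element == "H"
              and atoms[k].residue_index == atoms[i].residue_index
              and np.linalg.norm(coords[k] - coords[i]) <= MAX_DH_BOND]
        if not hs:
            continue
        for j in range(n):
            if j == i or atoms[j].element not in ("N", "O", "S"):
                continue
            if atoms[j].residue_index == atoms[i].residue_index:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= crit.hbond_max_dist:
                continue
            for k in hs:
                u = coords[i] - coords[k]
                v = coords[j] - coords[k]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang > crit.hbond_min_angle:
                    found["hbond"].add((atoms[i].residue_index, atoms[j].residue_index))
                    break

    # hydrophobic (Cα mode)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = atoms[i], atoms[j]
            if a.name != "CA" or b.name != "CA":
                continue
            if a.resname not in HYDROPHOBIC_RESIDUES or b.resname not in HYDROPHOBIC_RESIDUES:
                continue
            if abs(a.residue_index - b.residue_index) <= 1:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < crit.hydrophobic_max_dist:
                pair = tuple(sorted((a.residue_index, b.residue_index)))
                found["hydrophobic"].add(pair)

    # ring inventory
    rings = []
    by_res = {}
    for i, a in enumerate(atoms):
        by_res.setdefault(a.residue_index, {})[a.name] = i
    for res, named in by_res.items():
        resname = next(a.resname for a in atoms if a.residue_index == res)
        for ring_names in AROMATIC_RINGS.get(resname, []):
            if all(nm in named for nm in ring_names):
                rings.append((res, [named[nm] for nm in ring_names]))

    ligand_res = set()
    for cid, role in structure.chains:
        if role in ("ligand", "glycan"):
            ligand_res.update(g for (c, _), g in structure.renumber_map.items() if c == cid)
    cations = [i for i, a in enumerate(atoms)
               if (a.resname in CATION_ATOMS and a.name in CATION_ATOMS[a.resname])
               or (a.residue_index in ligand_res and a.element == "N")]

    for res, ring_idx in rings:
        for ci in cations:
            if atoms[ci].residue_index == res:
                continue
            dmin = min(np.linalg.norm(coords[k] - coords[ci]) for k in ring_idx)
            if dmin < crit.cation_pi_max_dist:
                found["cation_pi"].add((res, atoms[ci].residue_index))

    for x in range(len(rings)):
        for y in range(x + 1, len(rings)):
            ra, ia = rings[x]
            rb, ib = rings[y]
            if ra == rb:
                continue
            ca = coords[ia].mean(axis=0)
            cb = coords[ib].mean(axis=0)
            if np.linalg.norm(ca - cb) < crit.pi_pi_max_centroid_dist:
                found["pi_pi"].add(tuple(sorted((ra, rb))))
    return found


def random_frame(rng, n_res=40):
    """Random 200-atom structure mixing residue types in a 30 A box."""
    palette = [
        ("LEU", [("CA", "C")]),
        ("VAL", [("CA", "C")]),
        ("PHE", [(nm, "C") for nm in AROMATIC_RINGS["PHE"][0]]),
        ("LYS", [("NZ", "N")]),
        ("ARG", [("NH1", "N"), ("NH2", "N")]),
        ("SER", [("OG", "O"), ("HG", "H")]),
        ("THR", [("OG1", "O"), ("HG1", "H")]),
        ("GLY", [("O", "O")]),
        ("HIS", [(nm, "N" if nm.startswith("N") else "C")
                 for nm in AROMATIC_RINGS["HIS"][0]]),
    ]
    specs = []
    for resid in range(1, n_res + 1):
        resname, atom_names = palette[int(rng.integers(len(palette)))]
        origin = rng.uniform(0, 30, size=3)
        for k, (nm, elem) in enumerate(atom_names):
            if resname in AROMATIC_RINGS and nm in AROMATIC_RINGS[resname][0]:
                ang = np.radians(72.0 if resname == "HIS" else 60.0) * k
                pos = origin + [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]
            elif elem == "H":
                pos = origin + [0.96, 0.0, 0.0]
            else:
                pos = origin + rng.uniform(-0.5, 0.5, size=3) * (k > 0)
            specs.append((nm, elem, resname, resid, pos))
    return _build(specs)


class TestBruteForceOracle:
    def test_detectors_match_brute_force_on_random_frames(self):
        rng = np.random.default_rng(2024)
        crit = InteractionCriteria()
        for _ in range(20):
            s = random_frame(rng)
            coords = s.coordinates()
            expected = brute_force_events(s, coords, crit)
            got = {t: set() for t in expected}
            for ev in ap.detect_hbonds(s, coords, crit):
                got["hbond"].add((ev.residue_a, ev.residue_b))
            for ev in ap.detect_hydrophobic(s, coords, crit):
                got["hydrophobic"].add(tuple(sorted((ev.residue_a, ev.residue_b))))
            for ev in ap.detect_cation_pi(s, coords, crit):
                got["cation_pi"].add((ev.residue_a, ev.residue_b))
            for ev in ap.detect_pi_pi(s, coords, crit):
                got["pi_pi"].add(tuple(sorted((ev.residue_a, ev.residue_b))))
            assert got == expected

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        s = random_frame(rng)
        coords = s.coordinates()
        rot = Rotation.random(rng=rng).as_matrix()
        moved = coords @ rot.T + np.array([12.0, -4.0, 9.0])

        def summary(c):
            out = []
            for ev in ap.detect_all(
                ap.Trajectory(coords=c[None], structure=s)
            ):
                out.append((ev.type, ev.residue_a, ev.residue_b, round(ev.distance, 9)))
            return sorted(out)

        assert summary(coords) == summary(moved)


class TestOccupancy:
    def _events(self, frames_with_event, n_frames):
        return [
            ap.InteractionEvent(frame=f, type="hbond", residue_a=1, atom_a="OG",
                                residue_b=2, atom_b="O", distance=2.8, angle=160.0)
            for f in frames_with_event
        ]

    def test_every_frame_100(self):
        evs = self._events(range(4), 4)
        row = ap.occupancy(evs, {1}, "hbond", 4)
        assert row["occupancy_pct"] == 100.0

    def test_no_events_zero(self):
        row = ap.occupancy([], {1}, "hbond", 4)
        assert row["occupancy_pct"] == 0.0
        assert row["min_pairs"] == row["max_pairs"] == 0

    def test_three_of_four_frames(self):
        evs = self._events([0, 1, 3], 4)
        row = ap.occupancy(evs, {1}, "hbond", 4)
        assert row["occupancy_pct"] == pytest.approx(75.0)
        assert row["min_pairs"] == 0
        assert row["max_pairs"] == 1
        assert row["mean_pairs"] == pytest.approx(0.75)

    def test_site_filtering(self):
        evs = self._events([0], 2)
        assert ap.occupancy(evs, {5}, "hbond", 2)["occupancy_pct"] == 0.0
        assert ap.occupancy(evs, {2}, "hbond", 2)["occupancy_pct"] == 50.0

    def test_empty_site_rejected(self):
        with pytest.raises(ValidationError):
            ap.occupancy([], set(), "hbond", 2)

    def test_min_le_mean_le_max(self):
        evs = self._events([0, 0, 1], 3)  # two events frame 0? same list twice
        row = ap.occupancy(evs, None, "hbond", 3)
        assert row["min_pairs"] <= row["mean_pairs"] <= row["max_pairs"]

    def test_occupancy_monotone_in_distance_threshold(self):
        rng = np.random.default_rng(10)
        s = random_frame(rng, n_res=25)
        frames = s.coordinates()[None] + 0.05 * rng.standard_normal((5, s.n_atoms, 3))
        traj = ap.Trajectory(coords=frames, structure=s)
        occs = []
        for cutoff in (4.0, 5.0, 6.0, 8.0):
            crit = InteractionCriteria(cation_pi_max_dist=cutoff)
            evs = ap.detect_all(traj, crit, types=["cation_pi"])
            occs.append(ap.occupancy(evs, None, "cation_pi", 5)["occupancy_pct"])
        assert occs == sorted(occs)
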