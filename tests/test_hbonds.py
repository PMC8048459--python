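import numpy as np
import pytest

from xlinkforge import synthetic_data as sd
from xlinkforge.traj_analysis import (
    HBondCriteria,
    HBondResult,
    Trajectory,
    TrajAtom,
    hbond_distribution,
    hbonds_frame,
    minimum_image,
    resolve_donor_hydrogens,
)

CRIT = HBondCriteria(donors=frozenset({"HD9"}), acceptors=frozenset({"OD9"}))


def _planted_frame(d_a=0.28, angle_deg=180.0):
    """One donor N, its H, one acceptor O, at controlled geometry."""
    atoms = [
        TrajAtom(index=1, name="ND9", element="N", mass=14.0),
        TrajAtom(index=2, name="HD9", element="H", mass=1.0),
        TrajAtom(index=3, name="OD9", element="O", mass=16.0),
    ]
    alpha = np.radians(angle_deg)
    h = np.array([0.1, 0.0, 0.0])
    # place acceptor at angle alpha from the H->D direction, distance d_a from D
    w = np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    s = 0.1 * np.cos(alpha) + np.sqrt(max(0.01 * np.cos(alpha) ** 2 - 0.01 + d_a**2, 0))
    coords = np.stack([np.zeros(3), h, h + s * w])
    return coords, atoms, [(0, 1)]


class TestHbondsFrame:
    def test_planted_bond_detected(self):
        coords, atoms, bonds = _planted_frame(d_a=0.28, angle_deg=180.0)
        assert hbonds_frame(coords, atoms, bonds, CRIT) == [(0, 1, 2)]

    def test_distance_failure(self):
        coords, atoms, bonds = _planted_frame(d_a=0.32, angle_deg=180.0)
        assert hbonds_frame(coords, atoms, bonds, CRIT) == []

    def test_angle_failure(self):
        coords, atoms, bonds = _planted_frame(d_a=0.28, angle_deg=100.0)
        assert hbonds_frame(coords, atoms, bonds, CRIT) == []

    def test_angle_at_threshold_accepted(self):
        coords, atoms, bonds = _planted_frame(d_a=0.28, angle_deg=120.5)
        assert len(hbonds_frame(coords, atoms, bonds, CRIT)) == 1

    def test_hydrogen_acceptor_mode(self):
        crit = HBondCriteria(
            donors=frozenset({"HD9"}), acceptors=frozenset({"OD9"}),
            distance_mode="hydrogen-acceptor",
        )
        # D-A = 0.32 fails donor-acceptor, but H-A = 0.22 passes H-A mode
        coords, atoms, bonds = _planted_frame(d_a=0.32, angle_deg=180.0)
        assert hbonds_frame(coords, atoms, bonds, CRIT) == []
        assert len(hbonds_frame(coords, atoms, bonds, crit)) == 1

    def test_donor_without_hydrogen_warns_and_skips(self):
        atoms = [
            TrajAtom(index=1, name="ND9", element="N", mass=14.0),
            TrajAtom(index=2, name="OD9", element="O", mass=16.0),
        ]
        crit = HBondCriteria(donors=frozenset({"ND9"}), acceptors=frozenset({"OD9"}))
        coords = np.array([[0.0, 0, 0], [0.28, 0, 0]])
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            assert hbonds_frame(coords, atoms, [], crit) == []

    def test_heavy_donor_name_resolves_hydrogens(self):
        coords, atoms, bonds = _planted_frame()
        crit = HBondCriteria(donors=frozenset({"ND9"}), acceptors=frozenset({"OD9"}))
        assert hbonds_frame(coords, atoms, bonds, crit) == [(0, 1, 2)]

    def test_periodic_image_bond(self):
        coords, atoms, bonds = _planted_frame(d_a=0.28)
        box = np.diag([2.0, 2.0, 2.0])
        shifted = coords.copy()
        shifted[2] += np.array([2.0, 0.0, 0.0])  # move acceptor one image over
        assert hbonds_frame(shifted, atoms, bonds, CRIT, box=box) == [(0, 1, 2)]
        assert hbonds_frame(shifted, atoms, bonds, CRIT, box=None) == []


def brute_force_hbonds(coords, atoms, bonds, criteria, box=None):
    """Independent oracle: plain triple loop over donor-H pairs x acceptors."""
    neighbors = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    pairs = []
    for idx, a in enumerate(atoms):
        if a.name in criteria.donors:
            if a.element == "H":
                heavy = [n for n in neighbors.get(idx, []) if atoms[n].element != "H"]
                if heavy:
                    pairs.append((heavy[0], idx))
            else:
                for n in neighbors.get(idx, []):
                    if atoms[n].element == "H":
                        pairs.append((idx, n))
    pairs = sorted(set(pairs))
    found = []
    for d, h in pairs:
        for a_idx, atom in enumerate(atoms):
            if atom.name not in criteria.acceptors or a_idx in (d, h):
                continue
            ref = d if criteria.distance_mode == "donor-acceptor" else h
            dv = minimum_image((coords[a_idx] - coords[ref])[None], box)[0]
            if np.linalg.norm(dv) > criteria.d_max:
                continue
            v1 = minimum_image((coords[d] - coords[h])[None], box)[0]
            v2 = minimum_image((coords[a_idx] - coords[h])[None], box)[0]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle >= criteria.angle_min:
                found.append((d, h, a_idx))
    return sorted(found)


def random_hbond_frame(seed, n_atoms=200, box_len=2.0):
    """Random soup of donor N-H pairs, acceptor O, and inert C atoms."""
    rng = np.random.default_rng(seed)
    atoms, coords, bonds = [], [], []
    idx = 0
    while idx < n_atoms:
        kind = rng.integers(0, 3)
        pos = rng.uniform(0, box_len, size=3)
        if kind == 0 and idx + 1 < n_atoms:
            atoms.append(TrajAtom(index=idx + 1, name="ND9", element="N", mass=14.0))
            coords.append(pos)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(TrajAtom(index=idx + 2, name="HD9", element="H", mass=1.0))
            coords.append(pos + 0.1 * direction)
            bonds.append((idx, idx + 1))
            idx += 2
        elif kind == 1:
            atoms.append(TrajAtom(index=idx + 1, name="OD9", element="O", mass=16.0))
            coords.append(pos)
            idx += 1
        else:
            atoms.append(TrajAtom(index=idx + 1, name="C", element="C", mass=12.0))
            coords.append(pos)
            idx += 1
    return np.array(coords), atoms, bonds, np.diag([box_len] * 3)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_frames_match_oracle(self, seed):
        coords, atoms, bonds, box = random_hbond_frame(seed)
        fast = hbonds_frame(coords, atoms, bonds, CRIT, box=box)
        slow = brute_force_hbonds(coords, atoms, bonds, CRIT, box=box)
        assert fast == slow

    @pytest.mark.parametrize("seed", [100, 101])
    def test_oracle_match_without_box(self, seed):
        coords, atoms, bonds, _ = random_hbond_frame(seed)
        assert hbonds_frame(coords, atoms, bonds, CRIT) == brute_force_hbonds(
            coords, atoms, bonds, CRIT
        )


class TestHbondDistribution:
    def test_constant_planted_bond(self):
        recipe = sd.TrajectoryRecipe(seed=5, n_frames=50, n_sites=1, site_prob=1.0)
        traj, _ = sd.make_synthetic_trajectory(recipe)
        result = hbond_distribution(traj, CRIT)
        assert result.summary["median"] == 1
        assert result.summary["min"] == 1
        assert result.summary["max"] == 1
        assert result.summary["mean"] == 1
        assert result.summary["sd"] == 0

    def test_alternating_counts(self):
        # frames alternate between 2 and 4 active sites
        recipe = sd.TrajectoryRecipe(seed=5, n_frames=40, n_sites=4, site_prob=1.0)
        traj, _ = sd.make_synthetic_trajectory(recipe)
        broken = 0.45
        for f in range(0, 40, 2):  # deactivate sites 2, 3 on even frames
            for s in (2, 3):
                d_idx, h_idx, a_idx = (
                    traj.n_atoms - 12 + 3 * s,
                    traj.n_atoms - 12 + 3 * s + 1,
                    traj.n_atoms - 12 + 3 * s + 2,
                )
                direction = traj.coords[f, h_idx] - traj.coords[f, d_idx]
                direction /= np.linalg.norm(direction)
                traj.coords[f, a_idx] = traj.coords[f, d_idx] + broken * direction
        result = hbond_distribution(traj, CRIT)
        assert set(result.counts.tolist()) == {2, 4}
        assert result.summary["median"] == 3
        assert result.summary["mean"] == 3

    def test_conservation_invariant(self):
        recipe = sd.TrajectoryRecipe(seed=6, n_frames=60, n_sites=5, site_prob=0.5)
        traj, _ = sd.make_synthetic_trajectory(recipe)
        result = hbond_distribution(traj, CRIT)
        total = int(result.counts.sum())
        assert sum(result.per_donor.values()) == total
        assert sum(result.per_acceptor.values()) == total

    def test_binomial_generator_recovery(self):
        n, p, frames = 12, 0.6, 2000
        recipe = sd.TrajectoryRecipe(seed=42, n_frames=frames, n_sites=n, site_prob=p)
        traj, truth = sd.make_synthetic_trajectory(recipe)
        result = hbond_distribution(traj, CRIT)
        assert result.counts.tolist() == truth["planted_counts"]
        se = np.sqrt(n * p * (1 - p) / frames)
        assert abs(result.summary["mean"] - n * p) <= 3 * se

    def test_selection_restriction(self):
        recipe = sd.TrajectoryRecipe(seed=7, n_frames=10, n_sites=2, site_prob=1.0)
        traj, _ = sd.make_synthetic_trajectory(recipe)
        sel_sites = traj.select("chain X")
        sel_chains = traj.select("chain A B C")
        result = hbond_distribution(traj, CRIT, sel_sites, sel_chains)
        assert result.counts.sum() == 0  # planted bonds are site-internal

    def test_empty_selection_rejected(self):
        recipe = sd.TrajectoryRecipe(seed=7, n_frames=5)
        traj, _ = sd.make_synthetic_trajectory(recipe)
        with pytest.raises(ValueError, match="selects no atoms"):
            hbond_distribution(traj, CRIT, "chain Z", "chain A")

    def test_result_conservation_validated(self):
        with pytest.raises(ValueError, match="conserve"):
            HBondResult(
                counts=np.array([2]), per_donor={0: 1}, per_acceptor={1: 2},
                summary={},
            )
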