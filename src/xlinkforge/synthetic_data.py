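"""Synthetic fixtures with known ground truth.

Three families of generators:

* toy molecules carrying an explicit harmonic force field whose analytic
  Hessian (assembled by the normal-mode module) is the oracle for the
  parameter-derivation stage;
* reduced cross-link-shaped molecules with the standard cross-link atom
  naming, a declared two-residue boundary, cap atoms, and zero-sum charges;
* multi-chain helical trajectories with planted donor-hydrogen-acceptor
  geometries, optional two-conformer alternation, Gaussian positional
  noise, and a triclinic periodic box.

Every generator is deterministic given its seed, and the generating truth
is always returned alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import mass_of
from .normal_modes import HarmonicFF, build_mm_hessian
from .bonded_params import AngleTerm, BondTerm
from .qm_io import AtomRecord, CartesianHessian, KJ_PER_MOL_NM2, MoleculeGeometry
from .traj_analysis.core import TrajAtom, Trajectory


# --- toy molecules -----------------------------------------------------------


@dataclass
class MoleculeRecipe:
    """Atoms, coordinates, and generating harmonic terms for a toy molecule.

    Bond entries are (i, j, k_b, b0); angle entries are
    (i, j, k, k_theta, theta0_deg); a ``None`` equilibrium value means
    "take it from the geometry" (exact equilibrium).
    """

    atoms: list[tuple[str, str]]                      # (name, element)
    coords: np.ndarray
    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)


def make_toy_molecule(
    recipe: MoleculeRecipe,
) -> tuple[MoleculeGeometry, HarmonicFF, CartesianHessian]:
    """Geometry, generating force field, and its analytic Hessian.

    The Hessian is ground truth by construction: it is the exact second
    derivative of the generating harmonic energy at the given geometry.
    """
    n = len(recipe.atoms)
    coords = np.asarray(recipe.coords, dtype=float)
    atoms = [
        AtomRecord(index=k + 1, name=name, element=el, mass=mass_of(el))
        for k, (name, el) in enumerate(recipe.atoms)
    ]
    geom = MoleculeGeometry(atoms=atoms, coords=coords)

    bonds = []
    for entry in recipe.bonds:
        i, j, k_b, b0 = entry
        for idx in (i, j):
            if not 1 <= idx <= n:
                raise ValueError(f"bond ({i},{j}) references missing atom {idx}")
        if b0 is None:
            b0 = float(np.linalg.norm(coords[j - 1] - coords[i - 1]))
        lo, hi = (i, j) if i < j else (j, i)
        bonds.append(BondTerm(i=lo, j=hi, k_b=k_b, b0=b0))

    angles = []
    for entry in recipe.angles:
        i, j, k, k_theta, theta0 = entry
        for idx in (i, j, k):
            if not 1 <= idx <= n:
                raise ValueError(f"angle ({i},{j},{k}) references missing atom {idx}")
        if theta0 is None:
            u = coords[i - 1] - coords[j - 1]
            v = coords[k - 1] - coords[j - 1]
            cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            theta0 = float(np.degrees(np.arccos(np.clip(cos_t, -1, 1))))
        if i > k:
            i, k = k, i
        angles.append(AngleTerm(i=i, j=j, k=k, k_theta=k_theta, theta0=theta0))

    ff = HarmonicFF(bonds=bonds, angles=angles)
    hess = build_mm_hessian(geom, ff)
    return geom, ff, hess


def diatomic_recipe(k: float = 1000.0, b0: float = 0.10) -> MoleculeRecipe:
    """Two atoms on the x axis at their equilibrium separation."""
    return MoleculeRecipe(
        atoms=[("H1", "H"), ("H2", "H")],
        coords=np.array([[0.0, 0.0, 0.0], [b0, 0.0, 0.0]]),
        bonds=[(1, 2, k, b0)],
    )


def water_like_recipe(
    k1: float = 400000.0,
    k2: float = 350000.0,
    k_theta: float = 300.0,
    b1: float = 0.0957,
    b2: float = 0.0957,
    theta_deg: float = 104.5,
) -> MoleculeRecipe:
    """Bent triatomic (apex atom 1) with two bonds and one angle, at equilibrium."""
    theta = np.radians(theta_deg)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [b1, 0.0, 0.0],
            [b2 * np.cos(theta), b2 * np.sin(theta), 0.0],
        ]
    )
    return MoleculeRecipe(
        atoms=[("O1", "O"), ("H2", "H"), ("H3", "H")],
        coords=coords,
        bonds=[(1, 2, k1, None), (1, 3, k2, None)],
        angles=[(2, 1, 3, k_theta, None)],
    )


def bent_angle_only_recipe(k_theta: float = 300.0, theta_deg: float = 110.0) -> MoleculeRecipe:
    """Bent triatomic whose only generating term is the angle (no bonds)."""
    recipe = water_like_recipe(k_theta=k_theta, theta_deg=theta_deg)
    recipe.bonds = []
    recipe.angles = [(2, 1, 3, k_theta, None)]
    return recipe


def chain5_recipe() -> MoleculeRecipe:
    """Five-atom 3D zigzag chain: four bonds and three angles at equilibrium.

    Bond/angle stiffnesses sit at covalent-bond scale so the Cartesian
    footprint of the angles (k_theta / r^2) stays a small perturbation on
    the bond blocks, as in a real molecule.
    """
    directions = [
        np.array([1.0, 0.0, 0.0]),
        np.array([0.45, 0.89, 0.0]),
        np.array([0.45, 0.10, 0.89]),
        np.array([0.50, -0.72, 0.48]),
    ]
    coords = np.zeros((5, 3))
    for i, d in enumerate(directions, start=1):
        coords[i] = coords[i - 1] + 0.15 * d / np.linalg.norm(d)
    bond_ks = [250000.0, 300000.0, 280000.0, 320000.0]
    angle_ks = [250.0, 300.0, 350.0]
    return MoleculeRecipe(
        atoms=[("C1", "C"), ("C2", "C"), ("C3", "C"), ("N4", "N"), ("O5", "O")],
        coords=coords,
        bonds=[(i, i + 1, bond_ks[i - 1], None) for i in range(1, 5)],
        angles=[(i, i + 1, i + 2, angle_ks[i - 1], None) for i in range(1, 4)],
    )


def linear_triatomic(
    k1: float = 1500.0,
    k2: float = 1500.0,
    k_bend: float = 100.0,
    r12: float = 0.116,
    r23: float = 0.116,
) -> tuple[MoleculeGeometry, CartesianHessian]:
    """Collinear triatomic with stretch and (doubly degenerate) bend curvature.

    A harmonic angle term is singular at 180 degrees, so the Hessian is
    assembled in closed form from the linearized internal coordinates:
    stretches contribute k * u u^T blocks along the axis, and each
    perpendicular bend contributes k_bend * b b^T with b the linearized
    angle-change gradient. Exactly 5 zero modes remain (3 translations,
    2 rotations).
    """
    x = np.array([0.0, r12, r12 + r23])
    coords = np.column_stack([x, np.zeros(3), np.zeros(3)])
    atoms = [
        AtomRecord(index=1, name="O1", element="O", mass=mass_of("O")),
        AtomRecord(index=2, name="C2", element="C", mass=mass_of("C")),
        AtomRecord(index=3, name="O3", element="O", mass=mass_of("O")),
    ]
    geom = MoleculeGeometry(atoms=atoms, coords=coords)

    h = np.zeros((9, 9))
    for (a, b, k) in [(0, 1, k1), (1, 2, k2)]:
        # stretch along x between atoms a and b
        grad = np.zeros(9)
        grad[3 * a] = -1.0
        grad[3 * b] = 1.0
        h += k * np.outer(grad, grad)
    for axis in (1, 2):  # y and z bends
        grad = np.zeros(9)
        grad[3 * 0 + axis] = 1.0 / r12
        grad[3 * 2 + axis] = 1.0 / r23
        grad[3 * 1 + axis] = -(1.0 / r12 + 1.0 / r23)
        h += k_bend * np.outer(grad, grad)
    return geom, CartesianHessian(matrix=h, units=KJ_PER_MOL_NM2)


def rigid_transform(
    geom: MoleculeGeometry,
    hess: CartesianHessian,
    rotation: np.ndarray,
    translation: np.ndarray | None = None,
) -> tuple[MoleculeGeometry, CartesianHessian]:
    """Rotate + translate a geometry and apply the congruence transform to
    its Hessian (H' = B H B^T with B = blockdiag(R))."""
    r = np.asarray(rotation, dtype=float)
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-10):
        raise ValueError("rotation matrix must be orthogonal")
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    coords = geom.coords @ r.T + t
    n = geom.n_atoms
    big = np.kron(np.eye(n), r)
    matrix = big @ hess.matrix @ big.T
    matrix = 0.5 * (matrix + matrix.T)
    return (
        MoleculeGeometry(atoms=list(geom.atoms), coords=coords),
        CartesianHessian(matrix=matrix, units=hess.units),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with sign fixing."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# --- cross-link fixtures -----------------------------------------------------


@dataclass
class CrosslinkFixture:
    geometry: MoleculeGeometry
    bonds: list[tuple[str, str]]
    boundary: list[tuple[str, str]]
    cap_atoms: list[str]
    charges: dict[str, float]
    donor_names: set[str]
    acceptor_names: set[str]
    partition: tuple[set[str], set[str]]   # generating truth


_CROSSLINK_KINDS = {
    "DOGDIC-like": dict(n_hydroxyls=4),
    "GODIC-like": dict(n_hydroxyls=2),
    "MODIC-like": dict(n_hydroxyls=3),
}


def make_crosslink_fixture(kind: str = "DOGDIC-like", seed: int = 0) -> CrosslinkFixture:
    """Reduced cross-link-shaped molecule with a declared residue boundary.

    The lysine-derived side carries the backbone N/HN pair and the HD5/HD6
    amine hydrogens; the arginine-derived side carries the ND ring nitrogens
    and the hydroxyl ladder with HD10/HD12/HD13. Charges are random but
    mean-shifted to an exactly zero sum. The bond list is explicit (the
    geometry is a layout, not an optimized structure).
    """
    if kind not in _CROSSLINK_KINDS:
        raise ValueError(
            f"unknown cross-link kind {kind!r}; options: {sorted(_CROSSLINK_KINDS)}"
        )
    n_oh = _CROSSLINK_KINDS[kind]["n_hydroxyls"]

    side_a = ["N", "HN", "CA1", "C1", "OD1", "CB1", "ND2", "HD5", "HD6"]
    side_b = ["CD2", "ND4", "ND5", "ND6", "CC1", "CC2"]
    oh_oxygens = ["OD2", "OD3", "OD4", "OD5"][:n_oh]
    oh_hydrogens = ["HD10", "HD12", "HD13"][: max(n_oh - 1, 0)]
    side_b += oh_oxygens + oh_hydrogens
    caps = ["CM1", "CM2"]
    names = side_a + side_b + caps

    bonds = [
        ("N", "HN"), ("N", "CA1"), ("CA1", "C1"), ("C1", "OD1"),
        ("CA1", "CB1"), ("CB1", "ND2"), ("ND2", "HD5"), ("ND2", "HD6"),
        ("CB1", "CD2"),                      # boundary bond
        ("CD2", "ND4"), ("CD2", "ND5"), ("ND4", "CC1"), ("ND5", "CC1"),
        ("CC1", "ND6"), ("CC1", "CC2"),
        ("C1", "CM1"), ("ND6", "CM2"),       # methyl caps
    ]
    oh_parents = ["CC2", "CC2", "CC1", "CC2"]
    for o_name, parent in zip(oh_oxygens, oh_parents):
        bonds.append((parent, o_name))
    for h_name, o_name in zip(oh_hydrogens, oh_oxygens):
        bonds.append((o_name, h_name))

    def element_of(name: str) -> str:
        if name.startswith("H"):
            return "H"
        if name.startswith("N"):
            return "N"
        if name.startswith("O"):
            return "O"
        return "C"

    # deterministic spiral layout: consecutive atoms 0.15 nm apart
    t = np.arange(len(names))
    coords = np.column_stack(
        [0.35 * np.cos(0.45 * t), 0.35 * np.sin(0.45 * t), 0.042 * t]
    )
    atoms = [
        AtomRecord(index=k + 1, name=nm, element=element_of(nm), mass=mass_of(element_of(nm)))
        for k, nm in enumerate(names)
    ]
    geom = MoleculeGeometry(atoms=atoms, coords=coords)

    rng = np.random.default_rng(seed)
    raw = rng.normal(scale=0.3, size=len(names))
    raw -= raw.mean()                        # exact zero sum
    charges = {nm: float(q) for nm, q in zip(names, raw)}

    donor_names = {"HD5", "HD6", "HN"} | set(oh_hydrogens)
    acceptor_names = {"N", "ND2", "ND4", "ND5", "ND6", "OD1"} | set(oh_oxygens)
    return CrosslinkFixture(
        geometry=geom,
        bonds=bonds,
        boundary=[("CB1", "CD2")],
        cap_atoms=caps,
        charges=charges,
        donor_names=donor_names,
        acceptor_names=acceptor_names,
        partition=(set(side_a), set(side_b)),
    )


# --- synthetic trajectories --------------------------------------------------


@dataclass
class TrajectoryRecipe:
    """Recipe for a three-chain helical trajectory with planted H-bond sites."""

    seed: int
    n_frames: int = 100
    n_chains: int = 3
    n_residues: int = 8
    rise: float = 0.29                 # nm per residue
    twist_deg: float = 103.0
    chain_spacing: float = 0.8         # nm between chain axes
    noise_sigma: float = 0.0           # nm, isotropic per atom per frame
    n_sites: int = 1                   # planted donor-H-acceptor sites
    site_prob: float = 1.0             # per-site per-frame Bernoulli activity
    planted_distance: float = 0.28     # nm donor-acceptor
    planted_angle_deg: float = 180.0   # D-H-A
    broken_distance: float = 0.45      # nm for inactive sites
    two_conformer: bool = False
    conformer_amplitude: float = 0.08  # nm
    box_lengths: tuple = (6.0, 6.0, 6.0)
    box_skew: float = 0.0              # nm shear of the c vector (triclinic)
    enforce_planted: bool = True


def make_synthetic_trajectory(recipe: TrajectoryRecipe) -> tuple[Trajectory, dict]:
    """Generate a trajectory plus its generating truth.

    Returns (trajectory, truth) where truth holds per-frame planted-site
    counts, per-frame conformer labels, and the recipe parameters. Planted
    geometries are enforced after noise by projecting the hydrogen and
    acceptor onto the exact target geometry.
    """
    rng = np.random.default_rng(recipe.seed)
    if recipe.enforce_planted and recipe.noise_sigma > 0.02:
        warnings.warn(
            "large noise sigma: planted geometry is re-enforced post-noise, "
            "but unplanted contacts may fluctuate"
        )

    atoms: list[TrajAtom] = []
    base: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    chains = "ABCDEFGH"

    # three helical chains with backbone naming
    offsets = {"N": (0.05, 0.0, 0.0), "CA": (0.0, 0.0, 0.07),
               "C": (-0.05, 0.0, 0.14), "O": (-0.12, 0.05, 0.14)}
    twist = np.radians(recipe.twist_deg)
    idx = 0
    for c in range(recipe.n_chains):
        cx = recipe.chain_spacing * c + 1.0
        prev_c = None
        for r in range(recipe.n_residues):
            phi = twist * r
            center = np.array(
                [cx + 0.25 * np.cos(phi), 1.0 + 0.25 * np.sin(phi), 1.0 + recipe.rise * r]
            )
            res_atoms = {}
            for name in ("N", "CA", "C", "O"):
                dx, dy, dz = offsets[name]
                pos = center + np.array([dx, dy, dz])
                element = name[0]
                atoms.append(
                    TrajAtom(
                        index=idx + 1, name=name, element=element,
                        mass=mass_of(element), chain=chains[c],
                        resid=r + 1, resname="GLY",
                    )
                )
                base.append(pos)
                res_atoms[name] = idx
                idx += 1
            bonds += [
                (res_atoms["N"], res_atoms["CA"]),
                (res_atoms["CA"], res_atoms["C"]),
                (res_atoms["C"], res_atoms["O"]),
            ]
            if prev_c is not None:
                bonds.append((prev_c, res_atoms["N"]))
            prev_c = res_atoms["C"]

    # planted donor-H-acceptor probe sites, spaced well apart from the chains
    site_indices = []
    for s in range(recipe.n_sites):
        origin = np.array(
            [4.5, 0.7 + 1.1 * (s % 5), 0.7 + 1.1 * (s // 5)]
        )
        d_idx, h_idx, a_idx = idx, idx + 1, idx + 2
        for name, element, pos in [
            ("ND9", "N", origin),
            ("HD9", "H", origin + np.array([0.1, 0.0, 0.0])),
            ("OD9", "O", origin + np.array([recipe.planted_distance, 0.0, 0.0])),
        ]:
            atoms.append(
                TrajAtom(
                    index=idx + 1, name=name, element=element, mass=mass_of(element),
                    chain="X", resid=s + 1, resname="STE",
                )
            )
            base.append(pos)
            idx += 1
        bonds.append((d_idx, h_idx))
        site_indices.append((d_idx, h_idx, a_idx))

    base_coords = np.array(base)
    n_atoms = len(atoms)

    # two-conformer deformation pattern (fixed, seed-derived)
    delta = (
        rng.normal(size=base_coords.shape) * recipe.conformer_amplitude
        if recipe.two_conformer
        else None
    )

    box_matrix = np.array(
        [
            [recipe.box_lengths[0], 0.0, 0.0],
            [0.0, recipe.box_lengths[1], 0.0],
            [recipe.box_skew, recipe.box_skew, recipe.box_lengths[2]],
        ]
    )

    coords = np.empty((recipe.n_frames, n_atoms, 3))
    planted_counts = np.zeros(recipe.n_frames, dtype=int)
    conformers = np.zeros(recipe.n_frames, dtype=int)
    alpha = np.radians(recipe.planted_angle_deg)
    r_dh = 0.1

    for f in range(recipe.n_frames):
        frame = base_coords.copy()
        if delta is not None and f % 2 == 1:
            frame += delta
            conformers[f] = 1
        if recipe.noise_sigma > 0:
            frame += rng.normal(scale=recipe.noise_sigma, size=frame.shape)

        active = rng.random(recipe.n_sites) < recipe.site_prob
        planted_counts[f] = int(active.sum())
        for s, (d_idx, h_idx, a_idx) in enumerate(site_indices):
            u = random_rotation(rng)[:, 0]       # random unit vector
            d_pos = frame[d_idx]
            h_pos = d_pos + r_dh * u
            frame[h_idx] = h_pos
            if active[s] and recipe.enforce_planted:
                # in-plane direction perpendicular to u
                perp = np.cross(u, random_rotation(rng)[:, 1])
                norm = np.linalg.norm(perp)
                if norm < 1e-8:
                    perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
                    norm = np.linalg.norm(perp)
                perp /= norm
                w = -np.cos(alpha) * u + np.sin(alpha) * perp
                disc = r_dh**2 * np.cos(alpha) ** 2 - r_dh**2 + recipe.planted_distance**2
                s_len = r_dh * np.cos(alpha) + np.sqrt(max(disc, 0.0))
                frame[a_idx] = h_pos + s_len * w
            else:
                frame[a_idx] = d_pos + recipe.broken_distance * u
        coords[f] = frame

    traj = Trajectory(
        coords=coords,
        atoms=atoms,
        box=np.repeat(box_matrix[None], recipe.n_frames, axis=0),
        bonds=bonds,
        dt_ps=20.0,
    )
    truth = {
        "planted_counts": planted_counts.tolist(),
        "conformers": conformers.tolist(),
        "site_atoms": site_indices,
        "recipe": recipe,
    }
    return traj, truth
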