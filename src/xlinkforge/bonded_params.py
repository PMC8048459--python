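"""Harmonic bond and angle parameters from a Cartesian Hessian.

The force constant of an internal coordinate is extracted from the 3x3
interatomic sub-block of the Hessian: the block's eigenvalues are projected
(with absolute values, so soft or slightly negative directions cannot produce
a negative constant) onto the internal-coordinate direction. Bond constants
project onto the unit bond vector; angle constants combine the two arm
projections in reciprocal form. Equilibrium values are read directly from
the optimized geometry. Emitted constants follow the V = 1/2 k (x - x0)^2
convention.

All atom indices in this module are 1-based, matching AtomRecord.index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COINCIDENT_ATOM_TOL_NM, COLLINEAR_ANGLE_TOL_RAD
from .qm_io import (
    KJ_PER_MOL_NM2,
    CartesianHessian,
    MoleculeGeometry,
    canonical_pair,
    canonical_triplet,
)


class DerivationError(ValueError):
    """Geometry or Hessian unsuitable for deriving the requested term."""


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond: V = 1/2 k_b (b - b0)^2, k_b in kJ mol^-1 nm^-2, b0 in nm."""

    i: int
    j: int
    k_b: float
    b0: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError(f"bond indices not canonical: ({self.i}, {self.j})")
        if self.k_b < 0:
            raise ValueError(f"negative bond force constant {self.k_b}")
        if self.b0 <= 0:
            raise ValueError(f"non-positive equilibrium length {self.b0}")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle: V = 1/2 k_theta (theta - theta0)^2.

    k_theta in kJ mol^-1 rad^-2; theta0 stored in degrees; j is the apex.
    """

    i: int
    j: int
    k: int
    k_theta: float
    theta0: float

    def __post_init__(self):
        if self.i >= self.k:
            raise ValueError(f"angle indices not canonical: ({self.i}, {self.j}, {self.k})")
        if self.k_theta < 0:
            raise ValueError(f"negative angle force constant {self.k_theta}")
        if not 0.0 < self.theta0 < 180.0:
            raise ValueError(f"equilibrium angle {self.theta0} outside (0, 180)")


@dataclass
class ParameterSet:
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        bond_keys = [(b.i, b.j) for b in self.bonds]
        if len(set(bond_keys)) != len(bond_keys):
            raise ValueError("duplicate canonical bonds in ParameterSet")
        angle_keys = [(a.i, a.j, a.k) for a in self.angles]
        if len(set(angle_keys)) != len(angle_keys):
            raise ValueError("duplicate canonical angles in ParameterSet")


# --- core projections -------------------------------------------------------


def interatomic_block(h: CartesianHessian, a: int, b: int) -> np.ndarray:
    """Negated 3x3 off-diagonal sub-block coupling atoms a and b (1-based).

    Sign convention: block = -d2E / dr_a dr_b.
    """
    n = h.n_atoms
    for idx in (a, b):
        if not 1 <= idx <= n:
            raise IndexError(f"atom index {idx} out of range 1..{n}")
    if a == b:
        raise DerivationError("self-block is not an interatomic coupling")
    ia, ib = 3 * (a - 1), 3 * (b - 1)
    return -h.matrix[ia : ia + 3, ib : ib + 3]


def _projection_sum(block: np.ndarray, direction: np.ndarray) -> float:
    """Sum_m lambda_m |u . v_m| over the eigenpairs of a 3x3 block."""
    evals, evecs = np.linalg.eig(block)
    evals = np.real(evals)
    evecs = np.real(evecs)
    total = 0.0
    for m in range(3):
        v = evecs[:, m]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        total += evals[m] * abs(np.dot(direction, v / norm))
    return total


def _paired_projection(h: CartesianHessian, a: int, b: int, direction: np.ndarray) -> float:
    """Average the projection over the (a,b) and (b,a) blocks."""
    s_ab = _projection_sum(interatomic_block(h, a, b), direction)
    s_ba = _projection_sum(interatomic_block(h, b, a), direction)
    return 0.5 * (s_ab + s_ba)


def _require_units(h: CartesianHessian):
    if h.units != KJ_PER_MOL_NM2:
        raise DerivationError(
            f"Hessian must be in {KJ_PER_MOL_NM2}; convert first (got {h.units})"
        )


# --- bonds ------------------------------------------------------------------


def derive_bond(
    h: CartesianHessian, geom: MoleculeGeometry, pair: tuple[int, int]
) -> BondTerm:
    """Derive a harmonic bond term for the 1-based atom pair (i, j)."""
    _require_units(h)
    i, j = canonical_pair(*pair)
    r = geom.coords[j - 1] - geom.coords[i - 1]
    b0 = float(np.linalg.norm(r))
    if b0 < COINCIDENT_ATOM_TOL_NM:
        raise DerivationError(f"atoms {i} and {j} are coincident (|r| = {b0:g} nm)")
    u = r / b0
    k_b = _paired_projection(h, i, j, u)
    return BondTerm(i=i, j=j, k_b=max(k_b, 0.0), b0=b0)


# --- angles -----------------------------------------------------------------


def derive_angle(
    h: CartesianHessian, geom: MoleculeGeometry, triplet: tuple[int, int, int]
) -> AngleTerm:
    """Derive a harmonic angle term for the 1-based triplet (i, j, k), apex j.

    Per arm, the eigenvalues of the two interatomic blocks rooted at the
    terminal atom — (i, j) and (i, k) — are projected onto the in-plane unit
    vector perpendicular to that arm (u_Pi = u_N x u_ij, u_N the angle-plane
    normal): S_i = sum over both blocks of sum_m lambda_m |u_Pi . v_m|. Each
    arm then yields k_i = R_ij^2 S_i, and k_theta is the arm mean. For a
    Hessian generated by a lone harmonic angle this recovers the generating
    constant exactly (the classic single-block reciprocal form does not: it
    drops the 1-3 block and underestimates by roughly 1 - cos(theta0)).
    """
    _require_units(h)
    i, j, k = canonical_triplet(*triplet)
    r_ij = geom.coords[i - 1] - geom.coords[j - 1]
    r_kj = geom.coords[k - 1] - geom.coords[j - 1]
    R_ij = float(np.linalg.norm(r_ij))
    R_kj = float(np.linalg.norm(r_kj))
    if min(R_ij, R_kj) < COINCIDENT_ATOM_TOL_NM:
        raise DerivationError(f"degenerate angle geometry for triplet ({i},{j},{k})")
    u_ij = r_ij / R_ij
    u_kj = r_kj / R_kj

    cross = np.cross(u_ij, u_kj)
    sin_theta = float(np.linalg.norm(cross))
    cos_theta = float(np.clip(np.dot(u_ij, u_kj), -1.0, 1.0))
    theta = float(np.arctan2(sin_theta, cos_theta))
    if theta < COLLINEAR_ANGLE_TOL_RAD or np.pi - theta < COLLINEAR_ANGLE_TOL_RAD:
        raise DerivationError(
            f"triplet ({i},{j},{k}) is collinear; angle plane undefined"
        )
    u_n = cross / sin_theta
    u_pi = np.cross(u_n, u_ij)
    u_pk = np.cross(u_kj, u_n)

    # blocks with rows at the terminal atom keep the terminal-gradient
    # eigenvector aligned with u_P, so no transpose averaging here
    s_i = _projection_sum(interatomic_block(h, i, j), u_pi) + _projection_sum(
        interatomic_block(h, i, k), u_pi
    )
    s_k = _projection_sum(interatomic_block(h, k, j), u_pk) + _projection_sum(
        interatomic_block(h, k, i), u_pk
    )
    k_theta = max(0.5 * (R_ij**2 * s_i + R_kj**2 * s_k), 0.0)
    return AngleTerm(i=i, j=j, k=k, k_theta=k_theta, theta0=float(np.degrees(theta)))


# --- batch derivation -------------------------------------------------------


def bond_model_hessian(
    geom: MoleculeGeometry, bonds: list[BondTerm]
) -> np.ndarray:
    """Analytic Hessian of the derived harmonic bond terms at this geometry.

    Per bond, with u the unit bond vector and b the current length:
    diagonal blocks k u u^T + k (b - b0)/b (I - u u^T), off-diagonal the
    negative. Used to deflate the QM Hessian before angle extraction, so
    the stiff bond blocks do not bleed into the soft angle projections.
    """
    n = geom.n_atoms
    h = np.zeros((3 * n, 3 * n))
    for term in bonds:
        i, j = term.i - 1, term.j - 1
        r = geom.coords[j] - geom.coords[i]
        b = np.linalg.norm(r)
        u = r / b
        block = term.k_b * np.outer(u, u) + term.k_b * (b - term.b0) / b * (
            np.eye(3) - np.outer(u, u)
        )
        for a, c, sign in ((i, i, 1), (j, j, 1), (i, j, -1), (j, i, -1)):
            h[3 * a : 3 * a + 3, 3 * c : 3 * c + 3] += sign * block
    return h


def _angle_gradient_vector(
    geom: MoleculeGeometry, triplet: tuple[int, int, int]
) -> np.ndarray:
    """Gradient of the angle value embedded in the 3N coordinate vector."""
    i, j, k = triplet
    u = geom.coords[i - 1] - geom.coords[j - 1]
    v = geom.coords[k - 1] - geom.coords[j - 1]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos_t = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    di = (cos_t * uh - vh) / (nu * sin_t)
    dk = (cos_t * vh - uh) / (nv * sin_t)
    g = np.zeros(3 * geom.n_atoms)
    g[3 * (i - 1) : 3 * (i - 1) + 3] = di
    g[3 * (k - 1) : 3 * (k - 1) + 3] = dk
    g[3 * (j - 1) : 3 * (j - 1) + 3] = -(di + dk)
    return g


def derive_all(
    h: CartesianHessian,
    geom: MoleculeGeometry,
    pairs: list[tuple[int, int]],
    triplets: list[tuple[int, int, int]],
    provenance: dict | None = None,
    deflate_bonds: bool = True,
) -> ParameterSet:
    """One BondTerm per canonical pair and one AngleTerm per canonical triplet.

    Bonds are derived first; by default their model Hessian is subtracted
    before the angle projections (see :func:`bond_model_hessian`).
    """
    bonds = []
    for pair in pairs:
        try:
            bonds.append(derive_bond(h, geom, pair))
        except DerivationError as exc:
            raise DerivationError(f"pair {pair}: {exc}") from exc
    h_for_angles = h.matrix
    if deflate_bonds and bonds and triplets:
        h_for_angles = h.matrix - bond_model_hessian(geom, bonds)

    def angle_pass(current: list[AngleTerm] | None) -> list[AngleTerm]:
        out = []
        for idx, triplet in enumerate(triplets):
            matrix = h_for_angles
            if current is not None:
                # subtract the k grad(theta) grad(theta)^T footprint of every
                # other angle at its current estimate (exact at equilibrium)
                matrix = matrix.copy()
                for jdx, other in enumerate(current):
                    if jdx != idx and other.k_theta > 0:
                        g = _angle_gradient_vector(geom, triplets[jdx])
                        matrix -= other.k_theta * np.outer(g, g)
            try:
                out.append(
                    derive_angle(CartesianHessian(matrix, units=h.units), geom, triplet)
                )
            except DerivationError as exc:
                raise DerivationError(f"triplet {triplet}: {exc}") from exc
        return out

    angles = angle_pass(None)
    # fixed-point refinement: angles sharing atoms bleed into each other's
    # projections; mutual deflation converges when that coupling is < 1
    for _ in range(30):
        refined = angle_pass(angles)
        delta = max(
            (
                abs(n.k_theta - o.k_theta) / max(o.k_theta, 1e-12)
                for n, o in zip(refined, angles)
            ),
            default=0.0,
        )
        angles = refined
        if delta < 1e-12:
            break
    prov = dict(provenance or {})
    prov.setdefault("hessian_units", h.units)
    prov.setdefault("n_atoms", geom.n_atoms)
    return ParameterSet(bonds=bonds, angles=angles, provenance=prov)


# --- (de)serialization ------------------------------------------------------


def parameter_set_to_dict(p: ParameterSet) -> dict:
    return {
        "bonds": [
            {"i": b.i, "j": b.j, "k_b_kj_mol_nm2": b.k_b, "b0_nm": b.b0}
            for b in p.bonds
        ],
        "angles": [
            {
                "i": a.i,
                "j": a.j,
                "k": a.k,
                "k_theta_kj_mol_rad2": a.k_theta,
                "theta0_deg": a.theta0,
            }
            for a in p.angles
        ],
        "provenance": p.provenance,
    }


def parameter_set_from_dict(d: dict) -> ParameterSet:
    bonds = [
        BondTerm(i=b["i"], j=b["j"], k_b=b["k_b_kj_mol_nm2"], b0=b["b0_nm"])
        for b in d["bonds"]
    ]
    angles = [
        AngleTerm(
            i=a["i"],
            j=a["j"],
            k=a["k"],
            k_theta=a["k_theta_kj_mol_rad2"],
            theta0=a["theta0_deg"],
        )
        for a in d["angles"]
    ]
    return ParameterSet(bonds=bonds, angles=angles, provenance=d.get("provenance", {}))
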