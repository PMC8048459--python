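"""Bonded-term MM Hessian assembly and mass-weighted normal-mode analysis.

The Hessian of V = sum 1/2 k_b (b - b0)^2 + sum 1/2 k_theta (theta - theta0)^2
is obtained by complex-step differentiation of the analytic gradient, which
is exact to machine precision (no subtractive cancellation), so every
rotational-invariance and null-space property holds at tight tolerances.

Wavenumbers follow the imaginary-mode sign convention: a negative eigenvalue
of the mass-weighted Hessian is reported as a negative wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bonded_params import AngleTerm, BondTerm
from .constants import EIGENVALUE_TO_OMEGA2, SPEED_OF_LIGHT_CM_S
from .qm_io import KJ_PER_MOL_NM2, CartesianHessian, MoleculeGeometry, QMFrequencySet

#: modes with |wavenumber| below this (cm^-1) count as translational/rotational
ZERO_MODE_THRESHOLD_CM = 5.0

_COMPLEX_STEP = 1e-20


@dataclass
class HarmonicFF:
    """Bonded harmonic force field: bond and angle terms (1-based indices)."""

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)


@dataclass
class ModeSpectrum:
    wavenumbers: np.ndarray          # cm^-1, ascending, signed
    eigenvectors: np.ndarray         # columns: mass-weighted displacement vectors
    n_zero: int

    def nonzero_wavenumbers(self, threshold: float = ZERO_MODE_THRESHOLD_CM) -> np.ndarray:
        return self.wavenumbers[np.abs(self.wavenumbers) >= threshold]


@dataclass
class SpectrumComparison:
    modes: list[tuple[int, float, float, float]]   # (index, qm, mm, mm - qm)
    rms_difference: float
    n_modes: int


# --- energy and gradient (complex-safe) -------------------------------------


def bonded_energy(coords: np.ndarray, ff: HarmonicFF) -> float | complex:
    """Total bonded energy (kJ/mol) at the given (possibly complex) coords."""
    e = 0.0
    for b in ff.bonds:
        r = coords[b.j - 1] - coords[b.i - 1]
        blen = np.sqrt(np.dot(r, r))
        e = e + 0.5 * b.k_b * (blen - b.b0) ** 2
    for a in ff.angles:
        theta = _angle_value(coords, a)
        e = e + 0.5 * a.k_theta * (theta - np.radians(a.theta0)) ** 2
    return e


def _angle_value(coords: np.ndarray, a: AngleTerm):
    u = coords[a.i - 1] - coords[a.j - 1]
    v = coords[a.k - 1] - coords[a.j - 1]
    nu = np.sqrt(np.dot(u, u))
    nv = np.sqrt(np.dot(v, v))
    cos_t = np.dot(u, v) / (nu * nv)
    return np.arccos(cos_t)


def bonded_gradient(coords: np.ndarray, ff: HarmonicFF) -> np.ndarray:
    """Analytic gradient of the bonded energy; complex inputs propagate."""
    grad = np.zeros_like(coords)
    for b in ff.bonds:
        r = coords[b.j - 1] - coords[b.i - 1]
        blen = np.sqrt(np.dot(r, r))
        g = b.k_b * (blen - b.b0) * r / blen
        grad[b.j - 1] += g
        grad[b.i - 1] -= g
    for a in ff.angles:
        u = coords[a.i - 1] - coords[a.j - 1]
        v = coords[a.k - 1] - coords[a.j - 1]
        nu = np.sqrt(np.dot(u, u))
        nv = np.sqrt(np.dot(v, v))
        uh = u / nu
        vh = v / nv
        cos_t = np.dot(uh, vh)
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        theta = np.arccos(cos_t)
        pref = a.k_theta * (theta - np.radians(a.theta0))
        # d(theta)/dr_i and d(theta)/dr_k; apex takes minus the sum
        di = (cos_t * uh - vh) / (nu * sin_t)
        dk = (cos_t * vh - uh) / (nv * sin_t)
        grad[a.i - 1] += pref * di
        grad[a.k - 1] += pref * dk
        grad[a.j - 1] -= pref * (di + dk)
    return grad


# --- Hessian assembly -------------------------------------------------------


def build_mm_hessian(geom: MoleculeGeometry, ff: HarmonicFF) -> CartesianHessian:
    """Second derivatives of the bonded energy at the given geometry."""
    n = geom.n_atoms
    for b in ff.bonds:
        for idx in (b.i, b.j):
            if not 1 <= idx <= n:
                raise IndexError(f"bond references atom {idx}, molecule has {n}")
    for a in ff.angles:
        for idx in (a.i, a.j, a.k):
            if not 1 <= idx <= n:
                raise IndexError(f"angle references atom {idx}, molecule has {n}")
        theta = _angle_value(geom.coords.astype(float), a)
        if min(theta, np.pi - theta) < 1e-6:
            raise ValueError(
                f"angle ({a.i},{a.j},{a.k}) is collinear at this geometry; "
                "second derivative undefined"
            )

    dim = 3 * n
    hess = np.zeros((dim, dim))
    base = geom.coords.astype(complex)
    h = _COMPLEX_STEP
    for col in range(dim):
        x = base.copy()
        x[col // 3, col % 3] += 1j * h
        hess[:, col] = bonded_gradient(x, ff).imag.ravel() / h
    hess = 0.5 * (hess + hess.T)
    return CartesianHessian(matrix=hess, units=KJ_PER_MOL_NM2)


# --- normal modes -----------------------------------------------------------


def mode_spectrum(
    geom: MoleculeGeometry,
    h: CartesianHessian,
    zero_threshold: float = ZERO_MODE_THRESHOLD_CM,
) -> ModeSpectrum:
    """Eigen-decompose the mass-weighted Hessian F_ij = H_ij / sqrt(m_i m_j).

    Eigenvalues are converted to signed wavenumbers (cm^-1):
    nu = sign(lambda) * sqrt(|lambda|) / (2 pi c).
    """
    if h.units != KJ_PER_MOL_NM2:
        raise ValueError(f"Hessian must be in {KJ_PER_MOL_NM2}, got {h.units}")
    if h.n_atoms != geom.n_atoms:
        raise ValueError(
            f"geometry has {geom.n_atoms} atoms but Hessian is for {h.n_atoms}"
        )
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(geom.masses, 3))
    f = h.matrix * np.outer(inv_sqrt_m, inv_sqrt_m)
    evals, evecs = np.linalg.eigh(f)

    omega2 = evals * EIGENVALUE_TO_OMEGA2          # s^-2, signed
    wavenumbers = (
        np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi * SPEED_OF_LIGHT_CM_S)
    )
    order = np.argsort(wavenumbers)
    wavenumbers = wavenumbers[order]
    evecs = evecs[:, order]
    n_zero = int(np.sum(np.abs(wavenumbers) < zero_threshold))
    return ModeSpectrum(wavenumbers=wavenumbers, eigenvectors=evecs, n_zero=n_zero)


def compare_spectra(
    qm: QMFrequencySet,
    mm: ModeSpectrum,
    n_modes: int,
    zero_threshold: float = ZERO_MODE_THRESHOLD_CM,
) -> SpectrumComparison:
    """Rank-order comparison of the first n_modes vibrational wavenumbers.

    Near-zero modes (|nu| < threshold) are dropped from both spectra before
    aligning mode i with mode i.
    """
    qm_vib = qm.wavenumbers[np.abs(qm.wavenumbers) >= zero_threshold]
    mm_vib = mm.nonzero_wavenumbers(zero_threshold)
    if len(qm_vib) < n_modes or len(mm_vib) < n_modes:
        raise ValueError(
            f"need {n_modes} nonzero modes; QM has {len(qm_vib)}, MM has {len(mm_vib)}"
        )
    rows = []
    diffs = []
    for m in range(n_modes):
        diff = float(mm_vib[m] - qm_vib[m])
        rows.append((m, float(qm_vib[m]), float(mm_vib[m]), diff))
        diffs.append(diff)
    rms = float(np.sqrt(np.mean(np.square(diffs))))
    return SpectrumComparison(modes=rows, rms_difference=rms, n_modes=n_modes)
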