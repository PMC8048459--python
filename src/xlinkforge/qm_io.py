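"""Readers for QM-side inputs: formatted-checkpoint geometry/Hessian files,
plain wavenumber lists, and bonded-term request files.

The checkpoint dialect stores coordinates in Bohr and the force-constant
block as a lower triangle in Hartree/Bohr^2; everything is normalized here
(coordinates to nm, Hessian expanded to a full symmetric matrix) so no
downstream stage ever revisits unit or dimension questions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import (
    ATOMIC_NUMBER_BY_ELEMENT,
    BOHR_TO_NM,
    ELEMENT_BY_NUMBER,
    HARTREE_PER_BOHR2_TO_KJ_PER_MOL_NM2,
    mass_of,
)

HARTREE_PER_BOHR2 = "hartree_per_bohr2"
KJ_PER_MOL_NM2 = "kj_per_mol_nm2"

_SUPPORTED_UNITS = (HARTREE_PER_BOHR2, KJ_PER_MOL_NM2)


class ParseError(ValueError):
    """Malformed or internally inconsistent input file."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 1-based index, name, element symbol, mass (amu), charge (e)."""

    index: int
    name: str
    element: str
    mass: float
    charge: float = 0.0

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive, got {self.mass}")


@dataclass
class MoleculeGeometry:
    """Ordered atoms plus an N x 3 coordinate array in nm."""

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atoms)
        if n < 2:
            raise ValueError(f"geometry needs at least 2 atoms, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with {n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != n:
            raise ValueError("duplicate atom indices")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass
class CartesianHessian:
    """Full symmetric 3N x 3N second-derivative matrix with a unit tag."""

    matrix: np.ndarray
    units: str = KJ_PER_MOL_NM2

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 3:
            raise ValueError(f"Hessian must be square 3N x 3N, got {m.shape}")
        if self.units not in _SUPPORTED_UNITS:
            raise ValueError(f"unknown Hessian unit tag {self.units!r}")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-8 * scale:
            raise ValueError("Hessian not symmetric within 1e-8 relative")

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class QMFrequencySet:
    """Ascending list of vibrational wavenumbers in cm^-1."""

    wavenumbers: np.ndarray

    def __post_init__(self):
        self.wavenumbers = np.sort(np.asarray(self.wavenumbers, dtype=float))

    def __len__(self) -> int:
        return len(self.wavenumbers)


# --- formatted checkpoint dialect -------------------------------------------


def _read_section(lines: list[str], start: int, count: int, cast) -> list:
    """Collect `count` whitespace-separated values starting below `start`."""
    values: list = []
    i = start + 1
    while len(values) < count and i < len(lines):
        values.extend(cast(tok) for tok in lines[i].split())
        i += 1
    if len(values) != count:
        raise ParseError(
            f"section starting at line {start + 1} declared {count} values, "
            f"found {len(values)}"
        )
    return values


def read_checkpoint(path) -> tuple[MoleculeGeometry, CartesianHessian]:
    """Parse a formatted-checkpoint file into geometry (nm) and Hessian.

    Expects the sections "Atomic numbers", "Current cartesian coordinates"
    (Bohr) and "Cartesian Force Constants" (lower triangle, Hartree/Bohr^2).
    The Hessian is returned expanded to a full symmetric matrix, still in
    Hartree/Bohr^2.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    numbers: list[int] | None = None
    coords: list[float] | None = None
    tril: list[float] | None = None

    for i, line in enumerate(lines):
        if line.startswith("Atomic numbers"):
            numbers = _read_section(lines, i, _declared_count(line, i), int)
        elif line.startswith("Current cartesian coordinates"):
            coords = _read_section(lines, i, _declared_count(line, i), float)
        elif line.startswith("Cartesian Force Constants"):
            tril = _read_section(lines, i, _declared_count(line, i), float)

    if numbers is None or coords is None or tril is None:
        missing = [
            name
            for name, block in [
                ("Atomic numbers", numbers),
                ("Current cartesian coordinates", coords),
                ("Cartesian Force Constants", tril),
            ]
            if block is None
        ]
        raise ParseError(f"missing checkpoint sections: {', '.join(missing)}")

    n = len(numbers)
    if len(coords) != 3 * n:
        raise ParseError(
            f"coordinate count {len(coords)} inconsistent with {n} atoms"
        )
    dim = 3 * n
    expected = dim * (dim + 1) // 2
    if len(tril) != expected:
        raise ParseError(
            f"Hessian block has {len(tril)} values but {n} atoms require "
            f"{expected} (lower triangle of {dim}x{dim})"
        )

    atoms = []
    for k, z in enumerate(numbers):
        if z not in ELEMENT_BY_NUMBER:
            raise ParseError(f"unsupported atomic number {z}")
        el = ELEMENT_BY_NUMBER[z]
        atoms.append(
            AtomRecord(index=k + 1, name=f"{el}{k + 1}", element=el, mass=mass_of(el))
        )
    xyz = np.array(coords).reshape(n, 3) * BOHR_TO_NM

    matrix = np.zeros((dim, dim))
    rows, cols = np.tril_indices(dim)
    matrix[rows, cols] = tril
    matrix[cols, rows] = tril

    geom = MoleculeGeometry(atoms=atoms, coords=xyz)
    hess = CartesianHessian(matrix=matrix, units=HARTREE_PER_BOHR2)
    return geom, hess


def _declared_count(header: str, lineno: int) -> int:
    if "N=" not in header:
        raise ParseError(f"line {lineno + 1}: section header lacks 'N=' count")
    return int(header.split("N=")[1].split()[0])


def write_checkpoint(geom: MoleculeGeometry, hess: CartesianHessian, path) -> None:
    """Write the formatted-checkpoint dialect (round-trip partner of
    :func:`read_checkpoint`); converts nm back to Bohr."""
    if hess.units != HARTREE_PER_BOHR2:
        raise ValueError("write_checkpoint expects a Hartree/Bohr^2 Hessian")
    if hess.n_atoms != geom.n_atoms:
        raise ValueError(
            f"geometry has {geom.n_atoms} atoms but Hessian is for {hess.n_atoms}"
        )
    n = geom.n_atoms
    dim = 3 * n
    rows, cols = np.tril_indices(dim)
    tril = hess.matrix[rows, cols]
    coords_bohr = (geom.coords / BOHR_TO_NM).ravel()
    numbers = [ATOMIC_NUMBER_BY_ELEMENT[a.element] for a in geom.atoms]

    def fmt_block(values, per_line, fmt):
        out = []
        for i in range(0, len(values), per_line):
            out.append("".join(fmt(v) for v in values[i : i + per_line]))
        return out

    lines = ["Synthetic checkpoint"]
    lines.append(f"Number of atoms                            I     {n:12d}")
    lines.append(f"Atomic numbers                             I   N={n:12d}")
    lines.extend(fmt_block(numbers, 6, lambda v: f"{v:12d}"))
    lines.append(f"Current cartesian coordinates              R   N={dim:12d}")
    lines.extend(fmt_block(coords_bohr, 5, lambda v: f"{v:24.15E}"))
    lines.append(f"Cartesian Force Constants                  R   N={len(tril):12d}")
    lines.extend(fmt_block(tril, 5, lambda v: f"{v:24.15E}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --- unit conversion --------------------------------------------------------


def convert_hessian_units(h: CartesianHessian, target: str) -> CartesianHessian:
    """Rescale a Hessian between Hartree/Bohr^2 and kJ mol^-1 nm^-2.

    Forth-and-back conversion is an identity to 1e-12 relative.
    """
    if target not in _SUPPORTED_UNITS:
        raise ValueError(f"unknown Hessian unit tag {target!r}")
    if target == h.units:
        return replace(h, matrix=h.matrix.copy())
    if h.units == HARTREE_PER_BOHR2:
        scale = HARTREE_PER_BOHR2_TO_KJ_PER_MOL_NM2
    else:
        scale = 1.0 / HARTREE_PER_BOHR2_TO_KJ_PER_MOL_NM2
    return CartesianHessian(matrix=h.matrix * scale, units=target)


# --- frequency list ---------------------------------------------------------


def read_frequencies(path) -> QMFrequencySet:
    """Read a plain-text wavenumber list (one or more values per line,
    '#' comments allowed) into an ascending QMFrequencySet."""
    values: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                values.extend(float(tok) for tok in line.split())
    return QMFrequencySet(wavenumbers=np.array(values))


# --- pair / triplet request files -------------------------------------------


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """(i, j) and (j, i) name the same bond; smaller endpoint first."""
    return (i, j) if i < j else (j, i)


def canonical_triplet(i: int, j: int, k: int) -> tuple[int, int, int]:
    """(i, j, k) and (k, j, i) name the same angle (apex j fixed)."""
    return (i, j, k) if i < k else (k, j, i)


def _request_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def _check_atom(tag: str, idx_tok: str, name: str, geom: MoleculeGeometry, lineno: int, path):
    try:
        idx = int(idx_tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: atom ID {idx_tok!r} is not an integer") from None
    if not 1 <= idx <= geom.n_atoms:
        raise ParseError(
            f"{path}:{lineno}: atom ID {idx} out of range 1..{geom.n_atoms}"
        )
    actual = geom.atoms[idx - 1].name
    if actual != name:
        raise ParseError(
            f"{path}:{lineno}: atom {idx} is named {actual!r}, request says {name!r}"
        )
    return idx


def read_pair_triplet_requests(
    pairs_path, triplets_path, geom: MoleculeGeometry
) -> tuple[list[tuple[int, int]], list[tuple[int, int, int]]]:
    """Read bonded-pair and angle-triplet request files.

    Pair lines: ``name_i name_j id_i id_j``; triplet lines add a third
    name/ID column. Indices are 1-based, cross-checked against the geometry
    atom names. Symmetric duplicates are warned about and deduplicated.
    """
    pairs: list[tuple[int, int]] = []
    seen_pairs: set[tuple[int, int]] = set()
    for lineno, toks in _request_lines(pairs_path):
        if len(toks) != 4:
            raise ParseError(f"{pairs_path}:{lineno}: expected 4 fields, got {len(toks)}")
        i = _check_atom("pair", toks[2], toks[0], geom, lineno, pairs_path)
        j = _check_atom("pair", toks[3], toks[1], geom, lineno, pairs_path)
        if i == j:
            raise ParseError(f"{pairs_path}:{lineno}: pair endpoints are identical")
        key = canonical_pair(i, j)
        if key in seen_pairs:
            warnings.warn(f"{pairs_path}:{lineno}: duplicate pair {key}, skipping")
            continue
        seen_pairs.add(key)
        pairs.append(key)

    triplets: list[tuple[int, int, int]] = []
    seen_trip: set[tuple[int, int, int]] = set()
    for lineno, toks in _request_lines(triplets_path):
        if len(toks) != 6:
            raise ParseError(
                f"{triplets_path}:{lineno}: expected 6 fields, got {len(toks)}"
            )
        i = _check_atom("triplet", toks[3], toks[0], geom, lineno, triplets_path)
        j = _check_atom("triplet", toks[4], toks[1], geom, lineno, triplets_path)
        k = _check_atom("triplet", toks[5], toks[2], geom, lineno, triplets_path)
        if len({i, j, k}) != 3:
            raise ParseError(f"{triplets_path}:{lineno}: triplet atoms not distinct")
        key = canonical_triplet(i, j, k)
        if key in seen_trip:
            warnings.warn(
                f"{triplets_path}:{lineno}: duplicate triplet {key}, skipping"
            )
            continue
        seen_trip.add(key)
        triplets.append(key)

    return pairs, triplets


# --- JSON (de)serialization used by the CLI ---------------------------------


def geometry_to_dict(geom: MoleculeGeometry) -> dict:
    return {
        "atoms": [
            {
                "index": a.index,
                "name": a.name,
                "element": a.element,
                "mass": a.mass,
                "charge": a.charge,
            }
            for a in geom.atoms
        ],
        "coords_nm": geom.coords.tolist(),
    }


def geometry_from_dict(d: dict) -> MoleculeGeometry:
    atoms = [AtomRecord(**a) for a in d["atoms"]]
    return MoleculeGeometry(atoms=atoms, coords=np.array(d["coords_nm"]))


def hessian_to_dict(h: CartesianHessian) -> dict:
    return {"matrix": h.matrix.tolist(), "units": h.units}


def hessian_from_dict(d: dict) -> CartesianHessian:
    return CartesianHessian(matrix=np.array(d["matrix"]), units=d["units"])
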