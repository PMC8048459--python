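"""Trajectory container, atom selections, and periodic-boundary helpers.

Coordinates are stored in nm as a frames x atoms x 3 array; the periodic
box, when present, is one 3x3 cell-vector matrix per frame (rows are cell
vectors), supporting triclinic cells. Selections use a small grammar:
space-separated clauses like ``chain A and name N CA C O``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ..constants import mass_of
from ..qm_io import AtomRecord

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class TrajAtom:
    """One trajectory atom with chain/residue labels (index is 1-based)."""

    index: int
    name: str
    element: str
    mass: float
    chain: str = "A"
    resid: int = 1
    resname: str = "UNK"
    charge: float = 0.0


def guess_element(name: str) -> str:
    """Element from an atom name: leading letters, PDB-style (CA -> C)."""
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        raise ValueError(f"cannot guess element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Na", "Mg", "Fe", "Zn", "Se"):
        return two
    return stripped[0].upper()


@dataclass
class Trajectory:
    coords: np.ndarray                       # (n_frames, n_atoms, 3) nm
    atoms: list[TrajAtom]
    box: np.ndarray | None = None            # (n_frames, 3, 3) nm or None
    bonds: list[tuple[int, int]] = field(default_factory=list)  # 0-based pairs
    dt_ps: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"{len(self.atoms)} atoms but coords hold {self.coords.shape[1]}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3, 3):
                raise ValueError(f"box must be (frames, 3, 3), got {self.box.shape}")
            volumes = np.linalg.det(self.box)
            if np.any(volumes <= 0):
                raise ValueError("periodic box must have positive volume")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    # --- selection grammar ---------------------------------------------

    def select(self, expr: str) -> np.ndarray:
        """0-based atom indices matching a selection expression.

        Clauses joined by ``and``; each clause is ``all``, ``backbone``, or
        ``<field> <value>...`` with field one of name/chain/element/resname/resid.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in [c.strip() for c in expr.split(" and ")]:
            if not clause:
                continue
            toks = clause.split()
            key, values = toks[0].lower(), toks[1:]
            if key == "all":
                continue
            if key == "backbone":
                clause_mask = np.array(
                    [a.name in BACKBONE_NAMES for a in self.atoms]
                )
            elif key in ("name", "chain", "element", "resname"):
                if not values:
                    raise ValueError(f"selection clause {clause!r} lists no values")
                wanted = set(values)
                clause_mask = np.array(
                    [getattr(a, key if key != "chain" else "chain") in wanted
                     for a in self.atoms]
                )
            elif key == "resid":
                wanted_ids = {int(v) for v in values}
                clause_mask = np.array([a.resid in wanted_ids for a in self.atoms])
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
            mask &= clause_mask
        return np.nonzero(mask)[0]


# --- periodic boundary conditions -------------------------------------------


def minimum_image(displacements: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Works for triclinic cells: wrap fractional coordinates to [-0.5, 0.5).
    A ``None`` box is a no-op.
    """
    if box is None:
        return displacements
    inv = np.linalg.inv(box)
    frac = displacements @ inv
    frac -= np.round(frac)
    return frac @ box


# --- file I/O ----------------------------------------------------------------


def load_trajectory(topology_path, trajectory_path=None) -> Trajectory:
    """Read coordinates/trajectories (PDB, GRO, XTC, DCD, ...) via MDAnalysis."""
    import MDAnalysis as mda

    if trajectory_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(trajectory_path))

    atoms = []
    for i, a in enumerate(u.atoms):
        try:
            element = a.element if a.element else guess_element(a.name)
        except (mda.exceptions.NoDataError, AttributeError, ValueError):
            element = guess_element(a.name)
        element = element.capitalize()
        try:
            mass = mass_of(element)
        except KeyError:
            mass = float(a.mass) if a.mass > 0 else 1.0
        chain = getattr(a, "chainID", "") or getattr(a, "segid", "A") or "A"
        atoms.append(
            TrajAtom(
                index=i + 1,
                name=a.name,
                element=element,
                mass=mass,
                chain=str(chain).strip() or "A",
                resid=int(a.resid),
                resname=str(a.resname),
            )
        )

    frames = []
    boxes = []
    has_box = True
    for ts in u.trajectory:
        frames.append(ts.positions.copy() / 10.0)  # A -> nm
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            has_box = False
        else:
            boxes.append(
                mda.lib.mdamath.triclinic_vectors(ts.dimensions) / 10.0
            )
    coords = np.array(frames)
    box = np.array(boxes) if has_box and boxes else None
    bonds = []
    if hasattr(u, "bonds"):
        try:
            bonds = [(int(b[0].ix), int(b[1].ix)) for b in u.bonds]
        except Exception:
            bonds = []
    return Trajectory(coords=coords, atoms=atoms, box=box, bonds=bonds)


def write_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (coordinates nm -> A) with CONECT records."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        if traj.box is not None:
            a_len, b_len, c_len, alpha, beta, gamma = _cell_parameters(traj.box[f])
            lines.append(
                f"CRYST1{a_len * 10:9.3f}{b_len * 10:9.3f}{c_len * 10:9.3f}"
                f"{alpha:7.2f}{beta:7.2f}{gamma:7.2f} P 1           1"
            )
        for a, xyz in zip(traj.atoms, traj.coords[f] * 10.0):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.index % 100000:5d} {name:<4.4s} {a.resname:<4.4s}"
                f"{a.chain[:1]}{a.resid % 10000:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {a.element:>2.2s}"
            )
        lines.append("ENDMDL")
    for i, j in traj.bonds:
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _cell_parameters(box: np.ndarray) -> tuple[float, float, float, float, float, float]:
    a, b, c = box
    la, lb, lc = (float(np.linalg.norm(v)) for v in (a, b, c))
    alpha = float(np.degrees(np.arccos(np.dot(b, c) / (lb * lc))))
    beta = float(np.degrees(np.arccos(np.dot(a, c) / (la * lc))))
    gamma = float(np.degrees(np.arccos(np.dot(a, b) / (la * lb))))
    return la, lb, lc, alpha, beta, gamma
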