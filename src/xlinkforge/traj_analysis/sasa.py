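"""Shrake-Rupley solvent-accessible surface area on a deterministic lattice.

Each atom carries a test-point shell of radius r_atom + probe; points inside
any neighbouring shell are occluded and the per-atom area is the exposed
fraction of the full sphere. Points come from a golden-spiral lattice so
results are deterministic; defaults match 960 points and a 0.14 nm probe.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..constants import VDW_RADII_NM

DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit-sphere points (golden-spiral lattice)."""
    if n < 12:
        raise ValueError(f"need at least 12 sphere points, got {n}")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_radii(atoms, radii=None) -> np.ndarray:
    """Per-atom radii (nm): a uniform float, an element-keyed table, or the
    packaged Bondi table when ``radii`` is None."""
    if isinstance(radii, (int, float)):
        return np.full(len(atoms), float(radii))
    table = VDW_RADII_NM if radii is None else radii
    out = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        try:
            out[k] = table[a.element]
        except KeyError:
            raise KeyError(f"no SASA radius for element {a.element!r}") from None
    return out


def sasa_frame(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (nm^2) for one frame."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    n = len(coords)
    shell = radii + probe
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    cutoff = 2.0 * shell.max()
    neighbor_lists = tree.query_ball_tree(tree, r=cutoff)

    areas = np.zeros(n)
    for i in range(n):
        points = coords[i] + shell[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= shell[i] + shell[j]:
                continue
            exposed &= np.linalg.norm(points - coords[j], axis=1) >= shell[j]
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * shell[i] ** 2
    return areas


def sasa(
    traj_coords: np.ndarray,
    atoms=None,
    radii=None,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom, per-frame SASA (nm^2) for a (frames, atoms, 3) array.

    ``radii`` may be per-atom values, a uniform float, an element table, or
    None for the packaged Bondi table (``atoms`` then required).
    """
    coords = np.asarray(traj_coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if isinstance(radii, np.ndarray) and radii.shape == (coords.shape[1],):
        per_atom = radii
    elif atoms is not None or radii is None or isinstance(radii, (dict, float, int)):
        if atoms is None and not isinstance(radii, (float, int)):
            raise ValueError("atoms required to resolve per-element radii")
        per_atom = (
            np.full(coords.shape[1], float(radii))
            if isinstance(radii, (float, int))
            else atom_radii(atoms, radii)
        )
    else:
        per_atom = np.asarray(radii, dtype=float)
    return np.stack(
        [sasa_frame(coords[f], per_atom, probe, n_points) for f in range(len(coords))]
    )
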