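"""Kabsch superposition, pairwise RMSD matrices, and centroid extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory


@dataclass
class RMSDMatrix:
    matrix: np.ndarray            # (n, n) nm, symmetric, zero diagonal
    frame_indices: np.ndarray     # original frame numbers after striding
    selection: str

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(m) > 1e-12) or np.any(m < -1e-15):
            raise ValueError("RMSD matrix must be non-negative with a zero diagonal")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det +1) aligning centered mobile onto reference."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid-body fit of mobile onto reference (both (N, 3))."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot = kabsch_rotation(mob_c, ref_c)
    return mob_c @ rot.T + reference.mean(axis=0)


def kabsch_rmsd(
    frame_a: np.ndarray, frame_b: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """Least-squares RMSD (nm) after centroid removal and optimal rotation."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        a = a[selection]
        b = b[selection]
    if a.shape != b.shape:
        raise ValueError(f"selected atom counts differ: {a.shape[0]} vs {b.shape[0]}")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms for a unique superposition")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    rot = kabsch_rotation(a_c, b_c)
    diff = a_c @ rot.T - b_c
    return float(np.sqrt((diff**2).sum() / len(a)))


def net_rmsd_matrix(
    traj: Trajectory,
    selection: np.ndarray | str | None = None,
    stride: int = 1,
) -> RMSDMatrix:
    """All-pairs backbone RMSD over strided frames (every-previous-frame
    lower triangle mirrored to a full symmetric matrix)."""
    sel, label = _selection(traj, selection)
    frame_idx = np.arange(traj.n_frames)[::stride]
    if len(frame_idx) < 2:
        raise ValueError(f"need at least 2 frames after striding, got {len(frame_idx)}")
    frames = [traj.coords[f][sel] for f in frame_idx]
    n = len(frames)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d = kabsch_rmsd(frames[i], frames[j])
            matrix[i, j] = matrix[j, i] = d
    return RMSDMatrix(matrix=matrix, frame_indices=frame_idx, selection=label)


def _selection(traj: Trajectory, selection) -> tuple[np.ndarray, str]:
    if selection is None:
        return traj.select("backbone"), "backbone"
    if isinstance(selection, str):
        return traj.select(selection), selection
    return np.asarray(selection, dtype=int), "explicit indices"


def centroid_structure(
    traj_or_matrix, selection=None, beta: float = 1.0, stride: int = 1
) -> int:
    """Frame maximizing summed pairwise similarity s_ij = exp(-beta d_ij / <d>).

    Ties break to the lowest frame index; an all-identical trajectory
    degenerates to frame 0. Accepts a Trajectory or a precomputed RMSDMatrix.
    """
    if isinstance(traj_or_matrix, RMSDMatrix):
        rm = traj_or_matrix
    else:
        rm = net_rmsd_matrix(traj_or_matrix, selection=selection, stride=stride)
    d = rm.matrix
    n = len(d)
    off = d[~np.eye(n, dtype=bool)]
    mean_d = off.mean()
    if mean_d <= 0.0:
        return int(rm.frame_indices[0])
    s = np.exp(-beta * d / mean_d)
    np.fill_diagonal(s, 0.0)
    scores = s.sum(axis=1)
    best = int(np.argmax(scores))  # argmax returns the first (lowest) maximizer
    return int(rm.frame_indices[best])
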