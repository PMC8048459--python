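"""Principal component analysis of backbone positional fluctuations.

Frames are superposed in two passes (fit to the first frame, compute the
mean structure, re-fit to the mean) before the 3M x 3M positional
covariance is diagonalized. The eigenvalue sum equals the total positional
variance, and projecting onto all components reconstructs the centered data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .rmsd import superpose


@dataclass
class PCAResult:
    components: np.ndarray        # (3M, 3M), columns orthonormal
    eigenvalues: np.ndarray       # variance per component, non-increasing
    projections: np.ndarray       # (n_frames, 3M)
    mean: np.ndarray              # (M, 3) mean structure after superposition

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca_backbone(
    traj: Trajectory, selection: np.ndarray | str | None = None
) -> PCAResult:
    """PCA of the selected atoms' positions (default: backbone N/CA/C/O)."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if selection is None:
        sel = traj.select("backbone")
    elif isinstance(selection, str):
        sel = traj.select(selection)
    else:
        sel = np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise ValueError("selection must contain at least 3 atoms")

    frames = traj.coords[:, sel, :]
    # pass 1: remove rigid-body motion against the first frame, then the mean
    fitted = np.stack([superpose(f, frames[0]) for f in frames])
    mean = fitted.mean(axis=0)
    fitted = np.stack([superpose(f, mean) for f in fitted])
    mean = fitted.mean(axis=0)

    x = fitted.reshape(traj.n_frames, -1)
    centered = x - mean.ravel()
    cov = centered.T @ centered / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centered @ evecs
    return PCAResult(
        components=evecs, eigenvalues=evals, projections=projections, mean=mean
    )
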