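"""Geometric hydrogen-bond detection and per-trajectory distributions.

Criteria: donor-acceptor heavy-atom distance <= d_max (default 0.3 nm) and
donor-hydrogen-acceptor angle >= angle_min (default 120 degrees). A
hydrogen-acceptor distance mode is available behind a flag. Donor and
acceptor sets are atom-name sets; a listed name may be the hydrogen itself
(its bonded heavy atom becomes the donor) or the heavy atom (its bonded
hydrogens are enumerated), resolved through the bond graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory, minimum_image

#: default donor hydrogen names and acceptor names for the DOGDIC-style
#: cross-link atom labelling
DEFAULT_DONOR_NAMES = frozenset({"HD10", "HD12", "HD13", "HD5", "HD6", "HN"})
DEFAULT_ACCEPTOR_NAMES = frozenset(
    {"N", "ND2", "ND4", "ND5", "ND6", "OD1", "OD2", "OD3", "OD4", "OD5"}
)

DONOR_ACCEPTOR = "donor-acceptor"
HYDROGEN_ACCEPTOR = "hydrogen-acceptor"


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 0.30                  # nm
    angle_min: float = 120.0             # degrees
    donors: frozenset = DEFAULT_DONOR_NAMES
    acceptors: frozenset = DEFAULT_ACCEPTOR_NAMES
    distance_mode: str = DONOR_ACCEPTOR

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 <= self.angle_min <= 180:
            raise ValueError("angle_min must lie in [0, 180]")
        if self.distance_mode not in (DONOR_ACCEPTOR, HYDROGEN_ACCEPTOR):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")


@dataclass
class HBondResult:
    counts: np.ndarray                   # per-frame bond counts
    per_donor: dict[int, int]            # 0-based donor atom index -> tally
    per_acceptor: dict[int, int]
    summary: dict[str, float]

    def __post_init__(self):
        total = int(self.counts.sum())
        if sum(self.per_donor.values()) != total or sum(self.per_acceptor.values()) != total:
            raise ValueError("per-donor/per-acceptor tallies do not conserve the total")


def resolve_donor_hydrogens(
    atoms, bonds: list[tuple[int, int]], donor_names
) -> list[tuple[int, int]]:
    """(donor, hydrogen) 0-based index pairs for the requested donor names.

    Names matching hydrogens are paired with their bonded heavy atom; names
    matching heavy atoms contribute one pair per bonded hydrogen. Donors
    without a resolvable partner are skipped with a warning.
    """
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)

    pairs: list[tuple[int, int]] = []
    for idx, atom in enumerate(atoms):
        if atom.name not in donor_names:
            continue
        if atom.element == "H":
            heavies = [n for n in neighbors.get(idx, []) if atoms[n].element != "H"]
            if not heavies:
                warnings.warn(f"hydrogen {atom.name} (atom {idx + 1}) has no bonded heavy atom; skipped")
                continue
            pairs.append((heavies[0], idx))
        else:
            hydrogens = [n for n in neighbors.get(idx, []) if atoms[n].element == "H"]
            if not hydrogens:
                warnings.warn(f"donor {atom.name} (atom {idx + 1}) has no bonded hydrogen; skipped")
                continue
            pairs.extend((idx, h) for h in hydrogens)
    return sorted(set(pairs))


def hbonds_frame(
    coords: np.ndarray,
    atoms,
    bonds: list[tuple[int, int]],
    criteria: HBondCriteria,
    box: np.ndarray | None = None,
    donor_pairs: list[tuple[int, int]] | None = None,
    acceptor_indices: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples in one frame (0-based indices).

    Minimum-image displacements are used throughout when a box is given.
    """
    if donor_pairs is None:
        donor_pairs = resolve_donor_hydrogens(atoms, bonds, criteria.donors)
    if acceptor_indices is None:
        acceptor_indices = np.array(
            [i for i, a in enumerate(atoms) if a.name in criteria.acceptors], dtype=int
        )
    if len(donor_pairs) == 0 or len(acceptor_indices) == 0:
        return []

    cos_min = np.cos(np.radians(criteria.angle_min))
    out: list[tuple[int, int, int]] = []
    acc_pos = coords[acceptor_indices]
    for d_idx, h_idx in donor_pairs:
        ref = coords[d_idx] if criteria.distance_mode == DONOR_ACCEPTOR else coords[h_idx]
        disp = minimum_image(acc_pos - ref, box)
        dist = np.linalg.norm(disp, axis=1)
        near = dist <= criteria.d_max
        near &= acceptor_indices != d_idx
        near &= acceptor_indices != h_idx
        if not near.any():
            continue
        v_dh = minimum_image(coords[d_idx] - coords[h_idx], box)
        v_ha = minimum_image(acc_pos[near] - coords[h_idx], box)
        norm_dh = np.linalg.norm(v_dh)
        norm_ha = np.linalg.norm(v_ha, axis=1)
        ok = norm_ha > 1e-12
        cos_angle = np.full(len(v_ha), 2.0)
        cos_angle[ok] = (v_ha[ok] @ v_dh) / (norm_ha[ok] * norm_dh)
        # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
        hits = acceptor_indices[near][cos_angle <= cos_min]
        out.extend((d_idx, h_idx, int(a)) for a in hits)
    return sorted(out)


def hbond_distribution(
    traj: Trajectory,
    criteria: HBondCriteria,
    selection_a: np.ndarray | str | None = None,
    selection_b: np.ndarray | str | None = None,
) -> HBondResult:
    """Per-frame hydrogen-bond counts with donor/acceptor participation.

    When both selections are given, a bond counts if its donor lies in one
    selection and its acceptor in the other (either direction).
    """
    sel_a = _resolve_selection(traj, selection_a)
    sel_b = _resolve_selection(traj, selection_b)
    for label, sel in (("selection_a", sel_a), ("selection_b", sel_b)):
        if sel is not None and len(sel) == 0:
            raise ValueError(f"{label} selects no atoms")

    donor_pairs = resolve_donor_hydrogens(traj.atoms, traj.bonds, criteria.donors)
    acceptor_indices = np.array(
        [i for i, a in enumerate(traj.atoms) if a.name in criteria.acceptors], dtype=int
    )

    set_a = set(sel_a.tolist()) if sel_a is not None else None
    set_b = set(sel_b.tolist()) if sel_b is not None else None

    counts = np.zeros(traj.n_frames, dtype=int)
    per_donor: dict[int, int] = {}
    per_acceptor: dict[int, int] = {}
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        triples = hbonds_frame(
            traj.coords[f],
            traj.atoms,
            traj.bonds,
            criteria,
            box=box,
            donor_pairs=donor_pairs,
            acceptor_indices=acceptor_indices,
        )
        for d, h, a in triples:
            if set_a is not None and set_b is not None:
                crosses = (d in set_a and a in set_b) or (d in set_b and a in set_a)
                if not crosses:
                    continue
            counts[f] += 1
            per_donor[d] = per_donor.get(d, 0) + 1
            per_acceptor[a] = per_acceptor.get(a, 0) + 1

    summary = {
        "median": float(np.median(counts)),
        "min": float(counts.min()),
        "max": float(counts.max()),
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=0)),
    }
    return HBondResult(
        counts=counts, per_donor=per_donor, per_acceptor=per_acceptor, summary=summary
    )


def _resolve_selection(traj: Trajectory, sel) -> np.ndarray | None:
    if sel is None:
        return None
    if isinstance(sel, str):
        return traj.select(sel)
    return np.asarray(sel, dtype=int)
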