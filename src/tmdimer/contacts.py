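"""Interhelical residue-residue contact analysis.

A contact between residue i of helix 1 and residue j of helix 2 exists in
a frame when ANY bead of i (backbone or side chain) lies strictly closer
than the cutoff (default 6 A) to any bead of j.  Occupancy is the fraction
of pooled frames in which the contact exists.  Only interhelical contacts
are reported.  The strict "<" at the cutoff is deliberate and documented:
coordinates rounded to 0.1 A can sit exactly at 6.0 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeadTopology, BeadTrajectory


@dataclass
class ContactMap:
    """Residue x residue interhelical contact occupancy in [0, 1]."""

    residues: tuple[np.ndarray, np.ndarray]  # residue numbers per helix
    occupancy: np.ndarray  # (n_res1, n_res2)
    n_frames: int
    cutoff: float

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        expected = (len(self.residues[0]), len(self.residues[1]))
        if self.occupancy.shape != expected:
            raise ValueError("occupancy shape does not match residue labels")
        if ((self.occupancy < 0) | (self.occupancy > 1)).any():
            raise ValueError("occupancy must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, index=self.residues[0], columns=self.residues[1]
        )


def _residue_groups(topology: BeadTopology, helix: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unique residue numbers of one helix and the bead indices of each."""
    mask = topology.helix == helix
    resids = np.unique(topology.resid[mask])
    groups = [np.flatnonzero(mask & (topology.resid == r)) for r in resids]
    return resids, groups


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def residue_contact_matrix(
    frame: np.ndarray,
    topology: BeadTopology,
    cutoff: float = 6.0,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean residue x residue interhelical contact matrix for one frame.

    ``box`` (optional, orthorhombic edge lengths in A) switches on
    minimum-image distances; by default distances are plain Euclidean,
    matching trajectories whose periodic jumps were already removed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res1, groups1 = _residue_groups(topology, 0)
    res2, groups2 = _residue_groups(topology, 1)
    idx1 = np.concatenate(groups1)
    idx2 = np.concatenate(groups2)
    delta = frame[idx1][:, None, :] - frame[idx2][None, :, :]
    if box is not None:
        delta = _min_image(delta, np.asarray(box, dtype=float))
    close = (delta**2).sum(axis=2) < cutoff**2
    # collapse bead pairs to residue pairs: any-bead semantics
    lab1 = np.repeat(np.arange(len(groups1)), [len(g) for g in groups1])
    lab2 = np.repeat(np.arange(len(groups2)), [len(g) for g in groups2])
    out = np.zeros((len(res1), len(res2)), dtype=bool)
    np.logical_or.at(out, (lab1[:, None], lab2[None, :]), close)
    return out


def contact_occupancy(
    traj: BeadTrajectory,
    cutoff: float = 6.0,
    box: np.ndarray | None = None,
) -> ContactMap:
    """Occupancy = per-cell fraction of frames in contact, pooled over all
    frames (replicas are pooled by concatenating before the call)."""
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    res1, _ = _residue_groups(traj.topology, 0)
    res2, _ = _residue_groups(traj.topology, 1)
    acc = np.zeros((len(res1), len(res2)), dtype=float)
    for i in range(traj.n_frames):
        acc += residue_contact_matrix(traj.coords[i], traj.topology, cutoff, box)
    return ContactMap(
        residues=(res1, res2),
        occupancy=acc / traj.n_frames,
        n_frames=traj.n_frames,
        cutoff=cutoff,
    )


def contact_difference(map_a: ContactMap, map_b: ContactMap) -> np.ndarray:
    """Signed occupancy difference a - b, aligned by residue number.

    A point mutation changes a residue label (name) but not its number, so
    alignment is by number; a shape or numbering mismatch is a hard error.
    """
    for h in (0, 1):
        if len(map_a.residues[h]) != len(map_b.residues[h]) or not np.array_equal(
            map_a.residues[h], map_b.residues[h]
        ):
            raise ValueError("contact maps have mismatching residue numbering")
    return map_a.occupancy - map_b.occupancy
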