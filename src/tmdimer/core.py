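"""Core in-memory containers for bead-resolution helix dimer trajectories.

Coordinates are stored in Angstrom throughout the package; angles in
degrees wrapped to (-180, 180]; energies in kJ/mol; temperatures in K.
Unit conversion happens only at I/O boundaries (e.g. GRO files in nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BACKBONE = "BB"
SIDECHAIN = "SC"


def wrap_angle(a):
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class BeadTopology:
    """Static per-bead labels shared by every frame of a trajectory.

    Attributes
    ----------
    resid : (n_beads,) int array, 1-based residue numbers
    helix : (n_beads,) int array, 0 for the first helix, 1 for the second
    role : (n_beads,) str array, ``"BB"`` or ``"SC"``
    """

    resid: np.ndarray
    helix: np.ndarray
    role: np.ndarray

    def __post_init__(self):
        self.resid = np.asarray(self.resid, dtype=int)
        self.helix = np.asarray(self.helix, dtype=int)
        self.role = np.asarray(self.role, dtype="U2")
        n = len(self.resid)
        if len(self.helix) != n or len(self.role) != n:
            raise ValueError("topology arrays must have equal length")
        if not set(np.unique(self.helix)) <= {0, 1}:
            raise ValueError("helix labels must be 0 or 1")

    @property
    def n_beads(self) -> int:
        return len(self.resid)

    def backbone_indices(self, helix: int) -> np.ndarray:
        """Indices of backbone beads of one helix, in file (N->C) order."""
        return np.flatnonzero((self.helix == helix) & (self.role == BACKBONE))

    def residues(self, helix: int) -> np.ndarray:
        """Ordered unique residue numbers of one helix."""
        return self.resid[self.backbone_indices(helix)]


@dataclass
class BeadTrajectory:
    """Frames x beads x 3 coordinate array (Angstrom) plus bead labels."""

    coords: np.ndarray
    topology: BeadTopology
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.coords.shape[1] != self.topology.n_beads:
            raise ValueError(
                f"coords have {self.coords.shape[1]} beads but topology has "
                f"{self.topology.n_beads}"
            )
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    @staticmethod
    def concatenate(parts: list["BeadTrajectory"]) -> "BeadTrajectory":
        """Pool frames of several replicas sharing one topology."""
        first = parts[0]
        for p in parts[1:]:
            if p.n_beads != first.n_beads:
                raise ValueError("replicas disagree on bead count")
        coords = np.concatenate([p.coords for p in parts], axis=0)
        times = np.concatenate([p.times for p in parts])
        return BeadTrajectory(coords, first.topology, times)


@dataclass
class HelixAssignment:
    """Bead-index bookkeeping needed by the geometric descriptors.

    For each helix the assignment records the ordered backbone-bead indices
    of the helical span, the N-terminal-half subset used for the crossing
    angle, the "upper"-half subset anchoring the rotation-angle dihedrals,
    and the backbone-bead index of the reference residue.
    """

    backbone: tuple[np.ndarray, np.ndarray]
    n_half: tuple[np.ndarray, np.ndarray]
    upper_half: tuple[np.ndarray, np.ndarray]
    reference_bead: tuple[int, int]
    reference_residue: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self):
        self.backbone = tuple(np.asarray(b, dtype=int) for b in self.backbone)
        self.n_half = tuple(np.asarray(b, dtype=int) for b in self.n_half)
        self.upper_half = tuple(np.asarray(b, dtype=int) for b in self.upper_half)
        for h in (0, 1):
            if len(self.backbone[h]) < 4:
                raise ValueError("each helix needs at least 4 backbone beads")
            if len(self.n_half[h]) == 0 or len(self.upper_half[h]) == 0:
                raise ValueError("half subsets must be non-empty")
            if self.reference_bead[h] not in self.backbone[h]:
                raise ValueError("reference bead must belong to its helix")
        if set(self.backbone[0]) & set(self.backbone[1]):
            raise ValueError("helices must be disjoint")

    @property
    def max_index(self) -> int:
        return int(max(self.backbone[0].max(), self.backbone[1].max()))

    def validate_for(self, n_beads: int) -> None:
        if self.max_index >= n_beads:
            raise ValueError(
                f"assignment refers to bead {self.max_index} but frame has "
                f"only {n_beads} beads"
            )

    @classmethod
    def from_topology(
        cls,
        topology: BeadTopology,
        reference_residue: int | tuple[int, int],
        upper: str = "N",
        helical_span: tuple[int, int] | None = None,
    ) -> "HelixAssignment":
        """Build an assignment from bead labels.

        Parameters
        ----------
        reference_residue : residue number whose backbone bead anchors the
            rotation-angle dihedrals; a single number (homodimer) or a pair.
        upper : ``"N"`` (default) or ``"C"`` — which half of the helical span
            plays the role of the "upper" COG.
        helical_span : optional inclusive (first, last) residue range to
            restrict the helical part, excluding flexible termini.
        """
        if isinstance(reference_residue, (int, np.integer)):
            reference_residue = (int(reference_residue), int(reference_residue))
        if upper not in ("N", "C"):
            raise ValueError("upper must be 'N' or 'C'")
        backbone, n_half, upper_half, ref_beads = [], [], [], []
        for h in (0, 1):
            idx = topology.backbone_indices(h)
            if helical_span is not None:
                lo, hi = helical_span
                resid = topology.resid[idx]
                idx = idx[(resid >= lo) & (resid <= hi)]
            if len(idx) < 4:
                raise ValueError(f"helix {h} has fewer than 4 backbone beads")
            half = math.ceil(len(idx) / 2)
            backbone.append(idx)
            n_half.append(idx[:half])
            upper_half.append(idx[:half] if upper == "N" else idx[-half:])
            ref = idx[topology.resid[idx] == reference_residue[h]]
            if len(ref) != 1:
                raise ValueError(
                    f"reference residue {reference_residue[h]} not found "
                    f"exactly once on helix {h}"
                )
            ref_beads.append(int(ref[0]))
        return cls(
            backbone=(backbone[0], backbone[1]),
            n_half=(n_half[0], n_half[1]),
            upper_half=(upper_half[0], upper_half[1]),
            reference_bead=(ref_beads[0], ref_beads[1]),
            reference_residue=reference_residue,
        )
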