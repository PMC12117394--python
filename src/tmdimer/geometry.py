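"""Per-frame geometric descriptors of a two-helix bead dimer.

Four descriptors characterise the arrangement of a transmembrane helix
dimer (all computed from backbone-bead centers of geometry, COGs):

``d``
    Euclidean distance between the backbone-bead COGs of the two helices.
``omega`` (crossing angle)
    Signed dihedral over (N-half COG of helix 1, COG of helix 1,
    COG of helix 2, N-half COG of helix 2); positive values correspond to
    left-handed dimers, negative to right-handed ones.
``phase`` / ``position``
    Rotation angle of each helix about its own long axis, measured as the
    dihedral (COG of the partner helix, COG of the helix, upper-half COG
    of the helix, backbone bead of the reference residue).  ``phase`` is
    the angle of helix 1, ``position`` that of helix 2; swapping the helix
    labels exchanges the two.  An angle near 0 means the reference residue
    faces the partner helix (it sits at the dimer interface).
``dN`` / ``dC``
    Distances between the backbone beads of the first (respectively last)
    residues of the two helices.

Frames whose dihedral anchor points are collinear yield NaN plus an
explicit per-frame ``undefined`` flag rather than a silent 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BeadTrajectory, HelixAssignment, wrap_angle

#: below this sine of the plane-normal angle a dihedral is degenerate
_DEGENERATE_CROSS = 1e-10

DESCRIPTOR_COLUMNS = ["d", "omega", "phase", "position", "dN", "dC"]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) over four points, in (-180, 180].

    Standard two-plane convention: the angle between the half-plane
    containing p1 and the half-plane containing p4, about the p2->p3 axis,
    with the sign given by the right-hand rule about that axis.
    Returns NaN when either plane is degenerate (collinear points).
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    n2 = np.linalg.norm(b2)
    if (
        np.linalg.norm(c12) < _DEGENERATE_CROSS
        or np.linalg.norm(c23) < _DEGENERATE_CROSS
        or n2 < _DEGENERATE_CROSS
    ):
        return float("nan")
    ang = np.degrees(np.arctan2(np.dot(np.cross(c12, c23), b2) / n2, np.dot(c12, c23)))
    return wrap_angle(ang)


def _cog(frame: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return frame[idx].mean(axis=0)


def interhelical_distance(frame: np.ndarray, assignment: HelixAssignment) -> float:
    """COG-COG distance (A) between the backbone beads of the two helices."""
    assignment.validate_for(frame.shape[0])
    c0 = _cog(frame, assignment.backbone[0])
    c1 = _cog(frame, assignment.backbone[1])
    return float(np.linalg.norm(c0 - c1))


def crossing_angle(frame: np.ndarray, assignment: HelixAssignment) -> float:
    """Signed crossing angle Omega (degrees); NaN if degenerate."""
    assignment.validate_for(frame.shape[0])
    return dihedral(
        _cog(frame, assignment.n_half[0]),
        _cog(frame, assignment.backbone[0]),
        _cog(frame, assignment.backbone[1]),
        _cog(frame, assignment.n_half[1]),
    )


def rotation_angle(frame: np.ndarray, assignment: HelixAssignment, helix: int) -> float:
    """Rotation of one helix about its own axis, as a dihedral (degrees).

    Measured over (partner COG, own COG, own upper-half COG, reference
    bead): the dihedral axis runs along the helix, so the angle tracks how
    far the reference residue is rotated away from the dimer interface.
    """
    assignment.validate_for(frame.shape[0])
    other = 1 - helix
    return dihedral(
        _cog(frame, assignment.backbone[other]),
        _cog(frame, assignment.backbone[helix]),
        _cog(frame, assignment.upper_half[helix]),
        frame[assignment.reference_bead[helix]],
    )


def phase_position(frame: np.ndarray, assignment: HelixAssignment) -> tuple[float, float]:
    """(phase, position) = rotation angles of helix 1 and helix 2."""
    return (
        rotation_angle(frame, assignment, 0),
        rotation_angle(frame, assignment, 1),
    )


def termini_distances(frame: np.ndarray, assignment: HelixAssignment) -> tuple[float, float]:
    """(dN, dC): first-residue and last-residue backbone-bead distances (A)."""
    assignment.validate_for(frame.shape[0])
    b0, b1 = assignment.backbone
    dn = float(np.linalg.norm(frame[b0[0]] - frame[b1[0]]))
    dc = float(np.linalg.norm(frame[b0[-1]] - frame[b1[-1]]))
    return dn, dc


def compute_descriptors(
    traj: BeadTrajectory,
    assignment: HelixAssignment,
    replica: str | None = None,
) -> pd.DataFrame:
    """Descriptor table with one row per frame.

    Columns: ``frame, time, d, omega, phase, position, dN, dC, undefined``
    (plus ``replica`` when a label is given).  ``undefined`` marks frames
    with a degenerate dihedral; their angle entries are NaN.  Each frame is
    processed independently, so permuting frames permutes rows identically.
    """
    assignment.validate_for(traj.n_beads)
    rows = np.empty((traj.n_frames, 6), dtype=float)
    for i in range(traj.n_frames):
        f = traj.coords[i]
        dn, dc = termini_distances(f, assignment)
        rows[i] = (
            interhelical_distance(f, assignment),
            crossing_angle(f, assignment),
            rotation_angle(f, assignment, 0),
            rotation_angle(f, assignment, 1),
            dn,
            dc,
        )
    df = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
    df.insert(0, "frame", np.arange(traj.n_frames))
    df.insert(1, "time", traj.times)
    df["undefined"] = df[["omega", "phase", "position"]].isna().any(axis=1)
    if replica is not None:
        df["replica"] = replica
    return df


def concat_replicas(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-replica descriptor tables, preserving provenance labels."""
    parts = []
    for label, df in tables.items():
        part = df.copy()
        part["replica"] = label
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
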