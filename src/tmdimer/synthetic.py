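"""Synthetic coarse-grained helix dimer builder.

Generates ideal CG-style helices (one backbone bead per residue, optional
side-chain beads) and places two copies at a prescribed arrangement —
interhelical distance, crossing angle, per-helix rotation angles, axial
offset — so that trajectories with exactly known ground truth can exercise
the analysis stack.  Defaults follow canonical alpha-helix C-alpha
geometry: 1.5 A rise and 100 deg twist per residue on a 2.3 A radius.

The placement is solved, not assumed: after an analytic first guess the
builder measures the arrangement with :mod:`tmdimer.geometry` and applies
fixed-point corrections until the measured descriptors match the request
(the half-helix COGs carry a small azimuthal offset that an open-loop
construction would ignore).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .core import BACKBONE, SIDECHAIN, BeadTopology, BeadTrajectory, HelixAssignment, wrap_angle


class HelixClashWarning(UserWarning):
    """Requested interhelical distance lets beads interpenetrate."""


@dataclass(frozen=True)
class IdealHelixSpec:
    """Geometry of one ideal helix (distances in A, angles in degrees)."""

    n_residues: int = 26
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_radius: float = 2.3
    side_chain: bool = False
    side_chain_offset: float = 2.5

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4 (axis fit undefined below)")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be positive")
        if not 0 < self.twist_per_residue < 180:
            raise ValueError("twist_per_residue must be in (0, 180)")
        if self.helix_radius < 0:
            raise ValueError("helix_radius must be non-negative")


@dataclass(frozen=True)
class ArrangementSpec:
    """Target dimer arrangement in descriptor space.

    ``d`` is the backbone COG-COG distance; ``omega`` the signed crossing
    angle; ``phase``/``position`` the rotation angles of helix 1 and 2
    about their own axes; ``axial_offset`` a z-shift of helix 2 along the
    membrane normal (so the in-plane separation is sqrt(d^2 - offset^2)).
    """

    d: float = 8.0
    omega: float = 0.0
    phase: float = 0.0
    position: float = 0.0
    axial_offset: float = 0.0

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if abs(self.axial_offset) >= self.d and self.d > 0:
            raise ValueError("|axial_offset| must be smaller than d")
        for name in ("omega", "phase", "position"):
            object.__setattr__(self, name, wrap_angle(getattr(self, name)))


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-constant arrangement schedule plus isotropic jitter."""

    segments: tuple[tuple[ArrangementSpec, int], ...]
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        segments = tuple((a, int(n)) for a, n in self.segments)
        object.__setattr__(self, "segments", segments)
        if sum(n for _, n in segments) < 1:
            raise ValueError("total frame count must be >= 1")
        if any(n < 0 for _, n in segments):
            raise ValueError("segment frame counts must be non-negative")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class IdealHelix:
    """Bead coordinates of one helix, backbone COG at the origin, axis // z."""

    spec: IdealHelixSpec
    bb: np.ndarray  # (n_residues, 3)
    sc: np.ndarray | None  # (n_residues, 3) or None


def build_ideal_helix(spec: IdealHelixSpec) -> IdealHelix:
    """Place backbone beads on a circular helix with the given geometry.

    Bead k sits at angle k*twist and height k*rise; the set is translated
    so the backbone COG is at the origin.  The optional side-chain bead of
    each residue points radially outward at ``side_chain_offset`` beyond
    the backbone radius.
    """
    k = np.arange(spec.n_residues)
    theta = np.radians(spec.twist_per_residue) * k
    z = spec.rise_per_residue * k
    bb = np.column_stack(
        [spec.helix_radius * np.cos(theta), spec.helix_radius * np.sin(theta), z]
    )
    sc = None
    if spec.side_chain:
        r_sc = spec.helix_radius + spec.side_chain_offset
        sc = np.column_stack([r_sc * np.cos(theta), r_sc * np.sin(theta), z])
    cog = bb.mean(axis=0)
    bb = bb - cog
    if sc is not None:
        sc = sc - cog
    return IdealHelix(spec=spec, bb=bb, sc=sc)


def dimer_topology(spec: IdealHelixSpec) -> BeadTopology:
    """Bead labels for two copies of the helix: helix 0 beads then helix 1,
    residues numbered 1..n on each helix, BB bead (and SC bead) per residue."""
    resid, helix, role = [], [], []
    for h in (0, 1):
        for r in range(1, spec.n_residues + 1):
            resid.append(r)
            helix.append(h)
            role.append(BACKBONE)
            if spec.side_chain:
                resid.append(r)
                helix.append(h)
                role.append(SIDECHAIN)
    return BeadTopology(np.array(resid), np.array(helix), np.array(role))


def default_assignment(
    spec: IdealHelixSpec, reference_residue: int | None = None
) -> HelixAssignment:
    """Assignment matching :func:`dimer_topology`; reference defaults to the
    mid-span residue (whose bead sits near the COG height, where the
    rotation-angle dihedral is best conditioned)."""
    if reference_residue is None:
        reference_residue = (spec.n_residues + 1) // 2
    return HelixAssignment.from_topology(dimer_topology(spec), reference_residue)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _interleave(spec: IdealHelixSpec, bb: np.ndarray, sc: np.ndarray | None) -> np.ndarray:
    if sc is None:
        return bb
    out = np.empty((2 * spec.n_residues, 3))
    out[0::2] = bb
    out[1::2] = sc
    return out


def _assemble(helix: IdealHelix, beta: float, alpha: float, omega: float,
              dx: float, dz: float) -> np.ndarray:
    """One dimer frame: helix 1 spun by beta about z; helix 2 spun by alpha,
    tilted by omega about x, then shifted to (dx, 0, dz)."""
    spec = helix.spec
    r1 = _rot_z(beta)
    h1_bb = helix.bb @ r1.T
    h1_sc = helix.sc @ r1.T if helix.sc is not None else None
    r2 = _rot_x(omega) @ _rot_z(alpha)
    shift = np.array([dx, 0.0, dz])
    h2_bb = helix.bb @ r2.T + shift
    h2_sc = helix.sc @ r2.T + shift if helix.sc is not None else None
    return np.vstack(
        [_interleave(spec, h1_bb, h1_sc), _interleave(spec, h2_bb, h2_sc)]
    )


def place_dimer(
    helix: IdealHelix,
    arrangement: ArrangementSpec,
    assignment: HelixAssignment | None = None,
    tol_angle: float = 1e-3,
    max_iter: int = 100,
) -> np.ndarray:
    """Build a two-helix frame whose measured descriptors equal the spec.

    The crossing angle and the two rotation angles are refined by a
    fixed-point loop against :mod:`tmdimer.geometry` until they agree with
    the request to ``tol_angle`` degrees (d is exact by construction).
    Returns the (n_beads, 3) coordinate frame; bead order matches
    :func:`dimer_topology`.
    """
    spec = helix.spec
    if arrangement.d < 2 * spec.helix_radius:
        warnings.warn(
            f"interhelical distance {arrangement.d} A is below twice the "
            f"helix radius ({2 * spec.helix_radius} A): beads interpenetrate",
            HelixClashWarning,
            stacklevel=2,
        )
    if assignment is None:
        assignment = default_assignment(spec)
    dz = arrangement.axial_offset
    dx = math.sqrt(max(arrangement.d**2 - dz**2, 0.0))
    beta, alpha, omega = arrangement.phase, arrangement.position, arrangement.omega
    frame = _assemble(helix, beta, alpha, omega, dx, dz)
    for _ in range(max_iter):
        om_m = geometry.crossing_angle(frame, assignment)
        ph_m, po_m = geometry.phase_position(frame, assignment)
        e_om = wrap_angle(arrangement.omega - om_m)
        e_ph = wrap_angle(arrangement.phase - ph_m)
        e_po = wrap_angle(arrangement.position - po_m)
        if max(abs(e_om), abs(e_ph), abs(e_po)) < tol_angle:
            break
        # the rotation-angle dihedral axis (COG -> N-half COG) points toward
        # -z in this construction, so spin corrections enter with a minus
        omega += e_om
        beta -= e_ph
        alpha -= e_po
        frame = _assemble(helix, beta, alpha, omega, dx, dz)
    else:
        raise RuntimeError(
            "dimer placement did not converge; arrangement may be degenerate"
        )
    return frame


def generate_trajectory(
    helix: IdealHelix,
    traj_spec: TrajectorySpec,
    assignment: HelixAssignment | None = None,
) -> tuple[BeadTrajectory, pd.DataFrame]:
    """Piecewise-stationary trajectory with known per-frame ground truth.

    Each segment contributes ``n_frames`` copies of its placed arrangement
    with i.i.d. isotropic Gaussian jitter of ``jitter_sigma`` A per bead
    coordinate.  Returns the trajectory and a truth table with columns
    ``frame, segment, d, omega, phase, position, axial_offset``.
    Identical seeds yield byte-identical coordinates.
    """
    spec = helix.spec
    topology = dimer_topology(spec)
    rng = np.random.default_rng(traj_spec.seed)
    frames, records = [], []
    frame_no = 0
    for seg_idx, (arr, n_frames) in enumerate(traj_spec.segments):
        base = place_dimer(helix, arr, assignment)
        for _ in range(n_frames):
            f = base
            if traj_spec.jitter_sigma > 0:
                f = base + rng.normal(0.0, traj_spec.jitter_sigma, base.shape)
            frames.append(f)
            records.append(
                dict(
                    frame=frame_no,
                    segment=seg_idx,
                    d=arr.d,
                    omega=arr.omega,
                    phase=arr.phase,
                    position=arr.position,
                    axial_offset=arr.axial_offset,
                )
            )
            frame_no += 1
    traj = BeadTrajectory(np.array(frames), topology)
    return traj, pd.DataFrame.from_records(records)
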