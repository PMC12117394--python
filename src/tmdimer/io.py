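"""Readers and writers for the package's file formats.

Standard coordinate formats (PDB, GRO, multi-model PDB trajectories) are
read through MDAnalysis, which reports coordinates in Angstrom regardless
of the on-disk unit (GRO files in nm are scaled by 10 on read).  Two
plain-text formats are owned by this package and are the portability
contract:

* a fallback trajectory format — a ``# tmdimer trajectory v1`` header,
  then per frame a ``FRAME <index> time=<t>`` line followed by one
  ``x y z`` line per bead (Angstrom);
* PLUMED-dialect HILLS/COLVAR files — whitespace-separated columns under
  a ``#! FIELDS ...`` header line, field order preserved on write.

Analysis tables are tab-separated text with ``#``-prefixed provenance
headers (version, seed, parameters) so each output can be re-produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import BACKBONE, BeadTopology, BeadTrajectory
from .landscape import StateRegion, StateRegions
from .metad import FreeEnergySurface, HillsLog


class FormatError(ValueError):
    """A file failed to parse in any supported dialect."""


# ---------------------------------------------------------------------------
# PDB / GRO structures


_CHAIN_IDS = "AB"


def write_pdb(path, traj: BeadTrajectory, title: str | None = None) -> None:
    """Fixed-column PDB writer; multi-frame input becomes MODEL records."""
    top = traj.topology
    lines = []
    if title:
        lines.append(f"TITLE     {title}")
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:>4d}")
        serial = 1
        for h in (0, 1):
            idx = np.flatnonzero(top.helix == h)
            for i in idx:
                x, y, z = traj.coords[f, i]
                name = str(top.role[i])
                lines.append(
                    f"ATOM  {serial:>5d} {name:<4s}{'HLX':>4s} {_CHAIN_IDS[h]}"
                    f"{int(top.resid[i]):>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _topology_from_universe(u) -> BeadTopology:
    atoms = u.atoms
    try:
        chains = atoms.chainIDs
    except Exception:
        chains = None
    if chains is not None and len(set(chains)) == 2:
        order = sorted(set(chains))
        helix = np.array([order.index(c) for c in chains])
    elif len(u.segments) == 2:
        segs = list(u.segments)
        helix = np.array([segs.index(a.segment) for a in atoms])
    else:
        # single chain: split where the residue numbering restarts
        resids = atoms.resids
        drops = np.flatnonzero(np.diff(resids) < 0)
        if len(drops) != 1:
            raise FormatError(
                "two helices required: cannot identify two chains/segments "
                "or a single residue-numbering restart"
            )
        helix = np.zeros(len(resids), dtype=int)
        helix[drops[0] + 1 :] = 1
    role = np.array([BACKBONE if n.upper().startswith("BB") else "SC" for n in atoms.names])
    return BeadTopology(np.asarray(atoms.resids, dtype=int), helix, role)


def read_structure(path) -> BeadTrajectory:
    """Read a PDB/GRO coordinate file into a single-frame bead trajectory.

    Beads keep 1-based residue numbers; helix membership comes from the
    chain/segment labels (or a residue-numbering restart for single-chain
    files); bead role is ``BB`` for atoms named ``BB*``, else ``SC``.
    Coordinates are returned in Angstrom.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except FormatError:
            raise
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            raise FormatError(f"{path}: unparseable structure file: {exc}") from exc
    top = _topology_from_universe(u)
    coords = np.array(u.atoms.positions, dtype=float)
    return BeadTrajectory(coords[None], top)


# ---------------------------------------------------------------------------
# trajectories


TRAJ_MAGIC = "# tmdimer trajectory v1"


def write_trajectory_text(path, traj: BeadTrajectory) -> None:
    """Write the plain-text fallback trajectory format."""
    with open(path, "w") as fh:
        fh.write(TRAJ_MAGIC + "\n")
        fh.write(f"# n_beads={traj.n_beads}\n")
        for f in range(traj.n_frames):
            fh.write(f"FRAME {f} time={traj.times[f]:g}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def read_trajectory_text(path, topology: BeadTopology | None = None) -> BeadTrajectory:
    """Read the fallback format; a truncated final frame is dropped with a
    warning, and a mid-file bead-count mismatch is an error naming the frame."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != TRAJ_MAGIC:
        raise FormatError(f"{path}: line 1: missing '{TRAJ_MAGIC}' header")
    n_beads = None
    for ln in lines[1:3]:
        if ln.startswith("# n_beads="):
            n_beads = int(ln.split("=", 1)[1])
    if n_beads is None:
        raise FormatError(f"{path}: line 2: missing '# n_beads=' header")
    frames, times = [], []
    i = 2
    n_lines = len(lines)
    frame_no = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("FRAME"):
            raise FormatError(f"{path}: line {i + 1}: expected FRAME record")
        parts = line.split()
        t = float(parts[2].split("=", 1)[1]) if len(parts) > 2 else float(frame_no)
        block = lines[i + 1 : i + 1 + n_beads]
        if len(block) < n_beads:
            # file ended early: drop the truncated final frame
            warnings.warn(
                f"{path}: truncated final frame {frame_no} dropped",
                UserWarning,
                stacklevel=2,
            )
            break
        if any(b.startswith("FRAME") for b in block):
            raise FormatError(
                f"{path}: frame {frame_no}: fewer than {n_beads} beads before "
                "the next FRAME record"
            )
        try:
            coords = np.array([[float(v) for v in b.split()] for b in block])
            if coords.shape != (n_beads, 3):
                raise ValueError
        except ValueError:
            raise FormatError(
                f"{path}: frame {frame_no}: expected {n_beads} 'x y z' lines"
            ) from None
        frames.append(coords)
        times.append(t)
        frame_no += 1
        i += 1 + n_beads
    if not frames:
        raise FormatError(f"{path}: no complete frames")
    if topology is None:
        topology = BeadTopology(
            np.arange(1, n_beads + 1), np.zeros(n_beads, dtype=int),
            np.array([BACKBONE] * n_beads),
        )
    if topology.n_beads != n_beads:
        raise FormatError(
            f"{path}: file has {n_beads} beads but topology has {topology.n_beads}"
        )
    return BeadTrajectory(np.array(frames), topology, np.array(times))


def read_trajectory(path, topology_path=None) -> BeadTrajectory:
    """Read a trajectory in any supported dialect.

    Plain-text fallback files are detected by their magic header; anything
    else goes through MDAnalysis (multi-model PDB, or a coordinate file
    plus trajectory stream when ``topology_path`` is given).
    """
    path = Path(path)
    with open(path, "r", errors="replace") as fh:
        first = fh.readline().strip()
    if first == TRAJ_MAGIC:
        topo = None
        if topology_path is not None:
            topo = read_structure(topology_path).topology
        return read_trajectory_text(path, topo)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology_path is not None:
                u = mda.Universe(str(topology_path), str(path))
            else:
                u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"{path}: unparseable trajectory: {exc}") from exc
        top = _topology_from_universe(u)
        coords, times = [], []
        for ts in u.trajectory:
            coords.append(np.array(ts.positions, dtype=float))
            times.append(float(ts.time))
    return BeadTrajectory(np.array(coords), top, np.array(times))


# ---------------------------------------------------------------------------
# PLUMED-dialect files


def _read_plumed(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#! FIELDS"):
        raise FormatError(f"{path}: line 1: missing '#! FIELDS' header")
    names = header.split()[2:]
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != len(names):
        raise FormatError(
            f"{path}: {data.shape[1]} columns but {len(names)} FIELDS names"
        )
    return pd.DataFrame(data, columns=names)


def _write_plumed(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt="%.9g")


def write_hills(path, log: HillsLog, cv_name: str = "d") -> None:
    """Write a HILLS file: time, center, sigma, height, biasf columns."""
    df = pd.DataFrame(
        {
            "time": log.time,
            cv_name: log.center,
            f"sigma_{cv_name}": log.sigma,
            "height": log.height,
            "biasf": np.full(log.n_hills, log.bias_factor),
        }
    )
    _write_plumed(path, df)


def read_hills(path, temperature: float = 310.0) -> HillsLog:
    """Read a PLUMED-dialect HILLS file.

    Column conventions: first column ``time``, then the CV center, then
    ``sigma_*`` (width), ``height`` and ``biasf``.  The simulation
    temperature is not stored in the file and must be supplied.
    """
    df = _read_plumed(path)
    cols = list(df.columns)
    required = {"time", "height", "biasf"}
    if not required <= set(cols):
        raise FormatError(f"{path}: HILLS file needs columns {sorted(required)}")
    sigma_cols = [c for c in cols if c.startswith("sigma_")]
    cv_cols = [c for c in cols if c not in required and not c.startswith("sigma_")]
    if len(sigma_cols) != 1 or len(cv_cols) != 1:
        raise FormatError(f"{path}: expected exactly one CV and one sigma column")
    return HillsLog(
        time=df["time"].to_numpy(),
        center=df[cv_cols[0]].to_numpy(),
        sigma=df[sigma_cols[0]].to_numpy(),
        height=df["height"].to_numpy(),
        bias_factor=float(df["biasf"].iloc[0]),
        temperature=temperature,
    )


def write_colvar(path, times: np.ndarray, series: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"time": times, **series})
    _write_plumed(path, df)


def read_colvar(path) -> pd.DataFrame:
    return _read_plumed(path)


# ---------------------------------------------------------------------------
# tables, FES, regions


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Tab-separated table with '#' provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# tmdimer v{__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fes(path, fes: FreeEnergySurface, cv_name: str = "d",
              meta: dict | None = None) -> None:
    df = pd.DataFrame({cv_name: fes.grid, "free_energy_kJ_mol": fes.values})
    meta = dict(meta or {})
    meta.setdefault("temperature_K", fes.temperature)
    meta.setdefault("zero_convention", fes.zero_convention)
    write_table(path, df, meta)


def read_fes(path, temperature: float = 310.0) -> FreeEnergySurface:
    df = read_table(path)
    return FreeEnergySurface(
        grid=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy(),
        temperature=temperature,
    )


def write_density_map(path, dmap, meta: dict | None = None) -> None:
    """Gridded density as long-format TSV (x, y, density)."""
    xx, yy = np.meshgrid(dmap.x, dmap.y, indexing="ij")
    df = pd.DataFrame(
        {dmap.x_name: xx.ravel(), dmap.y_name: yy.ravel(), "density": dmap.density.ravel()}
    )
    meta = dict(meta or {})
    meta.setdefault("bandwidth", f"{dmap.bandwidth[0]:.6g},{dmap.bandwidth[1]:.6g}")
    meta.setdefault("n_samples", dmap.n_samples)
    write_table(path, df, meta)


def read_regions(path) -> StateRegions:
    """State regions from a key-value text config.

    One region per non-comment line:
    ``name x_axis y_axis xlo xhi ylo yhi [priority]``.
    """
    regions = []
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (7, 8):
            raise FormatError(f"{path}: line {ln_no}: expected 7 or 8 fields")
        name, xa, ya = parts[:3]
        try:
            xlo, xhi, ylo, yhi = (float(v) for v in parts[3:7])
            prio = int(parts[7]) if len(parts) == 8 else len(regions)
        except ValueError:
            raise FormatError(f"{path}: line {ln_no}: malformed bounds") from None
        regions.append(StateRegion(name, xa, ya, (xlo, xhi), (ylo, yhi), prio))
    return StateRegions(regions)


def write_regions(path, regions: StateRegions) -> None:
    lines = ["# name x_axis y_axis xlo xhi ylo yhi priority"]
    for r in regions:
        lines.append(
            f"{r.name} {r.x_axis} {r.y_axis} {r.x_bounds[0]:g} {r.x_bounds[1]:g} "
            f"{r.y_bounds[0]:g} {r.y_bounds[1]:g} {r.priority}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
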